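"""Seeded synthetic crop scenes: NDVI cubes, label maps, field objects.

The generator emulates the statistical structure an NDVI time-series
classification study assumes: a scene tiled into large rectangular
fields, one crop per field, ~15-day acquisition calendars over the
growing season, a per-field random offset (fields of the same crop differ
systematically) plus independent per-pixel noise, and disjoint
train/validation pixel pools drawn per class.

Randomness is driven by a single integer seed through a documented
``SeedSequence`` hierarchy: field-crop assignment, each field's offset,
and each field's pixel noise get independent substreams keyed by purpose
and field id, so enlarging the grid does not reshuffle unrelated draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .phenology import PhenologyProfile, evaluate_profile, preset_profiles, PRESETS

__all__ = [
    "SceneConfig",
    "NDVICube",
    "LabelMap",
    "ObjectMap",
    "SamplePool",
    "generate_scene",
    "split_pool",
    "generate_paired_sensor",
    "preset_config",
    "DEFAULT_DOYS",
]

# stream tags for the SeedSequence hierarchy
_STREAM_ASSIGN = 0
_STREAM_FIELD = 1
_STREAM_PIXEL = 2

#: default acquisition calendar: 14 dates, DOY 95-300 at ~15-day intervals,
#: emulating a merged two-sensor series over the growing season.
DEFAULT_DOYS: tuple[int, ...] = tuple(
    int(round(d)) for d in np.linspace(95, 300, 14)
)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic scene."""

    class_profiles: tuple[PhenologyProfile, ...]
    class_proportions: tuple[float, ...]
    acquisition_doys: tuple[int, ...] = DEFAULT_DOYS
    grid_height: int = 96
    grid_width: int = 96
    field_height: int = 8
    field_width: int = 8
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.class_proportions, float)
        if len(props) != len(self.class_profiles):
            raise ValueError("class_proportions and class_profiles length mismatch")
        if np.any(props <= 0):
            raise ValueError("class proportions must all be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {props.sum()}, not 1")
        doys = np.asarray(self.acquisition_doys)
        if np.any(np.diff(doys) <= 0):
            raise ValueError("acquisition_doys must be strictly increasing")
        if self.grid_height % self.field_height or self.grid_width % self.field_width:
            raise ValueError("field dimensions must divide grid dimensions")

    @property
    def n_fields(self) -> int:
        return (self.grid_height // self.field_height) * (self.grid_width // self.field_width)

    @property
    def n_classes(self) -> int:
        return len(self.class_profiles)


@dataclass
class NDVICube:
    """Per-pixel NDVI across ordered acquisition dates (the feature table).

    ``values`` has one row per pixel and one column per acquisition date.
    """

    values: np.ndarray
    doys: np.ndarray
    pixel_coords: np.ndarray  # (n_pixels, 2) row/col in the scene grid

    def __post_init__(self):
        if self.values.shape[1] != len(self.doys):
            raise ValueError("column count must equal number of acquisition DOYs")
        if np.any(self.values < -1) or np.any(self.values > 1):
            raise ValueError("NDVI values outside [-1, 1]")


@dataclass
class LabelMap:
    """Per-pixel class index in {1..K} plus the K class names."""

    labels: np.ndarray
    class_names: list[str] = dc_field(default_factory=list)

    def __post_init__(self):
        k = len(self.class_names)
        if k and (self.labels.min() < 1 or self.labels.max() > k):
            raise ValueError("labels outside {1..K}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ObjectMap:
    """Per-pixel field-object id; pixels sharing an id form one object."""

    object_id: np.ndarray

    def __post_init__(self):
        if np.any(self.object_id < 0):
            raise ValueError("object ids must be nonnegative")


@dataclass
class SamplePool:
    """Disjoint training / validation pixel index pools."""

    train_indices: np.ndarray
    validation_indices: np.ndarray
    train_counts: dict[int, int]
    validation_counts: dict[int, int]

    def __post_init__(self):
        if np.intersect1d(self.train_indices, self.validation_indices).size:
            raise ValueError("train and validation pools overlap")


def _assign_field_crops(config: SceneConfig) -> np.ndarray:
    """Largest-remainder allocation of crops to fields, seeded permutation."""
    props = np.asarray(config.class_proportions, float)
    n_fields = config.n_fields
    expected = props * n_fields
    if np.any(expected < 1.0):
        bad = int(np.argmin(expected))
        raise ValueError(
            f"class {config.class_profiles[bad].crop_name!r} expects "
            f"{expected[bad]:.2f} fields (<1); enlarge the grid or proportions"
        )
    counts = np.floor(expected).astype(int)
    remainder = expected - counts
    short = n_fields - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    crops = np.repeat(np.arange(1, config.n_classes + 1), counts)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_ASSIGN)))
    return rng.permutation(crops)


def generate_scene(config: SceneConfig) -> tuple[NDVICube, LabelMap, ObjectMap]:
    """Generate a seeded scene: NDVI cube, crop labels, field objects.

    The scene is tiled into rectangular fields, each field assigned one
    crop according to ``class_proportions``.  Pixel NDVI at each date is
    the crop's mean curve plus a per-field offset (drawn once per field
    with sd ``field_sd``, clipped so the field's peak stays inside the
    crop's peak envelope) plus independent per-pixel Gaussian noise (sd
    ``pixel_sd``); results are clipped to [-1, 1].  Object ids coincide
    with field ids.  Fully reproducible from ``config.seed``.
    """
    doys = np.asarray(config.acquisition_doys, float)
    n_rows_f = config.grid_height // config.field_height
    n_cols_f = config.grid_width // config.field_width
    field_crop = _assign_field_crops(config)

    curves = np.stack([
        np.asarray(evaluate_profile(p, doys)) for p in config.class_profiles
    ])  # (K, T)

    n_pixels = config.grid_height * config.grid_width
    rows, cols = np.divmod(np.arange(n_pixels), config.grid_width)
    field_of_pixel = (rows // config.field_height) * n_cols_f + (cols // config.field_width)

    values = np.empty((n_pixels, len(doys)))
    labels = np.empty(n_pixels, dtype=np.int64)
    for fid in range(config.n_fields):
        crop = field_crop[fid]          # 1-based class index
        profile = config.class_profiles[crop - 1]
        mask = field_of_pixel == fid
        rng_f = np.random.default_rng(
            np.random.SeedSequence((config.seed, _STREAM_FIELD, fid)))
        offset = rng_f.normal(0.0, profile.field_sd) if profile.field_sd > 0 else 0.0
        # keep the field's seasonal maximum inside the crop's peak envelope
        lo = profile.peak_ndvi_low - profile.peak_ndvi
        hi = profile.peak_ndvi_high - profile.peak_ndvi
        offset = float(np.clip(offset, lo, hi))
        base = curves[crop - 1] + offset
        if profile.pixel_sd > 0:
            rng_p = np.random.default_rng(
                np.random.SeedSequence((config.seed, _STREAM_PIXEL, fid)))
            noise = rng_p.normal(0.0, profile.pixel_sd, size=(int(mask.sum()), len(doys)))
        else:
            noise = 0.0
        values[mask] = base + noise
        labels[mask] = crop

    np.clip(values, -1.0, 1.0, out=values)
    cube = NDVICube(values=values, doys=np.asarray(config.acquisition_doys),
                    pixel_coords=np.column_stack([rows, cols]))
    label_map = LabelMap(labels=labels,
                         class_names=[p.crop_name for p in config.class_profiles])
    return cube, label_map, ObjectMap(object_id=field_of_pixel)


def split_pool(labels: LabelMap, per_class_counts: dict[int, tuple[int, int]],
               seed: int) -> SamplePool:
    """Draw disjoint train/validation pixel pools with per-class sizes.

    Parameters
    ----------
    per_class_counts : dict
        ``{class_index: (n_train, n_validation)}``; sampling is uniform
        without replacement within each class, seeded.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    train_parts, val_parts = [], []
    train_counts, val_counts = {}, {}
    for cls in sorted(per_class_counts):
        n_tr, n_va = per_class_counts[cls]
        pix = np.flatnonzero(labels.labels == cls)
        if n_tr + n_va > pix.size:
            raise ValueError(
                f"class {cls}: requested {n_tr}+{n_va} pixels, only {pix.size} available")
        if n_va == 0:
            warnings.warn(f"class {cls} has an empty validation pool", stacklevel=2)
        chosen = rng.choice(pix, size=n_tr + n_va, replace=False)
        train_parts.append(np.sort(chosen[:n_tr]))
        val_parts.append(np.sort(chosen[n_tr:]))
        train_counts[cls], val_counts[cls] = n_tr, n_va
    return SamplePool(
        train_indices=np.concatenate(train_parts) if train_parts else np.empty(0, int),
        validation_indices=np.concatenate(val_parts) if val_parts else np.empty(0, int),
        train_counts=train_counts, validation_counts=val_counts)


def default_pool(labels: LabelMap, seed: int, train_frac: float = 0.5) -> SamplePool:
    """Split every class ~50/50 into train and validation pools."""
    counts = {}
    for cls in range(1, labels.n_classes + 1):
        n = int((labels.labels == cls).sum())
        n_tr = int(round(n * train_frac))
        counts[cls] = (n_tr, n - n_tr)
    return split_pool(labels, counts, seed)


def generate_paired_sensor(ndvi: np.ndarray, gain: float, offset: float,
                           noise_sd: float, seed: int) -> np.ndarray:
    """Simulate a second sensor's NDVI as a noisy affine image of the first.

    Returns ``gain*ndvi + offset + N(0, noise_sd)`` clipped to [-1, 1].
    Emulates the cross-sensor relationship between two co-registered
    30-m sensors whose NDVI agree up to a near-identity linear map.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ndvi = np.asarray(ndvi, float)
    out = gain * ndvi + offset
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
        out = out + rng.normal(0.0, noise_sd, size=ndvi.shape)
    return np.clip(out, -1.0, 1.0)


def preset_config(name: str, seed: int = 0, grid_height: int = 96,
                  grid_width: int = 96, field_height: int = 8,
                  field_width: int = 8) -> SceneConfig:
    """SceneConfig for a named site preset (``"bole6"`` or ``"manas5"``)."""
    return SceneConfig(
        class_profiles=tuple(preset_profiles(name)),
        class_proportions=tuple(PRESETS[name]["proportions"]),
        grid_height=grid_height, grid_width=grid_width,
        field_height=field_height, field_width=field_width, seed=seed)
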