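"""Crop phenology profiles: smooth seasonal NDVI curves over day-of-year.

Each crop is described by a :class:`PhenologyProfile` — an off-season
baseline NDVI, a green-up / peak / senescence calendar, and an envelope
``[peak_ndvi_low, peak_ndvi_high]`` for the seasonal maximum.  The mean
curve is a pair of logistic limbs joined at ``peak_doy``: the rising limb
spans 5%→95% of the amplitude between ``greenup_doy`` and ``peak_doy``
(and symmetrically for the falling limb), and both limbs are normalized so
the curve attains exactly the envelope midpoint at ``peak_doy``.  This
supports asymmetric green-up and senescence rates (spring maize loses
greenness faster than cotton) while keeping the curve smooth and unimodal
per season.  Double-season crops (winter wheat followed by a summer crop)
take the pointwise maximum of their two seasonal curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PhenologyProfile", "evaluate_profile", "preset_profiles", "PRESETS"]

# logistic argument at which the limb has covered 95% of its amplitude
_LOGIT95 = math.log(19.0)


@dataclass(frozen=True)
class PhenologyProfile:
    """Seasonal NDVI trajectory of one crop class.

    Parameters
    ----------
    crop_name : str
        Human-readable class label.
    base_ndvi : float
        Off-season (bare soil / stubble) NDVI.
    greenup_doy, peak_doy, senescence_doy : float
        Calendar of the season, days of year in [1, 366],
        strictly increasing.
    peak_ndvi_low, peak_ndvi_high : float
        Envelope of the seasonal NDVI maximum; the noise-free curve peaks
        at the midpoint, field-level offsets move individual fields within
        the envelope.
    field_sd : float
        Standard deviation (NDVI units) of the per-field additive offset.
    pixel_sd : float
        Standard deviation of independent per-pixel, per-date noise.
    second_season : PhenologyProfile, optional
        Nested profile for double-season classes; the curve is the
        pointwise maximum of the two seasonal curves.
    """

    crop_name: str
    base_ndvi: float
    greenup_doy: float
    peak_doy: float
    senescence_doy: float
    peak_ndvi_low: float
    peak_ndvi_high: float
    field_sd: float = 0.0
    pixel_sd: float = 0.0
    second_season: Optional["PhenologyProfile"] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_ndvi < self.peak_ndvi_low <= self.peak_ndvi_high <= 1.0):
            raise ValueError(
                f"{self.crop_name}: require 0 <= base_ndvi < peak_ndvi_low "
                f"<= peak_ndvi_high <= 1, got base={self.base_ndvi}, "
                f"envelope=[{self.peak_ndvi_low}, {self.peak_ndvi_high}]"
            )
        if not (self.greenup_doy < self.peak_doy < self.senescence_doy):
            raise ValueError(f"{self.crop_name}: require greenup < peak < senescence DOY")
        for d in (self.greenup_doy, self.peak_doy, self.senescence_doy):
            if not (1 <= d <= 366):
                raise ValueError(f"{self.crop_name}: DOY {d} outside [1, 366]")
        if self.field_sd < 0 or self.pixel_sd < 0:
            raise ValueError(f"{self.crop_name}: negative noise sd")

    @property
    def peak_ndvi(self) -> float:
        """Midpoint of the peak envelope — the noise-free seasonal maximum."""
        return 0.5 * (self.peak_ndvi_low + self.peak_ndvi_high)


def _single_season(profile: PhenologyProfile, doy: np.ndarray) -> np.ndarray:
    base = profile.base_ndvi
    amp = profile.peak_ndvi - base
    g, p, s = profile.greenup_doy, profile.peak_doy, profile.senescence_doy
    # rising limb: logistic centred mid green-up, 5%->95% over [g, p]
    r_up = 2.0 * _LOGIT95 / (p - g)
    up = 1.0 / (1.0 + np.exp(-r_up * (doy - 0.5 * (g + p))))
    up /= 1.0 / (1.0 + math.exp(-r_up * (p - 0.5 * (g + p))))  # == 1 at peak
    # falling limb, mirrored over [p, s]
    r_dn = 2.0 * _LOGIT95 / (s - p)
    dn = 1.0 / (1.0 + np.exp(-r_dn * (0.5 * (p + s) - doy)))
    dn /= 1.0 / (1.0 + math.exp(-r_dn * (0.5 * (p + s) - p)))
    curve = np.where(doy <= p, up, dn)
    return base + amp * np.minimum(curve, 1.0)


def evaluate_profile(profile: PhenologyProfile, doy) -> np.ndarray | float:
    """Noise-free mean NDVI of a crop at the given day(s) of year.

    Equals ``base_ndvi`` far outside the season, attains the peak-envelope
    midpoint exactly at ``peak_doy``, and for double-season profiles is the
    pointwise maximum of the two seasonal curves.

    Raises
    ------
    ValueError
        If any ``doy`` is outside [1, 366].
    """
    arr = np.asarray(doy, dtype=float)
    if np.any((arr < 1) | (arr > 366)):
        raise ValueError("doy outside [1, 366]")
    out = _single_season(profile, arr)
    if profile.second_season is not None:
        out = np.maximum(out, _single_season(profile.second_season, arr))
    if np.isscalar(doy) or arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Site presets.  Calendars and peak envelopes follow the seasonal behaviour
# of the Xinjiang oasis cropping systems: cotton peaks 0.7-0.9 near DOY 200;
# spring maize peaks like cotton but senesces faster (clearly lower by DOY
# 250); watermelon and tomato peak near DOY 200 at 0.6-0.7; grape holds high
# NDVI over DOY 170-270 with the widest spread (0.4-0.7); winter wheat is the
# only crop green before late June; the wheat-summer class regreens for a
# second, summer season.  Noise magnitudes are chosen so that the wheat
# classes are easy while cotton / grape / maize overlap appreciably in the
# Bole preset; the Manas preset is better separated.

def _cotton() -> PhenologyProfile:
    return PhenologyProfile("cotton", 0.12, 140, 200, 285, 0.70, 0.90,
                            field_sd=0.050, pixel_sd=0.035)


def _maize() -> PhenologyProfile:
    # similar peak to cotton but faster post-peak decline
    return PhenologyProfile("spring_maize", 0.12, 132, 196, 248, 0.70, 0.85,
                            field_sd=0.050, pixel_sd=0.035)


def _grape() -> PhenologyProfile:
    # high DOY 170-270, largest within-class variability
    return PhenologyProfile("grape", 0.14, 148, 212, 300, 0.42, 0.70,
                            field_sd=0.085, pixel_sd=0.040)


def _watermelon() -> PhenologyProfile:
    return PhenologyProfile("watermelon", 0.12, 146, 200, 262, 0.60, 0.70,
                            field_sd=0.035, pixel_sd=0.030)


def _tomato() -> PhenologyProfile:
    return PhenologyProfile("tomato", 0.12, 152, 204, 272, 0.60, 0.70,
                            field_sd=0.030, pixel_sd=0.030)


def _wheat() -> PhenologyProfile:
    # winter wheat: green early spring, harvested late June
    return PhenologyProfile("winter_wheat", 0.12, 75, 135, 178, 0.60, 0.78,
                            field_sd=0.035, pixel_sd=0.030)


def _wheat_summer() -> PhenologyProfile:
    second = PhenologyProfile("summer_crop", 0.12, 192, 236, 292, 0.55, 0.70,
                              field_sd=0.0, pixel_sd=0.0)
    return PhenologyProfile("wheat_summer", 0.12, 75, 135, 178, 0.60, 0.78,
                            field_sd=0.035, pixel_sd=0.030, second_season=second)


def preset_profiles(name: str) -> list[PhenologyProfile]:
    """Return the crop profiles of a named site preset.

    ``"bole6"`` — cotton, spring maize, grape, winter wheat, watermelon,
    wheat-summer (six classes, cotton/grape/maize confusable).
    ``"manas5"`` — cotton, spring maize, winter wheat, tomato, wheat-summer.
    """
    if name == "bole6":
        return [_cotton(), _maize(), _grape(), _wheat(), _watermelon(), _wheat_summer()]
    if name == "manas5":
        return [_cotton(), _maize(), _wheat(), _tomato(), _wheat_summer()]
    raise KeyError(f"unknown preset {name!r}; available: bole6, manas5")


#: class mixing proportions per preset, roughly matching the surveyed-field
#: shares of each site (cotton dominant).
PRESETS: dict[str, dict] = {
    "bole6": {
        "proportions": [0.46, 0.06, 0.13, 0.125, 0.13, 0.095],
    },
    "manas5": {
        "proportions": [0.44, 0.195, 0.17, 0.14, 0.055],
    },
}
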