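"""Uncertainty-weighted fusion of probabilistic classifiers.

This is the analytical core of the package.  Each base classifier emits a
per-pixel probability row p(x) = (p_1, …, p_K); its reliability at that
pixel is summarized by the α-quadratic entropy

    H(p) = (2^{2α} / n) · Σ_k p_k^α (1 − p_k)^α ,    α ∈ (0, 1],

with α = 0.5 and n = K by default, so H ∈ [0, 1]: H = 0 for a certain
(degenerate) prediction and H = 1 at the uniform distribution.  Two
hybrid strategies combine F classifiers:

* **M-voting** — each classifier casts one vote; a unique plurality class
  wins, and vote ties are resolved by the classifier with the least
  uncertainty among those proposing a tied-top class.
* **P-fusion** — per-class scores Σ_f w_f(x) p_f^k(x) with uncertainty
  weights; the default ``complement`` mode uses w_f = 1 − S_f(x)
  (low-uncertainty classifiers up-weighted), the ``literal`` mode uses
  w_f = S_f(x).  The fused label is the argmax, ties to the lowest class
  index.

Both strategies run at pixel level or at object level, where all
pixel-classifier pairs of a field object vote (or contribute their
weighted probabilities) and the object's label is broadcast to its
member pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifiers import ClassifierOutput
from .simulate import ObjectMap

__all__ = [
    "UncertaintyVector",
    "FusionConfig",
    "FusedLabels",
    "alpha_quadratic_entropy",
    "m_voting_pixel",
    "p_fusion_pixel",
    "fuse_object",
    "run_fusion",
]


@dataclass
class UncertaintyVector:
    """Per-pixel, per-classifier α-quadratic entropy values S_f(x)."""

    h: np.ndarray  # (F, n_pixels) in [0, 1]
    alpha: float = 0.5
    convention_n: int | None = None

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if np.any(self.h < -1e-12) or np.any(self.h > 1 + 1e-9):
            raise ValueError("uncertainty values outside [0, 1]")


@dataclass(frozen=True)
class FusionConfig:
    """Which hybrid to run and how."""

    strategy: str = "m_voting"       # m_voting | p_fusion
    level: str = "pixel"             # pixel | object
    weight_mode: str = "complement"  # complement | literal (P-fusion only)
    alpha: float = 0.5
    convention_n: int | None = None  # None -> number of classes K

    def __post_init__(self):
        if self.strategy not in ("m_voting", "p_fusion"):
            raise ValueError("strategy must be m_voting or p_fusion")
        if self.level not in ("pixel", "object"):
            raise ValueError("level must be pixel or object")
        if self.weight_mode not in ("complement", "literal"):
            raise ValueError("weight_mode must be complement or literal")


@dataclass
class FusedLabels:
    """Fused per-pixel labels plus tie-break provenance."""

    labels: np.ndarray
    tie_break_used: np.ndarray  # bool per pixel (M-voting vote ties)


def alpha_quadratic_entropy(p, alpha: float = 0.5, convention_n: int | None = None):
    """α-quadratic entropy of probability row(s).

    ``H = (2^{2α}/n) · Σ_k p_k^α (1−p_k)^α`` with n defaulting to the
    number of classes K, which normalizes H into [0, 1].  Smaller H means
    a more reliable classification.  Accepts a single K-vector or an
    (n_pixels, K) table; returns a scalar or a length-n_pixels array.
    """
    arr = np.asarray(p, float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if np.any(arr < -1e-9) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be valid probability distributions")
    n = arr.shape[1] if convention_n is None else convention_n
    if n < 1:
        raise ValueError("convention_n must be >= 1")
    q = np.clip(arr, 0.0, 1.0)
    h = (2.0 ** (2 * alpha) / n) * np.power(q * (1.0 - q), alpha).sum(axis=1)
    return float(h[0]) if single else h


def _entropy_stack(outputs: list[ClassifierOutput], config: FusionConfig) -> np.ndarray:
    return np.stack([
        alpha_quadratic_entropy(o.proba, config.alpha, config.convention_n)
        for o in outputs
    ])  # (F, n_pixels)


def m_voting_pixel(labels_fc: np.ndarray, uncertainties: np.ndarray) -> FusedLabels:
    """Majority vote across classifiers with least-uncertainty tie-break.

    Parameters
    ----------
    labels_fc : (F, n_pixels) int array of per-classifier labels in 1..K.
    uncertainties : (F, n_pixels) array of S_f(x).
    """
    labels_fc = np.asarray(labels_fc)
    uncertainties = np.asarray(uncertainties, float)
    if labels_fc.shape != uncertainties.shape:
        raise ValueError("labels and uncertainties shapes differ")
    F, n = labels_fc.shape
    K = int(labels_fc.max())
    votes = np.zeros((n, K), dtype=np.int64)
    for f in range(F):
        votes[np.arange(n), labels_fc[f] - 1] += 1
    top = votes.max(axis=1)
    n_top = (votes == top[:, None]).sum(axis=1)
    fused = np.argmax(votes, axis=1) + 1           # unique plurality winner
    tie = n_top > 1
    if np.any(tie):
        for i in np.flatnonzero(tie):
            tied_classes = np.flatnonzero(votes[i] == top[i]) + 1
            cand = np.isin(labels_fc[:, i], tied_classes)
            f_best = np.flatnonzero(cand)[np.argmin(uncertainties[cand, i])]
            fused[i] = labels_fc[f_best, i]
    return FusedLabels(labels=fused, tie_break_used=tie)


def _weights(uncertainties: np.ndarray, mode: str) -> np.ndarray:
    return 1.0 - uncertainties if mode == "complement" else uncertainties.copy()


def p_fusion_pixel(proba_fck: np.ndarray, uncertainties: np.ndarray,
                   weight_mode: str = "complement") -> FusedLabels:
    """Probabilistic fusion: argmax_k Σ_f w_f(x) p_f^k(x).

    Parameters
    ----------
    proba_fck : (F, n_pixels, K) per-classifier probability tables.
    uncertainties : (F, n_pixels) array of S_f(x).
    weight_mode : ``"complement"`` → w = 1 − S (default, up-weights
        low-uncertainty classifiers); ``"literal"`` → w = S.
    """
    proba_fck = np.asarray(proba_fck, float)
    uncertainties = np.asarray(uncertainties, float)
    w = _weights(uncertainties, weight_mode)       # (F, n_pixels)
    scores = np.einsum("fp,fpk->pk", w, proba_fck)
    zero = scores.sum(axis=1) == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} pixel(s) had all-zero fusion weights; "
            "falling back to the unweighted mean", stacklevel=2)
        scores[zero] = proba_fck[:, zero, :].mean(axis=0)
    labels = np.argmax(scores, axis=1) + 1
    return FusedLabels(labels=labels, tie_break_used=np.zeros(len(labels), bool))


def fuse_object(outputs: list[ClassifierOutput], objects: ObjectMap,
                config: FusionConfig,
                uncertainties: np.ndarray | None = None) -> FusedLabels:
    """Object-level fusion: pool pixel-classifier evidence per field object.

    M-voting: every pixel contributes F per-classifier votes; the object
    takes the unique-plurality class, ties resolved by the least-uncertain
    pixel-classifier pair among those proposing a tied-top class.
    P-fusion: object score per class is Σ_{x∈object} Σ_f w_f(x) p_f^k(x).
    The object label is broadcast to all member pixels.
    """
    if uncertainties is None:
        uncertainties = _entropy_stack(outputs, config)
    labels_fc = np.stack([o.labels for o in outputs])      # (F, n)
    obj = np.asarray(objects.object_id)
    n = labels_fc.shape[1]
    if obj.shape[0] != n:
        raise ValueError("object map does not cover the pixel set")
    K = outputs[0].n_classes
    fused = np.empty(n, dtype=np.int64)
    tie = np.zeros(n, dtype=bool)
    if config.strategy == "p_fusion":
        proba = np.stack([o.proba for o in outputs])       # (F, n, K)
        w = _weights(uncertainties, config.weight_mode)
        pixel_scores = np.einsum("fp,fpk->pk", w, proba)   # (n, K)
    for oid in np.unique(obj):
        members = np.flatnonzero(obj == oid)
        if members.size == 0:
            raise ValueError(f"empty object {oid}")
        if config.strategy == "m_voting":
            v = np.bincount(labels_fc[:, members].ravel() - 1, minlength=K)
            top = v.max()
            tied_classes = np.flatnonzero(v == top) + 1
            if len(tied_classes) == 1:
                label = int(tied_classes[0])
            else:
                sub_labels = labels_fc[:, members]            # (F, m)
                sub_unc = uncertainties[:, members]
                cand = np.isin(sub_labels, tied_classes)
                flat = np.flatnonzero(cand.ravel())
                best = flat[np.argmin(sub_unc.ravel()[flat])]
                label = int(sub_labels.ravel()[best])
                tie[members] = True
        else:
            scores = pixel_scores[members].sum(axis=0)
            if scores.sum() == 0:
                warnings.warn(f"object {oid}: all-zero fusion weights; "
                              "falling back to the unweighted mean", stacklevel=2)
                scores = np.stack([o.proba[members] for o in outputs]).mean(axis=(0, 1))
            label = int(np.argmax(scores)) + 1
        fused[members] = label
    return FusedLabels(labels=fused, tie_break_used=tie)


def run_fusion(outputs: list[ClassifierOutput], config: FusionConfig,
               objects: ObjectMap | None = None) -> FusedLabels:
    """Compute uncertainties and dispatch to the configured hybrid.

    All classifier outputs must cover the same pixels; the result is
    deterministic and invariant to the order of ``outputs``.
    """
    if not outputs:
        raise ValueError("need at least one classifier output")
    n = len(outputs[0].labels)
    K = outputs[0].n_classes
    for o in outputs:
        if len(o.labels) != n or o.n_classes != K:
            raise ValueError("classifier outputs cover mismatched pixel/class sets")
    unc = _entropy_stack(outputs, config)
    if config.level == "object":
        if objects is None:
            raise ValueError("object-level fusion requires an ObjectMap")
        return fuse_object(outputs, objects, config, uncertainties=unc)
    if config.strategy == "m_voting":
        return m_voting_pixel(np.stack([o.labels for o in outputs]), unc)
    return p_fusion_pixel(np.stack([o.proba for o in outputs]), unc,
                          config.weight_mode)
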