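"""Accuracy assessment, McNemar comparison, and the training-size experiment.

Error-matrix metrics follow the standard remote-sensing accuracy
assessment: producer's accuracy (recall per reference class), user's
accuracy (precision per predicted class), overall accuracy, and the
kappa coefficient.  Pairwise classifier comparison uses McNemar's test
on the discordant correct/incorrect counts,

    Z = (f12 − f21) / sqrt(f12 + f21),

with categories S+ (Z > 1.96), S− (Z < −1.96) and N otherwise
(boundaries inclusive in N).  The experiment runner re-trains the three
base classifiers on seeded random training subsets of increasing size,
evaluates the three singles plus the four hybrids (2 strategies × 2
levels) on a fixed validation pool, aggregates mean ± SD over repeated
runs, and tallies McNemar categories per size group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, ClassifierOutput, train_and_predict, FAST_SVM_GRID
from .fusion import FusionConfig, run_fusion
from .simulate import NDVICube, LabelMap, ObjectMap, SamplePool

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "McNemarResult",
    "ExperimentResult",
    "error_matrix",
    "accuracy_metrics",
    "mcnemar",
    "run_experiment",
    "aggregate_mcnemar",
    "CONFIG_NAMES",
]

Z_CRIT = 1.96

#: the seven evaluated configurations: three singles, four hybrids
CONFIG_NAMES = (
    "rf", "svm", "c5",
    "mvote_pixel", "mvote_object", "pfusion_pixel", "pfusion_object",
)


@dataclass
class ErrorMatrix:
    """K×K confusion counts; rows = reference class, columns = predicted."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty error matrix")


@dataclass
class AccuracyReport:
    """PA/UA per class (%), OA (%), kappa.  Undefined marginals are NaN."""

    pa: np.ndarray
    ua: np.ndarray
    oa: float
    kappa: float


@dataclass
class McNemarResult:
    f12: int
    f21: int
    z: float
    category: str  # S+ | N | S-


@dataclass
class ExperimentResult:
    """All per-run records of a training-size experiment.

    ``records`` — one row per (config, size, run) with OA and per-class
    PA/UA; ``summary`` — mean and SD over runs per (config, size);
    ``predictions[(config, size, run)]`` — validation-pool labels;
    ``truth`` — validation-pool reference labels.
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    predictions: dict
    truth: np.ndarray
    sizes: list[int]
    runs: int


def error_matrix(pred, truth, n_classes: int, class_names=None) -> ErrorMatrix:
    """Confusion counts[i, j] = #{pixels with reference i+1, prediction j+1}."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty input")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (truth - 1, pred - 1), 1)
    return ErrorMatrix(counts=counts, class_names=list(class_names or []))


def accuracy_metrics(m: ErrorMatrix) -> AccuracyReport:
    """PA/UA/OA (percent) and kappa from an error matrix."""
    c = m.counts.astype(float)
    total = c.sum()
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    diag = np.diag(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(rows > 0, diag / rows, np.nan) * 100.0
        ua = np.where(cols > 0, diag / cols, np.nan) * 100.0
    oa = diag.sum() / total * 100.0
    p_o = diag.sum() / total
    p_e = (rows * cols).sum() / total ** 2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return AccuracyReport(pa=pa, ua=ua, oa=float(oa), kappa=float(kappa))


def mcnemar(pred1, pred2, truth) -> McNemarResult:
    """Paired significance of two classifiers on the same validation pixels.

    f12 counts pixels correct under classifier 1 but wrong under
    classifier 2 (f21 the reverse); Z = (f12 − f21)/sqrt(f12 + f21),
    defined as 0 when both discordant counts vanish.
    """
    pred1, pred2, truth = map(np.asarray, (pred1, pred2, truth))
    if not (pred1.shape == pred2.shape == truth.shape):
        raise ValueError("input lengths differ")
    ok1 = pred1 == truth
    ok2 = pred2 == truth
    f12 = int(np.sum(ok1 & ~ok2))
    f21 = int(np.sum(~ok1 & ok2))
    z = 0.0 if f12 + f21 == 0 else (f12 - f21) / np.sqrt(f12 + f21)
    if z > Z_CRIT:
        cat = "S+"
    elif z < -Z_CRIT:
        cat = "S-"
    else:
        cat = "N"
    return McNemarResult(f12=f12, f21=f21, z=float(z), category=cat)


def _default_specs(seed: int, svm_grid: dict) -> dict[str, ClassifierSpec]:
    return {
        "rf": ClassifierSpec("random_forest", seed=seed),
        "svm": ClassifierSpec("svm_rbf", {"grid": svm_grid}, seed=seed),
        "c5": ClassifierSpec("boosted_tree", seed=seed),
    }


def evaluate_all_configs(train_X, train_y, val_X, objects_val: ObjectMap,
                         n_classes: int, seed: int,
                         svm_grid: dict = FAST_SVM_GRID,
                         weight_mode: str = "complement") -> dict[str, np.ndarray]:
    """Train the three base classifiers once and label the validation pool
    under all seven configurations.  Returns {config_name: labels}."""
    specs = _default_specs(seed, svm_grid)
    outputs: dict[str, ClassifierOutput] = {
        name: train_and_predict(spec, train_X, train_y, val_X, n_classes=n_classes)
        for name, spec in specs.items()
    }
    triple = [outputs["rf"], outputs["svm"], outputs["c5"]]
    preds = {name: out.labels for name, out in outputs.items()}
    for strategy, tag in (("m_voting", "mvote"), ("p_fusion", "pfusion")):
        for level in ("pixel", "object"):
            cfg = FusionConfig(strategy=strategy, level=level, weight_mode=weight_mode)
            fused = run_fusion(triple, cfg, objects=objects_val if level == "object" else None)
            preds[f"{tag}_{level}"] = fused.labels
    return preds


def run_experiment(cube: NDVICube, labels: LabelMap, objects: ObjectMap,
                   pool: SamplePool, sizes: list[int], runs: int, seed: int,
                   svm_grid: dict = FAST_SVM_GRID, stratified: bool = False,
                   weight_mode: str = "complement") -> ExperimentResult:
    """Training-size × repeats experiment over all seven configurations.

    For each size × run a seeded simple-random subset (without
    replacement; optionally stratified by class) of the training pool is
    drawn, the three base classifiers are trained, and the three singles
    plus four hybrids are evaluated on the fixed validation pool.  Runs
    use independent substreams derived from ``seed``; results are fully
    reproducible.
    """
    sizes = sorted(int(s) for s in sizes)
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if max(sizes) > len(pool.train_indices):
        raise ValueError(
            f"largest size {max(sizes)} exceeds training pool {len(pool.train_indices)}")
    val_idx = pool.validation_indices
    truth = labels.labels[val_idx]
    val_X = cube.values[val_idx]
    objects_val = ObjectMap(object_id=objects.object_id[val_idx])
    K = labels.n_classes

    rows = []
    predictions: dict = {}
    for si, size in enumerate(sizes):
        for run in range(runs):
            sub_seed = int(np.random.SeedSequence((seed, si, run)).generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(sub_seed)
            train_idx = _draw_training(pool, labels, size, rng, stratified)
            train_X = cube.values[train_idx]
            train_y = labels.labels[train_idx]
            preds = evaluate_all_configs(train_X, train_y, val_X, objects_val,
                                         K, sub_seed, svm_grid, weight_mode)
            for name, p in preds.items():
                rep = accuracy_metrics(error_matrix(p, truth, K, labels.class_names))
                row = {"config": name, "size": size, "run": run,
                       "oa": rep.oa, "kappa": rep.kappa}
                for k in range(K):
                    row[f"pa_{k + 1}"] = rep.pa[k]
                    row[f"ua_{k + 1}"] = rep.ua[k]
                rows.append(row)
                predictions[(name, size, run)] = p
    records = pd.DataFrame(rows)
    summary = (records.drop(columns="run")
               .groupby(["config", "size"], sort=True)
               .agg(["mean", "std"]))
    summary.columns = [f"{a}_{b}" for a, b in summary.columns]
    summary = summary.reset_index()
    return ExperimentResult(records=records, summary=summary,
                            predictions=predictions, truth=truth,
                            sizes=sizes, runs=runs)


def _draw_training(pool: SamplePool, labels: LabelMap, size: int,
                   rng: np.random.Generator, stratified: bool) -> np.ndarray:
    if not stratified:
        return rng.choice(pool.train_indices, size=size, replace=False)
    # proportional stratified draw (largest-remainder rounding)
    idx = pool.train_indices
    y = labels.labels[idx]
    classes = np.unique(y)
    fracs = np.array([(y == c).sum() for c in classes]) / len(y)
    alloc = np.floor(fracs * size).astype(int)
    rem = fracs * size - alloc
    for j in np.argsort(-rem)[: size - alloc.sum()]:
        alloc[j] += 1
    parts = [rng.choice(idx[y == c], size=a, replace=False)
             for c, a in zip(classes, alloc) if a > 0]
    return np.concatenate(parts)


def aggregate_mcnemar(result: ExperimentResult,
                      groups: dict[str, list[int]] | None = None) -> pd.DataFrame:
    """Tally McNemar categories per ordered config pair and size group.

    ``groups`` maps a group name to the training sizes it contains
    (default: one group per size).  Each (pair, group) tally sums to
    group sizes × runs.
    """
    if groups is None:
        groups = {str(s): [s] for s in result.sizes}
    for gname, gsizes in groups.items():
        missing = set(gsizes) - set(result.sizes)
        if missing:
            raise ValueError(f"group {gname!r} references sizes {sorted(missing)} "
                             "not in the experiment")
    rows = []
    for c1, c2 in itertools.permutations(CONFIG_NAMES, 2):
        for gname, gsizes in groups.items():
            tally = {"S+": 0, "N": 0, "S-": 0}
            for size in gsizes:
                for run in range(result.runs):
                    res = mcnemar(result.predictions[(c1, size, run)],
                                  result.predictions[(c2, size, run)],
                                  result.truth)
                    tally[res.category] += 1
            rows.append({"classifier_1": c1, "classifier_2": c2, "group": gname,
                         "s_plus": tally["S+"], "n": tally["N"],
                         "s_minus": tally["S-"]})
    return pd.DataFrame(rows)
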