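"""Experiment engine: splits, learning curves, SML-vs-generic and Δ-ML.

The selected-ML (SML) protocol compares two training-set selections on
identical test molecules. For each structural class a fixed test set is put
aside; "generic" models draw training molecules uniformly from the whole
remaining pool, "selected" models draw only within the class. Both predict
the same class test set, so their errors are directly comparable. Learning
curves (MAE versus training-set size) are averaged over repeated draws, and
their log–log line fits expose the characteristic "same slope, lower
offset" signature of a successful partition.

Δ-ML trains on the difference between two levels of theory and adds the
predicted correction back onto the baseline values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import manhattan_distances

from .chemdata import Dataset
from .classify import ClassLabel, classify_smiles
from .krr import (
    DEFAULT_LAMBDA,
    HyperGrid,
    KernelModel,
    _solve_kernel_system,
    as_matrix,
    krr_predict,
    krr_train,
    mae,
    select_sigma_from_distances,
)
from .represent import RepresentationConfig, representation_matrix

__all__ = [
    "SplitSpec",
    "RepetitionSplit",
    "LearningCurve",
    "DeltaSpec",
    "make_splits",
    "run_learning_curve",
    "run_sml_comparison",
    "delta_train",
    "delta_predict",
    "fit_loglog",
    "scatter_table",
]


@dataclass(frozen=True)
class SplitSpec:
    """Training sizes, per-class test size, repetition count and seed."""

    train_sizes: tuple[int, ...]
    test_size_per_class: int = 200
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(self.train_sizes)
        if len(sizes) == 0 or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("train sizes must be a non-empty strictly increasing list")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.test_size_per_class < 1:
            raise ValueError("test sets must be non-empty")
        object.__setattr__(self, "train_sizes", sizes)


@dataclass
class RepetitionSplit:
    """One repetition's draws: class test sets plus nested training pools."""

    test: dict[ClassLabel, list[str]]
    generic: dict[int, list[str]]                       # size -> ids
    selected: dict[ClassLabel, dict[int, list[str]]]    # class -> size -> ids


@dataclass
class LearningCurve:
    """MAE statistics over repetitions at each training-set size."""

    sizes: list[int]
    mae_mean: list[float]
    mae_sd: list[float]
    label: str = ""
    selection: str = "generic"          # "generic" | "selected"
    class_id: Union[ClassLabel, str] = "all"

    def __post_init__(self) -> None:
        if not (len(self.sizes) == len(self.mae_mean) == len(self.mae_sd)):
            raise ValueError("sizes and MAE statistics must have equal lengths")
        if any(m < 0 for m in self.mae_mean):
            raise ValueError("MAE cannot be negative")


@dataclass(frozen=True)
class DeltaSpec:
    """Baseline and target levels of theory for Δ-ML."""

    baseline_level: str
    target_level: str

    def __post_init__(self) -> None:
        if self.baseline_level == self.target_level:
            raise ValueError("baseline and target levels must differ")


def make_splits(
    pool: Sequence[str],
    spec: SplitSpec,
    class_map: dict[str, ClassLabel],
) -> list[RepetitionSplit]:
    """Draw per-repetition test sets and nested training sets.

    Per repetition (seeded ``spec.seed + rep``): one test set per class,
    disjoint from every training draw of that repetition; generic training
    sets sampled uniformly from the whole pool minus all test molecules;
    selected training sets sampled within each class's remainder. Training
    sets are nested across sizes (smaller ⊂ larger).
    """
    pool = list(pool)
    classes = [c for c in ClassLabel if any(class_map[i] == c for i in pool)]
    max_size = max(spec.train_sizes)
    by_class = {c: [i for i in pool if class_map[i] == c] for c in classes}
    for c, ids in by_class.items():
        need = spec.test_size_per_class + max_size
        if len(ids) < need:
            raise ValueError(
                f"class {c.short} has {len(ids)} molecules but needs "
                f"{need} (test {spec.test_size_per_class} + train {max_size})"
            )
    if len(pool) - len(classes) * spec.test_size_per_class < max_size:
        raise ValueError(
            f"pool of {len(pool)} cannot supply {max_size} generic training "
            f"molecules after holding out {len(classes)} test sets"
        )

    out = []
    for rep in range(spec.repetitions):
        rng = np.random.default_rng(spec.seed + rep)
        test: dict[ClassLabel, list[str]] = {}
        remainder: dict[ClassLabel, list[str]] = {}
        for c in classes:
            perm = list(rng.permutation(by_class[c]))
            test[c] = perm[: spec.test_size_per_class]
            remainder[c] = perm[spec.test_size_per_class:]
        generic_pool = list(rng.permutation([i for ids in remainder.values() for i in ids]))
        generic = {n: generic_pool[:n] for n in spec.train_sizes}
        selected = {}
        for c in classes:
            perm = list(rng.permutation(remainder[c]))
            selected[c] = {n: perm[:n] for n in spec.train_sizes}
        out.append(RepetitionSplit(test=test, generic=generic, selected=selected))
    return out


def _default_class_map(dataset: Dataset) -> dict[str, ClassLabel]:
    return {m.id: classify_smiles(m.smiles) for m in dataset.molecules}


def _experiment(
    dataset: Dataset,
    rep_config: Optional[RepresentationConfig],
    splits: list[RepetitionSplit],
    label: tuple[str, str],
    modes: Sequence[str],
    grid: Optional[HyperGrid],
    lam: float,
    representations: Optional[np.ndarray],
) -> dict[str, dict[ClassLabel, np.ndarray]]:
    """Shared engine. Returns mode -> class -> (n_sizes, n_reps) MAE array.

    σ is re-selected by CV inside every training set; the full pairwise L1
    distance matrix is computed once and sliced per cell.
    """
    prop, level = label
    grid = grid or HyperGrid()
    ids = dataset.ids
    pos = {mid: i for i, mid in enumerate(ids)}
    if representations is None:
        X, _ = representation_matrix(dataset, config=rep_config)
    else:
        X = as_matrix(representations)
    y = dataset.values(prop, level)
    D = manhattan_distances(X, X)

    classes = list(splits[0].test.keys())
    sizes = sorted(splits[0].generic.keys())
    results = {
        mode: {c: np.empty((len(sizes), len(splits))) for c in classes}
        for mode in modes
    }

    def cell_mae(train_ids: list[str], test_ids: list[str]) -> float:
        tr = np.array([pos[i] for i in train_ids])
        te = np.array([pos[i] for i in test_ids])
        Dtr = D[np.ix_(tr, tr)]
        sigma = select_sigma_from_distances(Dtr, y[tr], grid, lam)
        alpha = _solve_kernel_system(np.exp(-Dtr / sigma), y[tr], lam)
        pred = np.exp(-D[np.ix_(te, tr)] / sigma) @ alpha
        return mae(pred, y[te])

    for r, split in enumerate(splits):
        for s, n in enumerate(sizes):
            if "generic" in modes:
                # one generic model per size, evaluated on every class test set
                tr = np.array([pos[i] for i in split.generic[n]])
                Dtr = D[np.ix_(tr, tr)]
                sigma = select_sigma_from_distances(Dtr, y[tr], grid, lam)
                alpha = _solve_kernel_system(np.exp(-Dtr / sigma), y[tr], lam)
                for c in classes:
                    te = np.array([pos[i] for i in split.test[c]])
                    pred = np.exp(-D[np.ix_(te, tr)] / sigma) @ alpha
                    results["generic"][c][s, r] = mae(pred, y[te])
            if "selected" in modes:
                for c in classes:
                    results["selected"][c][s, r] = cell_mae(
                        split.selected[c][n], split.test[c]
                    )
    return results


def _curve(maes: np.ndarray, sizes: list[int], label: str, selection: str,
           class_id) -> LearningCurve:
    return LearningCurve(
        sizes=list(sizes),
        mae_mean=[float(m) for m in maes.mean(axis=1)],
        mae_sd=[float(s) for s in maes.std(axis=1, ddof=1 if maes.shape[1] > 1 else 0)],
        label=label, selection=selection, class_id=class_id,
    )


def run_learning_curve(
    dataset: Dataset,
    rep_config: Optional[RepresentationConfig],
    splits: list[RepetitionSplit],
    label: tuple[str, str],
    selection: str = "generic",
    grid: Optional[HyperGrid] = None,
    lam: float = DEFAULT_LAMBDA,
    representations: Optional[np.ndarray] = None,
) -> LearningCurve:
    """One learning curve, pooled over all class test sets.

    ``label`` is (property, level), e.g. ("gap", "B3LYP"). With
    ``selection="selected"`` each class test set is predicted by its own
    class model; the per-class MAEs are averaged with equal class weights
    (test sets have equal size, so this is the pooled MAE).
    """
    if selection not in ("generic", "selected"):
        raise ValueError(f"unknown selection mode {selection!r}")
    res = _experiment(dataset, rep_config, splits, label, [selection], grid, lam,
                      representations)
    per_class = np.stack(list(res[selection].values()))  # (class, size, rep)
    pooled = per_class.mean(axis=0)
    return _curve(pooled, sorted(splits[0].generic.keys()),
                  f"{label[0]}@{label[1]}", selection, "all")


def run_sml_comparison(
    dataset: Dataset,
    rep_config: Optional[RepresentationConfig],
    spec: SplitSpec,
    label: tuple[str, str],
    grid: Optional[HyperGrid] = None,
    lam: float = DEFAULT_LAMBDA,
    class_map: Optional[dict[str, ClassLabel]] = None,
    representations: Optional[np.ndarray] = None,
) -> dict[ClassLabel, tuple[LearningCurve, LearningCurve]]:
    """Per class, the (generic, selected) learning-curve pair on shared tests.

    The generic model is trained on draws from the whole pool, the selected
    model on draws from the class alone; both are evaluated on the identical
    class test set in every repetition.
    """
    class_map = class_map or _default_class_map(dataset)
    splits = make_splits(dataset.ids, spec, class_map)
    res = _experiment(dataset, rep_config, splits, label,
                      ["generic", "selected"], grid, lam, representations)
    sizes = sorted(splits[0].generic.keys())
    name = f"{label[0]}@{label[1]}"
    return {
        c: (
            _curve(res["generic"][c], sizes, name, "generic", c),
            _curve(res["selected"][c], sizes, name, "selected", c),
        )
        for c in res["generic"]
    }


# ---------------------------------------------------------------------------
# Δ-ML
# ---------------------------------------------------------------------------

def delta_train(
    dataset: Dataset,
    rep_config: Optional[RepresentationConfig],
    train_ids: Sequence[str],
    spec: DeltaSpec,
    sigma_policy: Union[float, HyperGrid],
    prop: str = "gap",
    lam: float = DEFAULT_LAMBDA,
    representations: Optional[np.ndarray] = None,
) -> KernelModel:
    """Train a KRR model of the target-minus-baseline correction.

    ``sigma_policy`` is either a fixed width or a :class:`HyperGrid` for CV
    selection on the difference labels.
    """
    levels = dataset.levels()
    for lvl in (spec.baseline_level, spec.target_level):
        if lvl not in levels:
            raise ValueError(f"level {lvl!r} not present in dataset (has {levels})")
    if representations is None:
        X_all, _ = representation_matrix(dataset, config=rep_config)
    else:
        X_all = as_matrix(representations)
    pos = {mid: i for i, mid in enumerate(dataset.ids)}
    idx = np.array([pos[i] for i in train_ids])
    try:
        yb = dataset.values(prop, spec.baseline_level, train_ids)
        yt = dataset.values(prop, spec.target_level, train_ids)
    except KeyError as exc:
        raise ValueError(f"missing level data for a training molecule: {exc}") from exc
    diff = yt - yb
    X = X_all[idx]
    if isinstance(sigma_policy, HyperGrid):
        D = manhattan_distances(X, X)
        sigma = select_sigma_from_distances(D, diff, sigma_policy, lam)
    else:
        sigma = float(sigma_policy)
    return krr_train(X, diff, sigma, lam,
                     label=f"Δ{prop}:{spec.target_level}-{spec.baseline_level}")


def delta_predict(
    model: KernelModel, X_test, baseline_values
) -> np.ndarray:
    """Target-level estimates: baseline value + predicted correction."""
    base = np.asarray(baseline_values, dtype=float).ravel()
    if not np.all(np.isfinite(base)):
        raise ValueError("missing or non-finite baseline value for a test molecule")
    corr = krr_predict(model, X_test)
    if len(base) != len(corr):
        raise ValueError(f"{len(base)} baseline values for {len(corr)} test molecules")
    return base + corr


# ---------------------------------------------------------------------------
# Log–log curve fitting and scatter export
# ---------------------------------------------------------------------------

def fit_loglog(curve: LearningCurve) -> tuple[float, float]:
    """Least-squares line log10(MAE) = offset + slope·log10(N_tr)."""
    if len(curve.sizes) < 2:
        raise ValueError("need at least two sizes to fit a learning curve")
    m = np.asarray(curve.mae_mean, dtype=float)
    if np.any(m <= 0):
        raise ValueError("log-log fit requires strictly positive MAE")
    slope, offset = np.polyfit(np.log10(curve.sizes), np.log10(m), 1)
    return float(offset), float(slope)


def scatter_table(
    ids: Sequence[str],
    y_ref: Sequence[float],
    y_pred: Sequence[float],
    class_map: dict[str, ClassLabel],
    selection: str,
) -> pd.DataFrame:
    """Per-molecule predicted-vs-reference table with outlier flags.

    A molecule is flagged when its absolute error exceeds three times the
    MAE of its class.
    """
    df = pd.DataFrame({
        "id": list(ids),
        "y_ref": np.asarray(y_ref, dtype=float),
        "y_pred": np.asarray(y_pred, dtype=float),
        "class": [class_map[i].short for i in ids],
        "selection": selection,
    })
    df["abs_error"] = (df.y_pred - df.y_ref).abs()
    class_mae = df.groupby("class")["abs_error"].transform("mean")
    df["outlier"] = df.abs_error > 3 * class_mae
    return df
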