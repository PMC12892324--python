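"""Nested cross-validation with within-fold undersampling.

The outer training fold's inactives are split into nine disjoint,
size-balanced subsets; each subset is joined with the full set of fold
actives to form a roughly balanced training set.  Hyperparameters are
tuned per balanced subset in an inner 5-fold loop, the nine tuned models
vote on the untouched (imbalanced) validation fold, and per-fold modal
parameters feed the final retraining of a nine-member ensemble.

With ``n_subsets=1`` the same engine degenerates to the plain baseline
procedure (no undersampling) — a configuration, not separate code.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

ALGORITHMS = ("RF", "SVM", "XGB")

# Grids exactly as specified.  Dict values are listed in "simpler first"
# order, which doubles as the tie-break ordering for tuning and for modal
# parameter selection (fewer estimators, shallower finite depth before
# unlimited, smaller C, linear before rbf).
COMPLEXITY_ORDER: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [50, 100, 200], "max_depth": [10, 20, None]},
    "SVM": {"C": [0.1, 1, 10], "kernel": ["linear", "rbf"]},
    "XGB": {"n_estimators": [50, 100, 200], "max_depth": [3, 5, 7]},
}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [50, 100, 200], "max_depth": [None, 10, 20]},
    "SVM": {"C": [0.1, 1, 10], "kernel": ["linear", "rbf"]},
    "XGB": {"n_estimators": [50, 100, 200], "max_depth": [3, 5, 7]},
}


def build_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a classifier for one ensemble member.

    The gradient-boosted slot ("XGB") is backed by scikit-learn's
    GradientBoostingClassifier; the tuned parameters carry the same names
    and semantics.
    """
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "SVM":
        return SVC(random_state=seed, **params)
    if algorithm == "XGB":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def grid_combinations(algorithm: str, grid: dict[str, list] | None = None) -> list[dict]:
    """All parameter combinations, ordered simplest-first so that index-0
    ties resolve to the least complex model."""
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    order = COMPLEXITY_ORDER.get(algorithm, {})

    def rank(name, value):
        ordered = order.get(name)
        return ordered.index(value) if ordered is not None and value in ordered else 0

    names = list(grid)
    combos: list[dict] = [{}]
    for name in names:
        combos = [dict(c, **{name: v}) for c in combos for v in grid[name]]
    combos.sort(key=lambda c: tuple(rank(n, c[n]) for n in names))
    return combos


def _complexity_key(algorithm: str, name: str, value) -> int:
    ordered = COMPLEXITY_ORDER.get(algorithm, {}).get(name)
    if ordered is not None and value in ordered:
        return ordered.index(value)
    return 0


# ---------------------------------------------------------------------------
# Fold plan


@dataclass
class FoldPlan:
    """Outer-fold assignment plus per-fold balanced training subsets.

    ``balanced_subsets[f][i]`` is an index array (into the full dataset) of
    the i-th balanced subset of outer fold f: one slice of the fold's
    inactives joined with all of the fold's actives.
    """

    outer_assignments: np.ndarray  # fold index per compound, 0..outer_k-1
    balanced_subsets: list[list[np.ndarray]]
    seed: int
    outer_k: int
    n_subsets: int

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.outer_assignments == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.outer_assignments != fold)


def _balanced_subsets_for(
    train_idx: np.ndarray, y: np.ndarray, n_subsets: int, rng: np.random.Generator
) -> list[np.ndarray]:
    actives = train_idx[y[train_idx] == 1]
    inactives = train_idx[y[train_idx] == 0]
    if len(actives) < 1:
        raise ValueError("training fold contains no actives")
    if len(inactives) < n_subsets:
        raise ValueError(
            f"training fold has {len(inactives)} inactives, fewer than "
            f"n_subsets={n_subsets}"
        )
    shuffled = rng.permutation(inactives)
    # np.array_split yields sizes differing by at most 1, larger chunks first
    return [
        np.sort(np.concatenate([actives, chunk]))
        for chunk in np.array_split(shuffled, n_subsets)
    ]


def make_fold_plan(
    y, outer_k: int = 9, n_subsets: int = 9, seed: int = 0
) -> FoldPlan:
    """Stratified outer folds plus disjoint, covering, size-balanced
    inactive subsets (each joined with all fold actives)."""
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1, dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignments[val_idx] = fold
    rng = np.random.default_rng(seed)
    subsets = []
    for fold in range(outer_k):
        train_idx = np.flatnonzero(assignments != fold)
        subsets.append(_balanced_subsets_for(train_idx, y, n_subsets, rng))
    return FoldPlan(
        outer_assignments=assignments,
        balanced_subsets=subsets,
        seed=seed,
        outer_k=outer_k,
        n_subsets=n_subsets,
    )


def split_inactive_subsets(
    y, n_subsets: int = 9, seed: int = 0
) -> list[np.ndarray]:
    """Balanced subsets of a whole training set (the retraining split)."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    return _balanced_subsets_for(np.arange(len(y)), y, n_subsets, rng)


# ---------------------------------------------------------------------------
# Tuning


def tune_hyperparameters(
    X,
    y,
    algorithm: str,
    grid: dict[str, list] | None = None,
    inner_k: int = 5,
    seed: int = 0,
) -> dict:
    """Grid search maximizing mean inner-CV MCC; ties go to the simplest
    combination (the first in complexity order)."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    combos = grid_combinations(algorithm, grid)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() >= inner_k:
        splitter = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    else:
        # stratification impossible; fall back and let the degenerate-fold
        # skip logic below sort out unusable folds
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=inner_k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
            warnings.warn("skipping degenerate inner fold with a single class")
            continue
        folds.append((train_idx, val_idx))
    if not folds:
        raise ValueError("all inner folds degenerate; cannot tune")
    best_params, best_score = None, -np.inf
    for params in combos:
        scores = []
        for train_idx, val_idx in folds:
            model = build_estimator(algorithm, params, seed=seed)
            model.fit(X[train_idx], y[train_idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(matthews_corrcoef(y[val_idx], model.predict(X[val_idx])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:  # strict: earlier (simpler) combo wins ties
            best_params, best_score = params, mean_score
    return dict(best_params)


def modal_params(param_sets: list[dict], algorithm: str | None = None) -> dict:
    """Per-parameter independent mode; ties resolve to the simpler value."""
    if not param_sets:
        raise ValueError("empty parameter set list")
    result = {}
    for name in param_sets[0]:
        counts: dict = {}
        for ps in param_sets:
            counts[ps[name]] = counts.get(ps[name], 0) + 1
        top = max(counts.values())
        tied = [v for v, c in counts.items() if c == top]
        tied.sort(key=lambda v: _complexity_key(algorithm or "", name, v))
        result[name] = tied[0]
    return result


# ---------------------------------------------------------------------------
# Nested CV


def majority_label(votes: int, n_members: int) -> int:
    """Strict majority; with an odd member count no tie is possible."""
    return int(2 * votes > n_members)


@dataclass
class CVReport:
    fold_mcc: list[float]
    fold_ba: list[float]

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.fold_mcc))

    @property
    def sd_mcc(self) -> float:
        return float(np.std(self.fold_mcc, ddof=1))

    @property
    def mean_ba(self) -> float:
        return float(np.mean(self.fold_ba))

    @property
    def sd_ba(self) -> float:
        return float(np.std(self.fold_ba, ddof=1))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"fold": range(1, len(self.fold_mcc) + 1), "mcc": self.fold_mcc, "ba": self.fold_ba}
        )


def run_nested_cv(
    X,
    y,
    algorithm: str,
    plan: FoldPlan,
    grid: dict[str, list] | None = None,
    inner_k: int = 5,
    tune: bool = True,
    default_params: dict | None = None,
    seed: int = 0,
) -> tuple[CVReport, list[dict]]:
    """Outer loop of the undersampling workflow.

    Per outer fold: each balanced subset is tuned (inner 5-fold CV) and the
    i-th subset's winning parameters train the i-th model on that subset;
    the models vote on the imbalanced validation fold; strict majority
    gives the fold prediction.  Returns the per-fold metric report and the
    per-fold modal parameter sets.  ``tune=False`` trains every member with
    ``default_params`` instead (the default-parameter comparison arm).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if len(y) != len(plan.outer_assignments):
        raise ValueError("fold plan inconsistent with label vector length")
    fold_mcc, fold_ba, fold_modal = [], [], []
    for fold in range(plan.outer_k):
        val_idx = plan.validation_indices(fold)
        subsets = plan.balanced_subsets[fold]
        votes = np.zeros(len(val_idx), dtype=int)
        subset_params = []
        for i, subset in enumerate(subsets):
            try:
                if tune:
                    params = tune_hyperparameters(
                        X[subset], y[subset], algorithm, grid=grid, inner_k=inner_k, seed=seed
                    )
                else:
                    params = dict(default_params or {})
            except ValueError as exc:
                raise ValueError(f"outer fold {fold + 1}, subset {i + 1}: {exc}") from exc
            subset_params.append(params)
            model = build_estimator(algorithm, params, seed=seed)
            model.fit(X[subset], y[subset])
            votes += model.predict(X[val_idx]).astype(int)
        preds = np.array([majority_label(v, len(subsets)) for v in votes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_mcc.append(float(matthews_corrcoef(y[val_idx], preds)))
        fold_ba.append(float(balanced_accuracy_score(y[val_idx], preds)))
        fold_modal.append(modal_params(subset_params, algorithm))
    return CVReport(fold_mcc=fold_mcc, fold_ba=fold_ba), fold_modal


# ---------------------------------------------------------------------------
# Final ensemble


@dataclass
class EnsembleModel:
    """Nine classifiers fitted on balanced subsets of the full training set,
    sharing one parameter set."""

    members: list
    algorithm: str
    params: dict
    descriptor_kind: str
    width: int
    seed: int
    training_signature: str = ""
    n_members: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_members = len(self.members)
        if self.n_members < 1:
            raise ValueError("ensemble needs at least one member")


def _signature(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def retrain_final(
    X,
    y,
    algorithm: str,
    params: dict,
    n_subsets: int = 9,
    seed: int = 0,
    descriptor_kind: str = "continuous",
) -> EnsembleModel:
    """Fit one model per balanced subset of the full training set; every
    member's training set contains every training active."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    subsets = split_inactive_subsets(y, n_subsets=n_subsets, seed=seed)
    members = []
    for subset in subsets:
        model = build_estimator(algorithm, params, seed=seed)
        model.fit(X[subset], y[subset])
        members.append(model)
    return EnsembleModel(
        members=members,
        algorithm=algorithm,
        params=dict(params),
        descriptor_kind=descriptor_kind,
        width=X.shape[1],
        seed=seed,
        training_signature=_signature(X, y),
    )


def compare_paired_metrics(per_fold_a, per_fold_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired fold metrics."""
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors differ in length")
    if np.allclose(a, b):
        warnings.warn("all paired differences are zero; reporting p = 1")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Persistence


def save_ensemble(model: EnsembleModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(model.members):
        joblib.dump(member, directory / f"member_{i + 1}.joblib")
    meta = {
        "format_version": 1,
        "algorithm": model.algorithm,
        "params": {k: v for k, v in model.params.items()},
        "descriptor_kind": model.descriptor_kind,
        "width": model.width,
        "seed": model.seed,
        "training_signature": model.training_signature,
        "n_members": model.n_members,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_ensemble(directory) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    members = [
        joblib.load(directory / f"member_{i + 1}.joblib")
        for i in range(meta["n_members"])
    ]
    return EnsembleModel(
        members=members,
        algorithm=meta["algorithm"],
        params=meta["params"],
        descriptor_kind=meta["descriptor_kind"],
        width=meta["width"],
        seed=meta["seed"],
        training_signature=meta["training_signature"],
    )
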