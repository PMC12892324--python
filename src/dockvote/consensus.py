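"""Score fusion and evaluation.

Docking scores (negated, so higher = stronger) and ensemble vote sums are
each min-max normalized against fixed, training-set-derived bounds and
summed into a consensus score.  Decision thresholds come from the crossing
point of class-conditional Gaussian KDEs.  Normalized values are *not*
clipped: the bounds are fixed constants, so test compounds may fall
outside [0, 1] by design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score

#: Fixed normalization bounds derived from the reference training set.
VOTE_BOUNDS = (0.0, 9.0)
NEG_DOCK_BOUNDS = (-2.80, 12.073)

#: Shipped decision thresholds (KDE-derived on the reference test set).
DEFAULT_DOCK_THRESHOLD = -6.52
DEFAULT_CONSENSUS_THRESHOLD = 0.82

#: Offset added to the worst observed raw docking score for compounds that
#: were submitted to docking but produced no pose.
UNDOCKED_PENALTY_OFFSET = 0.02


@dataclass(frozen=True)
class NormBounds:
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError(f"x_max ({self.x_max}) must exceed x_min ({self.x_min})")


DEFAULT_VOTE_BOUNDS = NormBounds(*VOTE_BOUNDS)
DEFAULT_DOCK_BOUNDS = NormBounds(*NEG_DOCK_BOUNDS)


def normalize_minmax(x, bounds: NormBounds):
    """(x - x_min) / (x_max - x_min); intentionally unclipped."""
    x = np.asarray(x, dtype=float)
    out = (x - bounds.x_min) / (bounds.x_max - bounds.x_min)
    return float(out) if out.ndim == 0 else out


def consensus_score(
    raw_dock,
    votes,
    dock_bounds: NormBounds = DEFAULT_DOCK_BOUNDS,
    vote_bounds: NormBounds = DEFAULT_VOTE_BOUNDS,
):
    """normalize(-raw_dock) + normalize(votes); docking is negated because
    more negative raw scores mean stronger predicted binding."""
    return normalize_minmax(-np.asarray(raw_dock, dtype=float), dock_bounds) + normalize_minmax(
        votes, vote_bounds
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, BA, MCC, precision, recall/sensitivity, specificity, F1.

    Zero-denominator cases (MCC, precision, F1) are defined as 0 and
    flagged rather than raised.
    """
    flags: list[str] = []
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    n = c.total
    accuracy = (tp + tn) / n if n else 0.0

    if tp + fn == 0:
        sensitivity, flags = 0.0, flags + ["no_positives"]
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        specificity, flags = 0.0, flags + ["no_negatives"]
    else:
        specificity = tn / (tn + fp)
    ba = (sensitivity + specificity) / 2

    if tp + fp == 0:
        precision, flags = 0.0, flags + ["zero_precision_denominator"]
    else:
        precision = tp / (tp + fp)

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        mcc, flags = 0.0, flags + ["zero_mcc_denominator"]
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    if precision + sensitivity == 0:
        f1, flags = 0.0, flags + ["zero_f1_denominator"]
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)

    return {
        "accuracy": accuracy,
        "BA": ba,
        "MCC": mcc,
        "precision": precision,
        "recall": sensitivity,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "F1": f1,
        "flags": flags,
    }


def roc_auc(scores, labels) -> tuple[float | None, dict]:
    """Midrank-tie ROC AUC (pairwise concordance with ties counted 1/2).

    Missing (NaN) scores are excluded with a counted warning.  Returns
    (None, info) when only one class remains.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    info: dict = {"n_excluded_missing": 0}
    mask = ~np.isnan(scores)
    if (~mask).any():
        info["n_excluded_missing"] = int((~mask).sum())
        warnings.warn(f"excluded {info['n_excluded_missing']} compounds with missing scores")
        scores, labels = scores[mask], labels[mask]
    if len(np.unique(labels)) < 2:
        info["undefined"] = "single_class"
        return None, info
    return float(roc_auc_score(labels, scores)), info


# ---------------------------------------------------------------------------
# KDE threshold


def _mcc_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    preds = (scores > threshold).astype(int)
    c = confusion_from_labels(labels, preds)
    return classification_metrics(c)["MCC"]


def kde_threshold(
    scores_active, scores_inactive, grid_size: int = 512
) -> tuple[float, dict]:
    """Decision threshold at the crossing of the two class-conditional
    Gaussian KDEs (Scott bandwidth).

    The crossing is searched on a grid in the open interval between the
    inactive mode and the active mode, then refined by bisection.  Multiple
    crossings resolve to the one maximizing MCC on the input scores; no
    crossing falls back to the max-MCC score with a warning.
    """
    a = np.asarray(scores_active, dtype=float)
    i = np.asarray(scores_inactive, dtype=float)
    if len(a) < 5 or len(i) < 5:
        raise ValueError("need at least 5 scores per class for a KDE threshold")
    kde_a = stats.gaussian_kde(a, bw_method="scott")
    kde_i = stats.gaussian_kde(i, bw_method="scott")
    lo = min(a.min(), i.min())
    hi = max(a.max(), i.max())
    grid = np.linspace(lo, hi, grid_size)
    dens_a, dens_i = kde_a(grid), kde_i(grid)

    mode_a = grid[np.argmax(dens_a)]
    mode_i = grid[np.argmax(dens_i)]
    left, right = sorted((mode_i, mode_a))
    inside = (grid > left) & (grid < right)
    diff = dens_a - dens_i

    scores = np.concatenate([a, i])
    labels = np.concatenate([np.ones(len(a), dtype=int), np.zeros(len(i), dtype=int)])

    crossings = []
    idx = np.flatnonzero(inside[:-1] & (np.sign(diff[:-1]) * np.sign(diff[1:]) < 0))
    for j in idx:
        root = optimize.brentq(lambda x: kde_a(x)[0] - kde_i(x)[0], grid[j], grid[j + 1])
        crossings.append(float(root))

    info: dict = {"n_crossings": len(crossings), "fallback": False}
    if crossings:
        best = max(crossings, key=lambda t: _mcc_at_threshold(scores, labels, t))
        info["crossings"] = crossings
        return best, info

    warnings.warn("no KDE crossing between class modes; falling back to max-MCC score")
    info["fallback"] = True
    candidates = np.unique(scores)
    # thresholds between adjacent observed scores
    mids = (candidates[:-1] + candidates[1:]) / 2 if len(candidates) > 1 else candidates
    best = max(mids, key=lambda t: _mcc_at_threshold(scores, labels, t))
    return float(best), info


# ---------------------------------------------------------------------------
# Labels and imputation


def pchembl_label(pchembl: float, threshold: float = 6.0) -> str:
    """Active iff pChEMBL >= threshold (boundary inclusive)."""
    if not (np.isfinite(pchembl) and np.isfinite(threshold)):
        raise ValueError("pchembl and threshold must be finite")
    return "active" if pchembl >= threshold else "inactive"


def classify_consensus(score: float, threshold: float = DEFAULT_CONSENSUS_THRESHOLD) -> str:
    """Strictly-greater rule at the consensus threshold."""
    return "active" if score > threshold else "inactive"


def classify_docking(raw_score: float, threshold: float = DEFAULT_DOCK_THRESHOLD) -> str:
    """More negative = stronger; active at or below the raw-score threshold."""
    return "active" if raw_score <= threshold else "inactive"


@dataclass
class ConsensusResult:
    id: str
    norm_dock: float | None
    norm_votes: float | None
    consensus: float | None
    predicted_label: str  # "active" | "inactive" | "not_available"
    imputation_note: str = ""


def _resolve_parent(cid: str, duplicate_map: dict[str, str]) -> str:
    seen = {cid}
    while cid in duplicate_map:
        cid = duplicate_map[cid]
        if cid in seen:
            raise ValueError(f"cyclic duplicate map involving {cid!r}")
        seen.add(cid)
    return cid


def impute_missing(
    ids: list[str],
    duplicate_map: dict[str, str],
    dock_table: pd.DataFrame,
    vote_results,
    penalty_offset: float = UNDOCKED_PENALTY_OFFSET,
) -> pd.DataFrame:
    """Complete the raw docking and vote channels for ``ids``.

    ``dock_table`` has columns id, dock_score and optionally ``docked``
    (0 marks a compound submitted to docking that produced no pose).
    Rules, in order: (1) inherit a missing channel from the surviving
    duplicate (salt parent or de-stereo twin); (2) attempted-but-undocked
    compounds receive worst observed raw score + ``penalty_offset``;
    (3) anything still lacking a channel stays missing (NaN).
    """
    if "id" not in dock_table.columns or "dock_score" not in dock_table.columns:
        raise ValueError("dock table needs 'id' and 'dock_score' columns")
    dock = {
        str(r.id): float(r.dock_score)
        for r in dock_table.itertuples(index=False)
        if not pd.isna(r.dock_score)
    }
    undocked = set()
    if "docked" in dock_table.columns:
        undocked = {
            str(r.id)
            for r in dock_table.itertuples(index=False)
            if not bool(r.docked)
        }
    if hasattr(vote_results, "items"):
        votes = {str(k): int(v) for k, v in vote_results.items()}
    else:
        votes = {r.id: r.votes for r in vote_results}

    worst = max(dock.values()) if dock else None
    rows = []
    for cid in ids:
        note_parts = []
        raw_dock = dock.get(cid)
        vote = votes.get(cid)
        parent = _resolve_parent(cid, duplicate_map)
        if parent != cid:
            if raw_dock is None and parent in dock:
                raw_dock = dock[parent]
                note_parts.append(f"dock_from_duplicate:{parent}")
            if vote is None and parent in votes:
                vote = votes[parent]
                note_parts.append(f"votes_from_duplicate:{parent}")
        if raw_dock is None and cid in undocked:
            if worst is None:
                raise ValueError("cannot assign undocked penalty: no docked scores observed")
            raw_dock = worst + penalty_offset
            note_parts.append(f"undocked_penalty:{raw_dock:.4g}")
        rows.append(
            {
                "id": cid,
                "raw_dock": np.nan if raw_dock is None else raw_dock,
                "votes": np.nan if vote is None else vote,
                "imputation_note": ";".join(note_parts),
            }
        )
    return pd.DataFrame(rows)


def score_table(
    channels: pd.DataFrame,
    dock_bounds: NormBounds = DEFAULT_DOCK_BOUNDS,
    vote_bounds: NormBounds = DEFAULT_VOTE_BOUNDS,
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> list[ConsensusResult]:
    """Turn a completed channel table (id, raw_dock, votes, imputation_note)
    into per-compound consensus results; any missing channel yields
    predicted_label = not_available."""
    results = []
    for row in channels.itertuples(index=False):
        note = getattr(row, "imputation_note", "") or ""
        if pd.isna(row.raw_dock) or pd.isna(row.votes):
            missing = [
                name
                for name, val in (("dock", row.raw_dock), ("votes", row.votes))
                if pd.isna(val)
            ]
            note = ";".join(filter(None, [note, f"missing:{'+'.join(missing)}"]))
            results.append(
                ConsensusResult(
                    id=str(row.id),
                    norm_dock=None if pd.isna(row.raw_dock) else normalize_minmax(-row.raw_dock, dock_bounds),
                    norm_votes=None if pd.isna(row.votes) else normalize_minmax(row.votes, vote_bounds),
                    consensus=None,
                    predicted_label="not_available",
                    imputation_note=note,
                )
            )
            continue
        nd = normalize_minmax(-float(row.raw_dock), dock_bounds)
        nv = normalize_minmax(float(row.votes), vote_bounds)
        total = nd + nv
        results.append(
            ConsensusResult(
                id=str(row.id),
                norm_dock=nd,
                norm_votes=nv,
                consensus=total,
                predicted_label=classify_consensus(total, threshold),
                imputation_note=note,
            )
        )
    return results


def write_consensus_csv(results: list[ConsensusResult], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in results],
            "norm_dock": [np.nan if r.norm_dock is None else r.norm_dock for r in results],
            "norm_votes": [np.nan if r.norm_votes is None else r.norm_votes for r in results],
            "consensus": [np.nan if r.consensus is None else r.consensus for r in results],
            "predicted_label": [r.predicted_label for r in results],
            "imputation_note": [r.imputation_note for r in results],
        }
    ).to_csv(path, index=False)
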