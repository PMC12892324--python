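"""Apply a fitted ensemble to new compounds: per-member predictions,
vote sums, majority labels, and vote-sum ROC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dockvote.descriptors import DescriptorMatrix
from dockvote.imbalance_cv import EnsembleModel, majority_label


@dataclass
class VoteResult:
    id: str
    votes: int
    majority_label: str  # "active" | "inactive"
    member_predictions: list[int]

    def __post_init__(self) -> None:
        if self.votes != sum(self.member_predictions):
            raise ValueError("votes must equal the sum of member predictions")


def predict_votes(model: EnsembleModel, X: DescriptorMatrix) -> list[VoteResult]:
    """One VoteResult per compound; label is active iff a strict majority of
    members predicts active."""
    if X.kind != model.descriptor_kind:
        raise ValueError(
            f"descriptor kind mismatch: matrix is {X.kind!r}, "
            f"model expects {model.descriptor_kind!r}"
        )
    if X.width != model.width:
        raise ValueError(
            f"descriptor width mismatch: matrix has {X.width}, model expects {model.width}"
        )
    member_preds = np.vstack(
        [member.predict(X.features).astype(int) for member in model.members]
    )  # (n_members, n_compounds)
    results = []
    for j, cid in enumerate(X.ids):
        preds = member_preds[:, j].tolist()
        votes = int(sum(preds))
        label = "active" if majority_label(votes, model.n_members) else "inactive"
        results.append(
            VoteResult(id=cid, votes=votes, majority_label=label, member_predictions=preds)
        )
    return results


def vote_sums(results: list[VoteResult]) -> np.ndarray:
    return np.array([r.votes for r in results], dtype=float)


def vote_roc(results: list[VoteResult], labels) -> float | None:
    """ROC AUC of vote-sum scores with midrank tie handling; None when only
    one class is present."""
    from dockvote.consensus import roc_auc

    auc, _ = roc_auc(vote_sums(results), labels)
    return auc


def write_votes_csv(results: list[VoteResult], path) -> None:
    n_members = len(results[0].member_predictions) if results else 0
    rows = {
        "id": [r.id for r in results],
        "votes": [r.votes for r in results],
        "majority_label": [r.majority_label for r in results],
    }
    for m in range(n_members):
        rows[f"member_{m + 1}"] = [r.member_predictions[m] for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_votes_csv(path) -> list[VoteResult]:
    df = pd.read_csv(path, dtype={"id": str})
    member_cols = sorted(
        (c for c in df.columns if c.startswith("member_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return [
        VoteResult(
            id=row["id"],
            votes=int(row["votes"]),
            majority_label=row["majority_label"],
            member_predictions=[int(row[c]) for c in member_cols],
        )
        for _, row in df.iterrows()
    ]
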