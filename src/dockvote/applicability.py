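"""Applicability-domain assessment: exact Tanimoto k-nearest-neighbor
search of query compounds against the model-building set."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dockvote.descriptors import DescriptorMatrix


@dataclass
class NeighborReport:
    query_id: str
    neighbor_ids: list[str]
    similarities: list[float]
    neighbor_labels: list

    def __post_init__(self) -> None:
        sims = self.similarities
        if any(sims[i] < sims[i + 1] for i in range(len(sims) - 1)):
            raise ValueError("similarities must be sorted non-increasing")

    @property
    def top1(self) -> float:
        return self.similarities[0]


def _pairwise_tanimoto(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    q = query.astype(bool)
    r = ref.astype(bool)
    inter = q.astype(np.int64) @ r.astype(np.int64).T
    union = q.sum(axis=1, keepdims=True) + r.sum(axis=1)[None, :] - inter
    sims = np.ones_like(inter, dtype=float)  # both-empty pairs define sim = 1
    nz = union > 0
    sims[nz] = inter[nz] / union[nz]
    return sims


def knn_tanimoto(
    query: DescriptorMatrix,
    reference: DescriptorMatrix,
    ref_labels=None,
    k: int = 5,
) -> list[NeighborReport]:
    """Exact k nearest reference compounds per query by Tanimoto similarity.

    Ties are broken by reference storage order (stable sort on descending
    similarity).  If the reference set is smaller than k, all references
    are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    if query.width != reference.width:
        raise ValueError(
            f"fingerprint width mismatch: query {query.width}, reference {reference.width}"
        )
    labels = list(ref_labels) if ref_labels is not None else [None] * len(reference)
    sims = _pairwise_tanimoto(query.features, reference.features)
    k_eff = min(k, len(reference))
    reports = []
    for qi, qid in enumerate(query.ids):
        order = np.argsort(-sims[qi], kind="stable")[:k_eff]
        reports.append(
            NeighborReport(
                query_id=qid,
                neighbor_ids=[reference.ids[j] for j in order],
                similarities=[float(sims[qi, j]) for j in order],
                neighbor_labels=[labels[j] for j in order],
            )
        )
    return reports


def mean_nn_similarity(reports: list[NeighborReport]) -> float:
    """Mean of each query's top-1 (nearest-neighbor) similarity."""
    if not reports:
        raise ValueError("no neighbor reports")
    return float(np.mean([r.top1 for r in reports]))


def write_neighbors_csv(reports: list[NeighborReport], path) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "neighbor_rank": rank + 1,
            "neighbor_id": nid,
            "tanimoto": sim,
            "neighbor_label": lab if lab is not None else "",
        }
        for r in reports
        for rank, (nid, sim, lab) in enumerate(
            zip(r.neighbor_ids, r.similarities, r.neighbor_labels)
        )
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(reports: list[NeighborReport], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"n_queries": len(reports), "mean_nn_similarity": mean_nn_similarity(reports)},
            fh,
            indent=2,
        )


def plot_chemical_space(coords, labels, out_path, title: str = "chemical space"):
    """Extension hook: scatter any precomputed 2D embedding (e.g. from an
    external parametric t-SNE) colored by label.  The embedding itself is
    never computed here."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(labels):
        mask = labels == lab
        ax.scatter(coords[mask, 0], coords[mask, 1], s=12, alpha=0.7, label=str(lab))
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
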