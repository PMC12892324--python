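"""Seeded synthetic datasets with the statistical structure the pipeline
assumes: class imbalance, class-conditional descriptor separation, and
docking scores whose negated values run higher for actives.

Class-conditional Gaussians are deliberately the whole story — just enough
structure to exercise classifiers, vote sums, and KDE thresholds without
pretending to mimic real chemical feature correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dockvote.descriptors import BINARY_FINGERPRINT, CONTINUOUS, DescriptorMatrix

#: Raw docking scores center here so realistic thresholds (~ -6.5) bite.
DOCK_BASELINE = -5.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic dataset.

    ``effect_size`` is the per-feature mean shift (in SD units) between the
    active and inactive feature distributions; ``dock_gap`` is the mean
    difference of negated docking scores (actives minus inactives).
    """

    n_active: int
    n_inactive: int
    n_features: int = 20
    effect_size: float = 0.0
    dock_gap: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError(
                f"class counts must be >= 1, got n_active={self.n_active}, "
                f"n_inactive={self.n_inactive}"
            )
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _ids(n: int) -> list[str]:
    return [f"cpd_{i + 1:05d}" for i in range(n)]


def gen_descriptors(
    spec: SyntheticSpec, binarize: bool = False
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Descriptor matrix plus 0/1 label vector (actives first).

    Actives are drawn per feature from N(effect_size, 1), inactives from
    N(0, 1).  ``binarize`` thresholds at zero to yield 0/1 features.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_active + spec.n_inactive
    features = rng.standard_normal((n, spec.n_features))
    features[: spec.n_active] += spec.effect_size
    labels = np.zeros(n, dtype=int)
    labels[: spec.n_active] = 1
    kind = CONTINUOUS
    if binarize:
        features = (features > 0).astype(np.uint8)
        kind = BINARY_FINGERPRINT
    matrix = DescriptorMatrix(ids=_ids(n), features=features, kind=kind)
    return matrix, labels


def gen_docking_scores(labels: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """One raw docking score per compound (more negative = stronger).

    Actives: N(DOCK_BASELINE - dock_gap, noise_sd); inactives:
    N(DOCK_BASELINE, noise_sd).  Independent of the descriptor draw but
    deterministic under the same spec seed.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label vector is empty")
    rng = np.random.default_rng([spec.seed, 1])
    scores = DOCK_BASELINE + spec.noise_sd * rng.standard_normal(labels.size)
    scores[labels == 1] -= spec.dock_gap
    return scores


def gen_dataset(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray, np.ndarray]:
    """Convenience bundle: (descriptors, labels, raw docking scores)."""
    matrix, labels = gen_descriptors(spec)
    return matrix, labels, gen_docking_scores(labels, spec)


def write_dataset_csv(matrix: DescriptorMatrix, labels, desc_path, dock_scores=None, dock_path=None) -> None:
    df = matrix.to_frame()
    df.insert(1, "label", np.asarray(labels, dtype=int))
    df.to_csv(desc_path, index=False)
    if dock_scores is not None:
        if dock_path is None:
            raise ValueError("dock_path required when dock_scores given")
        pd.DataFrame({"id": matrix.ids, "dock_score": dock_scores}).to_csv(
            dock_path, index=False
        )


# Hand-curated standardization fixture: (id, raw smiles, expected canonical
# standardized form or None, expected rejection reason or None).  Expected
# forms were hand-checked against the salt-strip / neutralize / de-stereo
# rules and frozen as canonical SMILES.
TOY_SMILES: list[tuple[str, str, str | None, str | None]] = [
    ("toy_salt", "O=C([O-])c1ccccc1.[Na+]", "O=C(O)c1ccccc1", None),
    ("toy_amine", "CC[NH3+]", "CCN", None),
    ("toy_stereo_R", "C[C@H](N)C(=O)O", "CC(N)C(=O)O", None),
    ("toy_stereo_S", "C[C@@H](N)C(=O)O", "CC(N)C(=O)O", None),
    ("toy_inorganic", "[O-][Cl+3]([O-])([O-])[O-]", None, "inorganic"),
    ("toy_metal", "CCCC[Sn](CCCC)CCCC", None, "metal"),
    ("toy_quat", "C[N+](C)(C)C.[Cl-]", "C[N+](C)(C)C", None),
    ("toy_garbage", "not-a-smiles(", None, "parse_error"),
]


def gen_toy_smiles() -> list[tuple[str, str, str | None, str | None]]:
    """Fixed fixture covering salt stripping, neutralization, stereo merge,
    inorganic/metal rejection, retained permanent cation, and parse failure."""
    return list(TOY_SMILES)


def write_toy_smiles_csv(path) -> None:
    pd.DataFrame(
        [(cid, smi) for cid, smi, _, _ in TOY_SMILES], columns=["id", "smiles"]
    ).to_csv(path, index=False)
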