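"""Molecular featurization: circular fingerprints, Tanimoto similarity,
Crippen logP, and ingestion of precomputed continuous descriptor tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdFingerprintGenerator

BINARY_FINGERPRINT = "binary_fingerprint"
CONTINUOUS = "continuous"

DEFAULT_N_BITS = 2048


@dataclass
class DescriptorMatrix:
    """Compounds x features matrix tagged as binary fingerprint or continuous.

    Invariants enforced at construction: row count matches ``ids``, binary
    matrices contain only 0/1, and no entry is missing.
    """

    ids: list[str]
    features: np.ndarray
    kind: str = CONTINUOUS
    feature_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != len(self.ids):
            raise ValueError(
                f"row count {self.features.shape[0]} != number of ids {len(self.ids)}"
            )
        if self.kind not in (BINARY_FINGERPRINT, CONTINUOUS):
            raise ValueError(f"unknown descriptor kind: {self.kind!r}")
        if np.isnan(self.features.astype(float)).any():
            raise ValueError("descriptor matrix contains missing entries")
        if self.kind == BINARY_FINGERPRINT and not np.isin(self.features, (0, 1)).all():
            raise ValueError("binary fingerprint matrix has entries outside {0, 1}")

    @property
    def width(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "DescriptorMatrix":
        indices = np.asarray(indices)
        return DescriptorMatrix(
            ids=[self.ids[i] for i in indices],
            features=self.features[indices],
            kind=self.kind,
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"feature_{i + 1}" for i in range(self.width)]
        df = pd.DataFrame(self.features, columns=names)
        df.insert(0, "id", self.ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for compound {compound_id!r}" if compound_id else ""
        raise ValueError(f"unparseable structure{label}: {smiles!r}")
    return mol


def ecfp4(smiles_std: str, n_bits: int = DEFAULT_N_BITS, compound_id: str | None = None) -> np.ndarray:
    """Folded circular fingerprint of radius 2 (bond diameter 4) as a 0/1 vector."""
    mol = _mol_from_smiles(smiles_std, compound_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=np.uint8)


def fingerprint_matrix(
    ids: list[str], smiles: list[str], n_bits: int = DEFAULT_N_BITS
) -> DescriptorMatrix:
    if len(ids) != len(smiles):
        raise ValueError("ids and smiles differ in length")
    rows = [ecfp4(s, n_bits=n_bits, compound_id=i) for i, s in zip(ids, smiles)]
    return DescriptorMatrix(ids=list(ids), features=np.vstack(rows), kind=BINARY_FINGERPRINT)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|a & b| / |a | b|; defined as 1.0 when both vectors are all-zero."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def crippen_logp(smiles_std: str, compound_id: str | None = None) -> float:
    """Atom-contribution (Crippen) logP."""
    return float(Crippen.MolLogP(_mol_from_smiles(smiles_std, compound_id)))


def load_descriptor_table(
    path, ids: list[str] | None = None, id_column: str = "id"
) -> DescriptorMatrix:
    """Read a continuous descriptor CSV (id column + numeric columns).

    When ``ids`` is given, rows are aligned to that order; ids absent from
    the table are reported via a warning and an error is raised only if the
    matrix cannot be aligned.  Missing cells are rejected outright.
    """
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"descriptor table lacks id column {id_column!r}")
    values = df.drop(columns=[id_column])
    if values.isna().any().any():
        bad = df.loc[values.isna().any(axis=1), id_column].tolist()
        raise ValueError(f"descriptor table has missing cells for rows: {bad}")
    table_ids = df[id_column].tolist()
    if ids is not None:
        extra = [i for i in table_ids if i not in set(ids)]
        if extra:
            warnings.warn(f"descriptor table ids not in compound set: {extra}")
        index = {cid: pos for pos, cid in enumerate(table_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValueError(f"descriptor table is missing rows for ids: {missing}")
        order = [index[i] for i in ids]
        df = df.iloc[order]
        values = values.iloc[order]
        table_ids = list(ids)
    return DescriptorMatrix(
        ids=table_ids,
        features=values.to_numpy(dtype=float),
        kind=CONTINUOUS,
        feature_names=list(values.columns),
    )
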