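"""Molecule standardization: salt stripping, inorganic/metal rejection,
charge neutralization, stereochemistry removal, and duplicate merging.

The fixed pipeline order is: parse -> largest fragment -> element filter ->
neutralize -> remove stereo -> canonicalize.  Rejection is a result, not an
exception; downstream imputation relies on the bookkeeping produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

REJECT_NONE = "none"
REJECT_INORGANIC = "inorganic"
REJECT_METAL = "metal"
REJECT_PARSE = "parse_error"

LABEL_ACTIVE = "active"
LABEL_INACTIVE = "inactive"
LABEL_UNKNOWN = "unknown"

# Organic-subset allowlist; anything else (metals, metalloids beyond Si/Se)
# marks the compound as metal-containing.
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass
class CompoundRecord:
    """One molecule with provenance of standardization and merging."""

    id: str
    smiles_raw: str
    smiles_std: str | None = None
    label: str = LABEL_UNKNOWN
    cytotoxic: bool = False
    merged_from: list[str] = field(default_factory=list)
    reject_reason: str = REJECT_NONE

    def __post_init__(self) -> None:
        if self.id in self.merged_from:
            raise ValueError(f"record {self.id!r} lists itself in merged_from")

    @property
    def kept(self) -> bool:
        return self.reject_reason == REJECT_NONE


@dataclass
class StandardizationOutcome:
    smiles_std: str | None
    reject_reason: str
    transform_log: list[str]


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, int]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    # largest by heavy atoms; ties by molecular weight, then canonical string
    best = max(
        frags,
        key=lambda f: (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            Chem.MolToSmiles(f),
        ),
    )
    return best, len(frags)


def standardize_compound(smiles_raw: str) -> StandardizationOutcome:
    """Apply the standardization pipeline to a single SMILES string."""
    log: list[str] = []
    if not smiles_raw or not smiles_raw.strip():
        return StandardizationOutcome(None, REJECT_PARSE, ["empty_input"])
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return StandardizationOutcome(None, REJECT_PARSE, ["parse_failed"])
    log.append("parsed")

    mol, n_frags = _largest_fragment(mol)
    if n_frags > 1:
        log.append(f"salt_stripped({n_frags}->1 fragments)")

    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    if "C" not in symbols:
        log.append("rejected_inorganic")
        return StandardizationOutcome(None, REJECT_INORGANIC, log)
    disallowed = symbols - ALLOWED_ELEMENTS
    if disallowed:
        log.append(f"rejected_metal({','.join(sorted(disallowed))})")
        return StandardizationOutcome(None, REJECT_METAL, log)

    charge_before = Chem.GetFormalCharge(mol)
    mol = _UNCHARGER.uncharge(mol)
    if Chem.GetFormalCharge(mol) != charge_before:
        log.append("neutralized")

    if any(
        a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
    ) or any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()):
        log.append("stereo_removed")
    Chem.RemoveStereochemistry(mol)

    log.append("canonicalized")
    return StandardizationOutcome(Chem.MolToSmiles(mol), REJECT_NONE, log)


@dataclass
class RejectReport:
    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    n_merged: int = 0
    rejects_by_reason: dict = field(default_factory=dict)
    label_conflicts: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.n_kept + self.n_rejected + self.n_merged != self.n_input:
            raise AssertionError("reject report does not partition the input")


def standardize_dataset(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], dict[str, str], RejectReport]:
    """Standardize every record, then merge identical canonical forms.

    Returns kept records, a map removed_id -> surviving_id, and a report
    whose counts partition the input exactly.  Merged duplicates with
    conflicting labels resolve to 'active' (toxicology-conservative) and
    are logged in the report.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for i in ids:
            (dupes if i in seen else seen).add(i)
        raise ValueError(f"duplicate input ids: {sorted(dupes)}")

    report = RejectReport(n_input=len(records))
    kept: list[CompoundRecord] = []
    by_canonical: dict[str, CompoundRecord] = {}
    duplicate_map: dict[str, str] = {}

    for rec in records:
        outcome = standardize_compound(rec.smiles_raw)
        if outcome.reject_reason != REJECT_NONE:
            rec.smiles_std = None
            rec.reject_reason = outcome.reject_reason
            report.n_rejected += 1
            report.rejects_by_reason[outcome.reject_reason] = (
                report.rejects_by_reason.get(outcome.reject_reason, 0) + 1
            )
            continue
        canon = outcome.smiles_std
        survivor = by_canonical.get(canon)
        if survivor is None:
            rec.smiles_std = canon
            rec.reject_reason = REJECT_NONE
            by_canonical[canon] = rec
            kept.append(rec)
            report.n_kept += 1
        else:
            rec.smiles_std = canon  # standardized fine, merely merged away
            duplicate_map[rec.id] = survivor.id
            survivor.merged_from.append(rec.id)
            report.n_merged += 1
            if (
                rec.label != survivor.label
                and LABEL_UNKNOWN not in (rec.label, survivor.label)
            ):
                msg = (
                    f"label conflict merging {rec.id} ({rec.label}) into "
                    f"{survivor.id} ({survivor.label}); keeping 'active'"
                )
                logger.warning(msg)
                report.label_conflicts.append(msg)
                survivor.label = LABEL_ACTIVE
            survivor.cytotoxic = survivor.cytotoxic or rec.cytotoxic

    report.check_conservation()
    return kept, duplicate_map, report


# ---------------------------------------------------------------------------
# I/O


def read_compound_csv(path) -> list[CompoundRecord]:
    """CSV with columns id, smiles[, label, cytotoxic]; label may be 1/0 or
    active/inactive."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "smiles" not in df.columns:
        raise ValueError("compound CSV needs 'id' and 'smiles' columns")
    records = []
    for row in df.itertuples(index=False):
        label = LABEL_UNKNOWN
        if "label" in df.columns and not pd.isna(row.label):
            label = LABEL_ACTIVE if str(row.label) in ("1", "active") else LABEL_INACTIVE
        cytotoxic = bool(getattr(row, "cytotoxic", False)) if "cytotoxic" in df.columns else False
        records.append(
            CompoundRecord(id=str(row.id), smiles_raw=str(row.smiles), label=label, cytotoxic=cytotoxic)
        )
    return records


def read_sdf(path, id_property: str | None = None) -> list[CompoundRecord]:
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            records.append(CompoundRecord(id=f"sdf_{i + 1}", smiles_raw=""))
            continue
        cid = (
            mol.GetProp(id_property)
            if id_property and mol.HasProp(id_property)
            else (mol.GetProp("_Name") if mol.GetProp("_Name") else f"sdf_{i + 1}")
        )
        records.append(CompoundRecord(id=cid, smiles_raw=Chem.MolToSmiles(mol)))
    return records


def write_standardized_csv(records: list[CompoundRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles_raw": [r.smiles_raw for r in records],
            "smiles_std": [r.smiles_std or "" for r in records],
            "label": [r.label for r in records],
            "cytotoxic": [int(r.cytotoxic) for r in records],
            "reject_reason": [r.reject_reason for r in records],
            "merged_from": [";".join(r.merged_from) for r in records],
        }
    ).to_csv(path, index=False)


def write_duplicate_map(duplicate_map: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(duplicate_map.items()), columns=["removed_id", "surviving_id"]
    ).to_csv(path, index=False)


def read_duplicate_map(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["removed_id"], df["surviving_id"]))
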