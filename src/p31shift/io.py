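"""Reading and writing ³¹P shift datasets; SMILES parsing and canonicalization.

A dataset is a flat table of (SMILES, shift/ppm) observations. Multiple
entries for the same molecule are legitimate experimental variance and are
kept as independent records. Molecules are heavy-atom 2D structures
(hydrogens implicit); records whose SMILES fails RDKit sanitization are
excluded from all downstream stages, with counts reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: default logical → physical column names for delimited input
DEFAULT_COLUMN_MAP = {"smiles": "smiles", "shift": "shift"}

SHIFT_RANGE_PPM = (-1000.0, 1000.0)


class ParseError(ValueError):
    """A SMILES string could not be parsed/sanitized into a molecule."""


@dataclass(frozen=True)
class ShiftRecord:
    """One experimental (SMILES, ³¹P shift) observation."""

    record_id: str
    smiles: str
    shift_ppm: float
    source_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        lo, hi = SHIFT_RANGE_PPM
        if not (lo <= self.shift_ppm <= hi):
            raise ValueError(f"shift_ppm {self.shift_ppm} outside [{lo}, {hi}] ppm")


@dataclass
class DatasetLoad:
    """Result of reading a dataset file: records plus accounting."""

    records: list[ShiftRecord]
    n_rows: int
    n_dropped_shift: int
    path: Path | None = None
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def parse_molecule(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string into a heavy-atom molecule.

    Raises :class:`ParseError` on syntactically or valence-invalid input;
    never returns None.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ParseError(f"unparseable or valence-invalid SMILES: {smiles!r}")
    return mol


def try_parse(smiles: str) -> Chem.Mol | None:
    """Like :func:`parse_molecule` but returns None on failure."""
    try:
        return parse_molecule(smiles)
    except ParseError:
        return None


def canonicalize(mol: Chem.Mol) -> str:
    """Deterministic canonical SMILES; identical for any atom-order permutation."""
    return Chem.MolToSmiles(mol, canonical=True)


def canonical_smiles(smiles: str) -> str:
    return canonicalize(parse_molecule(smiles))


def has_phosphorus(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 15 for a in mol.GetAtoms())


def read_dataset(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    id_column: str | None = None,
) -> DatasetLoad:
    """Read a delimited (CSV/TSV by extension) or SDF shift dataset.

    ``column_map`` maps the logical names ``smiles``/``shift`` to the file's
    physical column names. Rows whose shift does not parse as a finite number
    in [−1000, 1000] ppm are dropped and counted; duplicate molecules are
    retained. Record ids come from ``id_column`` when given, else row order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".sdf":
        return _read_sdf(path, column_map)

    cmap = DEFAULT_COLUMN_MAP | (column_map or {})
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for logical in ("smiles", "shift"):
        if cmap[logical] not in df.columns:
            raise KeyError(
                f"mapped column {cmap[logical]!r} (for {logical!r}) not in {list(df.columns)}"
            )

    records: list[ShiftRecord] = []
    n_dropped = 0
    lo, hi = SHIFT_RANGE_PPM
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, cmap["shift"], None)
        if raw is None:  # itertuples munges non-identifier names
            raw = df.iloc[i][cmap["shift"]]
        shift = pd.to_numeric(raw, errors="coerce")
        if pd.isna(shift) or not (lo <= float(shift) <= hi):
            n_dropped += 1
            continue
        rid = str(df.iloc[i][id_column]) if id_column else f"r{i}"
        records.append(
            ShiftRecord(record_id=rid, smiles=str(df.iloc[i][cmap["smiles"]]), shift_ppm=float(shift))
        )
    if not records:
        raise ValueError(f"no valid records in {path}")
    logger.info("read %d records from %s (%d rows dropped)", len(records), path, n_dropped)
    return DatasetLoad(records, n_rows=len(df), n_dropped_shift=n_dropped, path=path)


def _read_sdf(path: Path, column_map: dict[str, str] | None) -> DatasetLoad:
    shift_tag = (column_map or {}).get("shift", "shift")
    records: list[ShiftRecord] = []
    n_rows = 0
    n_dropped = 0
    lo, hi = SHIFT_RANGE_PPM
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), sanitize=True)):
        n_rows += 1
        if mol is None or not mol.HasProp(shift_tag):
            n_dropped += 1
            continue
        shift = pd.to_numeric(mol.GetProp(shift_tag), errors="coerce")
        if pd.isna(shift) or not (lo <= float(shift) <= hi):
            n_dropped += 1
            continue
        records.append(ShiftRecord(f"r{i}", Chem.MolToSmiles(mol), float(shift)))
    if not records:
        raise ValueError(f"no valid records in {path}")
    return DatasetLoad(records, n_rows=n_rows, n_dropped_shift=n_dropped, path=path)


def write_dataset(records: list[ShiftRecord], path: str | Path) -> None:
    """Write records as CSV with the default column names (round-trip safe)."""
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "smiles": [r.smiles for r in records],
            "shift": [r.shift_ppm for r in records],
        }
    ).to_csv(path, index=False)


def write_predictions(
    rows: list[tuple[str, str, float]], path: str | Path
) -> None:
    """Write (record_id, smiles, predicted_shift_ppm) rows as CSV."""
    pd.DataFrame(rows, columns=["record_id", "smiles", "predicted_shift_ppm"]).to_csv(
        path, index=False
    )


@dataclass
class ValidityReport:
    """Accounting of sanitization / phosphorus filtering."""

    valid: list[ShiftRecord]
    n_parse_failed: int
    n_no_phosphorus: int


def filter_valid(records: list[ShiftRecord], require_phosphorus: bool = True) -> ValidityReport:
    """Drop records that fail sanitization (and, by default, P-free ones)."""
    valid: list[ShiftRecord] = []
    n_bad = 0
    n_nop = 0
    for rec in records:
        mol = try_parse(rec.smiles)
        if mol is None:
            n_bad += 1
            continue
        if require_phosphorus and not has_phosphorus(mol):
            n_nop += 1
            continue
        valid.append(rec)
    if n_bad or n_nop:
        logger.info("filtered %d parse failures, %d phosphorus-free records", n_bad, n_nop)
    return ValidityReport(valid, n_parse_failed=n_bad, n_no_phosphorus=n_nop)
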