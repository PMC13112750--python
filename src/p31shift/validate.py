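"""Chemically informed validation: subclass error analysis, substituent
increments, and dataset composition statistics.

Subclasses are assigned by SMARTS patterns over the phosphorus coordination
environment (tertiary phosphines R₃P, phosphine oxides R₃P=O, phosphonates
RP(=O)(OR)₂, phosphates (OR)₃P=O), with orthogonal flags for net formal
charge and P–Si bonds. The substituent-increment model

    δ_pred = B + n_β·A_β + n_γ·A_γ

relates the shift of an alkyl homolog to the carbon counts at topological
distance 2 (β, deshielding, A_β > 0) and 3 (γ, shielding, A_γ < 0) from
phosphorus, and is fitted by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdmolops
from rdkit.Chem.Scaffolds import MurckoScaffold

from .io import ShiftRecord, try_parse

#: SMARTS registry for the four phosphorus coordination classes (editable config)
SUBCLASS_SMARTS = {
    "phosphine": "[PX3;!$(P=O)]([#6])([#6])[#6]",
    "phosphine_oxide": "[PX4](=O)([#6])([#6])[#6]",
    "phosphonate": "[PX4](=O)([OX2])([OX2])[#6]",
    "phosphate": "[PX4](=O)([OX2])([OX2])[OX2]",
}
_SILYL = Chem.MolFromSmarts("[#15]~[Si]")
_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in SUBCLASS_SMARTS.items()}

SUBCLASS_LABELS = tuple(SUBCLASS_SMARTS) + ("charged", "silyl", "other")


def classify_subclass(mol: Chem.Mol) -> set[str]:
    """Subclass flags for one molecule; coordination classes plus charged/silyl."""
    labels = {name for name, patt in _PATTERNS.items() if mol.HasSubstructMatch(patt)}
    if not labels:
        labels.add("other")
    if Chem.GetFormalCharge(mol) != 0:
        labels.add("charged")
    if mol.HasSubstructMatch(_SILYL):
        labels.add("silyl")
    return labels


@dataclass
class SubclassErrorRow:
    label: str
    n: int
    mae: float | None
    rmse: float | None
    q50: float | None
    q95: float | None


def _error_row(label: str, errors: np.ndarray) -> SubclassErrorRow:
    if errors.size == 0:
        return SubclassErrorRow(label, 0, None, None, None, None)
    return SubclassErrorRow(
        label,
        int(errors.size),
        float(np.mean(errors)),
        float(np.sqrt(np.mean(errors**2))),
        # linear-interpolation quantiles: q50 of an odd-length list is its middle element
        float(np.percentile(errors, 50)),
        float(np.percentile(errors, 95)),
    )


def subclass_error_table(
    predictions: list[tuple[Chem.Mol, float, float]]
) -> list[SubclassErrorRow]:
    """Per-subclass n/MAE/RMSE/q50/q95 plus an all-neutral reference row."""
    if not predictions:
        raise ValueError("empty prediction list")
    errors: dict[str, list[float]] = {lab: [] for lab in SUBCLASS_LABELS}
    neutral: list[float] = []
    for mol, y, yhat in predictions:
        err = abs(y - yhat)
        for lab in classify_subclass(mol):
            errors[lab].append(err)
        if Chem.GetFormalCharge(mol) == 0:
            neutral.append(err)
    rows = [_error_row(lab, np.asarray(errors[lab])) for lab in SUBCLASS_LABELS]
    rows.append(_error_row("all_neutral", np.asarray(neutral)))
    return rows


def count_beta_gamma(mol: Chem.Mol) -> tuple[int, int]:
    """Carbon counts at heavy-atom shortest-path distance 2 (β) and 3 (γ) from P.

    Requires exactly one phosphorus atom (homologous-series use); ring carbons
    count once, at their shortest distance.
    """
    p_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 15]
    if len(p_atoms) != 1:
        raise ValueError(f"expected exactly one phosphorus atom, found {len(p_atoms)}")
    dist = rdmolops.GetDistanceMatrix(mol)[p_atoms[0]]
    carbons = np.array([a.GetAtomicNum() == 6 for a in mol.GetAtoms()])
    return int(np.sum(carbons & (dist == 2))), int(np.sum(carbons & (dist == 3)))


@dataclass
class IncrementFit:
    B: float
    A_beta: float
    A_gamma: float
    r_squared: float


def fit_increment_model(series: list[tuple[Chem.Mol, float]]) -> IncrementFit:
    """OLS fit of δ = B + n_β·A_β + n_γ·A_γ over a homologous series."""
    if len(series) < 3:
        raise ValueError("need at least 3 series members")
    counts = [count_beta_gamma(mol) for mol, _ in series]
    X = np.column_stack([np.ones(len(series)), [c[0] for c in counts], [c[1] for c in counts]])
    y = np.asarray([s for _, s in series], dtype=np.float64)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: series does not vary n_beta and n_gamma")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return IncrementFit(float(coef[0]), float(coef[1]), float(coef[2]), r2)


@dataclass
class DatasetSummary:
    n_records: int
    n_valid: int
    n_parse_failed: int
    n_distinct_molecules: int
    n_scaffolds: int
    scaffold_diversity_valid: float      # unique scaffolds / valid compounds
    scaffold_diversity_entries: float    # unique scaffolds / total entries
    heavy_atoms_mean: float
    heavy_atoms_median: float
    heavy_atoms_max: int
    shift_min: float
    shift_max: float
    shift_mean: float
    n_element_types: int


def dataset_summary(
    records: list[ShiftRecord], with_fingerprints: bool = False
) -> tuple[DatasetSummary, np.ndarray | None]:
    """Composition statistics; optionally 2048-bit radius-2 Morgan fingerprints."""
    mols, shifts = [], []
    n_bad = 0
    for rec in records:
        mol = try_parse(rec.smiles)
        if mol is None:
            n_bad += 1
            continue
        mols.append(mol)
        shifts.append(rec.shift_ppm)
    if not mols:
        raise ValueError("no valid molecules")
    canon = [Chem.MolToSmiles(m) for m in mols]
    scaffolds = {MurckoScaffold.MurckoScaffoldSmiles(mol=m) for m in mols}
    heavy = np.array([m.GetNumAtoms() for m in mols])
    elements = {a.GetSymbol() for m in mols for a in m.GetAtoms()}
    shifts_arr = np.asarray(shifts)
    summary = DatasetSummary(
        n_records=len(records),
        n_valid=len(mols),
        n_parse_failed=n_bad,
        n_distinct_molecules=len(set(canon)),
        n_scaffolds=len(scaffolds),
        scaffold_diversity_valid=len(scaffolds) / len(mols),
        scaffold_diversity_entries=len(scaffolds) / len(records),
        heavy_atoms_mean=float(heavy.mean()),
        heavy_atoms_median=float(np.median(heavy)),
        heavy_atoms_max=int(heavy.max()),
        shift_min=float(shifts_arr.min()),
        shift_max=float(shifts_arr.max()),
        shift_mean=float(shifts_arr.mean()),
        n_element_types=len(elements),
    )
    fps = None
    if with_fingerprints:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = np.array([gen.GetFingerprintAsNumPy(m) for m in mols], dtype=np.uint8)
    return summary, fps
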