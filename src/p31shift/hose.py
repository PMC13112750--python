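"""Sphere-environment (HOSE-style) lookup baseline for ³¹P shifts.

Each phosphorus atom's bonded environment is encoded, sphere by sphere, as a
canonical rooted fragment SMILES of all atoms within *s* bonds of the focus
atom (stereochemistry excluded; formal charges kept). Prediction is a table
lookup: training shifts are averaged per (sphere, code); a query is matched at
the deepest available sphere, falling back 4 → 3 → 2 → 1, and fails explicitly
when even the first sphere is unseen. Failure is a value, not an error, and
error metrics are computed only over successful matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .io import ShiftRecord, try_parse

DEFAULT_MAX_SPHERE = 4


def hose_code(mol: Chem.Mol, atom_index: int, sphere: int) -> str:
    """Canonical code for the ≤``sphere``-bond environment of one atom.

    Invariant to input atom ordering (canonical fragment SMILES rooted at the
    focus atom). Boundary atoms appear with their true implicit-H counts but
    without open-valence markers.
    """
    if not (0 <= atom_index < mol.GetNumAtoms()):
        raise IndexError(f"atom index {atom_index} out of range")
    if sphere < 1:
        raise ValueError("sphere must be >= 1")
    # enforceSize=False: for molecules smaller than the sphere, take the
    # largest available environment instead of an empty one
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, sphere, atom_index, enforceSize=False)
    atoms = {atom_index}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(atoms),
        bondsToUse=list(bond_ids),
        rootedAtAtom=atom_index,
        canonical=True,
        isomericSmiles=False,
    )


@dataclass
class HoseTable:
    """Sphere-indexed map: code -> (mean shift / ppm, support count)."""

    spheres: dict[int, dict[str, tuple[float, int]]]
    max_sphere: int

    @property
    def n_codes(self) -> int:
        return sum(len(t) for t in self.spheres.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"max_sphere": self.max_sphere,
                        "spheres": {str(s): t for s, t in self.spheres.items()}})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HoseTable":
        blob = json.loads(Path(path).read_text())
        spheres = {
            int(s): {c: (float(v[0]), int(v[1])) for c, v in t.items()}
            for s, t in blob["spheres"].items()
        }
        return cls(spheres, int(blob["max_sphere"]))


@dataclass(frozen=True)
class HosePrediction:
    """Either a predicted shift with its matched sphere/support, or a failure."""

    record_id: str
    shift_ppm: float | None
    sphere: int | None
    support: int | None

    @property
    def failed(self) -> bool:
        return self.shift_ppm is None


def build_table(records: list[ShiftRecord], max_sphere: int = DEFAULT_MAX_SPHERE) -> HoseTable:
    """Accumulate per-code running means over every training phosphorus atom."""
    if not records:
        raise ValueError("empty training set")
    acc: dict[int, dict[str, list[float]]] = {s: {} for s in range(1, max_sphere + 1)}
    for rec in records:
        mol = try_parse(rec.smiles)
        if mol is None:
            continue
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() != 15:
                continue
            for s in range(1, max_sphere + 1):
                code = hose_code(mol, atom.GetIdx(), s)
                acc[s].setdefault(code, []).append(rec.shift_ppm)
    spheres = {
        s: {code: (float(np.mean(v)), len(v)) for code, v in table.items()}
        for s, table in acc.items()
    }
    return HoseTable(spheres, max_sphere)


def predict_hose(table: HoseTable, mol: Chem.Mol, record_id: str = "") -> HosePrediction:
    """Deepest-sphere lookup per phosphorus atom, averaged across P atoms.

    The molecule fails when any of its phosphorus atoms matches no sphere
    down to 1.
    """
    shifts, spheres, supports = [], [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 15:
            continue
        hit = None
        for s in range(table.max_sphere, 0, -1):
            code = hose_code(mol, atom.GetIdx(), s)
            entry = table.spheres.get(s, {}).get(code)
            if entry is not None:
                hit = (entry[0], s, entry[1])
                break
        if hit is None:
            return HosePrediction(record_id, None, None, None)
        shifts.append(hit[0])
        spheres.append(hit[1])
        supports.append(hit[2])
    if not shifts:
        return HosePrediction(record_id, None, None, None)
    return HosePrediction(record_id, float(np.mean(shifts)), min(spheres), min(supports))


def predict_records(table: HoseTable, records: list[ShiftRecord]) -> list[HosePrediction]:
    out = []
    for rec in records:
        mol = try_parse(rec.smiles)
        if mol is None:
            out.append(HosePrediction(rec.record_id, None, None, None))
        else:
            out.append(predict_hose(table, mol, rec.record_id))
    return out


def failure_rate(predictions: list[HosePrediction]) -> float:
    """Percentage of failed predictions (0–100)."""
    if not predictions:
        raise ValueError("empty prediction list")
    return 100.0 * sum(p.failed for p in predictions) / len(predictions)


def hose_metrics(
    records: list[ShiftRecord], predictions: list[HosePrediction]
) -> dict[str, float | None]:
    """MAE/RMSE over successes only, plus the failure rate in percent."""
    truth = {r.record_id: r.shift_ppm for r in records}
    pairs = [(truth[p.record_id], p.shift_ppm) for p in predictions if not p.failed]
    rate = failure_rate(predictions)
    if not pairs:
        return {"mae": None, "rmse": None, "failed_pct": rate, "n_success": 0}
    y = np.array([a for a, _ in pairs])
    yhat = np.array([b for _, b in pairs])
    return {
        "mae": float(np.mean(np.abs(y - yhat))),
        "rmse": float(np.sqrt(np.mean((y - yhat) ** 2))),
        "failed_pct": rate,
        "n_success": len(pairs),
    }
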