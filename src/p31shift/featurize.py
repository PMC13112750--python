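"""Node/edge/global descriptor blocks for heavy-atom molecular graphs.

29 named node descriptors (two of them one-hot groups), 9 edge descriptors
and 9 molecule-level descriptors are computed per graph. The two node one-hots
(formal charge over {−3…+3, other}; hybridization over {S, SP, SP2, SP3,
SP3D, SP3D2, other}) expand the realized node width to ``NODE_WIDTH`` = 42
columns; "29" counts named descriptors, not columns.

Feature blocks are standardized per dimension (subtract mean, divide by
population standard deviation) with statistics fitted on the training split
only; zero-variance dimensions divide by 1 so constant columns scale to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

from .elements import element_properties
from .io import ShiftRecord, parse_molecule

# --- descriptor registries ---------------------------------------------------

FORMAL_CHARGE_CHOICES = (-3, -2, -1, 0, 1, 2, 3)  # + "other" bucket
HYBRIDIZATIONS = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2")  # + "other"

#: the 29 named node descriptors, in table order
NODE_FEATURE_NAMES = (
    "atomic_number",
    "degree",
    "atomic_radius",
    "atomic_volume",
    "formal_charge",        # one-hot, 8 columns
    "covalent_radius",
    "vdw_radius",
    "dipole_polarizability",
    "electron_affinity",
    "electrophilicity",
    "electronegativity",
    "n_electrons",
    "n_neutrons",
    "chiral_tag",
    "in_ring",
    "aromatic",
    "hybridization",        # one-hot, 7 columns
    "mass",
    "explicit_valence",
    "total_valence",
    "ring_size",
    "gasteiger_charge",
    "n_rings",
    "is_phosphorus",
    "aromatic_bond_count",
    "sum_bond_orders",
    "heavy_neighbor_count",
    "non_carbon_neighbor_count",
    "charge_difference",
)

EDGE_FEATURE_NAMES = (
    "bond_type",
    "in_ring",
    "conjugated",
    "aromatic",
    "ring_size",
    "stereo",
    "rotatable",
    "abs_degree_difference",
    "sum_degrees",
)

GLOBAL_FEATURE_NAMES = (
    "n_nitrogen",
    "phosphorus_ratio",
    "formal_charge",
    "tpsa",
    "molar_refractivity",
    "n_aromatic_rings",
    "aromatic_atom_ratio",
    "average_mass",
    "n_aromatic_atoms",
)

_NODE_WIDTHS = {"formal_charge": len(FORMAL_CHARGE_CHOICES) + 1, "hybridization": len(HYBRIDIZATIONS) + 1}


def _slices(names: tuple[str, ...], widths: dict[str, int]) -> dict[str, slice]:
    out, col = {}, 0
    for name in names:
        w = widths.get(name, 1)
        out[name] = slice(col, col + w)
        col += w
    return out


#: column slice of each named descriptor within its block (one-hots grouped)
NODE_FEATURE_SLICES = _slices(NODE_FEATURE_NAMES, _NODE_WIDTHS)
EDGE_FEATURE_SLICES = _slices(EDGE_FEATURE_NAMES, {})
GLOBAL_FEATURE_SLICES = _slices(GLOBAL_FEATURE_NAMES, {})

NODE_WIDTH = NODE_FEATURE_SLICES[NODE_FEATURE_NAMES[-1]].stop
EDGE_WIDTH = len(EDGE_FEATURE_NAMES)
GLOBAL_WIDTH = len(GLOBAL_FEATURE_NAMES)

FEATURE_SLICES = {
    "node": NODE_FEATURE_SLICES,
    "edge": EDGE_FEATURE_SLICES,
    "global": GLOBAL_FEATURE_SLICES,
}


class GraphBuildError(ValueError):
    """A record cannot be turned into a usable molecular graph."""


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with feature blocks and the shift target.

    ``edge_index`` holds directed edges (2 × 2·n_bonds): each bond appears in
    both directions with identical features. ``u`` is the molecule-level
    feature vector. ``p_indices`` are the phosphorus node indices.
    """

    record_id: str
    x: np.ndarray            # (n_atoms, NODE_WIDTH)
    edge_index: np.ndarray   # (2, n_directed_edges) int
    edge_attr: np.ndarray    # (n_directed_edges, EDGE_WIDTH)
    u: np.ndarray            # (GLOBAL_WIDTH,)
    p_indices: np.ndarray    # (n_P,) int
    y: float                 # shift / ppm

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]

    def validate(self) -> None:
        if self.p_indices.size < 1:
            raise GraphBuildError(f"{self.record_id}: no phosphorus atom")
        if self.edge_index.size and self.edge_index.max() >= self.n_atoms:
            raise GraphBuildError(f"{self.record_id}: edge index out of range")
        for arr in (self.x, self.edge_attr, self.u):
            if not np.all(np.isfinite(arr)):
                raise GraphBuildError(f"{self.record_id}: non-finite feature value")


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _gasteiger(mol: Chem.Mol) -> list[float]:
    try:
        ComputeGasteigerCharges(mol)
        charges = []
        for a in mol.GetAtoms():
            q = a.GetDoubleProp("_GasteigerCharge") if a.HasProp("_GasteigerCharge") else 0.0
            charges.append(q if math.isfinite(q) else 0.0)
        return charges
    except Exception:
        return [0.0] * mol.GetNumAtoms()


def node_features(mol: Chem.Mol) -> np.ndarray:
    """Per-atom descriptor matrix, shape (n_atoms, NODE_WIDTH)."""
    ri = mol.GetRingInfo()
    charges = _gasteiger(mol)
    rows = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        props = element_properties(atom.GetSymbol())
        neighbors = atom.GetNeighbors()
        bonds = atom.GetBonds()
        row: list[float] = [
            float(atom.GetAtomicNum()),
            float(atom.GetDegree()),
            props["atomic_radius_pm"],
            props["atomic_volume_cm3"],
        ]
        row += _one_hot(atom.GetFormalCharge(), FORMAL_CHARGE_CHOICES)
        row += [
            props["covalent_radius_pm"],
            props["vdw_radius_pm"],
            props["dipole_polarizability_au"],
            props["electron_affinity_ev"],
            props["electrophilicity_ev"],
            props["electronegativity_pauling"],
            float(atom.GetAtomicNum() - atom.GetFormalCharge()),  # electrons
            props["neutrons"],
            float(int(atom.GetChiralTag())),
            float(atom.IsInRing()),
            float(atom.GetIsAromatic()),
        ]
        row += _one_hot(str(atom.GetHybridization()), HYBRIDIZATIONS)
        row += [
            atom.GetMass(),
            float(atom.GetExplicitValence()),
            float(atom.GetTotalValence()),
            float(ri.MinAtomRingSize(i)) if atom.IsInRing() else 0.0,
            charges[i],
            float(ri.NumAtomRings(i)),
            1.0 if atom.GetAtomicNum() == 15 else 0.0,
            float(sum(b.GetIsAromatic() for b in bonds)),
            float(sum(b.GetBondTypeAsDouble() for b in bonds)),
            float(len(neighbors)),
            float(sum(n.GetAtomicNum() != 6 for n in neighbors)),
            charges[i] - atom.GetFormalCharge(),
        ]
        rows.append(row)
    x = np.asarray(rows, dtype=np.float64)
    assert x.shape[1] == NODE_WIDTH
    return x


def edge_features(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge index (2, 2·n_bonds) and feature matrix (2·n_bonds, 9)."""
    ri = mol.GetRingInfo()
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        row = [
            bond.GetBondTypeAsDouble(),
            float(bond.IsInRing()),
            float(bond.GetIsConjugated()),
            float(bond.GetIsAromatic()),
            float(ri.MinBondRingSize(bond.GetIdx())) if bond.IsInRing() else 0.0,
            float(int(bond.GetStereo())),
            1.0 if (bond.GetBondType() == Chem.BondType.SINGLE and not bond.IsInRing()) else 0.0,
            float(abs(a.GetDegree() - b.GetDegree())),
            float(a.GetDegree() + b.GetDegree()),
        ]
        src += [a.GetIdx(), b.GetIdx()]
        dst += [b.GetIdx(), a.GetIdx()]
        feats += [row, row]
    if not feats:  # e.g. PH3: single heavy atom, no bonds
        return np.zeros((2, 0), dtype=np.int64), np.zeros((0, EDGE_WIDTH))
    return np.asarray([src, dst], dtype=np.int64), np.asarray(feats, dtype=np.float64)


def global_features(mol: Chem.Mol) -> np.ndarray:
    """Molecule-level descriptor vector of width 9 (heavy atoms only)."""
    n = mol.GetNumAtoms()
    n_arom = sum(a.GetIsAromatic() for a in mol.GetAtoms())
    return np.asarray(
        [
            float(sum(a.GetAtomicNum() == 7 for a in mol.GetAtoms())),
            sum(a.GetAtomicNum() == 15 for a in mol.GetAtoms()) / n,
            float(Chem.GetFormalCharge(mol)),
            Descriptors.TPSA(mol),
            Crippen.MolMR(mol),
            float(rdMolDescriptors.CalcNumAromaticRings(mol)),
            n_arom / n,
            float(np.mean([a.GetMass() for a in mol.GetAtoms()])),
            float(n_arom),
        ],
        dtype=np.float64,
    )


def build_graph(record: ShiftRecord) -> MolGraph:
    """Assemble a MolGraph from a record; raises GraphBuildError on failure."""
    try:
        mol = parse_molecule(record.smiles)
    except Exception as exc:
        raise GraphBuildError(f"{record.record_id}: {exc}") from exc
    p_idx = np.asarray(
        [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 15], dtype=np.int64
    )
    edge_index, edge_attr = edge_features(mol)
    graph = MolGraph(
        record_id=record.record_id,
        x=node_features(mol),
        edge_index=edge_index,
        edge_attr=edge_attr,
        u=global_features(mol),
        p_indices=p_idx,
        y=record.shift_ppm,
    )
    graph.validate()
    return graph


def build_graphs(records: list[ShiftRecord]) -> tuple[list[MolGraph], list[tuple[str, str]]]:
    """Build graphs for all records; returns (graphs, [(record_id, reason)] skipped)."""
    graphs, skipped = [], []
    for rec in records:
        try:
            graphs.append(build_graph(rec))
        except GraphBuildError as exc:
            skipped.append((rec.record_id, str(exc)))
    return graphs, skipped


# --- standardization ---------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-block standardization statistics (population std; zero-var → 1)."""

    node_mean: np.ndarray
    node_std: np.ndarray
    edge_mean: np.ndarray
    edge_std: np.ndarray
    global_mean: np.ndarray
    global_std: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: getattr(self, k).tolist() for k in self.__dataclass_fields__})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=np.float64) for k, v in d.items()})


def _fit_block(rows: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    if rows.size == 0:
        return np.zeros(width), np.ones(width)
    mean = rows.mean(axis=0)
    std = rows.std(axis=0)  # population std
    std[std == 0.0] = 1.0
    return mean, std


def fit_scaler(graphs: list[MolGraph]) -> ScalerParams:
    """Fit per-dimension statistics over all atoms/edges/molecules (train only)."""
    if not graphs:
        raise ValueError("cannot fit scaler on empty graph list")
    nodes = np.vstack([g.x for g in graphs])
    edges = [g.edge_attr for g in graphs if g.edge_attr.size]
    edge_rows = np.vstack(edges) if edges else np.zeros((0, EDGE_WIDTH))
    globals_ = np.vstack([g.u for g in graphs])
    nm, ns = _fit_block(nodes, NODE_WIDTH)
    em, es = _fit_block(edge_rows, EDGE_WIDTH)
    gm, gs = _fit_block(globals_, GLOBAL_WIDTH)
    return ScalerParams(nm, ns, em, es, gm, gs)


def apply_scaler(graph: MolGraph, params: ScalerParams) -> MolGraph:
    """Standardize one graph's blocks; structure unchanged, new arrays."""
    if graph.x.shape[1] != params.node_mean.shape[0]:
        raise ValueError("node width mismatch between graph and scaler")
    return replace(
        graph,
        x=(graph.x - params.node_mean) / params.node_std,
        edge_attr=(graph.edge_attr - params.edge_mean) / params.edge_std
        if graph.edge_attr.size
        else graph.edge_attr.copy(),
        u=(graph.u - params.global_mean) / params.global_std,
    )


def invert_scaler(graph: MolGraph, params: ScalerParams) -> MolGraph:
    """Inverse of :func:`apply_scaler` (affine round-trip)."""
    return replace(
        graph,
        x=graph.x * params.node_std + params.node_mean,
        edge_attr=graph.edge_attr * params.edge_std + params.edge_mean
        if graph.edge_attr.size
        else graph.edge_attr.copy(),
        u=graph.u * params.global_std + params.global_mean,
    )
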