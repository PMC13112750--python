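"""Download-free synthetic organophosphorus fixtures.

Homologous n-alkyl series of six parent classes (primary/secondary/tertiary
phosphines, phosphine oxides, phosphonium and protonated phosphonium salts)
are generated with shifts from the linear increment model

    δ = B + n_β·A_β + n_γ·A_γ + ε,   ε ~ N(0, sd²),

so every pipeline stage is testable without downloading the experimental
dataset. Default coefficients are the literature substituent increments for
each class, making fixture shifts chemically plausible; the default label
noise of 2 ppm emulates the 1–3 ppm solvent/condition variability typical of
aggregated experimental ³¹P shifts. Substituents are linear acyclic chains so
β/γ counting is unambiguous. The generator does not emulate the heavy tails
(−457…+800 ppm), ring-system diversity, or element breadth of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ShiftRecord

#: literature (B, A_beta, A_gamma) in ppm per parent class
LITERATURE_INCREMENTS = {
    "RPH2": (-163.5, 35.5, -7.0),
    "R2PH": (-99.0, 22.0, -10.0),
    "R3P": (-62.0, 13.5, -4.0),
    "R3PH+": (-3.2, 8.6, -3.0),
    "R4P+": (25.3, 3.7, -1.5),
    "R3PO": (36.2, 4.0, -1.0),
}

#: number of alkyl arms and SMILES assembly recipe per parent class
_PARENTS = {
    "RPH2": (1, lambda arms: f"{arms[0]}P"),
    "R2PH": (2, lambda arms: f"{arms[0]}P{arms[1]}"),
    "R3P": (3, lambda arms: f"{arms[0]}P({arms[1]}){arms[2]}"),
    "R3PO": (3, lambda arms: f"{arms[0]}P({arms[1]})(=O){arms[2]}"),
    "R3PH+": (3, lambda arms: f"{arms[0]}[PH+]({arms[1]}){arms[2]}"),
    "R4P+": (4, lambda arms: f"{arms[0]}[P+]({arms[1]})({arms[2]}){arms[3]}"),
}

DEFAULT_NOISE_SD = 2.0  # ppm


@dataclass(frozen=True)
class SeriesSpec:
    parent: str
    B: float
    A_beta: float
    A_gamma: float
    max_chain: int = 4
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parent not in _PARENTS:
            raise ValueError(f"unknown parent class {self.parent!r}; one of {list(_PARENTS)}")
        if self.max_chain < 1 or self.noise_sd < 0:
            raise ValueError("max_chain >= 1 and noise_sd >= 0 required")

    @classmethod
    def from_literature(cls, parent: str, **kwargs) -> "SeriesSpec":
        B, ab, ag = LITERATURE_INCREMENTS[parent]
        return cls(parent, B, ab, ag, **kwargs)


#: ring substituents with symmetric attachment atoms (first == last ring atom)
RING_ARMS = ("c1ccccc1", "C1CCCCC1")


def _member_smiles(parent: str, arms: tuple[str, ...]) -> str:
    n_arms, recipe = _PARENTS[parent]
    if len(arms) != n_arms:
        raise ValueError(f"{parent} needs {n_arms} arms")
    return recipe(list(arms))


def _increment_shift(B: float, A_beta: float, A_gamma: float, smiles: str) -> float:
    # count beta/gamma carbons on the assembled molecule so ring arms are
    # handled by the same topological rule as linear chains
    from .io import parse_molecule
    from .validate import count_beta_gamma

    n_beta, n_gamma = count_beta_gamma(parse_molecule(smiles))
    return B + n_beta * A_beta + n_gamma * A_gamma


def gen_increment_series(spec: SeriesSpec) -> list[ShiftRecord]:
    """Uniform n-alkyl homologs (all arms of equal length 1..max_chain)."""
    rng = np.random.default_rng(spec.seed)
    n_arms, _ = _PARENTS[spec.parent]
    records = []
    for ln in range(1, spec.max_chain + 1):
        smiles = _member_smiles(spec.parent, ("C" * ln,) * n_arms)
        shift = _increment_shift(spec.B, spec.A_beta, spec.A_gamma, smiles) + (
            rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
        )
        records.append(ShiftRecord(f"{spec.parent}_n{ln}", smiles, float(shift)))
    return records


_RANDOM_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "OC", "OCC", "OCCC",
    "NC", "N(C)C", "SC", "SCC", "F", "Cl", "C(F)(F)F", "[Si](C)(C)C",
)


def gen_random_organophosphorus(n: int, seed: int = 0) -> list[str]:
    """n valence-valid acyclic SMILES, each with one P center; seeded."""
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = np.random.default_rng(seed)
    forms = (
        lambda a, b, c: f"P({a})({b}){c}",          # trivalent
        lambda a, b, c: f"O=P({a})({b}){c}",        # P(V) oxide
        lambda a, b, c: f"C[P+]({a})({b}){c}",      # phosphonium
    )
    out = []
    for _ in range(n):
        form = forms[rng.integers(len(forms))]
        subs = [str(_RANDOM_SUBSTITUENTS[i]) for i in rng.integers(len(_RANDOM_SUBSTITUENTS), size=3)]
        out.append(form(*subs))
    return out


@dataclass
class ToyDataset:
    """Shuffled mixture of increment-model families with stored ground truth."""

    records: list[ShiftRecord]
    truth: dict[str, tuple[float, float, float]]     # family -> (B, A_beta, A_gamma)
    family_of: dict[str, str] = field(default_factory=dict)  # record_id -> family

    def __len__(self) -> int:
        return len(self.records)


def gen_toy_dataset(
    n: int,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    max_chain: int = 5,
    families: tuple[str, ...] = tuple(LITERATURE_INCREMENTS),
    ring_fraction: float = 0.0,
) -> ToyDataset:
    """n records drawn from the six families with mixed arm lengths and noise.

    Arms are linear chains by default (unambiguous β/γ counting); with
    ``ring_fraction`` > 0 each arm is, with that probability, a phenyl or
    cyclohexyl ring instead, giving the corpus scaffold diversity for
    scaffold-split testing. Shifts always follow the increment model applied
    to the assembled molecule's actual β/γ carbon counts.
    """
    if n < 10:
        raise ValueError("n >= 10 required")
    rng = np.random.default_rng(seed)
    records: list[ShiftRecord] = []
    family_of: dict[str, str] = {}
    for i in range(n):
        family = str(families[rng.integers(len(families))])
        B, ab, ag = LITERATURE_INCREMENTS[family]
        n_arms, _ = _PARENTS[family]
        arms = tuple(
            str(RING_ARMS[rng.integers(len(RING_ARMS))])
            if rng.random() < ring_fraction
            else "C" * int(rng.integers(1, max_chain + 1))
            for _ in range(n_arms)
        )
        smiles = _member_smiles(family, arms)
        shift = _increment_shift(B, ab, ag, smiles) + (
            rng.normal(0.0, noise_sd) if noise_sd else 0.0
        )
        rid = f"toy{i}"
        records.append(ShiftRecord(rid, smiles, float(shift)))
        family_of[rid] = family
    truth = {f: LITERATURE_INCREMENTS[f] for f in families}
    return ToyDataset(records, truth, family_of)
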