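"""Bundled element-level property snapshot used for node featurization.

The table (``data/element_properties.csv``) is a frozen snapshot of standard
reference values (Pauling electronegativities, Cordero covalent radii, Bondi
van der Waals radii, CRC electron affinities, Parr electrophilicity indices,
empirical atomic radii/volumes, most-abundant-isotope neutron counts).
Freezing the values in the package keeps featurization reproducible against
upstream data-source drift.

Elements missing from the snapshot impute 0.0 for every property and emit a
single warning per element.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from importlib import resources

import pandas as pd

#: property columns, in the order they enter the node-feature matrix
PROPERTY_COLUMNS = (
    "atomic_radius_pm",
    "atomic_volume_cm3",
    "covalent_radius_pm",
    "vdw_radius_pm",
    "dipole_polarizability_au",
    "electron_affinity_ev",
    "electrophilicity_ev",
    "electronegativity_pauling",
)

_warned: set[str] = set()


@lru_cache(maxsize=1)
def element_table() -> pd.DataFrame:
    """The bundled element-property table, indexed by element symbol."""
    with resources.files("p31shift.data").joinpath("element_properties.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("symbol")


def element_properties(symbol: str) -> dict[str, float]:
    """Property dict for one element; zero-imputed if the element is unknown."""
    table = element_table()
    if symbol not in table.index:
        if symbol not in _warned:
            warnings.warn(
                f"element {symbol!r} missing from the bundled property table; "
                "imputing 0 for its element-level descriptors",
                stacklevel=2,
            )
            _warned.add(symbol)
        return {col: 0.0 for col in PROPERTY_COLUMNS} | {"neutrons": 0.0}
    row = table.loc[symbol]
    out = {col: float(row[col]) for col in PROPERTY_COLUMNS}
    out["neutrons"] = float(row["neutrons"])
    return out
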