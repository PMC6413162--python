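"""Packaged reference tables for the 22-molecule gas-phase benchmark.

The package ships transcriptions of the published per-molecule results
for the MM → SCC-DFTB/3ob connection leg: molecule metadata with the
constant ΔA offsets, the equilibrium (FEP/BAR) results with their
convergence metrics, and the nonequilibrium (JAR/CRO) results.  These
serve as inputs for the classification and cross-check machinery; the
package does not (and cannot, without the original force fields) rerun
the underlying simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = ["ReferenceTables", "load_reference_tables"]

_N_MOLECULES = 22


@dataclass(frozen=True)
class ReferenceTables:
    """The three benchmark tables indexed by molecule label.

    ``molecules`` is indexed by integer molecule number 1..22;
    ``equilibrium`` likewise; ``nonequilibrium`` is indexed by string
    labels because two molecules have extra 5 ps-switch rows
    (``"8_5ps"``, ``"9_5ps"``).
    """

    molecules: pd.DataFrame
    equilibrium: pd.DataFrame
    nonequilibrium: pd.DataFrame

    def lookup(self, molecule: Union[int, str], table: str, column: str) -> float:
        """Fetch one printed cell.

        Parameters
        ----------
        molecule : int or str
            Molecule number 1..22, or a string label such as ``"8_5ps"``.
        table : str
            One of ``"molecules"``, ``"equilibrium"``, ``"nonequilibrium"``.
        column : str
            Column name within that table.
        """
        try:
            df = getattr(self, table)
        except AttributeError:
            raise KeyError(f"unknown table {table!r}") from None
        if not isinstance(df, pd.DataFrame):
            raise KeyError(f"unknown table {table!r}")
        key: Union[int, str] = molecule
        if table != "nonequilibrium" and isinstance(molecule, str):
            key = int(molecule)
        if table == "nonequilibrium" and isinstance(molecule, int):
            key = str(molecule)
        if key not in df.index:
            raise KeyError(f"molecule {molecule!r} not in table {table!r}")
        if column not in df.columns:
            raise KeyError(f"column {column!r} not in table {table!r}")
        return df.at[key, column]

    def offset(self, molecule: int) -> float:
        """Constant ΔA offset (kcal/mol) for one molecule."""
        return float(self.lookup(molecule, "molecules", "offset"))


def _data_dir() -> Path:
    return Path(resources.files("fescheck") / "data")


def load_reference_tables(path: Optional[Union[str, Path]] = None) -> ReferenceTables:
    """Load the packaged benchmark tables (or transcriptions at ``path``).

    Validates that all 22 molecules are present in each table.
    """
    base = Path(path) if path is not None else _data_dir()
    molecules = pd.read_csv(base / "molecules.tsv", sep="\t", comment="#")
    equilibrium = pd.read_csv(base / "equilibrium.tsv", sep="\t", comment="#")
    nonequilibrium = pd.read_csv(
        base / "nonequilibrium.tsv", sep="\t", comment="#", dtype={"molecule": str}
    )

    molecules["zinc_id"] = molecules["zinc_id"].astype(str).str.zfill(8)
    molecules = molecules.set_index("molecule")
    equilibrium = equilibrium.set_index("molecule")
    nonequilibrium = nonequilibrium.set_index("molecule")

    for name, df, expected in (
        ("molecules", molecules, _N_MOLECULES),
        ("equilibrium", equilibrium, _N_MOLECULES),
        ("nonequilibrium", nonequilibrium, _N_MOLECULES + 2),
    ):
        if len(df) != expected:
            raise ValueError(f"{name} table has {len(df)} rows, expected {expected}")
        if df.isna().any().any():
            raise ValueError(f"{name} table has missing cells")

    base_rows = [m for m in nonequilibrium.index if "_" not in m]
    if sorted(int(m) for m in base_rows) != list(range(1, _N_MOLECULES + 1)):
        raise ValueError("nonequilibrium table does not cover molecules 1..22")

    return ReferenceTables(
        molecules=molecules, equilibrium=equilibrium, nonequilibrium=nonequilibrium
    )
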