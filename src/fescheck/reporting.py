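"""Report rows, reference-table cross checks, and protocol bookkeeping.

The summary-row layout mirrors the benchmark tables: for each molecule
(or toy system) one row with the one-sided forward block (ΔA, Hyst,
σΔA, mean, σ, Π), the one-sided backward block (same six columns, ΔA
reported as a positive magnitude per the tables' convention), then the
two-sided block (ΔA, Hyst, σΔA) and the distribution overlap percent —
16 columns in the printed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

from .diagnostics import (
    ClassificationResult,
    ClassificationThresholds,
    DiagnosticsBundle,
    classify,
)
from .reference import ReferenceTables

__all__ = [
    "SUMMARY_COLUMNS",
    "build_summary_row",
    "CrossCheck",
    "table_cross_checks",
    "protocol_bookkeeping",
    "classify_reference_molecule",
    "classify_reference_set",
]

SUMMARY_COLUMNS = [
    "fw_delta_a",
    "fw_hyst",
    "fw_sigma_delta_a",
    "fw_mean",
    "fw_sigma",
    "fw_pi",
    "bw_delta_a",
    "bw_hyst",
    "bw_sigma_delta_a",
    "bw_mean",
    "bw_sigma",
    "bw_pi",
    "two_sided_delta_a",
    "two_sided_hyst",
    "two_sided_sigma_delta_a",
    "overlap_percent",
]


def build_summary_row(
    fw_bundle: DiagnosticsBundle,
    fw_delta_a: float,
    bw_bundle: DiagnosticsBundle,
    bw_delta_a: float,
    two_sided_bundle: DiagnosticsBundle,
    two_sided_delta_a: float,
    overlap: float,
) -> pd.Series:
    """Assemble one 16-column report row in the printed column order.

    ``fw_delta_a``/``bw_delta_a`` are the one-sided estimates in each
    direction's native sign; the backward value is reported as a
    positive magnitude, matching the reference tables.  Any missing
    (NaN) metric raises, naming the offending column.
    """
    row = pd.Series(
        {
            "fw_delta_a": fw_delta_a,
            "fw_hyst": fw_bundle.hysteresis,
            "fw_sigma_delta_a": fw_bundle.sigma_delta_a,
            "fw_mean": fw_bundle.mean,
            "fw_sigma": fw_bundle.sigma,
            "fw_pi": fw_bundle.pi_value,
            "bw_delta_a": abs(bw_delta_a),
            "bw_hyst": bw_bundle.hysteresis,
            "bw_sigma_delta_a": bw_bundle.sigma_delta_a,
            "bw_mean": abs(bw_bundle.mean),
            "bw_sigma": bw_bundle.sigma,
            "bw_pi": bw_bundle.pi_value,
            "two_sided_delta_a": two_sided_delta_a,
            "two_sided_hyst": two_sided_bundle.hysteresis,
            "two_sided_sigma_delta_a": two_sided_bundle.sigma_delta_a,
            "overlap_percent": overlap,
        }
    )[SUMMARY_COLUMNS]
    for col, value in row.items():
        if not math.isfinite(value):
            raise ValueError(f"metric {col!r} is missing or non-finite")
    return row


@dataclass(frozen=True)
class CrossCheck:
    """One recomputed in-text arithmetic statement."""

    name: str
    computed: float
    quoted: float

    @property
    def discrepancy(self) -> float:
        return self.computed - self.quoted

    @property
    def consistent(self) -> bool:
        # quoted values are printed to 2 decimals (or rounded to integers
        # when prefixed "≈"); allow half a unit in the last quoted place
        step = 0.005 if self.quoted != round(self.quoted) else 0.5
        return abs(self.discrepancy) <= step + 1e-12


def table_cross_checks(tables: ReferenceTables) -> List[CrossCheck]:
    """Recompute the arithmetic cross-statements from the table cells.

    Each check takes printed cells from the packaged tables, performs
    the arithmetic stated in the benchmark's discussion, and records the
    computed value next to the quoted one.  Discrepancies are reported,
    never raised — two table/text conflicts are known and the tables are
    treated as canonical.
    """
    eq = tables.equilibrium
    ne = tables.nonequilibrium

    def e(mol: int, col: str) -> float:
        return float(eq.at[mol, col])

    def w(mol: str, col: str) -> float:
        return float(ne.at[mol, col])

    checks = [
        CrossCheck(
            "mol2_fep_fw_vs_cro_gap",
            abs(e(2, "fep_fw_delta_a") - w("2", "cro_delta_a")),
            16.32,
        ),
        CrossCheck(
            "mol2_mean_gap_fw_bw",
            abs(e(2, "fep_bw_mean")) - abs(e(2, "fep_fw_mean")),
            23.62,
        ),
        CrossCheck(
            "mol5_jar_fw_bw_disagreement",
            abs(w("5", "jar_fw_delta_a")) - abs(w("5", "jar_bw_delta_a")),
            1.66,
        ),
        CrossCheck(
            "mol6_fep_fw_bw_disagreement",
            abs(e(6, "fep_bw_delta_a")) - abs(e(6, "fep_fw_delta_a")),
            21.0,
        ),
        CrossCheck(
            "mol8_fep_fw_bw_disagreement",
            abs(e(8, "fep_fw_delta_a")) - abs(e(8, "fep_bw_delta_a")),
            6.0,
        ),
        CrossCheck(
            "mol9_jar_fw_bw_disagreement",
            abs(w("9", "jar_fw_delta_a")) - abs(w("9", "jar_bw_delta_a")),
            11.0,
        ),
    ]
    return checks


def _bundle_from_row(row: pd.Series, prefix: str, n: int = 10_000) -> DiagnosticsBundle:
    from .thermo import Thermo

    sigma = float(row[f"{prefix}_sigma"])
    return DiagnosticsBundle(
        mean=float(row[f"{prefix}_mean"]),
        sigma=sigma,
        hysteresis=float(row[f"{prefix}_hyst"]),
        sigma_delta_a=float(row[f"{prefix}_sigma_delta_a"]),
        pi_value=float(row[f"{prefix}_pi"]),
        sigma_over_kt=sigma / Thermo().kt,
        n=n,
    )


def classify_reference_molecule(
    tables: ReferenceTables,
    molecule: int,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ClassificationResult:
    """Good/bad/ugly verdict from a molecule's printed work metrics.

    Feeds the nonequilibrium table's 1 ps-switch columns (JAR fw/bw
    diagnostics, CRO diagnostics, overlap) to the classifier exactly as
    a pipeline run would.
    """
    row = tables.nonequilibrium.loc[str(molecule)]
    fw = _bundle_from_row(row, "jar_fw")
    bw = _bundle_from_row(row, "jar_bw")
    cro_bundle = DiagnosticsBundle(
        mean=float(row["jar_fw_mean"]),
        sigma=float(row["jar_fw_sigma"]),
        hysteresis=float(row["cro_hyst"]),
        sigma_delta_a=float(row["cro_sigma_delta_a"]),
        pi_value=float("nan"),
        sigma_over_kt=0.0,
        n=20_000,
        overlap_percent=float(row["overlap_percent"]),
    )
    return classify(
        fw, bw, float(row["jar_fw_delta_a"]), float(row["jar_bw_delta_a"]), cro_bundle, thresholds
    )


def classify_reference_set(
    tables: ReferenceTables,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> Dict[str, List[int]]:
    """Classify all 22 benchmark molecules from their printed metrics."""
    groups: Dict[str, List[int]] = {"good": [], "bad": [], "ugly": []}
    for molecule in sorted(int(m) for m in tables.nonequilibrium.index if "_" not in m):
        result = classify_reference_molecule(tables, molecule, thresholds)
        groups[result.label.value].append(molecule)
    return groups


def protocol_bookkeeping(
    runs: int, steps_per_run: int, save_every: int, switch_every: int
) -> Tuple[int, int]:
    """Frame and switch counts implied by an equilibrium/switching protocol.

    ``save_every`` is the restart-saving interval in dynamics steps,
    ``switch_every`` the switch-launch interval; the latter must be a
    multiple of the former (switches launch from saved frames).
    Returns ``(n_frames, n_switches)``.
    """
    for name, v in (
        ("runs", runs),
        ("steps_per_run", steps_per_run),
        ("save_every", save_every),
        ("switch_every", switch_every),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if switch_every % save_every != 0:
        raise ValueError("switch_every must be a multiple of save_every")
    if steps_per_run % save_every != 0 or steps_per_run % switch_every != 0:
        raise ValueError("intervals must divide steps_per_run")
    total = runs * steps_per_run
    return total // save_every, total // switch_every
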