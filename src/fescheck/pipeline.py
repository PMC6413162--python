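"""End-to-end toy pipeline: simulate → switch → estimate → diagnose → classify.

Glue that runs the full desk-scale protocol on one toy molecule and
collects everything a report row needs.  Default problem sizes mirror
the production protocol's ratios at roughly 1/100 the cost: 10^5
equilibrium steps saved every 10, switches of 10^3 steps launched from
every 5th saved frame (2000 per direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from .diagnostics import (
    ClassificationResult,
    ClassificationThresholds,
    DiagnosticsBundle,
    block_analysis_two_sided,
    classify,
    diagnose_one_sided,
    overlap_percent,
)
from .estimators import BarSolution, bar, cro, jar
from .io import Direction, EnergySeries, WorkSet
from .thermo import Thermo
from .toysim import ExactOracle, SwitchSchedule, ToyMolecule, exact_free_energy_gap, run_switches, sample_equilibrium

__all__ = ["ToyRunResult", "run_toy_pipeline"]


@dataclass
class ToyRunResult:
    """Everything the full pipeline computed for one toy molecule."""

    molecule: ToyMolecule
    thermo: Thermo
    seed: int
    eq_low: EnergySeries
    eq_high: EnergySeries
    work_fw: WorkSet
    work_bw: WorkSet
    jar_fw: float
    jar_bw: float
    cro_solution: BarSolution
    fw_bundle: DiagnosticsBundle
    bw_bundle: DiagnosticsBundle
    cro_bundle: DiagnosticsBundle
    overlap: float
    classification: ClassificationResult
    oracle: ExactOracle


def run_toy_pipeline(
    mol: ToyMolecule,
    seed: int = 0,
    thermo: Thermo = Thermo(),
    n_eq_steps: int = 100_000,
    save_every: int = 10,
    switch_steps: int = 1000,
    launch_every: int = 5,
    n_blocks: int = 10,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ToyRunResult:
    """Run the complete two-level protocol on one toy molecule.

    Seeds for the four stochastic stages (two equilibrium runs, two
    switch ensembles) are derived from ``seed`` so the whole pipeline is
    reproducible from a single integer.
    """
    eq_low = sample_equilibrium(
        mol, "low", n_steps=n_eq_steps, save_every=save_every, seed=seed * 4 + 0, thermo=thermo
    )
    eq_high = sample_equilibrium(
        mol, "high", n_steps=n_eq_steps, save_every=save_every, seed=seed * 4 + 1, thermo=thermo
    )
    work_fw = run_switches(
        mol,
        eq_low,
        SwitchSchedule(switch_steps, Direction.FORWARD),
        launch_every=launch_every,
        seed=seed * 4 + 2,
        thermo=thermo,
    )
    work_bw = run_switches(
        mol,
        eq_high,
        SwitchSchedule(switch_steps, Direction.BACKWARD),
        launch_every=launch_every,
        seed=seed * 4 + 3,
        thermo=thermo,
    )

    fw_bundle, jar_fw = diagnose_one_sided(work_fw.works, jar, thermo, n_blocks)
    bw_bundle, jar_bw = diagnose_one_sided(work_bw.works, jar, thermo, n_blocks)
    overlap = overlap_percent(work_fw.works, -work_bw.works)

    cro_total = cro(work_fw, work_bw, thermo)
    hyst, sigma_da, _ = block_analysis_two_sided(
        work_fw.works, work_bw.works, bar, thermo, n_blocks
    )
    cro_bundle = DiagnosticsBundle(
        mean=float(work_fw.works.mean()),
        sigma=float(work_fw.works.std(ddof=1)),
        hysteresis=hyst,
        sigma_delta_a=sigma_da,
        pi_value=float("nan"),
        sigma_over_kt=float(work_fw.works.std(ddof=1) / thermo.kt),
        n=len(work_fw) + len(work_bw),
        overlap_percent=overlap,
    )

    classification = classify(fw_bundle, bw_bundle, jar_fw, jar_bw, cro_bundle, thresholds)
    oracle = exact_free_energy_gap(mol, thermo)
    return ToyRunResult(
        molecule=mol,
        thermo=thermo,
        seed=seed,
        eq_low=eq_low,
        eq_high=eq_high,
        work_fw=work_fw,
        work_bw=work_bw,
        jar_fw=jar_fw,
        jar_bw=jar_bw,
        cro_solution=cro_total,
        fw_bundle=fw_bundle,
        bw_bundle=bw_bundle,
        cro_bundle=cro_bundle,
        overlap=overlap,
        classification=classification,
        oracle=oracle,
    )
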