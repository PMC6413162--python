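"""Convergence diagnostics for one- and two-sided free-energy estimates.

A free-energy estimate from exponential averaging is only trustworthy
when the underlying energy-gap or work distribution was sampled well
enough; this module implements the battery of heuristics used to judge
that:

* block analysis — split the data into contiguous blocks, compare the
  mean of the block estimates to the full-data estimate ("sample-size
  hysteresis", a bias indicator) and report the block standard
  deviation;
* distribution width — σ of the raw inputs relative to kT, with 4 kT as
  the absolute reliability threshold for one-sided estimators;
* overlap percentage — the area under the pointwise minimum of the
  forward and negated-backward densities;
* the Π bias heuristic — compares the sample size against the estimated
  dissipation of the unsampled direction; Π > 0.5 indicates a
  well-behaved one-sided distribution;
* good/bad/ugly classification — does the one-sided work estimator
  suffice, is a two-sided estimator needed, or does nothing converge;
* circular dihedral histograms — to diagnose conformational mismatch
  between levels of theory.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Tuple, Union

import numpy as np

from .estimators import ArrayLike, BarSolution, _as_finite_array
from .io import wrap_angle
from .thermo import Thermo

__all__ = [
    "DiagnosticsBundle",
    "ClassificationThresholds",
    "ClassificationResult",
    "Label",
    "CircularHistogram",
    "block_analysis",
    "block_analysis_two_sided",
    "overlap_percent",
    "pi_metric",
    "width_flag",
    "classify",
    "diagnose_one_sided",
    "circular_histogram",
    "population_shift",
]


@dataclass(frozen=True)
class DiagnosticsBundle:
    """All convergence metrics for one estimator on one input set."""

    mean: float
    sigma: float
    hysteresis: float
    sigma_delta_a: float
    pi_value: float
    sigma_over_kt: float
    n: int
    overlap_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.overlap_percent is not None and not (
            0.0 <= self.overlap_percent <= 100.0
        ):
            raise ValueError("overlap_percent must be in [0, 100]")


def _estimate(estimator: Callable, *args) -> float:
    out = estimator(*args)
    if isinstance(out, BarSolution):
        return out.delta_a
    return float(out)


def _block_slices(n: int, n_blocks: int) -> list[slice]:
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n < n_blocks:
        raise ValueError(f"need at least {n_blocks} values, got {n}")
    # contiguous equal-length blocks; a remainder shorter than a block
    # is dropped from the tail
    size = n // n_blocks
    return [slice(i * size, (i + 1) * size) for i in range(n_blocks)]


def block_analysis(
    values: ArrayLike,
    estimator: Callable[[np.ndarray, Thermo], float],
    thermo: Thermo,
    n_blocks: int = 10,
) -> Tuple[float, float, float]:
    """Sample-size hysteresis and block scatter of a one-sided estimate.

    Returns ``(hysteresis, sigma_delta_a, delta_a_total)`` where
    hysteresis is the signed difference mean(ΔA_i) - ΔA_total over the
    ``n_blocks`` contiguous blocks and sigma_delta_a is the sample
    standard deviation (n-1 denominator) of the block estimates.
    """
    x = _as_finite_array(values, "values")
    blocks = _block_slices(x.size, n_blocks)
    x = x[: (x.size // n_blocks) * n_blocks]  # drop tail remainder everywhere
    da_total = _estimate(estimator, x, thermo)
    da_blocks = np.array([_estimate(estimator, x[s], thermo) for s in blocks])
    return (
        float(da_blocks.mean() - da_total),
        float(da_blocks.std(ddof=1)) if n_blocks > 1 else 0.0,
        float(da_total),
    )


def block_analysis_two_sided(
    values_fw: ArrayLike,
    values_bw: ArrayLike,
    estimator: Callable[[np.ndarray, np.ndarray, Thermo], Union[float, BarSolution]],
    thermo: Thermo,
    n_blocks: int = 10,
) -> Tuple[float, float, float]:
    """Block analysis for two-sided estimators (BAR/CRO).

    Both input sets are blocked in parallel: block *i* of the estimate
    combines block *i* of the forward data with block *i* of the
    backward data.
    """
    fw = _as_finite_array(values_fw, "values_fw")
    bw = _as_finite_array(values_bw, "values_bw")
    fw_slices = _block_slices(fw.size, n_blocks)
    bw_slices = _block_slices(bw.size, n_blocks)
    fw = fw[: (fw.size // n_blocks) * n_blocks]
    bw = bw[: (bw.size // n_blocks) * n_blocks]
    da_total = _estimate(estimator, fw, bw, thermo)
    da_blocks = np.array(
        [_estimate(estimator, fw[sf], bw[sb], thermo) for sf, sb in zip(fw_slices, bw_slices)]
    )
    return (
        float(da_blocks.mean() - da_total),
        float(da_blocks.std(ddof=1)) if n_blocks > 1 else 0.0,
        float(da_total),
    )


def overlap_percent(
    samples_fw: ArrayLike,
    samples_bw_negated: ArrayLike,
    bins: int = 100,
) -> float:
    """Percentage overlap of two sample distributions.

    Both sets are histogrammed as probability densities on a common grid
    of ``bins`` equal-width bins spanning the union of their ranges; the
    result is 100 · Σ min(p_fw, p_bw) · Δx.  Backward samples must be
    pre-negated so both distributions live on the forward axis.
    """
    a = _as_finite_array(samples_fw, "samples_fw")
    b = _as_finite_array(samples_bw_negated, "samples_bw_negated")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        if a.min() == b.min():
            return 100.0  # all samples identical and coincident
        warnings.warn("zero-width common range; overlap undefined, returning 0")
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    dx = edges[1] - edges[0]
    return float(100.0 * np.minimum(pa, pb).sum() * dx)


def pi_metric(
    samples: ArrayLike,
    thermo: Thermo,
    delta_a_estimate: Optional[float] = None,
) -> float:
    """One-sided Π bias heuristic for an energy-gap or work distribution.

    Under a Gaussian model of the sampled distribution the dissipated
    work of the *unsampled* direction is W_dis = σ²/(2kT), and

        Π = sqrt(2 ln n) - sqrt(2 W_dis / kT).

    Larger is better; values above 0.5 indicate that the sample is large
    enough to compensate the estimator's intrinsic bias.  The Gaussian
    reconstruction uses only σ, so ``delta_a_estimate`` is accepted for
    interface symmetry but not consumed.
    """
    x = _as_finite_array(samples, "samples")
    if x.size < 2:
        raise ValueError("pi_metric requires at least 2 samples")
    kt = thermo.kt
    w_dis = x.std(ddof=1) ** 2 / (2.0 * kt)
    return float(np.sqrt(2.0 * np.log(x.size)) - np.sqrt(2.0 * w_dis / kt))


def width_flag(sigma: float, thermo: Thermo) -> Tuple[float, bool]:
    """Distribution-width reliability flag.

    Returns ``(sigma/kT, sigma <= 4 kT)``; beyond four thermal energies
    of spread a one-sided exponential average is considered untrustworthy
    regardless of the other metrics.  The boundary is inclusive.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    ratio = sigma / thermo.kt
    return float(ratio), bool(ratio <= 4.0)


class Label(str, enum.Enum):
    GOOD = "good"
    BAD = "bad"
    UGLY = "ugly"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the good/bad/ugly decision rule (all configurable).

    ``pi_min`` — minimum one-sided Π for a trustworthy forward work
    distribution; ``hyst_max`` — maximum |sample-size hysteresis| in
    kcal/mol; ``agreement_max`` — maximum forward/backward magnitude
    disagreement of the one-sided estimates in kcal/mol;
    ``overlap_min`` — minimum forward/backward work-distribution overlap
    (percent) for the two-sided estimator; ``cro_sigma_max`` — maximum
    block σΔA (kcal/mol) of the two-sided estimate, flagging block-level
    instability that hysteresis alone can miss.
    """

    pi_min: float = 0.5
    hyst_max: float = 1.0
    agreement_max: float = 1.0
    overlap_min: float = 5.0
    cro_sigma_max: float = 5.0

    def __post_init__(self) -> None:
        for name in ("hyst_max", "agreement_max", "overlap_min", "cro_sigma_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ClassificationResult:
    label: Label
    checks: Mapping[str, bool]
    thresholds: ClassificationThresholds


def classify(
    fw_bundle: DiagnosticsBundle,
    bw_bundle: DiagnosticsBundle,
    jar_fw: float,
    jar_bw: float,
    cro_bundle: DiagnosticsBundle,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ClassificationResult:
    """Good/bad/ugly classification from work-based diagnostics.

    *Good*: the one-sided forward work estimate alone is converged — its
    Π exceeds ``pi_min``, its |hysteresis| stays within ``hyst_max`` and
    the forward and backward one-sided estimates agree in magnitude
    within ``agreement_max``.  *Bad*: the one-sided estimates fail but
    the two-sided estimate passes (|hysteresis| within ``hyst_max``,
    block σΔA within ``cro_sigma_max``, overlap at least
    ``overlap_min``).  *Ugly*: even the two-sided estimate fails.

    ``jar_fw``/``jar_bw`` may be given in either the signed low→high
    convention or the positive-magnitude reporting convention; only
    their magnitudes are compared.
    """
    t = thresholds
    agreement = abs(abs(jar_fw) - abs(jar_bw))
    overlap = cro_bundle.overlap_percent
    if overlap is None:
        raise ValueError("cro_bundle must carry an overlap_percent")
    checks = {
        "jar_fw_pi": fw_bundle.pi_value > t.pi_min,
        "jar_fw_hyst": abs(fw_bundle.hysteresis) <= t.hyst_max,
        "jar_fw_bw_agreement": agreement <= t.agreement_max,
        "cro_hyst": abs(cro_bundle.hysteresis) <= t.hyst_max,
        "cro_sigma_delta_a": cro_bundle.sigma_delta_a <= t.cro_sigma_max,
        "cro_overlap": overlap >= t.overlap_min,
    }
    if checks["jar_fw_pi"] and checks["jar_fw_hyst"] and checks["jar_fw_bw_agreement"]:
        label = Label.GOOD
    elif checks["cro_hyst"] and checks["cro_sigma_delta_a"] and checks["cro_overlap"]:
        label = Label.BAD
    else:
        label = Label.UGLY
    return ClassificationResult(label=label, checks=checks, thresholds=t)


def diagnose_one_sided(
    values: ArrayLike,
    estimator: Callable[[np.ndarray, Thermo], float],
    thermo: Thermo,
    n_blocks: int = 10,
    overlap: Optional[float] = None,
) -> Tuple[DiagnosticsBundle, float]:
    """Full one-sided diagnostics bundle plus the total estimate."""
    x = _as_finite_array(values, "values")
    hyst, sigma_da, da_total = block_analysis(x, estimator, thermo, n_blocks)
    sigma = float(x.std(ddof=1)) if x.size > 1 else 0.0
    ratio, _ = width_flag(sigma, thermo)
    bundle = DiagnosticsBundle(
        mean=float(x.mean()),
        sigma=sigma,
        hysteresis=hyst,
        sigma_delta_a=sigma_da,
        pi_value=pi_metric(x, thermo) if x.size > 1 else float("nan"),
        sigma_over_kt=ratio,
        n=x.size,
        overlap_percent=overlap,
    )
    return bundle, da_total


@dataclass(frozen=True)
class CircularHistogram:
    """Normalized dihedral-angle histogram on [-180, 180)."""

    bin_edges: np.ndarray
    densities: np.ndarray  # probability density per degree
    n: int

    def __post_init__(self) -> None:
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.densities * widths))
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"densities integrate to {total}, not 1")


def circular_histogram(angles: ArrayLike, bin_width: float = 5.0) -> CircularHistogram:
    """Histogram dihedral angles (degrees) with bins aligned to -180.

    ``bin_width`` must divide 360 evenly; input angles are wrapped to
    [-180, 180) first.
    """
    x = wrap_angle(_as_finite_array(angles, "angles"))
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 360 evenly")
    edges = -180.0 + bin_width * np.arange(int(round(n_bins)) + 1)
    counts, _ = np.histogram(x, bins=edges)
    densities = counts / (x.size * bin_width)
    return CircularHistogram(bin_edges=edges, densities=densities, n=x.size)


def population_shift(hist_a: CircularHistogram, hist_b: CircularHistogram) -> float:
    """Overlap percentage of two dihedral populations on the same grid.

    Same pointwise-minimum kernel as :func:`overlap_percent`, evaluated
    on the circle; 100% means identical populations, 0% means the two
    levels of theory prefer disjoint angle ranges.
    """
    if hist_a.bin_edges.shape != hist_b.bin_edges.shape or not np.allclose(
        hist_a.bin_edges, hist_b.bin_edges
    ):
        raise ValueError("histograms are on different bin grids")
    widths = np.diff(hist_a.bin_edges)
    return float(100.0 * np.sum(np.minimum(hist_a.densities, hist_b.densities) * widths))
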