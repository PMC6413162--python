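"""Free-energy estimators for connecting two levels of theory.

Implements the four estimators used to evaluate the vertical
"connection legs" of an indirect (S)QM/MM thermodynamic cycle:

* ``fep``  — one-sided exponential averaging of instantaneous energy
  gaps, ΔA = -kT ln⟨exp(-ΔU/kT)⟩ (free energy perturbation);
* ``jar``  — the same functional applied to finite-time switching work
  (Jarzynski's equality);
* ``bar``  — Bennett's acceptance ratio, the optimal two-sided
  combination of forward and backward energy gaps via Fermi functions;
* ``cro``  — Crooks' equation, BAR with work values in place of energy
  gaps.

The MM→SQM gap carries a constant part of order 10^4–10^5 kcal/mol, so
every exponential average is evaluated through a mean-centred
log-sum-exp: inputs are shifted by their sample mean, the average is
taken in log space, and the shift is restored analytically.  This makes
each estimator exactly equivariant under constant offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .io import WorkSet
from .thermo import Thermo

__all__ = [
    "BarSolution",
    "ConvergenceError",
    "fep",
    "jar",
    "bar",
    "cro",
    "cumulant2",
    "compose_indirect_cycle",
    "exp_average_free_energy",
]

ArrayLike = Union[Sequence[float], np.ndarray]


class ConvergenceError(RuntimeError):
    """Raised when the Bennett self-consistency equation cannot be bracketed."""


@dataclass(frozen=True)
class BarSolution:
    """Solution of the Bennett/Crooks self-consistency equation.

    ``c_constant`` is the Bennett constant C = ΔA + kT ln(N_bw/N_fw) at
    which the forward and backward Fermi sums balance; ``residual`` is
    the remaining imbalance (kcal/mol) at the returned root.
    """

    delta_a: float
    c_constant: float
    iterations: int
    residual: float
    n_fw: int
    n_bw: int


def _as_finite_array(values: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def exp_average_free_energy(values: ArrayLike, thermo: Thermo) -> float:
    """-kT ln⟨exp(-x/kT)⟩ over the samples, via mean-centred log-sum-exp.

    Shared kernel of :func:`fep` and :func:`jar`; exactly shift
    equivariant: feeding ``values + c`` returns the result plus ``c``.
    """
    x = _as_finite_array(values, "values")
    kt = thermo.kt
    shift = x.mean()
    centred = x - shift
    return shift - kt * (logsumexp(-centred / kt) - np.log(x.size))


def fep(delta_u: ArrayLike, thermo: Thermo) -> float:
    """One-sided free energy from instantaneous energy gaps.

    ``delta_u`` are U_high - U_low evaluated on frames sampled at the
    low level (forward) or U_low - U_high on frames sampled at the high
    level (backward); the returned ΔA is in the direction of the input.
    """
    return exp_average_free_energy(delta_u, thermo)


def jar(work: Union[WorkSet, ArrayLike], thermo: Thermo) -> float:
    """Free energy from nonequilibrium switching work (Jarzynski).

    Accepts a :class:`~fescheck.io.WorkSet` or a bare array of work
    values.  A backward work set yields ΔA(high→low); the caller negates
    it when reporting in the low→high convention.
    """
    values = work.works if isinstance(work, WorkSet) else work
    return exp_average_free_energy(values, thermo)


def _bennett_imbalance(c: float, fw: np.ndarray, bw: np.ndarray, kt: float) -> float:
    # log sum_j f(bw_j + C) - log sum_i f(fw_i - C), with f the Fermi
    # function; log f(x) = -log(1 + exp(x/kT)) computed overflow-free.
    log_f_bw = -np.logaddexp(0.0, (bw + c) / kt)
    log_f_fw = -np.logaddexp(0.0, (fw - c) / kt)
    return logsumexp(log_f_bw) - logsumexp(log_f_fw)


def bar(
    delta_u_fw: ArrayLike,
    delta_u_bw: ArrayLike,
    thermo: Thermo,
    tol_kt: float = 1e-9,
    max_iterations: int = 200,
) -> BarSolution:
    """Bennett's acceptance ratio from forward and backward energy gaps.

    Parameters
    ----------
    delta_u_fw : array-like
        U_high - U_low on frames sampled at the low level.
    delta_u_bw : array-like
        U_low - U_high on frames sampled at the high level.
    thermo : Thermo
        Ensemble definition.
    tol_kt : float
        Root tolerance on the Bennett constant, in units of kT.
    max_iterations : int
        Iteration cap for the bracketed root search.

    Notes
    -----
    The Bennett constant C is located by bracketed root finding on the
    (strictly decreasing) log-imbalance of the two Fermi sums; the free
    energy is then assembled as ΔA = C - kT ln(N_bw/N_fw), which carries
    the sample-count correction when the two sets differ in size.
    Unequal sample counts are fully supported.
    """
    fw = _as_finite_array(delta_u_fw, "delta_u_fw")
    bw = _as_finite_array(delta_u_bw, "delta_u_bw")
    kt = thermo.kt

    # Pre-centre so the root search runs near zero even when the raw gap
    # sits at +-10^4 kcal/mol; restored exactly at the end.
    pooled = np.concatenate([fw, -bw])
    shift = pooled.mean()
    fw_c = fw - shift
    bw_c = bw + shift
    pooled_c = pooled - shift

    spread = pooled_c.std()
    # margin covers the count-ratio term, which can push the root outside
    # the sample range when one side has far more data
    margin = 10.0 * spread + kt * (2.0 + abs(math.log(bw.size / fw.size)))
    lo = pooled_c.min() - margin
    hi = pooled_c.max() + margin

    g_lo = _bennett_imbalance(lo, fw_c, bw_c, kt)
    g_hi = _bennett_imbalance(hi, fw_c, bw_c, kt)
    for _ in range(10):
        if g_lo >= 0.0 >= g_hi:
            break
        lo -= 4.0 * margin
        hi += 4.0 * margin
        g_lo = _bennett_imbalance(lo, fw_c, bw_c, kt)
        g_hi = _bennett_imbalance(hi, fw_c, bw_c, kt)
    else:
        raise ConvergenceError(
            f"no sign change for Bennett constant in [{lo + shift:.6g}, {hi + shift:.6g}]"
        )

    c_root, res = brentq(
        _bennett_imbalance,
        lo,
        hi,
        args=(fw_c, bw_c, kt),
        xtol=tol_kt * kt,
        rtol=8.881784197001252e-16,
        maxiter=max_iterations,
        full_output=True,
    )
    residual = abs(_bennett_imbalance(c_root, fw_c, bw_c, kt)) * kt
    delta_a = c_root + shift - kt * np.log(bw.size / fw.size)
    return BarSolution(
        delta_a=float(delta_a),
        c_constant=float(c_root + shift),
        iterations=int(res.iterations),
        residual=float(residual),
        n_fw=fw.size,
        n_bw=bw.size,
    )


def cro(
    work_fw: Union[WorkSet, ArrayLike],
    work_bw: Union[WorkSet, ArrayLike],
    thermo: Thermo,
    **kwargs,
) -> BarSolution:
    """Crooks' equation: BAR with nonequilibrium work replacing energy gaps.

    ``work_fw`` holds W(low→high), ``work_bw`` holds W(high→low) with
    its native sign.  With zero-length (instantaneous) switches the work
    values coincide with instantaneous energy gaps and ``cro`` reduces
    to :func:`bar` by construction — the solver is shared.
    """
    fw = work_fw.works if isinstance(work_fw, WorkSet) else work_fw
    bw = work_bw.works if isinstance(work_bw, WorkSet) else work_bw
    return bar(fw, bw, thermo, **kwargs)


def cumulant2(values: ArrayLike, thermo: Thermo) -> float:
    """Second-order cumulant estimate: mean - variance/(2 kT).

    Exact when the input distribution is Gaussian; for strongly
    non-Gaussian (e.g. bimodal) inputs it can deviate arbitrarily from
    the exponential average and serves only as a quick Gaussian-regime
    cross-check.
    """
    x = _as_finite_array(values, "values")
    if x.size < 2:
        raise ValueError("cumulant2 requires at least 2 samples")
    return float(x.mean() - x.var(ddof=1) / (2.0 * thermo.kt))


def compose_indirect_cycle(
    da0_low_high: float, da_low: float, da1_low_high: float
) -> float:
    """High-level free energy from the indirect cycle.

    ΔA(0→1, high) = -ΔA(0, low→high) + ΔA(0→1, low) + ΔA(1, low→high):
    the horizontal leg is evaluated at the cheap level and book-ended by
    the two vertical connection legs.
    """
    for name, v in (
        ("da0_low_high", da0_low_high),
        ("da_low", da_low),
        ("da1_low_high", da1_low_high),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return -da0_low_high + da_low + da1_low_high
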