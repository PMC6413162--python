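"""Two-level toy molecules, canonical sampling, and switching work.

This module emulates, at desk scale, the data-generating protocol of a
gas-phase connection-leg study: a molecule is described by two separable
potentials ("low" = cheap sampling level, "high" = accurate level)
built from harmonic *stiff* terms (bond/angle-like coordinates) and
periodic *dihedral* terms (Fourier series), plus a large constant energy
offset on the high level mimicking the ~10^4 kcal/mol gap between an MM
and an SQM total energy.  Mismatches between the levels — shifted
harmonic minima, different force constants, dihedral wells at different
angles with level-dependent barriers — reproduce the failure modes that
make one-sided estimators unreliable on real molecules.

Sampling is Metropolis Monte Carlo with per-coordinate local moves
(valid because the potentials are separable), which realises the exact
canonical distribution of the requested level; equilibrium runs
additionally mix in occasional uniform dihedral "jump" proposals so
multi-well dihedrals equilibrate across high barriers, mirroring the
randomized-dihedral restarts of a production protocol.  Switching runs
use local moves only: a finite-time switch cannot hop a high barrier,
which is precisely the physics being emulated.

Because every potential is separable, a quadrature oracle provides the
exact free-energy gap ΔA = -kT ln(Z_high/Z_low) to arbitrary precision,
giving ground truth against which the estimators are tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad

from .io import Direction, EnergySeries, Level, WorkSet, wrap_angle
from .thermo import Thermo

__all__ = [
    "HarmonicTerm",
    "FourierComponent",
    "DihedralTerm",
    "ToyMolecule",
    "SwitchSchedule",
    "ExactOracle",
    "mixed_energy",
    "sample_equilibrium",
    "run_switches",
    "exact_free_energy_gap",
    "gaussian_work_generator",
    "good_molecule",
    "bad_molecule",
    "ugly_molecule",
    "toy_fixtures",
]


@dataclass(frozen=True)
class HarmonicTerm:
    """One stiff coordinate: U_level(x) = 0.5 k_level (x - x0_level)^2.

    ``k`` in kcal/mol/unit^2, ``x0`` in the coordinate's unit (think of
    an Å bond length); both levels must be bound (k > 0).
    """

    k_low: float
    x0_low: float
    k_high: float
    x0_high: float

    def __post_init__(self) -> None:
        if self.k_low <= 0 or self.k_high <= 0:
            raise ValueError("harmonic force constants must be positive")


@dataclass(frozen=True)
class FourierComponent:
    """One dihedral Fourier component k (1 + cos(n χ - δ)), angles in degrees."""

    k: float
    n: int
    delta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class DihedralTerm:
    """One periodic coordinate with a Fourier series per level."""

    low: Tuple[FourierComponent, ...]
    high: Tuple[FourierComponent, ...]
    name: str = "chi"

    def __post_init__(self) -> None:
        object.__setattr__(self, "low", tuple(self.low))
        object.__setattr__(self, "high", tuple(self.high))
        if not self.low or not self.high:
            raise ValueError("each level needs at least one Fourier component")


def _fourier_energy(components: Sequence[FourierComponent], chi: np.ndarray) -> np.ndarray:
    e = np.zeros_like(chi, dtype=float)
    for c in components:
        e = e + c.k * (1.0 + np.cos(np.deg2rad(c.n * chi - c.delta)))
    return e


@dataclass(frozen=True)
class ToyMolecule:
    """Separable two-level potential: stiff + dihedral terms + constant offset.

    The coordinate vector concatenates the stiff coordinates (unbounded,
    in their natural units) followed by the dihedral angles (degrees,
    wrapped to [-180, 180)).  ``constant_offset`` (kcal/mol) is added to
    every high-level total energy.
    """

    stiff_terms: Tuple[HarmonicTerm, ...] = ()
    dihedral_terms: Tuple[DihedralTerm, ...] = ()
    constant_offset: float = 0.0
    name: str = "toy"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stiff_terms", tuple(self.stiff_terms))
        object.__setattr__(self, "dihedral_terms", tuple(self.dihedral_terms))
        if not self.stiff_terms and not self.dihedral_terms:
            raise ValueError("molecule needs at least one coordinate")
        if not math.isfinite(self.constant_offset):
            raise ValueError("constant_offset must be finite")

    @property
    def n_stiff(self) -> int:
        return len(self.stiff_terms)

    @property
    def n_dihedral(self) -> int:
        return len(self.dihedral_terms)

    @property
    def n_coords(self) -> int:
        return self.n_stiff + self.n_dihedral

    @property
    def dihedral_names(self) -> List[str]:
        names = []
        for i, term in enumerate(self.dihedral_terms, start=1):
            names.append(term.name if term.name != "chi" else f"chi{i}")
        return names

    # -- per-coordinate energies -------------------------------------------

    def per_coord_energy(self, x: np.ndarray, level: Level) -> np.ndarray:
        """Energy of each coordinate's own term, shape = x.shape.

        The constant offset is *not* included (it belongs to the total,
        not to any single coordinate).
        """
        x = np.asarray(x, dtype=float)
        e = np.zeros_like(x)
        for i, term in enumerate(self.stiff_terms):
            k, x0 = (
                (term.k_low, term.x0_low) if level is Level.LOW else (term.k_high, term.x0_high)
            )
            e[..., i] = 0.5 * k * (x[..., i] - x0) ** 2
        for j, term in enumerate(self.dihedral_terms):
            comps = term.low if level is Level.LOW else term.high
            e[..., self.n_stiff + j] = _fourier_energy(comps, x[..., self.n_stiff + j])
        return e

    def total_energy(self, x: np.ndarray, level: Level) -> np.ndarray:
        """Total potential energy at one level, including the offset on high."""
        e = self.per_coord_energy(x, Level(level)).sum(axis=-1)
        if Level(level) is Level.HIGH:
            e = e + self.constant_offset
        return e

    def u_low(self, x: np.ndarray) -> np.ndarray:
        return self.total_energy(x, Level.LOW)

    def u_high(self, x: np.ndarray) -> np.ndarray:
        return self.total_energy(x, Level.HIGH)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "name": self.name,
            "offset": self.constant_offset,
            "stiff": [
                {"k_low": t.k_low, "x0_low": t.x0_low, "k_high": t.k_high, "x0_high": t.x0_high}
                for t in self.stiff_terms
            ],
            "dihedrals": [
                {
                    "name": t.name,
                    "low": [{"k": c.k, "n": c.n, "delta": c.delta} for c in t.low],
                    "high": [{"k": c.k, "n": c.n, "delta": c.delta} for c in t.high],
                }
                for t in self.dihedral_terms
            ],
        }

    @classmethod
    def from_dict(cls, data: Dict) -> "ToyMolecule":
        stiff = tuple(HarmonicTerm(**t) for t in data.get("stiff", []))
        dihedrals = tuple(
            DihedralTerm(
                low=tuple(FourierComponent(**c) for c in t["low"]),
                high=tuple(FourierComponent(**c) for c in t["high"]),
                name=t.get("name", "chi"),
            )
            for t in data.get("dihedrals", [])
        )
        return cls(
            stiff_terms=stiff,
            dihedral_terms=dihedrals,
            constant_offset=float(data.get("offset", 0.0)),
            name=data.get("name", "toy"),
        )


@dataclass(frozen=True)
class SwitchSchedule:
    """λ path of a finite-time switch from one level to the other.

    λ runs monotonically 0 → 1 over ``n_steps`` increments (linear by
    default); the base level is the schedule direction's origin (low for
    forward switches, high for backward ones).
    """

    n_steps: int
    direction: Direction
    lambda_path: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        object.__setattr__(self, "direction", Direction(self.direction))
        path = self.lambda_path
        if path is None:
            path = np.linspace(0.0, 1.0, self.n_steps + 1)
        else:
            path = np.asarray(path, dtype=float)
            if path.size != self.n_steps + 1:
                raise ValueError("lambda_path must have n_steps + 1 points")
            if path[0] != 0.0 or path[-1] != 1.0 or np.any(np.diff(path) < 0):
                raise ValueError("lambda_path must run monotonically from 0 to 1")
        object.__setattr__(self, "lambda_path", path)


def mixed_energy(mol: ToyMolecule, x: np.ndarray, lam: float) -> np.ndarray:
    """Total energy of the λ-mixed Hamiltonian (1-λ) U_low + λ U_high."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return (1.0 - lam) * mol.u_low(x) + lam * mol.u_high(x)


def _proposal_scales(
    mol: ToyMolecule, thermo: Thermo, stiff_factor: float, dihedral_step: float
) -> np.ndarray:
    """Per-coordinate random-walk step widths.

    Stiff coordinates step a ``stiff_factor`` multiple of the thermal
    width of the stiffer level; dihedrals step ``dihedral_step`` degrees.
    Equilibrium sampling uses large moves (only the stationary ensemble
    matters); switching uses small ones emulating the limited relaxation
    of femtosecond-scale dynamics.
    """
    scales = np.empty(mol.n_coords)
    for i, t in enumerate(mol.stiff_terms):
        scales[i] = stiff_factor * math.sqrt(thermo.kt / max(t.k_low, t.k_high))
    scales[mol.n_stiff :] = dihedral_step
    return scales


def _dihedral_mask(mol: ToyMolecule) -> np.ndarray:
    mask = np.zeros(mol.n_coords, dtype=bool)
    mask[mol.n_stiff :] = True
    return mask


def _metropolis_sweep(
    per_coord_e,
    x: np.ndarray,
    e_cur: np.ndarray,
    scales: np.ndarray,
    dih_mask: np.ndarray,
    kt: float,
    rng: np.random.Generator,
    jump_prob: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """One per-coordinate Metropolis update; returns new (x, per-coord energies).

    ``per_coord_e`` maps a coordinate array to per-coordinate term
    energies.  Separability makes per-coordinate accept/reject exact.
    """
    prop = x + rng.standard_normal(x.shape) * scales
    if jump_prob > 0.0 and dih_mask.any():
        jump = (rng.random(x.shape) < jump_prob) & dih_mask
        prop = np.where(jump, rng.uniform(-180.0, 180.0, x.shape), prop)
    prop[..., dih_mask] = wrap_angle(prop[..., dih_mask])
    e_prop = per_coord_e(prop)
    accept = rng.random(x.shape) < np.exp(np.minimum(0.0, -(e_prop - e_cur) / kt))
    return np.where(accept, prop, x), np.where(accept, e_prop, e_cur)


def _initial_state(mol: ToyMolecule, level: Level, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(mol.n_coords)
    for i, t in enumerate(mol.stiff_terms):
        x[i] = t.x0_low if level is Level.LOW else t.x0_high
    # randomize all rotatable bonds before production
    x[mol.n_stiff :] = rng.uniform(-180.0, 180.0, mol.n_dihedral)
    return x


def sample_equilibrium(
    mol: ToyMolecule,
    level: Level | str,
    n_steps: int = 100_000,
    save_every: int = 10,
    seed: int = 0,
    thermo: Thermo = Thermo(),
    n_equilibration: int = 1000,
    jump_prob: float = 0.1,
    stiff_factor: float = 1.5,
    dihedral_step: float = 25.0,
) -> EnergySeries:
    """Canonical-ensemble trajectory at one level of theory.

    Runs a per-coordinate Metropolis chain whose stationary distribution
    is exactly ∝ exp(-U_level/kT); saves every ``save_every``-th
    configuration and records both levels' total energies, the dihedral
    angles, and the coordinates (so switches can be launched from the
    frames).  Deterministic for a fixed seed.

    ``jump_prob`` is the per-step probability of proposing a uniform
    random angle for each dihedral instead of a local move, keeping
    multi-well dihedrals ergodic even across high barriers.
    """
    level = Level(level)
    if n_steps < save_every:
        raise ValueError("n_steps must be >= save_every")
    if n_steps <= 0 or save_every <= 0:
        raise ValueError("step counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kt = thermo.kt
    scales = _proposal_scales(mol, thermo, stiff_factor, dihedral_step)
    dih_mask = _dihedral_mask(mol)

    def per_coord_e(x: np.ndarray) -> np.ndarray:
        return mol.per_coord_energy(x, level)

    x = _initial_state(mol, level, rng)
    e = per_coord_e(x)
    for _ in range(n_equilibration):
        x, e = _metropolis_sweep(per_coord_e, x, e, scales, dih_mask, kt, rng, jump_prob)

    n_frames = n_steps // save_every
    saved = np.empty((n_frames, mol.n_coords))
    frame = 0
    for step in range(1, n_frames * save_every + 1):
        x, e = _metropolis_sweep(per_coord_e, x, e, scales, dih_mask, kt, rng, jump_prob)
        if step % save_every == 0:
            saved[frame] = x
            frame += 1

    dihedrals = None
    if mol.n_dihedral:
        import pandas as pd

        dihedrals = pd.DataFrame(saved[:, mol.n_stiff :], columns=mol.dihedral_names)
    return EnergySeries(
        sampling_level=level,
        frame_index=np.arange(1, n_frames + 1) * save_every,
        u_low=mol.u_low(saved),
        u_high=mol.u_high(saved),
        dihedrals=dihedrals,
        coords=saved,
    )


def run_switches(
    mol: ToyMolecule,
    starts: EnergySeries,
    schedule: SwitchSchedule,
    launch_every: int = 5,
    seed: int = 0,
    thermo: Thermo = Thermo(),
    timestep_fs: float = 1.0,
    stiff_factor: float = 0.5,
    dihedral_step: float = 3.0,
) -> WorkSet:
    """Finite-time switching work from equilibrium start frames.

    Launches one switch from every ``launch_every``-th saved frame of
    ``starts`` and propagates local Metropolis dynamics on the λ-mixed
    potential while λ advances along the schedule.  Work accumulates in
    slow-growth form, W = Σ_j [U_{λ(j+1)}(x_j) - U_{λ(j)}(x_j)], which
    for the linear mixing equals Σ_j Δλ_j (U_target - U_base)(x_j).
    With ``n_steps = 1`` every work value is exactly the instantaneous
    energy gap at the start frame (the one-sided estimator limit).

    The default step sizes are deliberately small: one switching step
    stands in for roughly a femtosecond of Langevin dynamics, so a
    dihedral moves only a few degrees per step and cannot cross high
    barriers within a short switch — the physics behind one-sided
    estimator failure.

    Each switch uses an independent child random stream derived from
    ``(seed, switch index)``, so the set of switches is independent of
    evaluation order.
    """
    if starts.coords is None:
        raise ValueError("starts must carry coordinates (run sample_equilibrium)")
    base_level = Level.LOW if schedule.direction is Direction.FORWARD else Level.HIGH
    if starts.sampling_level is not base_level:
        raise ValueError(
            f"{schedule.direction.value} switches must start from "
            f"{base_level.value}-level sampling, got {starts.sampling_level.value}"
        )
    if launch_every < 1:
        raise ValueError("launch_every must be >= 1")

    x = np.array(starts.coords[::launch_every], dtype=float)
    n_switch = x.shape[0]
    kt = thermo.kt
    scales = _proposal_scales(mol, thermo, stiff_factor, dihedral_step)
    dih_mask = _dihedral_mask(mol)
    path = schedule.lambda_path

    # per-switch child streams, merged into one vectorized ensemble
    children = np.random.SeedSequence(seed).spawn(n_switch)
    n_steps = schedule.n_steps
    normals = np.empty((n_switch, n_steps, mol.n_coords))
    uniforms = np.empty((n_switch, n_steps, mol.n_coords))
    for j, ss in enumerate(children):
        rng_j = np.random.default_rng(ss)
        normals[j] = rng_j.standard_normal((n_steps, mol.n_coords))
        uniforms[j] = rng_j.random((n_steps, mol.n_coords))

    if base_level is Level.LOW:
        e_base_pc = mol.per_coord_energy(x, Level.LOW)
        gap_sign = 1.0
    else:
        e_base_pc = mol.per_coord_energy(x, Level.HIGH)
        gap_sign = -1.0

    def per_coord_mixed(xx: np.ndarray, lam: float) -> np.ndarray:
        e_low = mol.per_coord_energy(xx, Level.LOW)
        e_high = mol.per_coord_energy(xx, Level.HIGH)
        if base_level is Level.LOW:
            return (1.0 - lam) * e_low + lam * e_high
        return (1.0 - lam) * e_high + lam * e_low

    work = np.zeros(n_switch)
    e_cur = e_base_pc
    for j in range(n_steps):
        dlam = path[j + 1] - path[j]
        # instantaneous base→target gap, including the constant offset
        gap = gap_sign * (mol.u_high(x) - mol.u_low(x))
        work += dlam * gap
        lam_next = path[j + 1]
        prop = x + normals[:, j, :] * scales
        prop[:, dih_mask] = wrap_angle(prop[:, dih_mask])
        e_prop = per_coord_mixed(prop, lam_next)
        e_cur = per_coord_mixed(x, lam_next)
        accept = uniforms[:, j, :] < np.exp(np.minimum(0.0, -(e_prop - e_cur) / kt))
        x = np.where(accept, prop, x)

    end_dihedrals = None
    if mol.n_dihedral:
        import pandas as pd

        end_dihedrals = pd.DataFrame(x[:, mol.n_stiff :], columns=mol.dihedral_names)
    return WorkSet(
        direction=schedule.direction,
        switch_steps=n_steps,
        timestep_fs=timestep_fs,
        switch_id=np.arange(n_switch),
        works=work,
        end_dihedrals=end_dihedrals,
    )


@dataclass(frozen=True)
class ExactOracle:
    """Quadrature partition functions and the exact free-energy gap."""

    z_low: float
    z_high: float
    delta_a_exact: float


def _log_z_harmonic(k: float, x0: float, kt: float) -> float:
    sigma = math.sqrt(kt / k)
    val, err = quad(
        lambda x: math.exp(-0.5 * k * (x - x0) ** 2 / kt),
        x0 - 12 * sigma,
        x0 + 12 * sigma,
        limit=200,
        epsabs=0.0,
        epsrel=1e-11,
    )
    if err > 1e-9 * val:
        raise RuntimeError("harmonic quadrature did not converge")
    return math.log(val)


def _log_z_dihedral(components: Sequence[FourierComponent], kt: float) -> float:
    chi_grid = np.linspace(-180.0, 180.0, 721)
    umin = float(_fourier_energy(components, chi_grid).min())

    def boltz(chi: float) -> float:
        e = float(_fourier_energy(components, np.array(chi)))
        return math.exp(-(e - umin) / kt)

    val, err = quad(boltz, -180.0, 180.0, limit=400, epsabs=0.0, epsrel=1e-11)
    if err > 1e-9 * val:
        raise RuntimeError("dihedral quadrature did not converge")
    return math.log(val) - umin / kt


def exact_free_energy_gap(mol: ToyMolecule, thermo: Thermo = Thermo()) -> ExactOracle:
    """Exact ΔA(low→high) by per-coordinate quadrature.

    Separability factorises each level's configurational partition
    function into per-coordinate integrals (harmonic terms over ±12σ,
    dihedrals over the full period); the constant offset enters the gap
    additively.  Relative quadrature accuracy is driven below 1e-8.
    """
    kt = thermo.kt
    log_z_low = 0.0
    log_z_high = 0.0
    for t in mol.stiff_terms:
        log_z_low += _log_z_harmonic(t.k_low, t.x0_low, kt)
        log_z_high += _log_z_harmonic(t.k_high, t.x0_high, kt)
    for d in mol.dihedral_terms:
        log_z_low += _log_z_dihedral(d.low, kt)
        log_z_high += _log_z_dihedral(d.high, kt)
    delta_a = -kt * (log_z_high - log_z_low) + mol.constant_offset
    return ExactOracle(
        z_low=math.exp(log_z_low), z_high=math.exp(log_z_high), delta_a_exact=float(delta_a)
    )


def gaussian_work_generator(
    delta_a_true: float,
    w_dis: float,
    n: int,
    direction: Direction | str = Direction.FORWARD,
    seed: int = 0,
    thermo: Thermo = Thermo(),
    switch_steps: int = 1000,
) -> WorkSet:
    """Crooks-consistent Gaussian work samples.

    Forward work ~ N(ΔA + W_dis, 2 kT W_dis) and backward work
    ~ N(-ΔA + W_dis, 2 kT W_dis): this mean/variance pairing satisfies
    the work fluctuation theorem exactly in distribution, so forward and
    negated-backward densities cross at ΔA.  ``w_dis`` is the dissipated
    work per direction; ``w_dis = 0`` degenerates to every sample
    equalling ±ΔA.
    """
    if w_dis < 0:
        raise ValueError("w_dis must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    direction = Direction(direction)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean = (delta_a_true if direction is Direction.FORWARD else -delta_a_true) + w_dis
    sigma = math.sqrt(2.0 * thermo.kt * w_dis)
    works = mean + sigma * rng.standard_normal(n)
    return WorkSet(
        direction=direction,
        switch_steps=switch_steps,
        timestep_fs=1.0,
        switch_id=np.arange(n),
        works=works,
    )


# ---------------------------------------------------------------------------
# Packaged fixture molecules: the three convergence regimes
# ---------------------------------------------------------------------------


def good_molecule() -> ToyMolecule:
    """Near-identical levels: slight stiff mismatch, same dihedral well.

    Both levels prefer the same dihedral angle with similar barriers, so
    work distributions are narrow and one-sided work estimates converge.
    """
    return ToyMolecule(
        name="good",
        stiff_terms=(HarmonicTerm(k_low=100.0, x0_low=1.0, k_high=120.0, x0_high=1.01),),
        dihedral_terms=(
            DihedralTerm(
                low=(FourierComponent(k=1.5, n=1, delta=-120.0),),
                high=(FourierComponent(k=1.8, n=1, delta=-120.0),),
            ),
        ),
        constant_offset=15_000.0,
    )


def bad_molecule() -> ToyMolecule:
    """Shifted dihedral wells, moderate barriers: only two-sided converges.

    Three mismatched rotatable bonds: one whose single well slides from
    +60° (low) to +140° (high) over a ~3 kT barrier amplitude, a second
    sliding 120°, and a third with a two-well topology (+60°/-120°,
    ~6 kT barrier) that is nearly degenerate at the low level but
    strongly biased to -120° at the high level — forward switches
    starting in the "wrong" well sometimes cross and sometimes stall,
    which broadens and skews the forward work distribution.  Stiff
    mismatches add baseline width.  One-sided work estimates fail the
    Π criterion; pooling both directions still converges.
    """
    kt = Thermo().kt
    return ToyMolecule(
        name="bad",
        stiff_terms=(
            HarmonicTerm(k_low=100.0, x0_low=1.0, k_high=180.0, x0_high=1.05),
            HarmonicTerm(k_low=300.0, x0_low=2.0, k_high=390.0, x0_high=2.03),
        ),
        dihedral_terms=(
            DihedralTerm(
                low=(FourierComponent(k=0.9, n=1, delta=-120.0),),
                high=(FourierComponent(k=0.9, n=1, delta=-40.0),),
            ),
            DihedralTerm(
                low=(FourierComponent(k=1.5, n=1, delta=-180.0),),
                high=(FourierComponent(k=1.5, n=1, delta=-60.0),),
            ),
            DihedralTerm(
                low=(
                    FourierComponent(k=3.0 * kt, n=2, delta=-60.0),
                    FourierComponent(k=0.15, n=1, delta=-120.0),
                ),
                high=(
                    FourierComponent(k=3.0 * kt, n=2, delta=-60.0),
                    FourierComponent(k=2.0, n=1, delta=60.0),
                ),
            ),
        ),
        constant_offset=25_000.0,
    )


def ugly_molecule() -> ToyMolecule:
    """Shifted minima behind a ≥ 12 kT barrier: an unreachable well.

    The key dihedral shares a two-well topology (+60°/-120°) at both
    levels with a ~14 kT barrier, far above what a finite-time switch
    can cross; the low level locks the +60° well (the other essentially
    unvisited) while the high level prefers -120°.  Forward switches
    never reach the high level's dominant well, backward switches mostly
    start in it and stall, so forward and negated-backward work
    distributions barely overlap and even the two-sided estimator
    struggles.  Additional sliding dihedrals add realistic width.
    """
    kt = Thermo().kt
    barrier = 14.0 * kt  # ~8.3 kcal/mol
    return ToyMolecule(
        name="ugly",
        stiff_terms=(HarmonicTerm(k_low=100.0, x0_low=1.0, k_high=180.0, x0_high=1.05),),
        dihedral_terms=(
            DihedralTerm(
                low=(
                    FourierComponent(k=barrier / 2.0, n=2, delta=-60.0),
                    FourierComponent(k=3.0, n=1, delta=-120.0),
                ),
                high=(
                    FourierComponent(k=barrier / 2.0, n=2, delta=-60.0),
                    FourierComponent(k=0.9, n=1, delta=60.0),
                ),
            ),
            DihedralTerm(
                low=(FourierComponent(k=1.5, n=1, delta=-180.0),),
                high=(FourierComponent(k=1.5, n=1, delta=-60.0),),
            ),
            DihedralTerm(
                low=(FourierComponent(k=1.2, n=1, delta=60.0),),
                high=(FourierComponent(k=1.2, n=1, delta=160.0),),
            ),
        ),
        constant_offset=29_000.0,
    )


def toy_fixtures() -> Dict[str, ToyMolecule]:
    """The three packaged fixture molecules keyed by expected class."""
    return {"good": good_molecule(), "bad": bad_molecule(), "ugly": ugly_molecule()}
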