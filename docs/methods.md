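# Methods

## Conventions

Energies are kcal/mol, temperatures kelvin, angles degrees in
[−180, 180), timesteps femtoseconds. kB = 0.0019872041 kcal/mol/K and
the default bath is 300 K (kT ≈ 0.5962 kcal/mol). All ΔA, ΔU and W are
stored in the low→high direction for forward data and with their native
high→low sign for backward data; negation happens only inside an
estimator that requires it. Report rows mirror the benchmark tables'
convention of printing backward ΔA as positive magnitudes, but storage
never does. Large constant portions of the low→high gap are carried as
a per-molecule "offset" that is added to positive reported values and
subtracted from negative ones (zero maps to zero), so the interesting
digits stay visible next to a ~10⁴ kcal/mol baseline.

## Estimators

All exponential averages go through a mean-centred log-sum-exp: inputs
are shifted by their sample mean, averaged in log space, and the shift
restored analytically. This makes FEP and JAR *exactly* equivariant
under constant offsets and immune to overflow at MM→SQM energy scales.
FEP and JAR are literally the same kernel applied to energy gaps or
work values.

BAR/CRO solve for the Bennett constant C by bracketed root finding
(Brent) on the log-imbalance of the two Fermi-function sums, which is
strictly decreasing in C. The bracket spans the pooled, mean-centred
inputs ±(10σ plus a margin covering the sample-count term) and expands
geometrically if the root lies outside (relevant when one side has far
more data); tolerance is 10⁻⁹ kT on C, at most 200 iterations. The free
energy is assembled as ΔA = C − kT ln(N_bw/N_fw), which carries the
count correction exactly when N_bw ≠ N_fw (production protocols
routinely have 10× more low-level than high-level frames). The returned
solution records C, the iteration count and the residual imbalance.

No analytic estimator variance is reported; uncertainty comes only from
the block machinery below.

## Convergence battery

*Block analysis.* The data are cut into 10 contiguous equal blocks (a
tail remainder shorter than one block is dropped everywhere, so block
mean and total estimate see the same data). Hysteresis is the signed
difference mean(ΔA_block) − ΔA_total; σΔA is the n−1 standard deviation
of the block estimates. Two-sided estimators block both inputs in
parallel.

*Width.* σ of the raw inputs relative to kT, with σ ≤ 4 kT (boundary
inclusive) as the reliability flag for one-sided estimators.

*Overlap.* Both sample sets are histogrammed as densities on a common
grid of 100 equal-width bins (configurable) spanning the union of their
ranges; the overlap is 100·Σ min(p_fw, p_bw)·Δx. Backward samples must
be pre-negated onto the forward axis. The same pointwise-minimum kernel
serves for circular dihedral populations (default bin width 5°, bins
aligned to −180°).

*Π heuristic.* The implemented form is a Gaussian reconstruction: the
dissipated work of the unsampled direction is estimated as
W_dis = σ²/(2kT) and Π = √(2 ln n) − √(2 W_dis/kT), i.e. √(2 ln n) −
σ/kT. It is monotone in the right directions (up in n, down in σ) and
0.5 is the documented trust threshold. The published per-molecule Π
columns were produced by a formula that is not printed in full
anywhere we can recompute from, so numeric agreement with those columns
is *not* claimed or tested; the packaged tables simply carry the
printed values.

## Good/bad/ugly classification

Defaults (all configurable, always recorded in the output):

| criterion | threshold |
|---|---|
| one-sided forward Π | > 0.5 |
| one-sided \|hysteresis\| | ≤ 1 kcal/mol |
| fw/bw one-sided magnitude disagreement | ≤ 1 kcal/mol |
| two-sided \|hysteresis\| | ≤ 1 kcal/mol |
| two-sided block σΔA | ≤ 5 kcal/mol |
| two-sided overlap | ≥ 5 % |

*Good* = the three one-sided JAR criteria pass; *bad* = JAR fails but
the three two-sided CRO criteria pass; *ugly* = both fail. The
two-sided σΔA criterion is part of the rule because hysteresis alone
does not flag block-level instability: in the reference benchmark the
three molecules that defeat even CRO all show two-sided block σΔA of
7–10 kcal/mol while every merely "bad" molecule stays below 4.5, and
with this criterion the classifier reproduces the published 11/8/3
grouping exactly from the printed metrics. The 5 % overlap floor sits
between the ~9 % that the benchmark calls sufficient for a two-sided
method and the < 4 % cases called insufficient.

## Toy simulator

A toy molecule is a separable sum of harmonic "stiff" terms
U = ½k(x−x₀)² with level-dependent k and x₀, and periodic dihedral
terms Σ k_n(1 + cos(nχ − δ)) with level-dependent Fourier series, plus
a constant offset added to the high level. Separability is what makes
an exact oracle possible: each level's configurational partition
function factorises into per-coordinate integrals, evaluated by
adaptive quadrature (harmonic terms over ±12 thermal widths, dihedrals
over the full period, relative tolerance 10⁻¹¹ with a 10⁻⁹ convergence
guard), giving ΔA_exact = −kT ln(Z_high/Z_low) + offset.

*Dynamics.* Sampling is per-coordinate Metropolis Monte Carlo — exact
for separable potentials and guaranteeing the correct stationary
canonical distribution, which is the only property the estimators rely
on. Inertial Langevin dynamics is emulated, not replicated. Two move
regimes are used deliberately:

- **equilibrium runs** take large local steps (1.5 thermal widths;
  25° for dihedrals) plus, with probability 0.1 per dihedral per step, a
  uniform random-angle jump proposal. The jumps keep multi-well
  dihedrals ergodic across arbitrarily high barriers, standing in for
  the randomized-dihedral restarts and very long runs of a production
  protocol.
- **switching runs** take only small local steps (0.5 thermal widths;
  3° for dihedrals), so one Monte Carlo step stands in for roughly a
  femtosecond of Langevin dynamics. A 1000-step switch therefore cannot
  cross a high dihedral barrier — precisely the physics that makes
  one-sided estimators fail on real molecules. These step sizes are
  part of the model definition, not tuning knobs.

*Work accumulation.* λ runs 0→1 (linear by default, configurable
monotone path) and work accumulates in slow-growth form
W = Σ_j [U_{λ(j+1)}(x_j) − U_{λ(j)}(x_j)]; the energy-difference form is
used rather than a ∂U/∂λ integral because finite-time slow-growth
"energy differences" *are* nonequilibrium work values. A 1-step
schedule reduces every work value to the instantaneous gap at the start
frame, recovering the one-sided equilibrium estimator exactly. Each
switch draws from an independent child random stream spawned from
(seed, switch index), so switch ensembles are order-independent and can
be vectorised.

*Gaussian generator.* Forward work ~ N(ΔA + W_dis, 2 kT W_dis) and
backward work ~ N(−ΔA + W_dis, 2 kT W_dis) satisfy the work
fluctuation theorem exactly in distribution; forward and
negated-backward densities cross at ΔA. It exercises the regime where
the Π heuristic's Gaussian assumption is exact.

*Problem sizes.* The default desk-scale pipeline uses 10⁵ equilibrium
steps saved every 10 and 2000 switches of 1000 steps per direction —
the production protocol's launch ratios at roughly 1/100 the cost. The
full three-fixture pipeline runs in about half a minute on one CPU.

## Fixture molecules

Three packaged toys realise the convergence regimes, with offsets of
15,000–29,000 kcal/mol so every code path runs at realistic scales:

- **good** — near-identical levels: mild stiff mismatch, same dihedral
  well at both levels. Work distributions are narrow; JAR alone
  converges.
- **bad** — three mismatched rotatable bonds: wells sliding 80° and
  120° between levels over moderate barriers, plus a two-well dihedral
  (~6 kT barrier) nearly degenerate at the low level but strongly
  biased at the high level. Switches starting in the "wrong" well
  sometimes cross and sometimes stall, broadening the forward work
  distribution until Π fails while pooled two-sided data still
  converge.
- **ugly** — the two-well dihedral's barrier is raised to ~14 kT
  (≥ 12 kT, uncrossable in a 1000-step switch) and the levels lock
  opposite wells. Forward switches never reach the high level's
  dominant well; forward and negated-backward work densities barely
  overlap and even CRO becomes untrustworthy.

## What the toys do and do not show

The simulator reproduces the *mechanisms* of estimator failure —
stiff-mismatch broadening, dihedral population shifts, unreachable
wells, offset-dominated energy scales, Crooks-consistent work
statistics — with an exact ground truth. It does not reproduce coupled
anharmonic degrees of freedom, inertial dynamics, solvent, or real
force-field/SQM energetics; passing here validates the estimators and
diagnostics, not any claim about a particular real molecule. The
published per-molecule ΔA values in the packaged tables are inputs
(they require the original force fields and SQM method to regenerate),
used only for classification and arithmetic cross checks.

## Numerical notes and edge cases

- Empty inputs, non-finite values, duplicate switch ids and
  non-increasing frame indices are rejected at the container boundary,
  with row indices in the message where applicable.
- Text I/O writes 17 significant digits and parses with round-trip
  float precision, so write→read is bit-exact.
- Identical sample sets give exactly 100 % overlap; a zero-width common
  range returns 0 % with a warning.
- The two known internal inconsistencies between the benchmark's
  discussion text and its tables are resolved in favour of the tables;
  the cross-check report computes from table cells only and flags
  discrepancies instead of raising.
- Degenerate W_dis = 0 in the Gaussian generator returns exactly ±ΔA
  for every sample.
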