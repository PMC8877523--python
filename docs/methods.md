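# Methods

## Model

A polyampholyte is an ordered sequence of `N` unit charges `q_i = ±1` in
*favorable units*: `+1` is the species the applied field drives through the
pore for the chosen engagement direction (the anion cis→trans under +150 mV,
the cation trans→cis), `−1` the antagonistic species. Index 0 is the head —
the first monomer to exit on the receiving side. A chain engaged from the
other end is modelled by reversing the sequence.

The α-hemolysin channel is a 1D lattice of axial sites spaced by the monomer
size `a = 2 nm`; the pore proper holds five monomers, with one additional
tabulated boundary site at each end (sites `s = −1 … 5`, cis edge at `−1`).
The chain is rigid on this lattice: its configuration is a single offset
`x`, the net number of forward hops since engagement. Engagement (`x = 0`)
deploys the pore already filled — head at the far edge — which sidesteps any
entry-mechanism modelling. Total energy is the sum of independent
per-monomer terms

```
E(x) = Σ_i Φ_species(i)(s_i(x)),    s_i = (4+x)−i  (cis→trans),  i−x  (trans→cis)
```

with the cis bulk as the energy zero and the trans bulk at `+V` (cation) or
`−V` (anion), `V = e·150 mV / k_BT ≈ 5.84` at 298 K. Chain connectivity
enters only through the common offset; conformational entropy, monomer–
monomer interactions and any perturbation of the small-ion free energies by
the moving chain are neglected, which is defensible while the pore is filled
and at the high ionic strength typical of translocation experiments.

### The free-energy profile

The working per-species site energies derive from published per-ion
free-energy magnitudes for α-hemolysin under +150 mV (seven axial values per
species). Two conventions of that table required fixing, and we fixed them
once, by calibration against the reference single-sequence statistics (the
regular N = 20, Q = 8 benchmark sequence: 86 % success, mean 66 MCT from
10,000 trials):

1. **Axis orientation.** The tabulated positions are listed from the trans
   side. Read the other way, the cation row would *fall* toward the trans
   side — opposite to a +150 mV potential on trans — and every sequence
   would engage ~36 k_BT above its retracted state, making rejection
   dominant for all sequences (the benchmark row then yields 3.5 % success
   and mean 7.6×10⁴ MCT, two orders of magnitude off).
2. **Reference level.** Each species' row is expressed relative to the
   solution it is attracted toward; re-referencing both rows to the cis bulk
   (subtract the cis-edge value) makes each profile join its two bulk levels
   smoothly (cation: 0 → 5.46 vs bulk +5.84; anion: 0 → −5.80 vs bulk
   −5.84).

A systematic scan over axis/sign/reference/scale transformations shows this
reading is the unique one reproducing the reference statistics; it then
reproduces the *other* eight benchmark rows and all ensemble-level
observables with no further freedom. The resulting physics is exactly the
documented field asymmetry: the anion's driving force is localized over the
last two bonds at the trans edge, the cation's is spread along the channel.
Isolated antagonistic charges cross almost freely, while an antagonistic
block of length `b` faces a barrier of roughly `(b−1)·V` — which is why
`Qmin`, the minimum 5-monomer window charge, is the operational predictor of
trapping. `V = 5.84` (the physical value; `6.0` changes no conclusion) and
the profile are exposed in `PoreProfile` and via a TSV override.

### Dynamics and outcomes

Each Monte Carlo time step (MCT) proposes `Δx = ±1` with probability 1/2 and
accepts with the Metropolis probability `min(1, e^(−ΔE))`; the clock
advances on every attempt. One MCT is one attempted whole-chain hop (no
N-sweep convention). Absorbing states: translocation at `x = N+1` (tail
strictly past the pore), rejection at `x = −6` (head strictly past the cis
boundary site); transient offsets are `−5 … N`. A trial still transient
after `t_w` attempts (default `1.6×10⁵`; `10⁶` for deep-percentile studies)
is *trapped*; absorption exactly on the `t_w`-th attempt counts as absorbed.
Mean/SD translocation times are conditional on success — trapped and
rejected trials do not contribute — matching how the reference statistics
pair the time moments with a success rate.

### Random numbers

Per-trial seeds are derived counter-style (splitmix64) from the master seed,
a CRC key of the charge pattern, and the trial index. Batches are therefore
order-independent, two runs with the same seed are byte-identical, and
raising `t_w` is a pathwise continuation (a trial absorbed under a short
clock is absorbed identically under a longer one). The acceptance draw is
skipped for downhill moves; this changes the random stream, not the law.

## Exact solver

The dynamics is a birth–death chain on `N+6` transient states with
`p_x = ½·min(1, e^(−[E(x+1)−E(x)]))`, `q_x` mirrored, and a lazy remainder.
Splitting probabilities use the classical product-of-ratios formula with all
products in log space (landscape drops of ~100 k_BT would overflow linear
space). Absorption-time distributions iterate the occupancy vector for
`t_w` steps (numba-compiled, `O(t_w·N)`), conserving mass to < 10⁻¹²; this
is preferred over eigendecomposition because `t_w ≤ 10⁶` and ≤ 46 states
make direct iteration exact to round-off. Mean first-passage times solve the
tridiagonal first-step equations (`scipy.linalg.solve_banded`) with a
residual check; the conditional decomposition
`τ = P_tr·τ_tr + (1−P_tr)·τ_rej` holds by linearity and is verified to
10⁻⁸. For extremely steep landscapes the linear solve can be
ill-conditioned; the time-domain iteration is then the robust route and the
solver raises rather than returning a silently inaccurate mean.

## Synthetic ensembles

The generators produce exactly the study conditions: i.i.d. ±1 sites
(unbiased ensemble, `⟨Q⟩ = 0`), composition shuffles for exact-`Q`
subensembles (conditioning on `Q` is exact, not by rejection), and full
enumeration for small subensembles (e.g. all 190 sequences with `Q = 16`,
`N = 20`). They emulate *sequence* disorder only: real IDPs have correlated
charge patterning, variable charge spacing along the backbone, and
conformational degrees of freedom that the 1D rigid-chain model deliberately
omits — so passing tests establishes the statistics of the lattice model,
not of any particular protein. Protein input is supported by reducing a
FASTA sequence to its charged residues (D,E → −1; K,R → +1; histidine
dropped by default because its protonation near neutral pH is ambiguous —
configurable).

## Problem sizes

The validation suite and `scripts/acceptance.py` use scaled-down ensembles
chosen so binomial errors sit well inside the tolerances: 5,000 random
N = 20 sequences × 4 trials (global fractions and percentile times), 2,000
N = 40 sequences × 2 trials, ≥ 2,000 descriptor-filtered Q = 10 shuffles × 5
trials (reverse direction), the complete Q = 16 subensemble × 100 trials,
and 10,000 trials for single-sequence statistics. The N = 40 translocated
fraction is dominated by rare high-`Q` sequences and is the noisiest
reported quantity (sequence-sampling SE ≈ 0.15 pp at this size). Tail
exponents are least-squares slopes on log–log axes over `t ∈ [10⁴, 10⁵]`
(global) with the engagement-transient first bin and bins with < 5 counts
excluded.

## Numerical conventions

* Histogram bin `k` covers `[k·δt − δt/2, k·δt + δt/2)`; reference binnings:
  δt = 1600 MCT (translocation PDFs), 20 MCT (rejection PDFs), 400 MCT
  (percentile tables), 1000 MCT (single-sequence PDFs).
* Outcome percentages use attempts (sequence × trial) as denominator; PDFs
  normalize by events of their own kind. Both are exposed.
* Percentile times report the smallest grid multiple of δt at which the
  cumulative translocated fraction of all attempts reaches the target;
  fractions beyond ~9 % need `t_w = 10⁶` to be reachable.
* Zero-event conditional moments are NaN, never zero.

## Known limitations

* No continuous-space interpolation of the profile, no field perturbation of
  the ion free energies, no partial-chain or kinetic-MC moves.
* The Sinai-regime scaling of neutral infinite chains (`⟨n²⟩ ~ (log t)⁴`)
  has no finite-pore analogue here and is out of scope; the theory module
  covers the finite-`μ` closed forms only.
* The effective theory drive `U` matching the pore simulations is below the
  bare `V` (the drop is spread over several bonds for one species); no
  hard-coded mapping between the two is assumed.
* Aggregation/complexation of polyampholytes and pore conductivity are not
  modelled.
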