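# Methods

## Scope and model family

`grncompare` compares three deterministic, continuous formalisms for
dynamic gene-regulatory-network (GRN) models of N genes, each written
as N coupled ODEs for the gene-product concentrations X_i(t):

* **ANN** (recurrent-network rate law):
  `dX_i/dt = v_i f(Σ_j w_ij X_j − ϑ_i) − k_i X_i`, with f a sigmoid.
  Additive input processing; production bounded in (0, v_i).
* **S-system** (power-law kinetics):
  `dX_i/dt = α_i Π_j X_j^g_ij − β_i Π_j X_j^h_ij`.
  Multiplicative input processing; unbounded rates; negative kinetic
  orders create singularities as the regulator concentration
  approaches zero.
* **GRLOT** (general rate law of transcription):
  `dX_i/dt = v_i Π_j Ki_j^n/(I_j^n+Ki_j^n) · Π_k A_k^n/(A_k^n+Ka_k^n) − k_i X_i`.
  One Hill-type factor in (0, 1) per regulator; activator and
  inhibitor forms are complements.

The sigmoid f is the standard logistic `1/(1+e^(−x))`; it is a single
swappable function (`grncompare.models.SIGMOID`, or the `sigmoid`
argument of `ann_rate`), since the rate law itself only requires some
sigmoidal transfer.  Power-law bases are floored at 1e−12 before
exponentiation so that fractional powers of (numerically) non-positive
states stay real; a non-positive concentration combined with a
negative kinetic order still raises an explicit singularity error in
the direct `ss_rate` API, while integration paths use a guarded
variant and rely on blow-up detection instead.

## Reference cases and study conditions

Cases A–C are 5-gene networks with hand-chosen parameters in all three
formalisms (a uniform cascade; a branched cascade with asymmetric
co-regulation; the same plus a positive X3→X2 and a negative X5⊣X2
feedback loop).  All constructed models use degradation 0.3 per gene
(β_i in the S-system, with the degradation kinetic order fixed at 1 on
the diagonal) and an input gene X1 without regulators whose decay
drives the network.  Cases D (3-gene ANN oscillator) and E (5-gene
power-law benchmark) have fixed topologies but their literature
parameter values are not bundled; the builders raise until values are
supplied, rather than guessing.  Case F is the synthetic-yeast network
(CBF1, GAL4, SWI5, GAL80, ASH1); only the preprocessing contract for
its published switch-on/switch-off expression tables is implemented
(restrict to the window (10, 100] minutes: the first 10-minute
interval covers the medium shift, and after 100 minutes the system is
externally perturbed).

Training data are noise-free model outputs sampled on 200 evenly
spaced points.  The time horizon is not part of the printed study
conditions; the package fixes t_end = 20 time units — about six
degradation time constants at rate 0.3, long enough to cover the
transient and the approach to steady state — and records it in every
dataset's metadata.  The *sparse* dataset uses starting set 1 only,
the *detailed* dataset all five printed starting sets.  A
multiplicative-Gaussian noise hook exists for extensions but defaults
off.  Datasets are integrated with an adaptive explicit Runge–Kutta
4(5) scheme (rtol 1e−7, atol 1e−9; tightened from the conventional
1e−6/1e−8 so that halving the tolerances moves no sampled
concentration of cases A–C by more than 1e−5).  Integration failures —
solver breakdown, non-finite states, |X| beyond 1e6 — return flagged
trajectories rather than exceptions.

## Reverse engineering

The estimation problem minimizes the squared deviation between
observed and simulated trajectories with the network structure held
fixed: only parameters attached to edges of the known topology (plus
per-gene scalars) are searched.  A *node model* integrates one gene's
rate equation with all other genes supplied from the data
(piecewise-linear interpolation); a *network model* integrates the
full coupled system from the data's initial state only.  The two-phase
strategy first fits the N node models independently (bottom-up),
assembles the best ones into a network parameter vector, and then
refines the whole network with the assembled model seeding 10% of the
initial population (top-down).  Search intervals: ANN w ∈ [−15, 15],
v ∈ [0, 3], ϑ ∈ [0, 7], k ∈ [0, 2]; S-system g, h ∈ [−3, 3], α, β ∈
[0, 15]; GRLOT exponents ∈ [0, 7] (activator role) and [−5, 5]
(inhibitor role), K ∈ [1e−3, 40], k ∈ [0, 2], v ∈ [0, 3] (the GRLOT
maximal rate interval mirrors the ANN one; K has a positive floor to
keep the rate law finite).  The S-system degradation orders are
searched on the diagonal only, matching the constructed references.

### The evolutionary algorithm

Real-valued genotypes confined to the intervals above; per
generation: linear rank-based fitness assignment (selection pressure
1.8), roulette-wheel selection over rank scores, BLX-α blend crossover
(α = 0.5, rate 0.6), real-number creep mutation (rate 0.1 per
position, additive Gaussian with scale 5% of each bound width annealed
geometrically to 0.1% of that by the final generation), clipping to
bounds, and single-elite cloning.  Candidates whose simulation fails
receive a worst-fitness sentinel (1e30) instead of aborting the run.

The cloning/creep operator pair is additionally realized as three
*climber lineages*: creep-mutated clones of the current best
individual and of two roulette-selected individuals, eight clones per
lineage per generation, with each lineage's creep scale adapted by the
one-fifth success rule and stagnated lineages restarted from fresh
roulette picks.  This design decision addresses a property of these
estimation problems that plain blend crossover handles poorly: the
fitness landscapes contain long, curved, strongly correlated valleys
(for example α/β compensation in the S-system and v/ϑ/w compensation
in the ANN), plus broad quasi-steady-state impostor basins.  The
adaptive climbers descend such valleys to machine-level residuals once
a lineage enters the right basin, while the blended herd and the
restarts keep sampling basins; without this realization of the
operators, the blend-crossover herd alone tends to stall well above
the residual level at which parameters are pinned down.

Every optimization is repeated independently (five repeats by
default) and the best run is kept; repeats are the mechanism for
escaping local minima.  All randomness flows from a single seed
through spawned child generators, so any fit is exactly reproducible.

### Candidate scoring

EA fitness evaluation integrates candidates with a fixed-step
classic Runge–Kutta scheme on the sample grid, vectorized across the
whole population (and across trajectories), which is what makes
population-scale search affordable on one core.  Coarsely sampled
data are refined with internal sub-steps so that every trajectory is
integrated with roughly 200 steps regardless of its sampling density.
Verification and validation always re-simulate with the adaptive
integrator.

## Evaluation measures

* `p_fit(observed, predicted) = 1/(1+E)` with E the squared deviation
  averaged over all points and genes (trajectories pooled).  `P_ver`
  scores the training data, `P_val` unseen data; `ΔP_fit = P_val −
  P_ver`.  Narrative quality bands: < 0.9 very poor; 0.95–0.99 same
  range but possibly different patterns; > 0.99 converging; > 0.999
  highly accurate.  The 0.9–0.95 band ("poor") is an interpolation
  between the stated bands and is labelled as such.
* `p_inf = 0.5(1 + r)` with r the Pearson correlation between the
  reference and recovered parameter vectors.  The vectors concatenate
  all *free* parameters in a documented canonical order (per gene:
  ANN v, ϑ, k, then w by source; S-system α, β, g by source, h_kk;
  GRLOT v, k, then n, K per regulator); masked structural zeros are
  excluded so they cannot inflate the correlation.  P_inf is only
  defined within a method; cross-method cells report it as not
  computable and fall back to the qualitative comparison.
* Validation protocol: the input gene's degradation constant (k_1, or
  β_1 in the S-system) is set to 0.1 (raised input level) and 0.5
  (lowered input level) in both the reference and the fitted model;
  the perturbed reference generates the unseen data.  `P_val` is the
  arithmetic mean of the two condition scores, and both conditions
  are also reported separately.
* Qualitative features (`q_com`): uniform degradation — all
  degradation rates in [0.2, 0.4]; constant signal propagation —
  max/min signal-strength ratio < 2; asymmetric branching /
  co-regulation — relative difference of the two relevant signals
  > 20%; positive/negative feedback — sign of the X3→X2 / X5→X2
  signal.  Signal strength per method: |w| (ANN), |g| (S-system),
  Hill exponent n with the regulator role carrying the sign (GRLOT).
  Degradation rate for the S-system check is β_i.
* `relative_difference = Σ ((X − X̂)/X)²` for comparisons on
  biological data, where absolute scales differ between genes; the
  perturbation workflow normalizes it per point as `1/(1 + f/(pN))`
  so that self-comparison scores 1.

## Study orchestration

A study enumerates (case × generation method × density × inference
method) cells; each cell derives a stable sub-seed from the master
seed and the cell name (SHA-256 based), so single cells can be
recomputed in isolation and results are independent of worker count
(per-cell process parallelism via joblib is optional).  Cell failures
are recorded in the provenance file, never fatal.  Reports are CSV
tables: within-method cells with P_inf/P_ver/P_val/ΔP_fit, the full
cross grid with fitting scores, and the qualitative feature grid.

## Scaled-down reproduction regime

The full-scale configuration (population 500, 300 generations, five
repeats per node and network optimization) corresponds to roughly
150 000 candidate simulations per optimization.  The package's test
suite and the acceptance script run a desk-scale regime instead:
population 100, 100 generations, five repeats — about 1/75 of the
full-scale budget per run — with problem sizes otherwise unchanged
(5-gene cases, 200-point series).  Under this regime the within-method
recovery picture is reproduced qualitatively and most scores
quantitatively; the residual optimizer error is visible mainly in
validation scores of sparse-data cells, which are extremely sensitive
to small parameter errors (see limitations).

## Known limitations

* Parameter identifiability of sparse (single-trajectory) data is
  genuinely poor: different parameter vectors reproduce the training
  trajectory to high accuracy yet diverge under input perturbation.
  Validation scores of sparse cells therefore carry substantial
  run-to-run variance at desk scale.
* The original study's time horizon and expression-level ranges are
  not recoverable; all quantitative reproduction is defined relative
  to this package's own generated data under the conditions stated
  above.
* The S-system fitness landscape contains quasi-steady-state impostor
  optima (large α_i, β_i of similar magnitude) whose basin dwarfs the
  true parameters' basin under single-trajectory data; multi-
  trajectory (detailed) data largely removes them because a fast-
  relaxing candidate cannot match five different initial conditions.
* Biological-data fitting (case F) is supported structurally but the
  published expression tables are external and not bundled; nothing
  quantitative about that system is asserted by the tests.
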