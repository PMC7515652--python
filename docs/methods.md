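# Methods

`unbindkit` implements a protocol for estimating drug–receptor dissociation
kinetics and rate-limiting transition states from biased simulations. The
stages mirror how the protocol would run against a molecular-dynamics
engine; here every stage is exercised against a built-in overdamped-Langevin
toy simulator, so each claim the package makes is verifiable against closed
forms, dense-grid oracles or brute-force sampling.

## The toy simulator

The configurational landscape is an analytic Gaussian mixture,

    E(x) = -(1/β) log Σᵢ wᵢ N(x; μᵢ, Σᵢ),

integrated with Euler–Maruyama overdamped Langevin dynamics

    x ← x + (Δt/γ) F(x) + √(2Δt/(βγ)) ξ,   F = -∇E,  ξ ~ N(0, I).

The invariant measure is the Boltzmann density exp(−βE) for any friction γ,
which makes equilibrium statistics checkable in closed form (e.g. the
variance 1/(βκ) in a harmonic well), and the explicit γ keeps Kramers-rate
reasoning meaningful. The production protocol the package emulates uses a
thermostatted leap-frog integrator; overdamped dynamics is sufficient for
first-passage statistics and far easier to verify, which is the point of the
toy. Step sizes must satisfy Δt ≪ 2γ/κ_max for the stiffest curvature
κ_max of the surface; the packaged scenarios use Δt = 0.002–0.005 with
κ_max ≲ 20.

Well-tempered metadynamics deposits Gaussian hills along one or two linear
collective variables (CVs) s = A·x with effective height

    h_eff = h · exp(−V(s)/((γ_wt − 1) k_BT)),

where V(s) is the bias already accumulated at the walker's CV value and γ_wt
the bias factor. The bias is accumulated on a cached grid over CV space
(spacing ≤ hill width / 5, linear interpolation for values and forces), so
the per-step cost is independent of the number of hills. Consequences of the
grid: recorded hill heights follow the well-tempered schedule to within the
interpolation error of V at the hill centre (tests allow 3% relative), and
the bias is flat (zero force) outside the configured grid range. The
`temperature` field of `MetadParams` is expressed directly as an energy
(k_B ≡ 1) and defaults to 1/β of the surface.

Hill heights, widths, bias factors and deposition intervals default to the
protocol's published operating point (0.5 kJ/mol, width 0.05 in CV units,
γ_wt = 20, production intervals {20, 30, 50} ps). The published hill width
is unitless because the biased coordinate is a learned linear combination;
in this package widths are in the CV's own units and the desk-scale
configuration sets them to the toy-well geometry (width 0.12–0.15 for wells
of σ ≈ 0.25).

### Packaged study systems

* `double-well-1d` — two equal Gaussians at ±1 with σ = 0.24, β = 1, giving
  a barrier of ≈ 8 k_BT at the midpoint (barrier ≈ sep²/(8σ²)·(1/β) − ln 2 /β).
  This is the system for the hyperdynamics and committor checks; brute-force
  unbiased first passage to x > 1 takes ≈ 355 time units, reachable by
  direct sampling (500 runs) in seconds thanks to the compiled kernel.
* `three-state-2d` — a bound ground state (OS), a metastable vestibule-like
  intermediate (VRS) displaced off-axis, and a shallow dissociated state
  (DS), with mixture weights (0.55, 0.35, 0.10) chosen so the barrier
  ordering reproduces the two-step unbinding topology: the return barrier
  VRS→OS is the smallest, OS→VRS intermediate, VRS→DS the largest, making
  the final dissociation step rate-limiting.
* `planted-feature-blocks` — three independent smooth signals, five noisy
  copies each, for feature-selection recovery.

Synthetic feature channels for the 2-D scenarios are linear projections of
position (three redundant copies per direction, scale-jittered) plus
i.i.d. Gaussian noise of σ = 0.15. What the generator does **not** emulate:
non-linear feature–coordinate relationships, slow protein degrees of freedom
orthogonal to the CVs, multiple competing unbinding pathways with comparable
flux, and memory effects from inertial/solvent dynamics. Passing tests
therefore demonstrate correctness of the machinery and calibration of the
statistics under the model's own assumptions — not force-field accuracy on
a real receptor.

## Feature selection

Candidate features are compared by the information distance
d = 1 − I(X;Y)/H(X,Y) estimated from equal-width 2-D histograms (50 bins by
default; reduce for short series). d is symmetric, zero iff the joint
histogram is deterministic, and →1 under independence. Features are
clustered by k-medoids with deterministic farthest-point seeding (the most
central feature first), PAM-style alternation, and the cluster count chosen
as the sharpest elbow — the maximal second difference of distortion versus
k — capped at `max_clusters` (20 by default), smallest k among ties. A
single cluster with near-zero distortion short-circuits to k = 1 (all
features redundant). Constant series carry zero information by convention
and warn. Histogram MI needs ≳10 frames per feature to avoid strong
positive bias; the code warns below that.

## Learned reaction coordinate

The RC is the 1-D bottleneck of a predictive encoder–decoder: a linear
encoder z = w·x followed by two ELU layers of width K = 128 and a linear
output, trained full-batch with RMSprop (5000 epochs, learning rate 2·10⁻⁴
by default) to predict the features a short lag Δt ahead (2 ps by default).
Biased training data are reweighted per source frame with exp(βV(t)),
normalised within the batch — an approximation to the propagator-corruption
correction that is valid at short lags, which is why the default lag is
short. Design choices:

* Features are standardised (zero mean, unit variance) before training;
  reported coefficients refer to standardised features.
* Full-batch gradients keep training exactly reproducible for a fixed seed;
  with zero bias the reweighted objective is *identical* (bit-for-bit) to
  the unweighted one.
* The sign/scale degeneracy of w is resolved at reporting time: coefficients
  are rescaled to unit maximum magnitude, the largest-magnitude coefficient
  is made positive, and values are rounded to one decimal.
* Forward/backward passes and RMSprop (ρ = 0.9, ε = 10⁻⁸) are implemented
  directly in numpy; the network is small enough that this is both fast and
  dependency-free. Non-finite loss aborts training with a diagnostic.

The two-round protocol (train on unbiased data → bias along RC₁ →
retrain with reweighting) is exercised by the pipeline; on the toy landscape
the round-2 RC aligns with the dissociation direction at least as well as
round 1.

## Kinetics

Infrequent-metadynamics wall times are rescaled to unbiased times by the
accumulated-bias acceleration factor

    t = Σᵢ Δτ · exp(β V(tᵢ)),

summed over frames up to the dissociation event (first frame whose distance
coordinate strictly exceeds the threshold; censored runs are retained and
flagged, never dropped). The rescaled times tᵢ are modelled hierarchically:

    tᵢ | τᵢ ~ Exponential(mean τᵢ),
    log τᵢ | τ, σ ~ Normal(log τ, σ),
    log σ ~ Normal(1, 2),
    λ = 1/τ ~ half-Cauchy.

Numerical and design choices:

* The "Normal(1, 2)" prior width is interpreted as a standard deviation
  (configurable).
* The half-Cauchy scale on λ is 1 in units of the inverse mean input time.
  All inference runs on times normalised by their sample mean (canonicalised
  to 9 significant digits so that rescaling the raw input cannot perturb the
  chaotic sampler trajectory at the ulp level); posterior summaries are
  therefore *exactly* scale-equivariant.
* Point estimate: posterior median (robust, always inside the credible
  interval); interval: central 75%.
* Sampler: affine-invariant ensemble MCMC (40 walkers, 2500 steps, 1000
  burn-in by default) with a differential-evolution move mixture, which
  mixes the (2+n)-dimensional hierarchy far better than the stretch move.
  Convergence is gated on split-R̂ of log τ across walkers at 1.05;
  non-convergence flags the result but still returns it. Calibration-style
  tests use a lighter 1200/400 configuration, enough for stable interval
  endpoints.
* The σ → 0 (error-free, pooled) limit is computed by deterministic
  quadrature on a dense log-τ grid rather than MCMC; its posterior mode
  matches the exponential-MLE mean to O(1/n).
* Censored runs can contribute survival terms exp(−t_cens/τ); off by
  default to match the all-events-observed use case.

Model validation is a one-sample Kolmogorov–Smirnov test of the times
against Exponential(τ̂) with τ̂ the posterior median (per-run τᵢ would
overfit). The asymptotic p-value is the reporting default; the null
calibration test verifies the p-value distribution is uniform with 4000
replicates, so its Monte-Carlo error (0.003) sits well inside the ±0.01
acceptance band on the 5% rejection rate.

Convergence with the deposition interval is assessed by re-fitting per
interval and tabulating the relative change of τ̂ between successive
intervals; on the double well the two longest intervals agree more closely
than the two shortest, and the rescaled estimate brackets the brute-force
MFPT within a factor of 3 at 15 runs per interval.

## Landscape and pathways

Frames from the biased production runs are reweighted with final-bias
weights w_t ∝ exp(βV_final(s_t)) (max-subtracted before exponentiation;
always normalised). The time-dependent-constant refinement of the weights
is deliberately out of scope. The reweighted features go through:

1. **Weighted PCA** — eigendecomposition of the weighted covariance about
   the weighted mean; integer weights are exactly equivalent to frame
   replication; zero-variance components are dropped with a warning.
2. **Cluster count** — k-means + Calinski–Harabasz on the first two
   components, k from 2 (the index is undefined at k = 1) to a configured
   maximum, deterministic per seed. Transition states are saddles, not
   clusters, and are never counted as states.
3. **GMM free-energy surface** — a Gaussian mixture with the selected k on
   the first three components assigns frames to states; weighted mean, full
   covariance (needed for credible saddles in correlated coordinates;
   configurable to diagonal) and mixture weight are then computed per state
   in N dimensions (N = 10 at production scale, 2–3 for toys). A small
   ridge (10⁻⁶ of the mean variance) regularises covariances.
4. **NEB** — improved-tangent nudged elastic band with FIRE relaxation,
   32 images, spring constant auto-scaled to the initial energy range, and
   climbing-image refinement of the highest image (active after the first
   few iterations so the saddle is always climbed, not just bracketed).
   Convergence: maximum perpendicular force < 10⁻⁴. Non-convergence
   returns the partial path flagged. Endpoints must be minima
   (gradient-norm check), verified or refined via BFGS polishing.
5. **Rates and MFPTs** — per-edge relative Kramers rates
   k ∝ (Πω_min/Π'ω_saddle)·exp(−βΔF‡) from analytic surface Hessians, the
   saddle's single negative mode removed (an edge whose saddle does not
   have exactly one negative eigenvalue is flagged invalid). Two minima are
   adjacent only if their NEB path does not pass within a proximity
   tolerance of a third minimum. MFPTs come from the linear system of the
   Markov jump process; only *relative* times are meaningful because the
   friction prefactor is omitted, and the rate-limiting step (largest
   adjacent-pair MFPT) is invariant under uniform rate rescaling.
6. **State assignment** — maximum responsibility under the fitted mixture;
   exact ties resolve to the lowest component index.

## Collective variables and contacts

The hydration-style CV uses the rational switching function
s(r) = (1−(r/R₀)⁶)/(1−(r/R₀)¹⁰) with R₀ = 0.3 nm; the removable 0/0
singularity at r = R₀ is evaluated as the limit 6/10 (with one series term
for continuity in a 10⁻⁹ neighbourhood), and the hydration count is the sum
over water distances. Unbinding detection uses strict exceedance
(d > threshold), and contacts use strict inequality (d < cutoff counts,
d = cutoff does not) — boundary behaviour fixed here since the convention
is otherwise ambiguous. Contact fractions are weighted indicator means per
channel; the 15% display threshold filters the report view only, never the
stored profile. Lengths are nm internally; the contact cutoff (5 Å) is
accepted in Å with explicit unit naming to avoid silent mixed-unit errors.

## Orchestration and reproducibility

A single global seed drives everything. Per-stage seeds derive from it via
`SeedSequence(entropy=(seed, stage_key, replica))` with a fixed stage-key
registry, so adding a stage never shifts another stage's stream. Every
pipeline stage writes a parameter manifest; the end-to-end summary is
byte-identical across runs at the same (config, seed). Configuration is
TOML; block and key names are validated and a missing block is reported by
name.

## Problem sizes

Tests and the acceptance script run the statistics at sizes chosen for the
toy systems: 500 brute-force first-passage runs, 15 infrequent-metadynamics
replicas per deposition interval at three intervals, 200 replications for
credible-interval coverage, 4000 for KS-null calibration, 400-point-per-axis
grids for saddle oracles, 3000–4000-frame training sets with hidden width
16 for RC recovery. The published operating point (20 000 × 145 features,
K = 128, 5000 epochs) remains the default of the configuration objects.

## Known limitations

* Linear CVs only in the biasing kernel (matching the learned linear RC);
  the hydration-style CV is available for analysis but not as a biased toy
  coordinate.
* The exp(βV) short-lag reweighting is an approximation to the full
  propagator correction; long lags on strongly biased data will bias the RC.
* Histogram MI is biased upward for short series; the dissimilarity is not
  a metric (no triangle inequality guarantee).
* The Kramers prefactor omits friction, so absolute rates from the network
  are not comparable across surfaces — only within one.
* Ensemble-sampler walkers are correlated, so split-R̂ across walkers is a
  heuristic gate, not a guarantee; the pooled grid posterior is exact.
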