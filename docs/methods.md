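# Methods

## Reaction schemes and conventions

All concentrations are nM, all times seconds; second-order rate constants are
nM⁻¹s⁻¹. Species order is (P, D*, D, PD*, PD, T) with T = D*·P·D the ternary
complex. One 18-mer duplex is one binding equivalent: anisotropy reports only
the first binding event on the labeled probe, so a second protein on the same
oligomer is never represented.

**Association** is the single reversible step P + D* ⇌ PD*. **Simple
competition** adds irreversible competitor capture P + D → PD at k₁′ (default
k₁: same chemistry on an unlabeled molecule; configurable). Capture is modeled
as irreversible because the scheme is only applied where k₁′[D] ≫ k₋₁; the
probe step stays reversible, so released protein can transiently rebind free
probe — this produces a real few-percent rise of k_obs with competitor excess
(the retardation fades as [D] grows) that is invisible at experimental
replicate spread but detectable at the synthetic noise floor.

**Ternary mechanism.** Four rate constants: k₂/k₋₂ put the competitor on/off
the probe-bound protein, k₃ releases the pre-bound probe from the ternary
complex, k₋₃ re-forms it from the competitor-bound protein plus free probe.
The asymmetry (k₂ ≠ k₋₃, k₋₂ ≠ k₃) is expected — the incoming DNA binds a
different, weaker site. The network also carries the binary *capture* steps so
that the free protein left by pre-equilibration (~14 nM at the standard
37/25 nM mix) can bind either DNA directly, but during the exchange phase the
binary complexes do not dissociate directly: probe release goes exclusively
through the ternary complex. The binary off-rate k₋₁ therefore enters a
dissociation experiment only through the pre-equilibrated t = 0 state. This
is a deliberate convention: an active direct-release path at the k₋₁ values
consistent with the association experiment would dominate the exchange
kinetics at low competitor and erase the concentration dependence of k_obs
that defines the mechanism; the ternary scheme is a four-rate-constant model.

The doubly-labeled ternary complex D*·P·D* is excluded: free labeled DNA is
negligible at the experimental stoichiometry (25 nM probe vs 37 nM protein).
Competitor depletion is modeled explicitly — no pseudo-first-order shortcut —
because the designs reach down to tens of nM competitor where the extent of
exchange is visibly partial. Multi-site competitors (plasmids) enter as
site concentration = particle concentration × sites per particle; simulations
are exactly invariant under redistributing sites and particle count at equal
per-site rate constants. The admissible plasmid range is 5–450 sites per
4.5 kb particle; the generator default is 200 (5 nM of plasmid then behaves
like 1 µM of single-site oligomer). Pre-equilibration solves the binding
quadratic in its numerically stable form (smaller root).

Both K_D helpers return plain rate ratios. Note one documented discrepancy:
the ratio k₋₂/k₂ at the wild-type point estimates is ≈ 2.37 µM, while 2.6 µM
is sometimes quoted for the second site; the quoted figure likely derives from
a per-replicate fit and is not used as an oracle anywhere.

## Synthetic stopped-flow traces

The generator emulates the structure of shot-averaged stopped-flow anisotropy
data:

* log-spaced time grids (500 points/trace by default; linear grids available),
  25 ms windows for association, 1–5 s for dissociation;
* a 1.5 ms dead time (typical for the instrument class; configurable) — no
  sample precedes it;
* anisotropy calibration r_free = 0.05, r_bound = 0.25 (representative
  fluorescein-18mer values; fitting uses the calibrated conversion, so the
  absolute values are immaterial);
* i.i.d. Gaussian noise of σ = noise_sd/√shots on the averaged trace, with
  single-shot noise_sd = 0.013 and 10 shots averaged, i.e. ~2% of the
  free-to-bound span — consistent with published residual panels;
* deterministic seeding: trace i uses stream seed ⊕ i, so identical seeds
  give bit-identical series.

Standard designs: association mixes 30 nM probe with 60–250 nM protein (six
concentrations); dissociation pre-equilibrates 37 nM protein with 25 nM probe
(k₋₁ = 5 s⁻¹ — the association experiment only bounds it below 10 s⁻¹ — giving
K_D ≈ 1.6 nM) and adds competitor at 76 nM–4 µM (six concentrations) for
ternary constructs or 0.4–4 µM (three) for the simple-competition mutants.

What the generator does *not* emulate: photon-level shot noise in the
parallel/perpendicular channels (noise is applied to computed anisotropy),
drifting baselines, mixing artifacts, pipetting error in the nominal
concentrations, or day-to-day preparation variability. Passing recovery tests
therefore demonstrates identifiability and correctness of the fitting
machinery under the stated noise model, not robustness to every real-world
systematic. In particular, because the synthetic calibration is known exactly,
equilibrium amplitudes carry real information about K_D = k₋₁/k₁: the 95%
profile bound on k₋₁ from a 25 ms association window is roughly ±0.3 s⁻¹
around the truth here, far tighter than in a real experiment where the
signal-to-concentration conversion is itself estimated; the published-style
upper bound (< 10 s⁻¹) is checked as an inequality.

## Fitting

Per-trace single-exponential fits (offset + amplitude·e^(−k_obs·t)) use a
half-life initialization and a positivity bound on k_obs; traces whose fitted
amplitude is within 4× the point noise (estimated from first differences) are
reported as flat with k_obs = 0 rather than raising — the "no observable
release" controls hit this path. k_obs replots are ordinary least squares.

Global fits integrate the full scheme for every trace (LSODA via
`scipy.integrate.odeint` with an analytic Jacobian, rtol 1e-8, atol 1e-9 nM;
mass conservation holds to ~10× these along any trajectory) and minimize the
summed squared anisotropy residuals with unit weights (all traces share one
noise level by construction; per-trace weights are a constructor away for
imported data). Parameters are optimized as log₁₀ values within [−5, 4]
(they span five orders of magnitude).

Three optimizer details matter and were each verified to change results:

* **Finite-difference step.** The objective carries relative noise of order
  the integrator rtol; the default ~1e-8 derivative step sits inside that
  noise and stalls the trust-region search along sloppy directions. The step
  is fixed at 1e-3 log-units.
* **Sloppy ridge.** The observable cannot see PD* ⇌ T conversion (both carry
  the bound signal), so k₂ and k₋₂ are individually constrained only through
  the early-time lag they imprint; the strong combination is
  K = (k₋₂ + k₃)/k₂. Start candidates therefore walk this ridge explicitly:
  a hyperbola fit of k_obs(D) supplies k₃ and K, and alternates vary the
  k₋₂/k₂ split over three decades.
* **Multistart with screening.** The candidate pool (heuristic + ridge
  alternates + a seeded Latin hypercube over ±2 decades) is screened by one
  objective evaluation each; local optimization (TRF, `x_scale='jac'`, with
  up to three restarts to reset the trust region) runs from the best
  `n_starts` candidates. Ties within 1e-10 in final chi2 resolve to the
  earliest start. Default n_starts = 16; the recovery experiments use 4–6,
  which the screening makes sufficient in practice.

Standard errors come from a finite-difference Gauss–Newton covariance at the
optimum, back-transformed from log space. Profile-likelihood bounds rescan one
parameter on a 0.15-decade grid (warm-starting the nested refits) until the
variance-normalized chi2 rises by 3.84 (95%, one parameter), with the crossing
interpolated linearly; the normalization uses σ̂² = chi2/dof since fits are
unweighted. A parameter with no influence on the observable is reported
"unbounded within range". The residual bootstrap resamples residuals within
each trace, refits from the point estimate, and reports percentile intervals;
it is deterministic under a fixed seed.

During ternary fits k₁/k₋₁ stay fixed at association-derived values (the
standard two-experiment workflow); they can be freed explicitly.

## Model discrimination

Candidate schemes are fitted to the same series with the same seeds and ranked
by AIC = n·ln(chi2/n) + 2·n_free; ΔAIC > 10 is labeled decisive. Two
complementary diagnostics accompany the ranking: an OLS t-test (two-sided,
α = 0.05) on the k_obs-vs-competitor slope — the signature of DNA-dependent
release — and per-trace Wald–Wolfowitz runs tests plus skewness on the signed
residuals, which expose the long same-sign runs the wrong scheme leaves
behind (gross misfit is called at p < 0.01 per trace). Fewer than three
distinct competitor concentrations cannot separate the mechanisms and the
verdict says so. Because the simple-competition mechanism carries the genuine
few-percent k_obs rise noted above, the trend test retains a ~10%
false-positive rate on scheme-2 data at the synthetic noise floor; the AIC
ranking is the robust discriminator.

## Recovery experiments and problem sizes

`run_recovery` simulates n independent series at a preset truth (replicate
seeds drawn from one base seed) and refits from scratch. The shipped
acceptance script uses 10 replicates per construct with 500-point traces and
n_starts = 6 (wild type) or 4 (single-parameter mutant fits) — sizes chosen so
the full set of recoveries completes in minutes on one CPU while the medians
sit well inside the published replicate SDs. Self-recovery on noiseless data
is exact to at least four significant figures for every scheme.

## Known limitations

* The inhibitor scenario is represented as a config annotation only: high
  affinity active-site inhibitors do not change the rate or mechanism of DNA
  release, so no inhibitor kinetics are modeled.
* The simple-competition scheme is only meaningful where capture outruns
  release (k₁′[D] ≫ k₋₁); it is not fitted outside that regime.
* No Bayesian posterior sampling; uncertainty is Gauss–Newton SEs, profile
  bounds, and bootstrap percentiles.
* Laser-microirradiation accumulation kinetics (the in-cell counterpart of
  these experiments) are out of scope.
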