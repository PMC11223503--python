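# Methods

## Model overview

Each cortical region k of subject j is a Wilson–Cowan module: excitatory
(E) and inhibitory (I) mean-field populations with sigmoidal input
integration,

    tau_e dE_k/dt = -E_k + (1 - E_k) S_e(c1 E_k - c2 I_k + g Σ_l C_kl E_l + P; a_e, θ_k)
    tau_i dI_k/dt = -I_k + (1 - I_k) S_i(c3 E_k - c4 I_k; a_i, θ_i)

with S(x; a, θ) = 1/(1+e^{-a(x-θ)}) − 1/(1+e^{aθ}), offset so S(0)=0 and
rest is a fixed point at P=0. C is the structural connectome (symmetric
anatomical connection densities in [0,1], zero diagonal); long-range
coupling enters the excitatory population only, and no conduction delays
are modelled. Pathology perturbs only the excitatory threshold, linearly in
the normalized regional Aβ and tau burdens and their product:

    θ_k = θ0 + θ^Aβ·Aβ_k + θ^Tau·Tau_k + θ^Aβ·Tau·Aβ_k·Tau_k.

The total afferent excitatory input per region — local input to both
populations, long-range input, and the external input — is the drive fed to
a balloon-type hemodynamic model (signal s, inflow f, volume v,
deoxyhemoglobin q; constants κ=0.65 s⁻¹, γ=0.41 s⁻¹, τ_h=0.98 s, α=0.32,
ρ_e=0.34, V0=0.02, k1=7ρ_e, k2=2, k3=2ρ_e−0.2). The drive is mean-centered
(scaled by an efficacy ε_n) before entering the balloon system, so
sustained baseline firing maps to zero BOLD deviation — fALFF concerns
fluctuations, not offsets. BOLD is decimated to the fMRI TR (0.681 s) by
block averaging, and fALFF is the periodogram power in [0.01, 0.08) Hz over
(0, 0.25] Hz after linear detrending (raw boxcar periodogram by default,
Welch and amplitude-mode variants by flag; the DC bin is excluded, which
detrending makes moot anyway).

## Two operating points

`WCParams` defaults are the classical oscillatory constants (c1=16, c2=12,
c3=15, c4=3, a_e=1.3, θ0=4, a_i=2, θ_i=3.7, τ=8 ms, P=1.25, g=1). These are
used by the dynamics sanity checks (fixed-point constancy, g=0 decoupling,
RK4 self-convergence, boundedness, threshold monotonicity), integrated with
fixed-step RK4 at dt=1 ms for reproducibility; a seeded Euler–Maruyama
branch provides state noise when requested.

The *fitting* configuration (`ModelConfig`) deliberately uses a different
operating point: a_e=0.85, τ_e=τ_i=0.35 s, P=0.8, ε_n=0.03, dt=10 ms, and a
deterministic seeded multisine external input (24 equal-amplitude
sinusoids spanning 0.01–0.30 Hz, RMS 0.4). Why: with 8 ms time constants
every spectral feature of the dynamics sits orders of magnitude above the
0–0.25 Hz analysis band, so the simulated fALFF responds to the thresholds
only through aliasing and envelope artifacts — an effectively chaotic map
that no derivative-free optimizer can invert at realistic budgets. At the
fitting operating point every region has a stable fixed point whose
susceptibility corner frequency sweeps through the analysis band as the
threshold moves, and the broadband input probes that susceptibility
deterministically. The simulated fALFF is then a smooth, mostly monotone
function of each regional threshold, the forward model is exactly
reproducible (fixed `sim_seed`), and the correlation-distance objective has
a clean basin at the true weights. With τ=0.35 s, RK4 at dt=10 ms is deeply
converged. The achieved sampling interval after integer-block decimation
(0.68 s) is passed to the spectral stage rather than the nominal TR.

## Estimation

Per subject, SUVR maps are min–max normalized within subject and tracer;
the objective is 1 − Pearson r between observed and simulated regional
fALFF (Spearman by flag); the search is scipy differential evolution over
a box of ±θ0/2 per weight (popsize scaled so the evaluation budget, default
300, is respected; no polishing; deterministic under the given seed). The
Pearson correlation of the subject's normalized Aβ and tau fields is
reported as a collinearity diagnostic. Flat pathology fields make the
corresponding weight non-identifiable and raise a warning.

Simulation length during fitting defaults to the acquisition-like 585 s
retained window; tests and the shipped experiments use a 200 s window
(`small_test_profile`), which preserves recovery quality at a quarter of
the cost. Identifiability limits: because fALFF is invariant to affine
transformations of the BOLD, the overall scale of the three weights is only
weakly constrained (estimates are often proportional to, but larger than,
the truth); and when a subject's true weights produce little spatial fALFF
contrast (e.g. all thresholds pushed onto the insensitive flank), an
observation noise of sd 0.01 can favour a sign-mirrored solution — in the
shipped 8-subject experiment this costs zero to two subjects depending on
the seed, with sign-recovery rates of 70–95% across seeds.

## Group statistics

Per region, each factor's perturbation is normalized by the total shift:
contribution_f = t_f / |θ_k − θ0|, so the three shares sum to
sign(θ_k − θ0). To make that identity *exact* in floating point the shares
are rounded within a few ulp by a closure search; regions where the
identity is unrepresentable in doubles (extreme cancellation between the
three terms — all shares of magnitude ≥ 2, observed in ~0.005% of
region-subject pairs) are flagged as degenerate with zero contributions,
extending the θ_k = θ0 flag. AD-vs-CU contrasts use the two-sample
Wilcoxon rank-sum normal approximation with average-rank tie correction
and 0.5 continuity correction; the pattern is the signed z vector (AD > CU
positive; an absolute-value mode exists for unsigned maps, but the signed
default is what downstream Spearman correlations need).

## Transcriptomics

Representative probes are chosen by leave-one-out Gaussian-kernel
regression over 3-D sample coordinates (weight exp(−d²/2σ²)); accuracy is
the Pearson r between predicted and observed intensities, ties break to
the lexicographically first probe id. Gene–pattern association is Spearman
rho with a percentile bootstrap CI (default 99%, 100 000 resamples; the
test profile uses 2 000): regions are resampled in pairs, degenerate
(constant) resamples contribute rho = 0, and a gene is selected when the
CI excludes zero. Percentile (not BCa) intervals are the simplest
defensible choice given no further specification. Spatial autocorrelation
is *not* corrected — the resampling unit is the region pair — so selection
rates on spatially smooth patterns are anti-conservative in the same way
the original procedure is; a spin-test permutation is out of scope. Note
that percentile CIs *widen* slightly with more resamples (extreme
empirical quantiles from few draws are biased toward the center); what
tightens with the resample count is the Monte-Carlo scatter of the bounds,
and that is what the tests assert.

## Enrichment and drugs

ORA is the upper-tail hypergeometric test P(X ≥ k) against any user GMT,
BH-corrected; the default background is the expression-matrix gene
universe. Enriched terms are clustered by Cohen's kappa between their
membership indicators on the query set, average-linkage on 1 − kappa, cut
at linkage kappa 0.3 (the cut is applied at the linkage level; the
lowest-p term represents each cluster, ties to the smaller term id).
Cell-type enrichment uses row-normalized specificity (each gene's
expression shares across cell types summing to 1; raw-expression mode by
flag): the query's mean specificity per type is compared to n_boot random
same-size gene lists drawn without replacement, p = (1 + #{boot ≥ obs}) /
(n_boot + 1) (add-one correction, so p is bounded below by 1/(n_boot+1)),
δ = (obs − boot mean)/boot sd, BH across types.

Drug signatures are full rankings of the gene universe (rank 1 = most
up-regulated). The query-vs-rest Mann–Whitney U replaces comparison to "a
randomly selected gene set": it has the identical null distribution and no
sampling noise. U counts (query, rest) pairs where the query gene ranks
better, z uses the no-ties normal approximation with continuity
correction (positive = up-regulating), and p is exact (full U null pmf by
recurrence) for universes up to 60 genes, asymptotic beyond. BH runs
across the drug library; output is sorted by |z| with id tie-breaks.

## Synthetic data

The generators emulate the statistical shape of the real-world inputs this
kind of analysis consumes, not their biology: connectomes are uniform-weight random graphs resampled
until connected (density ~0.3); AD pathology fields are gamma-distributed
regional loads (shape 2, scale 0.35/0.30 for Aβ/tau on top of a baseline
of 1) smoothed by two rounds of connectome-neighbor averaging to mimic
spatially contiguous deposition, while CU fields are low-level unstructured
noise; AD theta magnitudes are uniform on [0.3, 1]·theta_scale with random
signs (clearly separated from zero so sign recovery is meaningful), CU
thetas are exactly zero. Observed fALFF is the package's own forward model
plus iid Gaussian noise on the fALFF vector (sd 0.01 by default), clipped
to [0, 1] — noise on fALFF rather than on BOLD because the fit operates on
fALFF. Planted associate genes are standardized mixtures a·pattern +
√(1−a²)·noise with a = 2 sin(π·rho_S/6), the bivariate-normal inversion of
the Spearman–Pearson relation. Cell-type specificity is row-normalized
gamma expression with a multiplicative boost (default 5) for the planted
set/type. Drug libraries shrink the sort keys of query genes toward the
top (up) or bottom (down) with a strength parameter; strength 1 places the
query exactly at the extreme. None of this captures PET tracer kinetics,
scanner noise, donor-level expression normalization, or real ontology
structure — passing tests demonstrate that the *pipeline* recovers planted
structure under its stated noise model, not that it would recover biology
from real data.

Generator defaults use clinically realistic group sizes (47 CU, 16 AD)
where group structure matters, and a small test profile (16 regions, 6+6
subjects, a few hundred genes) everywhere runtime does.

## Numerical choices and limitations

- Fixed-step RK4 (dt 1 ms classical / 10 ms fitting profile) rather than
  adaptive stepping, for bit-reproducibility; stochastic runs use
  Euler–Maruyama with pre-generated seeded increments.
- Balloon integration aborts with region and step if flow or volume become
  non-positive; network integration aborts naming the first non-finite
  step.
- Zero-variance simulated or observed fALFF vectors give objective 1 with
  a warning (correlation undefined).
- Stage seeds in the pipeline derive from one global seed by fixed
  offsets; two runs from the same config are byte-identical (manifest
  timestamps aside).
- The three-weight model is only identifiable up to the fALFF map's
  sensitivity: strongly collinear Aβ/tau fields (reported as a diagnostic)
  and low-contrast theta configurations degrade sign recovery; no
  hierarchical priors or gradient-based refinement are provided.
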