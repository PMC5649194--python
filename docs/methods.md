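# Methods

This note documents the models, the numerical choices behind them, what the
synthetic generators do and do not emulate, and the design decisions taken
where the analysis was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Units and physical constants

All public interfaces use pN for force, nm for length, kPa for elastic
moduli, and pN·nm for energy. The thermal energy is derived, never
hard-coded: k_B = 1.380649×10⁻² pN·nm/K exactly (the SI value re-expressed),
so k_B·T ≈ 4.11 pN·nm at the default 298 K. Temperature is configurable
through `ThermalContext`.

## Hertz (conical Sneddon) indentation

The approach-curve model is F = [2 E tanα / (π(1−ν²))] δ² with a conical
tip of half-angle α = 0.31 rad and ν = 0.5 (incompressible cell surface),
fitted over 0 ≤ δ ≤ 50 nm. Fitting details:

* The curve is first baseline-corrected by subtracting a line fitted to the
  non-contact region (outer 30% of the separation range by default).
* The contact point is initialised by a threshold detector — the first
  separation, scanning far to near, where the force exceeds 3σ of the
  far-field noise and stays above it for ≥5 samples — and then refined as a
  free nuisance parameter of the least-squares fit. The refinement window
  is ±30 nm around the detector's estimate: a threshold-crossing detector
  locates contact late by construction (at σ = 10 pN force noise the 3σ
  threshold is only crossed ~15 nm past true contact for a ~500 kPa
  surface), and the window must cover that bias. A ±10 nm window leaves a
  large positive modulus bias; ±30 nm removes it.
* The modulus is optimised on a log scale (it is a positive scale
  parameter) with `scipy.optimize.least_squares` (trf, bounded).
* Curves with no detected contact are returned as non-converged fits;
  windows with fewer than 5 points raise.

The per-cell summary is the mode of a single Gaussian fitted by least
squares to the Freedman–Diaconis histogram of converged moduli (≥30
required). The reported width is the fitted Gaussian σ itself; the
half-width at half-maximum would be 1.177σ. If the Gaussian fit fails, the
histogram argmax is reported with σ = NaN (ties broken toward the lower
modulus).

## Polymer models and fitting

Retract segments between contact (or a previous rupture) and a rupture are
fitted in the force-vs-extension plane. The WLC interpolation formula
F(x) = (k_B T/l_p)[0.25(1−x/L_c)⁻² + x/L_c − 0.25] is evaluated directly;
the FJC law x(F) = L_c[coth(y) − 1/y], y = F l_k/k_B T, is inverted to
F(x) by vectorised bisection to a relative force tolerance of 10⁻⁶ (the
segments are sampled on the extension axis). Near y = 0 the Langevin
function is evaluated by its series y/3 − y³/45 to avoid cancellation.

Parameters are bounded — L_c ∈ (max observed extension, 10× that],
stiffness length ∈ [0.01, 10] nm — and the optimiser restarts three times
from perturbed initialisations (perturbations drawn from the pipeline RNG),
keeping the lowest residual with ties broken toward smaller L_c. Two
robustness measures matter in practice:

* A final Nelder–Mead polish refines the best candidate: the FJC objective
  passes through a numerical inversion whose tolerance plateaus can stall
  finite-difference gradient steps slightly short of the optimum.
* A fit whose optimum sits on a parameter bound is flagged non-converged.
  Such fits arise from truncated low-force fragments that do not identify
  (L_c, stiffness); including them would skew contour-length summaries.

Fitted stiffness lengths below 0.1 nm — shorter than a glycosidic bond —
are reported as fitted but carry a `sub_physical` flag; no floor is
applied. The extensible-FJC segment elasticity is deliberately not
implemented: the two-parameter FJC is the model actually fitted here.

## Event detection and curve routing

Unbinding events are excursions below −3σ_noise on the baseline-corrected
retract trace (σ_noise: 1.4826×MAD of the non-contact region). Two
controls make the detector robust at realistic noise:

* below-threshold runs separated by <10 samples are merged when the force
  stays below baseline across the gap — threshold chatter on a tether's
  rising flank — while a deep peak followed by a return to baseline is
  never merged (that return *is* the rupture);
* merged runs with fewer than 3 below-threshold samples are discarded as
  isolated noise spikes. On pure-noise curves the per-curve false-positive
  rate is below 1% (tested).

The rupture force is the unsigned peak of the run; the rupture distance is
the separation just past the run, where force returns to baseline. Events
with rupture distance <5 nm are nonspecific (tip–surface snap-off); the
5 nm convention is the standard single-molecule force-spectroscopy cut
separating snap-off from tether extension. Curves route by specific-event
count: one event → FJC, two or more → WLC, matching how single- and
multiple-event fingerprints are conventionally analysed.

Baseline correction accepts a `noncontact_fraction` argument. The default
outer 30% is the safe general choice, but for long retract traces whose
fingerprints occupy only the near end, the pipeline uses the outer 50%:
extrapolating a short far-end line across a ~500 nm trace adds a per-curve
offset of a few pN at the near end, which measurably biases the
(degenerate) L_c–stiffness landscape of the polymer fits.

## Expression preprocessing and the moderated test

Pipeline order: log2 → subtract each array's weighted global median
(weight-1 spots only) → impute weight-0 spots at the array median →
quantile normalization (tied ranks averaged) → per-gene median over
replicate spots. Two scope decisions:

* Quantile normalization runs within each strain by default (the arrays
  being forced onto a common distribution are that strain's replicates);
  `quantile_scope="all"` normalizes across all arrays.
* The imputed values exist only to complete the quantile columns. Gene
  summaries use weight-1 spots exclusively, falling back to imputed values
  only when an array has no good spot for a gene: imputed values are biased
  toward the array median with less noise, and letting them into gene
  summaries shrinks apparent variances enough to inflate the moderated
  test's null p<0.01 rate visibly above 1%.

The empirical-Bayes prior (d₀, s₀²) is estimated by method of moments on
z = log s²_g: with s²_g ~ s₀²F(d_g, d₀), e = z − ψ(d_g/2) + log(d_g/2) has
variance ψ′(d_g/2) + ψ′(d₀/2), so d₀ follows from a trigamma inverse
(Newton iteration on 1/ψ′, which is nearly linear) and s₀² from the mean
of e. When the empirical variance of e does not exceed ψ′(d_g/2), d₀ = ∞
(no variance heterogeneity) and every gene uses s₀². d₀ = 0 reduces the
statistic to the ordinary pooled t-test (tested against scipy). P-values
use Student's t with d₀ + d_g degrees of freedom; BH adjustment is the
exact step-up (tested against brute force and statsmodels).

Fold change is the difference of group means on the log2 scale; the screen
keeps |log2 FC| ≥ 1 and p < 0.01 (both configurable).

## Sparse PLS and the clustered image map

`spls_fit` alternates u ← soft-threshold(Mv, keepX), v ←
soft-threshold(Mᵀu, keepY) on M = XᵀY (unit-normalising after each
thresholding; the threshold λ is the (keep+1)-th largest magnitude, so at
most `keep` loadings survive), to a 10⁻⁹ loading tolerance or 500
iterations, then deflates both blocks against t = Xu in regression mode.
With sparsity disabled, component 1 equals the leading singular pair of
XᵀY (tested to 10⁻⁸), and regression deflation makes the X-scores mutually
orthogonal. Loadings are oriented so each component's largest-magnitude
entry is positive; the fit contains no randomness, so identical inputs give
identical selections. Defaults ncomp = 2, keepX = 50/component, keepY =
all; none of these are dictated by the method and all are configurable.

Correlation-circle coordinates are the Pearson correlations of each
variable with the first two X-scores; variables with radius > 0.5 are
flagged as well represented. The similarity between phenotype j and gene i
is Σ_h r_h(i)·r_h(j) over components — the clustered-image-map construction
— which Cauchy–Schwarz bounds to [−1, 1] when scores are orthogonal. Both
axes are clustered by complete linkage on Euclidean distances between
similarity profiles and cut into 4 phenotype and 6 gene groups by default.
Integration runs on replicate-level profiles (15 rows for 5 strains × 3
replicates) to keep the sample count above the component count; a
strain-mean variant is a one-line `groupby` away from the same interface.

Enrichment of a gene cluster in an annotation category is the upper-tail
hypergeometric probability P(X ≥ k) with cluster size n, category size f
and a user-supplied universe size N; annotation is a flat user table, and
no specific annotation universe is assumed.

## Synthetic data: what it emulates, and what it does not

The generators plant known truth and are byte-deterministic for a fixed
config (one `numpy` Generator per call, seeded from the config).

* **Force-volume maps**: per-curve moduli from Normal(E_mean, E_sd²)
  truncated >0, baseline noise before a fixed contact point, Hertz force
  beyond it. Strain presets carry the five strains' published stiffness
  distributions (e.g. BY4743 483 ± 61 kPa, L62 239 ± 52 kPa).
* **Retract curves**: with the strain's event probability (10% for
  BY4743, up to 33% for L62), one or more tethers with contour lengths
  from Normal(Lc_mean, Lc_sd²) truncated >0, sorted so ruptures occur at
  increasing distance; the force follows the strain's polymer model
  (negative on retract) up to a drawn rupture force (~60 ± 5 pN), then
  snaps to baseline. The last sampled point of each tether carries the
  drawn rupture force itself — the sampling grid rarely lands on the
  rupture extension, and the peak is what a detector reports.
* **Expression**: gene baselines log-normal (log2 ~ N(8, 1.5²)), 5 strains
  × 3 replicates, 2 replicate spots per gene with 0.1 jitter and 2% weight
  dropout, residual noise 0.25 on the log2 scale. Each industrial strain
  gets 150 planted DE genes of which 71 form a common core. Planted
  effects default to |log2 FC| = 2 (4-fold): the screened lists contain
  genes changed by *at least* 2-fold (reported changes span ~1.5- to
  20-fold), and planting exactly at the 2-fold screening threshold would
  make every planted gene a coin flip against the fold-change filter
  rather than a recoverable signal.
* **Linked phenotypes**: noisy linear read-outs of planted gene-set means
  at a stated signal-to-noise ratio, with an optional unlinked control
  phenotype (the analogue of a variable that ends up inside the 0.5
  correlation circle).

Not emulated: instrument artifacts (drift, hydrodynamic drag, piezo
hysteresis), spatial structure within force-volume maps (bud scars),
probe-sequence effects, dye bias, and array spatial artifacts. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under the stated noise models, not robustness to instrument-specific
systematics.

## Problem sizes

The test suite and acceptance script run the study-scale analyses directly:
1,024-curve force-volume maps per strain for modulus recovery, 500 retract
curves for contour-length recovery, 1,000 for adhesion frequency, and
2,000-gene expression matrices. The end-to-end pipeline demo
(`PipelineConfig` defaults, CLI `report`) uses smaller sizes — 12×12 maps,
120 retract curves, 400 genes — chosen so a complete five-strain run
finishes in well under a minute while exercising every stage; all sizes
are configurable.

## Known limitations

* The Hertz model assumes an elastic half-space; no bottom-effect or shell
  corrections are applied, and only the conical tip geometry is provided.
* The WLC/FJC fits treat segments independently; simultaneous multi-tether
  fits are not attempted.
* The hydrophobicity index uses the bounded convention
  100·(A₀−A_F)/A₀ ∈ [0, 100]; the literal unbounded reading
  100·(A₀−A_F)/A_F is available via `convention="literal"` for comparison,
  and which denominator a given laboratory protocol intends should be
  checked against its reported ranges.
* Quantile normalization requires complete columns, hence the imputation
  compromise described above.
* sPLS keepX/keepY have no data-driven tuning (no cross-validation); they
  are study-design choices.
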