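# Methods

## Model and notation

For SNP j, γ<sub>j</sub> (SE σ<sub>Xj</sub>) is its effect on the exposure
and Γ<sub>j</sub> (SE σ<sub>Yj</sub>) its effect on the outcome, taken
from two non-overlapping GWAS and aligned to a common effect allele. Under
valid instruments Γ<sub>j</sub> = θγ<sub>j</sub>, and θ is the causal
effect of the exposure on the outcome (a log odds ratio when the outcome
GWAS is a disease case-control analysis; `exp(θ)` is reported as the OR).

### Harmonization

Exposure/outcome records are matched by SNP id only (positions are used
solely for clumping windows). Outcome alleles identical to the exposure's
are kept; swapped alleles negate Γ and complement the outcome EAF;
complementary-strand relabeling (A↔T, C↔G) is attempted before a pair is
dropped as incompatible. Palindromic (A/T, C/G) SNPs cannot be
strand-resolved from alleles and are removed by default. An opt-in
frequency-inference mode retains them when both effect-allele frequencies
are informative (MAF < 0.42 on both sides), aligning by frequency side;
it is off by default because blanket removal is the more conservative and
more reproducible policy, and SNPs with missing EAF can never be
frequency-inferred. Harmonizing an empty intersection is an error —
estimators must never run silently on nothing.

### Instrument selection

The cascade is: p-value filter (strict `<`; default 1×10⁻⁵ for molecular
exposures, 5×10⁻⁸ for the disease when instrumented in reverse MR) →
greedy LD clumping → outcome-association exclusion (p < 5×10⁻⁸) →
strength filter (F > 10 and MAF > 0.01). Clumping sorts by p (ties broken
lexicographically by SNP id for determinism), accepts the best remaining
SNP and discards remaining SNPs on the same chromosome within the window
(|Δpos| ≤ window_kb·1000, default 10,000 kb) with r² ≥ r2_max (default
0.001). LD is a local precomputed symmetric r² matrix; pairs it does not
cover are treated as unlinked and logged once — this replaces a reference
panel or network LD service without changing the algorithm. Whether the
outcome-association exclusion runs before or after clumping is not
determined by the design it mirrors; the default is after clumping and a
flag swaps the order.

Per-SNP instrument strength uses R² = 2·maf·(1−maf)·β² (standardized-trait
approximation) with F = R²(n−2)/(1−R²) when EAF and n are available, else
the Wald fallback F = (β/se)²; which formula was used is recorded per SNP.
SNPs with missing EAF skip the MAF gate (they can still be excluded by F).
Proxy substitution (best candidate with r² > 0.8, ties by higher r² then
lower p) exists but is off by default in the pipeline — it is only
meaningful when a wanted SNP is missing from one GWAS.

### Estimators

* **IVW**: weighted regression of Γ on γ through the origin, weights
  1/σ<sub>Y</sub>². Default is the multiplicative random-effects model —
  SE scaled by max(1, √(Q/(m−1))) — matching the dominant convention in
  two-sample MR software; the fixed-effects model is one flag away and the
  scale factor is recorded. The max(1, ·) floor means the random-effects
  SE never deflates below fixed.
* **MR-Egger**: weighted regression with a free intercept after orienting
  every SNP to its exposure-increasing allele (the fit is otherwise not
  allele-code invariant). The intercept estimates average directional
  pleiotropy; slope and intercept use t(m−2) inference and the same
  multiplicative SE floor with Q<sub>egger</sub>/(m−2).
* **Weighted median**: per-SNP ratios θ<sub>j</sub> = Γ<sub>j</sub>/γ<sub>j</sub>
  with inverse-variance weights using the first-order ratio variance
  σ<sub>Yj</sub>²/γ<sub>j</sub>² (the second-order σ<sub>Xj</sub> term is
  deliberately omitted — simplest defensible choice, and the weights only
  rank SNPs); the estimate interpolates the weighted quantile function at
  0.5 across cumulative midpoints p<sub>j</sub> = Σ<sub>k≤j</sub>w<sub>k</sub> − w<sub>j</sub>/2.
* **Mode-based**: Gaussian-kernel density over the ratios (inverse-variance
  weights for the weighted mode, equal weights for the simple/"sample"
  mode), bandwidth φ·0.9·min(sd, iqr/1.34)·m^(−1/5) (φ = 1 by default),
  evaluated on a 512-point grid spanning [min θ − 3bw, max θ + 3bw]; argmax
  ties return the midpoint of the tied grid points; all ratios identical
  returns that common value.
* SEs for median/mode come from a seeded parametric bootstrap (resampling
  γ<sub>j</sub>, Γ<sub>j</sub> from normals at their observed values and
  SEs; 1,000 replicates by default) so every stochastic SE is reproducible
  from the run manifest. p-values are two-sided normal except Egger's t.

With two SNPs only IVW runs; with one, only the Wald ratio — the
degradation is recorded on the estimate.

### Sensitivity

Cochran's Q = Σw<sub>j</sub>(Γ<sub>j</sub> − θ̂γ<sub>j</sub>)² with χ²(m−1)
p-value; Q at the fixed-effects estimate is the minimum over θ (tested
against numerical minimization). MR-PRESSO follows the published reference
algorithm: observed RSS uses leave-one-out IVW predictions; the null
distribution redraws γ*<sub>j</sub> ~ N(γ<sub>j</sub>, σ<sub>Xj</sub>) and
Γ*<sub>j</sub> ~ N(γ<sub>j</sub>θ̂<sub>(−j)</sub>, σ<sub>Yj</sub>) and
recomputes RSS with leave-one-out estimates on the simulated data; the
global p carries the add-one correction so it lies in [1/(n_sim+1), 1].
Per-SNP outlier p-values are empirical tail proportions,
Bonferroni-corrected by m, flagged below α = 0.05; the corrected estimate
is IVW on the unflagged SNPs; the (optional) distortion test compares the
raw/corrected shift with shifts from removing random same-size SNP
subsets. The simulations show the global test is mildly conservative
(null-p mean ≈ 0.515, rejection ≈ 4% at α = 0.05): this is a property of
the leave-one-out-centred parametric scheme itself — the simulation means
are built from noisy observed effects — and is visible in the acceptance
measurements rather than hidden.

### Strict screening and mediation

The four gates (IVW p < 0.05; strict sign agreement of all five betas — a
beta of exactly 0 fails; MR-PRESSO global p > 0.05; Egger-intercept p >
0.05) are evaluated independently and conjoined, so improving any single
gate can never un-pass a decision. "Pleiotropy test" is mapped to the
Egger intercept, and the MR-PRESSO gate is applied separately, so both
readings of a pleiotropy gate are enforced. A missing MR-PRESSO p (< 4
instruments) fails its gate: passing requires positive evidence.

Mediation is the product of coefficients: indirect = β<sub>A</sub>β<sub>B</sub>,
first-order (Sobel) SE, two-sided normal p, plus an optional Monte-Carlo
CI from resampling β<sub>A</sub>, β<sub>B</sub> (both are reported; the
delta-method and Monte-Carlo intervals can disagree when either leg is
imprecise, and printed Z/CI pairs from the two conventions are not
mutually convertible). β<sub>B</sub> is estimated after removing from the
mediator's instruments every SNP used in the exposure→mediator analysis
plus, by default, any SNP in LD (r² ≥ 0.001) with one — a literal
SNP-set exclusion, not multivariable MR. The mediated proportion
indirect/β<sub>T</sub> is reported as a signed percentage with no
clamping; opposite signs of indirect and total effect set an
inconsistent-mediation flag, and |β<sub>T</sub>| below 10⁻⁸ makes the
proportion an error rather than a huge number. Reverse MR re-runs the
pipeline with outcome and exposure swapped (instruments at 5×10⁻⁸);
a reverse IVW p < 0.05 removes the pathway from the final table; when no
reverse instruments can be selected the check warns and does not flag.
No multiple-testing correction is applied to pathway p-values by default
(raw 0.05, as in the screening design this mirrors); `--fdr` appends an
informational Benjamini–Hochberg column.

## Synthetic data

The generator emulates the statistical structure of two-sample MR on
biobank-scale GWAS, not the biology: per SNP, maf ~ U(0.05, 0.5), true
effect γ ~ N(0, gamma_sd²) with the effect allele then oriented to the
exposure-increasing allele (γ ≥ 0 — the convention under which
"directional" pleiotropy and the Egger intercept are meaningful);
pleiotropy α = 0 for valid SNPs and α ~ N(mean, sd²) for the invalid
fraction (balanced mode forces mean 0); Γ = θγ + α; sampling SEs
σ = 1/√(2n·maf(1−maf)) with independent N(0, σ²) noise per sample and
Wald p-values. Defaults — m = 50 instruments, n = 100,000, gamma_sd =
0.03 — give mean per-SNP F ≈ 33, strong instruments whose p-values
predominantly clear the 1×10⁻⁵ exposure threshold. Pleiotropy defaults
(mean 0.01, sd 0.005) put the directional-pleiotropy bias at roughly half
the default causal effect while keeping the Egger intercept detectable
with ~90% power at m = 50. The mediation triple plants two disjoint
instrument blocks (exposure instruments propagating θ<sub>XM</sub>,
θ<sub>XM</sub>θ<sub>MY</sub>+direct; mediator-only instruments propagating
θ<sub>MY</sub>) so the instrument-adjustment step is exercised exactly as
on real data. LD is block-diagonal with constant within-block r². One
global seed expands into named substreams (maf, gamma, pleiotropy, per-
sample noise), so changing one component leaves the others fixed.

What the generator does **not** model: case-control likelihoods for the
binary outcome (the same standardized-trait SE form is used on the
log-odds scale), realistic LD from reference panels, winner's-curse-
corrected discovery, sample overlap, or population stratification.
Passing tests therefore demonstrate correctness of the estimators and the
decision logic under the assumed sampling model, not robustness to those
real-data complications.

## Measured finite-sample behaviour

The simulation studies (see `scripts/acceptance.py`) quantify three small,
well-understood deviations from ideal behaviour rather than hiding them:

* **Weak-instrument attenuation.** With mean F ≈ 33, IVW, Egger and the
  weighted median are attenuated toward the null by ≈ θ·σ<sub>X</sub>²/E[γ²]
  ≈ θ/F̄ (≈ −0.005 at θ = 0.2) — the classical regression-dilution of
  ratio-based two-sample MR. CI coverage is unaffected (measured 95%).
* **MR-PRESSO conservatism.** Null global p mean ≈ 0.515 (above).
* **Plug-in proportion bias.** The mediated proportion
  β̂<sub>A</sub>β̂<sub>B</sub>/β̂<sub>T</sub> carries a small positive
  finite-sample bias (≈ +0.2 percentage points at the planted 13.04%),
  dominated by the convexity of 1/β̂<sub>T</sub> and instrument-selection
  effects.

## Numerical and design choices

* 95% intervals use the exact normal/t quantile (1.959964…), the same
  quantile for the CI and the Z test, so |Z| ≥ 1.96 ⇔ CI excludes 0.
* Output floats are written at %.17g, so tables round-trip exactly.
* Determinism: every stochastic path (generator, bootstraps, MR-PRESSO,
  Monte-Carlo CIs, catalog orchestration) is driven by named
  seed-sequence substreams; identical inputs and seed give bit-identical
  results, independent of thread count (all computation is single-threaded
  numpy).
* Per-exposure failures in catalog runs (no instruments, empty
  harmonization) degrade to logged skips with the stage recorded — a
  catalog screen of hundreds of traits must survive individual failures.
* Problem sizes in tests and the acceptance script (50-instrument GWAS,
  150–2,000 replicates, 300-draw MR-PRESSO nulls) were chosen so each
  Monte-Carlo check resolves the effect it measures with 2–10× margin on
  one CPU core.

## Known limitations

No multivariable MR, Steiger filtering, CAUSE/contamination-mixture
estimators, funnel/radial diagnostics or I² — outside this design. No
VCF-encoded summary statistics and no networked data or LD retrieval. The
reverse-MR check requires the outcome GWAS to contain genome-wide-
significant instruments of its own; otherwise reverse causation is
reported as unassessable rather than absent.
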