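# Methods

## Scope

`circacost` implements a complete desk-scale analysis of why circadian
amplitude tracks transcription level in multi-organ expression atlases:
rhythm detection, amplitude–expression variance attribution, an mRNA
energy-cost model, a PCA-based partition of amplitude variance over region
costs with a permutation null, and tissue-specificity / enrichment
controls. A synthetic-data generator with known ground truth makes every
stage testable without external downloads.

## Rhythm detection

Each transcript's series is compared to discretized cosine templates
cos(2π(t − φ)/T) on a phase grid (default: T = 24 h, φ ∈ {0, 2, …, 22} h)
via Kendall's τ. For a template with tie-group sizes t₁…t_g over n
timepoints, the exact null distribution of Kendall's S under permutation
of the (untied, continuous) data follows from the inversion-count
generating function of a random multiset permutation, the Gaussian
multinomial [n]_q!/∏ᵢ[tᵢ]_q!, evaluated by exact integer polynomial
multiplication and division. S = D − 2k, where D is the number of
template-discriminating pairs and k the inversion count, so upper-tail
probabilities are cumulative sums of the coefficient list. The engine is
verified against brute-force enumeration over all n! orderings for n ≤ 8.

Per transcript the p-value is the minimum one-sided (positive
association) tail over the distinct template rank patterns, Bonferroni-
multiplied by the number of patterns and capped at 1. This combination is
deliberately conservative: the realized type-I rate on null data is below
the nominal α (measured ≈ 0.6 α at α = 0.05 with 24 timepoints), and
Benjamini–Hochberg false-discovery control downstream inherits that
margin. Cycling = BH-adjusted p < 0.05. Constant series are excluded from
testing and flagged (`tested = False`, p = 1).

**Amplitude** is the one-cycle median sign-adjusted deviation from the
median expression: with s_t the sign of the best template's cosine at
time t, amplitude = median over the first full period of
s_t·(x_t − median(x)), floored at 0. On a noiseless sampled cosine of
amplitude A this returns ≈ 0.68–0.71 A depending on where the phase falls
relative to the 2-h grid; the constant is pinned by the repository's own
oracle tests. Its scale cancels from every downstream correlation and R².
The estimator's relative error grows like noise_cv / relative amplitude,
which matters for the generator defaults (below). Numerical choices:
cosine values are rounded to 9 decimals before ranking so analytic ties
(e.g. symmetric points around a zero crossing) are tied exactly; template
ties are broken toward smaller period, then smaller phase lag.

## Amplitude–expression attribution

Mean expression is the arithmetic mean over timepoints. Quintiles split
all expressed genes into five equal bins by mean expression (stable ties,
sizes differing by ≤ 1); each bin's share of all cycling genes is the
headline quantity, with the within-bin cycling fraction reported
alongside under its own label. The regression is ordinary least squares
of log amplitude on log mean expression over cycling genes with positive
amplitude (zero-amplitude records are excluded and counted); R² = r² is
read as the fraction of amplitude variance attributable to expression
level. The `top_fraction` option first restricts the universe to the top
fraction of all expressed genes, then intersects with the cycling set —
the "top 50% most expressed" control for low-abundance noise. Natural
logs internally; r, R² and slope are base- and scale-invariant.

## Energy cost model

Costs are expressed in activated phosphate bonds (~P). Per region,
cost = Σ_base count·(synthesis_base + elongation); the per-molecule total
adds one initiation+termination overhead. At steady state a pool of E
copies decaying at d per hour is replaced at rate E·d, so the ongoing
cost is E·d·(per-molecule cost), in relative ~P/h (expression is in
arbitrary units). The overhead is charged per synthesis event (i.e. it is
multiplied by the replacement rate); setting `overhead = 0` in the table
removes it. The default table ships as editable TOML data with
order-of-magnitude ribonucleotide values (A 50, C 46, G 51, U 47;
elongation 2; overhead 10 ~P); every shipped analysis is correlational
and invariant to the exact entries. A single decay rate per gene is
assumed (decay treated as sequence-determined and time-invariant).
Region analyses use the steady-state (copy-number- and decay-weighted)
region costs: this is what makes the three region costs strongly
inter-correlated and couples them to amplitude through expression.

## Variance partition

The three log steady-state region costs of cycling genes are
standardized and the 3×3 **correlation** matrix eigen-decomposed
(correlation rather than covariance because raw region costs differ by
orders of magnitude); components are ordered by eigenvalue, and each
loading vector is oriented so its largest-magnitude entry is positive.
Log amplitude is regressed on each orthogonal PC score alone; because the
scores are orthogonal, the per-PC R² values sum to the full-model R²
(checked to 1e-8). Significance: amplitude is shuffled B times (default
1000) and the total R² recomputed; perm_p = (1 + #{null ≥ observed})/(B+1),
the +1 correction giving finite-sample validity and a floor of 1/(B+1).

## Specificity and enrichment controls

Cyclic tissue number counts the organs in which a transcript is called
cycling. The partial correlation r_xy·z uses the closed form
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), cross-checked against
residual-correlation and an independent library implementation.
Enrichment is an internal hypergeometric over-representation test
against the background of all expressed genes: fold = (k/n)/(K/N), p the
upper tail P(X ≥ k), BH across terms; no term-hierarchy handling (flat
GMT sets). The fold-enrichment–amplitude relation is computed over
significant terms (adj p < 0.05), optionally restricted to the top-k most
enriched, and optionally controlling each term's mean member log
expression — per-term rather than per-gene means, flagged in the output.
Group contrasts (e.g. housekeeping-style lists) report the mean
log-amplitude difference with a two-sided Wilcoxon rank-sum p.

## Synthetic data: what is emulated, and what is not

Rhythmic genes follow x_g(t) = m_g(1 + (A_g/m_g)cos(2π(t−φ_g)/T))·ε_gt
with mesors lognormal (log-mean 3, log-sd 1), phases uniform, and
multiplicative lognormal noise of coefficient of variation `noise_cv`.
The default sampling grid is CT18–CT64 every 2 h (24 points, two full
cycles), matching the dense microarray design of the emulated atlas; the
sparser RNA-seq design is a config change.

The amplitude model is log A = c₀ + b·log m + e with fixed slope
b = 1.5 and e truncated-normal such that A/m stays in
[rel_amplitude_min, rel_amplitude_max] (default (0, 0.95]; configs whose
parameters would push amplitude to or above the mesor are rejected before
generation, since expression would go negative). The residual sd is
solved by 1-D root finding (Brent, tolerance 1e-10) so that the
population corr²(log m, log A) over the realized rhythmic set equals
`coupling_r2` exactly, *including* the truncation's effect on the
moments — the cap therefore does not distort the planted coupling
(verified: planted 0.700 at n = 5000). With coupling_r2 = 0 the slope is
dropped and the residual sd fixed at |b|·sd(log m).

Rhythmic-gene assignment is biased toward highly expressed genes
(sampling weights ∝ exp(bias·u) with u the signed mesor rank in [−1, 1],
default bias 2.0). This plants the observed phenomenon that the cycling
fraction rises steeply with expression level, over and above the
detection-floor gradient, and is what the quintile analysis is designed
to detect.

Default noise_cv = 0.015 and rel_amplitude_median = 0.2 put the standard
conditions in a low-attenuation regime: the sign-adjusted-median
amplitude estimator has relative error ≈ noise_cv/(0.7·A/m), and BH false
positives carry noise-floor amplitudes with high leverage in the log-log
regression, so noisy defaults would systematically understate a planted
coupling. The defaults are chosen so that measured R² reflects the
planted R² (the regime in which observed atlas-scale R² values are read
as the coupling itself); robustness at realistic noise is exercised
separately — detector power and phase recovery at noise_cv = 0.1, null
calibration (rank-based, hence noise-level-free), and FDR control.

Multi-organ structure: rhythmic-anywhere genes get independent Bernoulli
organ memberships (default probability 0.25; a 20% "broadly rhythmic"
subset uses 0.8), with at least one organ guaranteed; mesors, amplitudes
and phases are shared across organs, noise is organ-specific. Transcript
models draw region lengths uniformly (5'UTR 50–300, CDS 300–3000, 3'UTR
100–2000 nt), Dirichlet base compositions (zero concentrations allowed
as structural zeros) and lognormal decay rates (median 0.1/h ≈ 7 h
half-life). Gene sets are sampled with membership weights that can be
tilted toward high expression, planting the enrichment confounder.

Not emulated: probe- or read-level measurement, between-replicate
structure, organ-specific amplitude or phase differences, non-stationary
baselines, correlated gene programs, or any relation between sequence
composition and expression or decay. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
declared generative model, not performance on real atlas data.

## Problem sizes

The shipped test and acceptance runs use 2000–5000 genes × 24 timepoints,
20-seed replications, and B = 200–1000 permutations (the permutation
calibration uses B = 200 across 200 seeds; the single-dataset null uses
the full B = 1000). These sizes give binomial/KS margins well inside the
asserted tolerances while keeping a full run under a few minutes on one
CPU.

## Known limitations

- The Bonferroni min-p scan is conservative; realized type-I error and
  FDR run below nominal. Power is correspondingly pessimistic near the
  detection floor.
- The exact null assumes untied data; tied expression values are handled
  in the observed statistic (tau-b) but the tail is computed under the
  untied model.
- Amplitude is estimated from the first sampled cycle only, and its
  phase-grid dependence (≈ ±2% in log units) is folded into the reported
  values.
- The energy model prices synthesis only — no translation cost, no
  nucleotide recycling, no genome-annotation ingestion beyond the region
  FASTA/TSV conventions.
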