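# circacost

Why do some genes oscillate with large circadian amplitude while others
barely move? Across mammalian organs, the strongest single predictor of a
rhythmic transcript's amplitude is simply how highly it is expressed —
and, because transcription costs energy, rhythmically down-regulating
highly expressed genes is an energy-saving strategy. `circacost` is an
analysis pipeline for quantifying that story on gene × timepoint
expression matrices: it detects rhythmic transcripts, measures how much
amplitude variance the transcription level explains, prices each
transcript's synthesis in activated phosphate bonds (~P), partitions
amplitude variance over the energetic costs of the 5′UTR, CDS and 3′UTR,
and runs the tissue-specificity and pathway-enrichment controls. It is
aimed at computational chronobiologists who want these analyses as
tested, reusable components, exercisable end to end on synthetic data
with known ground truth.

## The statistics at the core

- **Rhythm detection.** Each series is compared to discretized cosines
  cos(2π(t − φ)/T) by Kendall's τ. The p-value per template is the exact
  one-sided tail of Kendall's S under permutation, computed from the
  inversion generating function of a multiset permutation (the Gaussian
  multinomial [n]_q!/∏[tᵢ]_q!, handling template ties exactly); the
  per-gene p is the Bonferroni-combined minimum over distinct template
  rank patterns, with Benjamini–Hochberg control across genes
  (cycling ⇔ adj p < 0.05). Amplitude is the one-cycle median
  sign-adjusted deviation from the median expression.
- **Variance attribution.** OLS of log A on log Ē over cycling genes;
  R² = r² is the fraction of amplitude variance explained by expression
  level. Quintile reports give each expression bin's share of all
  cycling genes.
- **Energy cost.** Per molecule, cost = Σ_b count_b·(synthesis_b +
  elongation) + overhead; at steady state, cost rate = Ē·d·cost_molecule
  (~P/h) for decay rate d.
- **Variance partition.** PCA (correlation matrix) of the three log
  region costs; log amplitude regressed on each orthogonal PC; per-PC R²
  sums to the full-model R²; significance from B amplitude shuffles,
  p = (1 + #{null ≥ obs})/(B + 1).
- **Controls.** Cyclic tissue number, partial correlation
  r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), hypergeometric
  enrichment with fold = (k/n)/(K/N), and rank-sum group contrasts.

## Worked example

The `analysis/` drivers run the whole study on simulated data:

```sh
python analysis/01_simulate.py --n-genes 2000 --n-organs 4 --seed 0
python analysis/02_detect_rhythms.py
python analysis/03_expression_amplitude.py
python analysis/04_energy_cost.py
python analysis/05_variance_partition.py
python analysis/06_specificity_function.py
```

Representative output (organ 1 of the default run):

```
organ_01: 434/2000 transcripts cycling (adj p < 0.05); median cycling amplitude 5.92
organ_01: cycling-gene share bottom->top quintile 0.06 0.10 0.15 0.32 0.36 | R^2 = 0.65 (r = 0.80, slope = 1.44, n = 434); top-50% R^2 = 0.50
organ_01: cost~amplitude r by region 5utr=0.61 cds=0.60 3utr=0.53 | expression~total cost r = 0.82
organ_01: predictor variance on PC1 81%; amplitude variance explained PC1 41.6%, PC2+PC3 0.6%, total 42.3% (perm p = 0.000999, B = 1000, n = 434)
  organ_01: 0.80 -> 0.80   (expression~amplitude r, raw -> controlling tissue number)
```

Reading this: about a fifth of genes cycle, and they concentrate heavily
in the upper expression quintiles (36% of cycling genes in the top 20%
of expression versus 6% in the bottom 20%). Expression level explains
65% of the amplitude variance among cycling genes (r = 0.80), and the
relationship survives restriction to the top-half expressed genes.
Steady-state region costs — which inherit copy number — correlate with
amplitude (r ≈ 0.5–0.6 per region), and their first principal component
alone explains 42% of amplitude variance while PC2+PC3 add under 1%;
1000 amplitude shuffles never reach the observed R² (p = 1/1001).
Controlling for the number of organs a gene cycles in leaves the
expression–amplitude correlation unchanged, so tissue sharing is not
what drives it.

## Layout

- `src/circacost/` — the library: `synthetic_data`, `rhythm_detection`,
  `expression_amplitude`, `energy_cost`, `variance_partition`,
  `specificity_function`, `io`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — model assumptions, parameter defaults and rationale,
  numerical choices, limitations.
- `tests/` — unit, property (hypothesis) and acceptance tests.
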