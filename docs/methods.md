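# Methods

This note documents the models, defaults and numerical choices behind
`nemaquant`, and what the synthetic-world tests do and do not demonstrate
about real soil samples.

## Reference framework and monophyly

Assay targets are families or genera of soil nematodes represented in a
gapped SSU rDNA alignment with a taxonomy table and a reference phylogeny.
A single sequence signature can only represent a taxon that forms a clade,
so each family is tested for monophyly before design:

- Trees are treated as **rooted as written** in the Newick file; monophyly
  is evaluated on that rooted topology. For genuinely unrooted input the
  outermost grouping acts as the root and results are rooting-dependent.
- The report is computed on the smallest clade (MRCA subtree) spanning the
  member leaves; non-member leaves inside it are enumerated as intruders.
  Single-leaf taxa are monophyletic by convention; taxa with no leaf in the
  tree are unresolvable.
- Non-monophyletic families are replaced by their monophyletic constituent
  genera (the pattern used for the fungivorous Diphtherophoridae, split into
  *Diphtherophora* and *Tylolaimophorus* assays); families with no
  monophyletic representation at either rank are flagged un-assayable, the
  situation of the large poly/paraphyletic Rhabditidae.

Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing reports. IUPAC ambiguity codes are retained; two bases match
when their ambiguity sets intersect, which makes in-silico mismatch counts
conservative lower bounds for specificity claims.

**Coverage counting.** `coverage_fraction` is 100 × (genera present in a
habitat with a qPCR assay) / (present genera excluding obligate plant
parasites), rounded to the nearest percent. On the packaged survey table
this gives 72 % (13/18) for the forest and 65 % (20/31) for the field. The
original survey text quotes 59 % for the field; that number is not
recoverable from the published genus table under any obvious counting rule,
so the package reports the rule-based value and notes the discrepancy here
rather than reconciling it.

## Melting temperature

Primer Tm uses the unified two-state nearest-neighbor formalism: duplex ΔH
and ΔS are sums of stacked-dinucleotide terms plus terminal initiation
terms (parameter table versioned in `data/nn_unified.csv`), the entropy is
salt-corrected by 0.368·(L−1)·ln[Na⁺], and

    Tm = 1000·ΔH / (ΔS + R·ln(C/x)) − 273.15

with R = 1.987 cal/(mol·K), C the primer concentration and x = 4 for
non-self-complementary duplexes (x = 1 plus a symmetry entropy term for
self-complementary ones). Defaults are 50 mM Na⁺-equivalent and 200 nM
primer — a deliberate choice: the wet-lab protocol's stated primer
concentration (200 µg/µl) is dimensionally implausible and was evidently
meant as 200 nM. Degenerate primers are expanded (≤ 64 variants) and the
worst-case (lowest) Tm is reported, the conservative direction for the
shared 63 °C annealing temperature. Golden values in the test suite were
frozen from an independent hand-summation of the parameter table.

## Assay design

- **Signature windows** are enumerated on the ungapped coordinates of the
  representative (lexicographically first) target member, for every length
  in the primer range (default 18–25 nt). A window qualifies when every
  target member agrees with the representative at every column and every
  non-target carries at least 3 mismatching columns (configurable). Ranking
  puts the worst-case non-target 3′-region (terminal 5 nt) mismatch count
  first, then the total count.
- **Pairs** combine a forward window with a downstream reverse window
  (reverse primer = reverse complement). Both Tm values must fall within
  63 ± 1 °C, differ by ≤ 2 °C, and bracket an amplicon of 80–400 nt.
  Candidate order is deterministic: worst Tm deviation, then total
  deviation, then primer sequence.
- **Specificity.** Empirical ΔCt is the gap between the latest-amplifying
  target and the earliest-amplifying non-target, and always overrides the
  in-silico proxy. The proxy is an explicit heuristic: a non-target is
  predicted non-amplifiable when either primer has ≥ 2 mismatches in its
  3′-terminal 5 nt or ≥ 4 total mismatches; otherwise it contributes
  3.3 cycles per total mismatch (one tenfold dilution ≈ 3.3 cycles). When
  no non-target is predicted amplifiable, ΔCt is *not available*, which
  ranks above any numeric gap during selection — no non-target signal is
  the best possible outcome.
- **Annealing-temperature optimum.** A profile passes when Ct rises by at
  least 1 cycle/°C above 63 °C (the threshold separates the sharp-optimum
  shape from a flat profile) and the 63 °C Ct is the profile minimum within
  0.5 cycles.
- **Selection** discards candidates with numeric ΔCt < 12 cycles, keeps the
  largest gap, breaks ties by the lowest Ct per unit of template and
  finally by primer sequence, making the choice invariant under candidate
  ordering. Negative empirical gaps (non-target earlier than target) are
  always discarded by the same filter.

## Calibration

Ordinary least squares of Ct on log₁₀(N) over dilution series of 1, 5, 10,
50 and 100 hand-picked nematodes (fractional N supported for sub-individual
dilution series; linearity is expected down to 1/1000 of an individual,
roughly one cell's rDNA complement). R² is the squared Pearson correlation
of observed and fitted Ct. The slope must be negative — more template
amplifies earlier; a non-negative slope flags the curve invalid with a
warning and blocks downstream use. Amplification efficiency derives from
the slope as 10^(−1/a) − 1.

Family-level assays refit a single line on the **pooled raw points** of the
constituent genus series rather than averaging slopes, so the family R²
honestly reflects between-genus spread in body size and rDNA dosage (the
mechanism behind the comparatively low Cephalobidae R²). Only genera
actually observed in the microscopy samples are pooled. Both per-genus and
pooled fits are available since the original choice is not documented.

Ct at or above 60 cycles (the protocol's cycle count) is below detection:
density is a censored zero and the censoring flag propagates to profile
totals instead of being dropped.

## Quantification

density(taxon) = correction × dilution_adjustment × 10^((Ct − b)/a), per
100 ml of elutriated soil.

- **Extraction correction.** The spiked mammalian internal standard tracks
  lysis/purification recovery. The published protocol states the purpose
  but not the arithmetic, so the formula is an explicit design choice:
  fold-recovery = 2^(internal Ct − reference Ct) under ~100 % PCR
  efficiency, with a configurable efficiency base. A missing internal
  standard yields factor 1 with a warning.
- **Dilution bookkeeping.** Calibration lysates were assayed at 1000×
  dilution and field lysates at 50×, so a default adjustment of
  1000/50 = 20 multiplies field densities. This too is exposed in
  configuration and logged rather than hard-coded, because the original
  arithmetic is unrecoverable.
- **Coverage diagnosis.** OLS of log₁₀(qPCR total) on log₁₀(microscopy
  total); the slope should be indistinguishable from 1 and samples should
  sit within ±0.5 log₁₀ of the fitted trend (vertical distance; the band
  is parallel to the trend line). Externally studentized residuals flag
  outliers at |t| > 2. Non-positive totals are excluded with a warning; a
  perfect fit returns zero studentized residuals, and with fewer than four
  points external studentization is undefined (NaN).

## Survey statistics

- **Moving average.** The survey-plot convention is followed literally:
  with window 2 the value plotted at position i is the mean of raw points
  i+1 and i+2 (points 2 and 3 are portrayed at position 1), so the first
  raw point never enters the trend and the output has n − window elements.
  At the boundary window = n, the single truncated element mean(points
  2..n) is returned — the stated rule exhausts the series there and this is
  the documented, tested choice. The conventional trailing alignment is
  available via `alignment="trailing"`.
- **Mann-Whitney U**: exact enumeration when n+m ≤ 12 and tie-free,
  otherwise the tie-corrected normal approximation without continuity
  correction (so identical samples give p = 1); the method used is
  reported. Two-sided p doubles the smaller tail, capped at 1.
- **Welch t** on log₁₀ totals with Welch–Satterthwaite degrees of freedom.
- **Mantel**: the classic Z statistic (sum of off-diagonal elementwise
  products) with the normalized r also reported; the null permutes rows
  and columns of X simultaneously; p uses the add-one convention
  (#{Z_perm ≥ Z_obs} + 1)/(n_perm + 1) and can never be 0. Default 9,999
  permutations, seeded. `n_permutations="all"` enumerates every
  non-identity permutation for small matrices. The partial form correlates
  elementwise OLS residuals of X|Z and Y|Z; it requires an explicit third
  matrix — the default comparison between two seasonal community matrices
  (squared Euclidean distance over fungivore time-profiles) is the simple
  test.
- **Covariate windows** sum a daily series over the window strictly before
  the sampling day (default 21 days, the rainfall convention) and reject
  incomplete windows.

## Synthetic world

The generator reproduces the study's shapes, not its biology:

- **Reference set**: 15 taxa × 2 genera × 2 members descend from one
  ancestral sequence with 2 %/1 %/0.5 % family/genus/member substitution
  divergence and family-shared deletions in a variable region (so the
  alignment is genuinely gapped). Each taxon's two planted 20-mers are
  drawn to have Tm within ~0.8 °C of 63 °C, lie one 110-nt amplicon gap
  apart, are identical across members, and are verified ≥ 6 mismatches from
  every non-target (resampled otherwise; an impossible layout raises).
- **Calibration series**: Ct = a·log₁₀(N) + b + N(0, 0.3²) cycles over the
  1–100 design; the default true (a, b) pairs are the 15 packaged assay
  parameters.
- **Survey**: 18 sampling weeks over a 40-week season, 4 field + 2 forest
  composites per week; per-taxon densities follow log-normal scatter
  (σ = 0.15 log₁₀) around smooth sinusoidal trajectories with site-specific
  offsets; extraction recovery varies by N(0, 0.5²) cycles on the internal
  standard; microscopy totals carry log-normal observation error
  (σ = 0.2 log₁₀, which puts ≈ 98.8 % of samples inside the ±0.5-log
  band).

What passing tests show: the pipeline's algebra closes exactly (zero noise
in → planted truth out), estimators are unbiased with correct interval
coverage under Gaussian Ct noise, and the combinatorial procedures agree
with brute force. What they do not show: robustness to life-stage
structure and per-taxon rDNA dosage variation, PCR inhibition by soil
compounds, primer performance against unsequenced relatives, or any other
property of real environmental DNA. The study's own field numbers that
depend on unpublished per-sample raw data (the seasonal density curves, the
observed coverage slope and in-band fraction, and the site-comparison
p-values) are out of reach at desk scale and are deliberately not asserted.

## Problem sizes

Test and script problem sizes are the package's own choices: 1200-column
alignments with 60 sequences, 500-replicate recovery simulations, 2000
Mann-Whitney null draws, 500 Mantel null draws at 199 permutations, and
exhaustive enumeration up to 8 leaves / 5 entities — all small enough to
re-run routinely while leaving the statistical assertions well-powered.
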