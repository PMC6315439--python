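# Methods

## The comparison model

The pipeline implements vote-counting meta-analysis of differential
proteomics tables: no effect sizes are pooled and no heterogeneity model is
fit. A protein is a consensus hit within one stratum of one disease when at
least `min_studies` independent studies report it after harmonization
(default 2), and its *direction class* records whether the supporting
studies agree: `consistent_up`, `consistent_down`, or `mixed`. Cross-disease
overlap is the symbol intersection of two consensus lists; mixed entries
participate (a protein can be robustly dysregulated in both diseases while
disagreeing in direction), and a boolean flags the pairs whose direction
classes are both consistent and equal.

Assumptions this encodes:

- Studies are exchangeable votes. A study contributes at most one vote per
  symbol (duplicates are collapsed at ingest), and votes are unweighted —
  a 2-patient 2D-gel study counts as much as a large label-free cohort.
- Official gene symbols are the common currency across species and
  platforms; harmonization is case-insensitive symbol equality, with no
  orthology resource consulted.
- Biofluid and tissue/cell strata are never pooled. Secretion or leakage
  into CSF/serum can accompany a decrease in the tissue, so the two
  compartments may legitimately disagree; the overlap is reported per
  stratum.

## Harmonization rules

- **Fold-change gate.** "At least 20% change" is read as the symmetric
  ratio rule: keep FC ≥ τ or FC ≤ 1/τ with τ = 1.2, boundaries inclusive.
  Ratios are symmetric in log space, so up- and down-regulation are treated
  equally (down cutoff ≈ 0.833). The alternative arithmetic reading
  |FC − 1| ≥ 0.2 (down cutoff 0.8) is available via
  `apply_fc_filter(..., convention="arithmetic")`; the ratio convention is
  the default because a 1.2× increase and its exact inverse should gate
  identically. Studies whose authors already applied their own cutoff
  (`fc_prefiltered`) pass through unchanged, and direction-only records
  (no numeric FC) always pass — qualitative reports were included by the
  source comparison after the original authors' own thresholds.
- **Deduplication.** Multiple rows mapping to one symbol within a study
  (isoforms, peptides) collapse to the record with the largest |log FC|;
  if the duplicates disagree in direction the study contributes that symbol
  to *neither* direction (all rows flagged `direction_conflict` and logged).
  How the source comparison handled isoform conflicts is not documented;
  abstention is the conservative choice for a vote counter.
- **Bookkeeping.** No operation ever deletes a row: excluded records stay in
  the table with an `excluded_reason` (`unmapped`, `below_fc_threshold`,
  `duplicate_collapsed`, `direction_conflict`), so filters are idempotent and
  auditable.

## Over-representation statistics

For a query of n symbols drawn from a background of N, a term of K members
overlapping the query in k:

- **Hypergeometric / Fisher upper tail**: p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n),
  evaluated in log space (scipy) so backgrounds of 10⁵ symbols are stable.
- **EASE-style score**: the same tail evaluated at k − 1 on unchanged
  margins — the "remove one gene from the overlap" jackknife that penalizes
  single-gene support; k = 1 returns 1. This is the standard public reading
  of the EASE adjustment; the original tool's exact contingency handling is
  not specified line-by-line anywhere reproducible.
- **Binomial tail** with q = K/N, the convention of pathway-database
  over-representation services.
- **Benjamini–Hochberg**: step-up adjusted p = min_{j≥i}(p₍ⱼ₎·m/j) capped at
  1, computed across exactly the tested terms (those with k ≥ 3 by default).
  Following the tools being emulated, hypergeometric/EASE results are
  filtered on **raw** p ≤ 0.05 (adjusted values are carried for
  transparency), while binomial results filter on the **adjusted** value;
  both behaviours are switchable (`filter_on="raw"|"adjusted"`).
- **Term merging**: terms with *identical* overlap-symbol sets describe the
  same signal and merge into one record keeping the smallest-p member's
  statistics, names joined with " / ".
- The background defaults to the union of the GMT membership when no
  explicit universe is supplied; results depend on this choice and the
  collection used, so both are the caller's responsibility.

## Network summaries

Edge tables are undirected, self-loop-free, max-deduplicated, with combined
scores either on [0,1] or STRING's 0–1000 export scale. Filtering at the
conventional high-confidence 0.700 is boundary-inclusive. Components and
degrees come from networkx; components are ordered by size then
lexicographic minimum, and the degree ranking breaks ties alphabetically,
so summaries are order-invariant. Evidence-channel columns are tolerated
but never interpreted.

## Validation arithmetic

- **Densitometry**: band density / loading-control density; group effect
  reported as 100·(mean_disease/mean_control − 1) %.
- **Group test gate**: both groups pass Shapiro–Wilk at α = 0.05 → Student
  (equal-variance) two-tailed t-test, matching the "independent two-tail
  t-test" convention of SPSS-era analyses; otherwise two-tailed
  Mann–Whitney U, exact for combined n ≤ 20 (typical validation group sizes
  are 4–5) and normal-approximated with continuity correction above.
  Groups below n = 3 and (near-)constant groups skip the gate and go
  nonparametric, since Shapiro–Wilk is undefined there.
- **OD calibration**: piecewise-linear interpolation through the step-tablet
  (grey, OD) points, exact at the knots, clamped to the end ODs outside the
  calibrated range; the negative-control mean OD is subtracted afterwards.
  Background-corrected ODs may come out negative and are reported as-is
  (with a warning) rather than clipped, keeping group means unbiased.
- **Pfaffl ratio**: E_target^ΔCt_target / E_ref^ΔCt_ref with efficiencies in
  (1, 2] and ΔCt = mean Ct(control) − mean Ct(sample).
- **Efficiency estimation**: log₁₀(fluorescence) is fit over every 4-point
  cycle window; the window maximizing R² (earliest on ties) gives
  E = 10^slope. This is a simplified stand-in for dedicated
  window-of-linearity software, whose full algorithm is not published in
  closed form; E > 2 clips to 2 with a warning, E ≤ 1 (no amplification)
  raises.

## Synthetic-data generator

`simulate_study_set` emulates the statistical structure the comparison
operates on, starting at the published-table level (no spectra or peptide
inference): a universe of `n_genes` symbols; a planted dysregulated set per
disease with a shared core; per-study Bernoulli detection of planted genes
(`detect_prob`); direction flips with `flip_prob`; fold changes
2^N(±mean_log_fc, σ) on the reported side; unplanted genes appearing at
`background_rate` with log2 FC ~ N(0, 0.5), many inside the 20% band so the
gate has work to do; and accessions drawn from recognizable styles
(NP_…, gi|…, IPI…) so identifier mapping is exercised. All draws come from
one seeded generator; identical configs give byte-identical files.

Defaults (chosen once as a realistic benign regime, and documenting the
recovery conditions the pipeline is expected to meet): 5 studies per
disease in one stratum, detect_prob = 0.95, flip_prob = 0.02,
background_rate = 0.01, mean |log2 FC| = log2 1.5 ≈ 0.585 with σ = 0.3
(so roughly 15% of planted draws fall below the 1.2 gate and exercise the
exclusion bookkeeping), universe of 500 genes with 40 planted per disease
and 15 shared — the shared-core scale the real comparison resolved. Under
these conditions the recovered cross-disease overlap reaches Jaccard ≥ 0.9
against the planted shared set in ≥ 95 of 100 seeds (regression-tested);
the noiseless limit (detection 1, no flips, no background, σ = 0) recovers
the planted consensus exactly.

What the generator does *not* model — and therefore what passing tests do
not show about real data: correlated detection across studies sharing a
platform or lab, systematic direction biases between strata, abundance-
dependent detection, within-study p-value selection, or symbol-mapping
errors beyond simple misses. Real multi-study comparisons face all of
these; the generator validates the machinery, not the biology.

## Published-table fixtures

Three small tables transcribed from the published comparison's printed
per-protein citation lists ship with the package (`prometa/data/`): the two
biofluid proteins with explicit citations (cystatin C ×4 down,
chitinase-3-like 1 ×3 up), the eleven tissue/cell proteins upregulated in
≥ 3 studies, and the fifteen proteins reported in both diseases with their
supporting studies split per disease. Rebuilding presence matrices from
them reproduces the printed counts exactly. The per-study directions behind
the fifteen-protein table were published only as a figure, so that table
carries a placeholder direction and is used strictly for membership and
support counts. On the cross-disease comparison the SMA side is treated as
the prior comparison's published list (taken as-is), while the ALS side is
re-derived at min_studies = 2 — mirroring how the comparison was actually
run.

## Numerical and design notes

- Tails and BH come from scipy/statsmodels; enumeration oracles in the test
  suite verify them independently for all margins with N ≤ 12 and lists of
  length ≤ 5.
- All ranked outputs break ties alphabetically, so runs are reproducible to
  the byte.
- Problem sizes in tests and the acceptance script (500-gene universe,
  5 studies per disease, 100-seed regression loops, 20-seed acceptance
  averages) were chosen so the whole suite completes in well under a minute
  while keeping binomial sampling error far from the asserted margins.
- Known limitations: no orthology-aware mapping, no study weighting or
  quality scores, flat gene sets (no GO graph propagation), no pooled
  effect sizes, and the EASE/efficiency components are documented
  approximations of tools whose exact algorithms are unpublished.
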