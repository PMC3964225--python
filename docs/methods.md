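# Methods

## Quantitation model

Reporter-ion ratios are multiplicative, so all protein-level statistics
are computed in log10 space.  For one protein in one sample, the
recalculated ratio is the geometric mean of the ratios of its
qualifying peptides — non-decoy identifications with confidence ≥ 0.95
(`min_confidence`) that carry a ratio for that sample.  Dispersion is
summarized as the **error factor**

    EF% = (10^(t_{0.975, n−1} · SE) − 1) × 100,

where SE is the standard error of the peptide log10 ratios and n the
peptide count: EF% is the percent half-width of the multiplicative 95%
confidence interval of the ratio.  EF% is 0 when all peptides agree
exactly and +∞ for a single-peptide ratio (no CI can be formed; such
ratios are always removed by the peptide-count filter anyway).

Reliability filtering happens per sample-level ratio: it survives only
with ≥ 3 peptides (`min_peptides`) and EF% < 11.1 (`max_ef_percent`,
i.e. the 95% CI no wider than ×1.111).  Of the proteins that retain at
least one ratio, only the `floor(0.95·n)` with the smallest worst-case
(max-over-samples) EF% are kept (`keep_fraction`), ties broken by input
order.  The floor is deliberate: retention is a hard percentile, so a
single-protein list with `keep_fraction < 1` keeps nothing.

The EF threshold is applied per sample-level ratio (rather than to one
per-protein scalar) because a protein can be tightly measured in one
set and poorly in another; the percentile retention then ranks proteins
by their worst surviving EF.

## Local FDR

Identification reliability is controlled with a target-decoy **local**
FDR.  Entries (protein scores, higher = better; the score is a summed
−log10(1 − confidence) over distinct peptides, capped per peptide) are
ranked by decreasing score; each target's raw estimate is
min(1, decoys/targets) inside the rank window of `window` entries
centered on it; the raw sequence is then projected onto non-decreasing
(with decreasing score) sequences by pool-adjacent-violators, and decoy
entries get local FDR 1.  Proteins with local FDR > 0.05 are removed
when sets are merged.

The window is a bandwidth: with window w the estimator resolves decoy
density only down to ~1/w, so judging *calibration at a 5% cutoff*
needs w of order 100 (the suite uses 101).  The pipeline default
(w = 20) is deliberately local — it reacts quickly to the score region
where decoys appear — at the price of granular estimates; with a 5%
acceptance cutoff it effectively accepts zero-decoy windows, which is
slightly anti-conservative in the estimate it reports but still keeps
the realized false-discovery proportion of the accepted set well under
5% in the simulator (measured directly by the calibration test).

## Dysregulation calling

A protein is called **up** when its ratio-to-reference is ≥ 1.5
(`up_threshold`) in ≥ 50% (`majority`, boundary inclusive) of the
cancer samples with a present value, **down** when ≤ 0.67
(`down_threshold`) in ≥ 50%.  The denominator is *present* cancer
values: sparsely quantified proteins are judged on the evidence that
exists, which reduces to the all-samples denominator on dense matrices
but generalizes to sparse ones.  With the default thresholds a protein
can never satisfy both rules in the same sample; if contrived
thresholds make both majorities pass, the larger fraction wins (an
exact tie goes to up — an arbitrary but deterministic choice).  An
all-missing row has both fractions 0 and is called none.

## Clustering and separation test

Ratios are log2-transformed (the base only rescales distances; the
merge topology is invariant).  Sample–sample distances are
pairwise-complete city-block: the mean |Δlog2| over proteins present in
both samples, rescaled by the total protein count so sparser pairs are
not systematically closer — the behavior of the classic expression-
clustering tools with missing data.  A pair sharing no protein is an
error rather than a guess.  Agglomeration (average linkage by default;
complete and single exposed) is cut at the root into two groups and the
composition tallied against the cancer/normal labels.

The separation statistic is deliberately scalar: per sample, the mean
|log2 ratio| over the protein set (dysregulation pushes this score up
in both directions of regulation), compared between groups with
Welch's unequal-variance two-tailed t-test.  The folded score
distribution makes the test mildly conservative for small groups; at
the 10 vs 10 design size its type-I error is at the nominal 5% (checked
by simulation in the suite).

## Validation calculators

* **IHC**: intensity (0–3) + frequency (0–4) give a combined 0–7
  score per core; tumor vs matched normal differences within ±1
  (`tolerance`) are "no change", larger differences are
  increased/decreased.  The convention that intensity 0 and frequency 0
  occur together is enforced.
* **ΔΔCt**: per sample, ΔCt = Ct(gene) − mean Ct of exactly three
  housekeeping genes; per matched pair, ΔΔCt = ΔCt(tumor) −
  ΔCt(normal); the per-gene fold is the geometric mean over pairs of
  2^(−ΔΔCt) (equivalently 2^(−mean ΔΔCt)), with a paired two-tailed
  t-test of the ΔΔCt values against zero.  Folds below 1 are reported
  as negative reciprocals (0.0769 → −13.0), the usual qPCR convention.
  Zero-variance ΔΔCt across pairs degenerates the t-test; the p-value
  is then 0 or 1 by the sign of the mean.
* **Densitometry**: per pair, (cancer band / cancer loading) /
  (normal band / normal loading); the arithmetic mean fold over pairs
  plus a paired t-test on log2 folds.
* **ELISA cutoff**: control mean + k·SD (sample SD, k = 2 by default),
  an upper reference limit — the marker here is elevated in cases, so
  "mean ± 2 SD" is implemented one-sided upward; `k` is exposed.
* **Contingency**: Pearson chi-square without continuity correction on
  2×2 tables, 1 df, two-sided; zero margins are an error.  The packaged
  serum-marker tables reproduce their printed p-values for status,
  grade and sex; the stage table is shipped as printed although its
  margins are internally inconsistent, and no p-value is asserted
  for it.

## Synthetic data

`simulate_peptide_sets` emulates the discovery design: 10 tumor/normal
pairs distributed over seven 4-plex sets (three study samples per set
plus a pooled-normal reference channel whose tag position is
randomized per set — a no-op on ratios, recorded as metadata), 1600
true proteins with 15 up at fold 2.0 and 40 down at fold 0.45, peptide
counts of 1 + Poisson(4) per protein per set, and lognormal
multiplicative peptide noise at 20% CV.  The identification list is
contaminated with false targets (default 15% of the protein count) and
decoy (`REV_`) entries; `decoy_fraction` is the decoy share of the
*false* identifications (0.5 = the standard concatenated-search
assumption that an incorrect match lands on target and decoy sequence
with equal probability — this is what makes decoy counting estimate the
false-target density at all).

Two regimes matter:

* **Zero noise** (`peptide_cv=0`, all peptides confident): aggregated
  ratios equal the true folds exactly, every filter passes (except the
  hard 5% percentile retention, which trims the same tail of proteins
  in every set), and the full pipeline recovers ~95% of dysregulated
  proteins with zero false calls and a pure 10-tumor cluster.  This is
  the end-to-end correctness check.
* **Default noise** (20% CV, ~5 peptides/protein/set): the EF < 11.1%
  gate is then the binding filter — a 5-peptide ratio has a typical
  EF ≈ 28%, and passing needs either ≥ ~17 peptides or a luckily small
  sampled dispersion — so only a minority of sample-ratios survive and
  most proteins end up sparsely quantified or unquantified.  This
  mirrors real studies of this design, where only a few hundred of
  ~1600 identified proteins are reliably quantified.  What the tests
  assert in this regime is therefore *fidelity*, not coverage: every
  dysregulated protein that stays quantified is called in the correct
  direction, nulls stay uncalled, and the false-call rate stays low.
  Recovery of a fixed protein list is a coverage property governed by
  abundance (peptide depth), which the generator deliberately keeps
  homogeneous.

The generator does not simulate channel isotope impurity, peptide
abundance heterogeneity, shared/razor peptides, or chromatographic
batch effects; passing tests speak to the estimators and decision
rules, not to robustness against those real-data features.

Validation cohorts: IHC normal scores are drawn low (intensity and
frequency 1–2) so a +3 true shift stays in range; Ct tables place
housekeeping genes at Ct 18–22 with gene ΔCt baseline 5 and additive
Gaussian noise (0 by default); ELISA levels are right-skewed draws
affinely rescaled to the exact configured group mean/SD (control
1.233 ± 0.648 ng/mL, so the k=2 cutoff is exactly 2.529), which keeps
group summary statistics exact at any cohort size — with heavy noise
and tiny cohorts the rescaling could go negative, in which case the
generator raises rather than clipping.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from a
single integer; identical seeds give byte-identical outputs.  The test
suite runs the full default-size simulation for the zero-noise
end-to-end check and scaled-down designs (≈120 proteins, 3 sets)
elsewhere; FDR calibration pools 25 seeded identification lists of 640
entries.  The packaged-matrix computations are milliseconds.

## Known limitations

* The identification score is a confidence-sum surrogate; it is not a
  search-engine score, and the local-FDR estimator's bandwidth/cutoff
  interaction described above is inherent to windowed counting.
* The Welch separation statistic is one defensible scalarization of
  "group difference over a protein set"; a per-protein moderated test
  with multiplicity control is out of scope by design.
* The secretome stage consumes annotation flags; it never runs the
  predictors, so its output is only as good as the supplied flags.
* Merging assumes ratios to a *common pooled reference* are comparable
  across sets; no additional cross-set normalization is applied.
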