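# Methods

## Catalog statistics

A circRNA catalog record is a genomic interval plus junction-read evidence.
Internally all coordinates are 0-based half-open (BED convention); 1-based
inclusive dialects are converted on load (`start − 1`), which round-trips
losslessly. Malformed rows (e.g. `end ≤ start`) are returned as error
records, never silently dropped.

**Junction ratio.** `bsj_reads / total_junction_reads` — the circular
fraction of transcription at the junction site. Undefined (returned as
missing) when nothing aligns to the site; `bsj > total` is a hard error.

**Frequency and abundance.** Frequency counts samples with at least
`min_reads` junction reads (default 2, the conventional detection floor for
a circRNA in a sample). Abundance is the column sum over all samples;
ranks are descending with ties broken lexicographically by `circ_id` so
output is deterministic. The "top quartile" flag is inclusive:
`abundance ≥ 75th percentile` under the linear-interpolation percentile
definition.

**Circ–linear screen.** For top-quartile circRNAs only, the Spearman
correlation (scipy, average ranks for ties) between junction counts and
host-gene FPKM, over samples with `count ≥ detection_min` (default 1;
set 2 to mirror the frequency rule) and non-missing FPKM. FPKM is never
zero-imputed. Fewer than 3 usable samples yields a missing ρ with a recorded
reason. The inclusion rule for the compendium-scale correlation is exposed
as configuration because the convention is not standardized across studies.

**Integration.** Records match across databases when chromosome and strand
agree and both endpoints lie within `match_tolerance` nt. Pooled records are
clustered in a canonical (chrom, start, end, strand) sort, which makes
membership permutation-invariant to catalog input order. Identical
coordinates on opposite strands are kept separate and flagged. Venn region
counts are exact source-set combinations and sum to the number of distinct
circRNAs.

**Prioritization.** Candidates are ordered by (database support, abundance,
mean junction ratio, conservation breadth), all descending, ties by id. A
candidate that strictly dominates on all four axes is necessarily first;
with no integration data the order degenerates to abundance.

## Assay design

Primer binding is modeled as perfect string matching — no mismatch
tolerance, no nearest-neighbor thermodynamics (only the Wallace-rule Tm,
2(A+T)+4(G+C), is reported). The rationale: junction assays are validated by
exact sequencing of the amplified junction, and a mismatch model would add
parameters nothing in the workflow can falsify.

A circular isoform is a contiguous exon block concatenated in transcript
order (minus-strand exons reverse-complemented), with the BSJ between the
string's last and first base. The BSJ-centered pseudo-reference is the last
`flank` nt followed by the first `flank` nt, so every circular k-mer
(k ≤ L) occurs in the doubled sequence.

Junction-spanning primers straddle the BSJ with ≥ `min_overlap` nt
(default 6, minimum 4) on each side, must pass GC ∈ [30%, 70%] and contain
no homopolymer of 6+, must bind the circle exactly once, and must be absent
from the un-rotated linear sequence. Padlock arms are reverse complements of
the two adjacent windows flanking the BSJ (default 15 + 15 nt,
configurable), so in-silico ligation reconstructs the reverse complement of
the BSJ-spanning window; ligation therefore requires the circular junction.

Rolling-circle reverse transcription around a circle of length L yields a
concatemer ladder: round-k amplicon = round-1 + (k−1)·L, capped at
`max_rounds` = 3 by default. Round-1 length is the circular distance from
the forward primer's 5' base, across the BSJ, to the reverse primer's 5'
base, inclusive. In-silico PCR on circular templates enumerates sites on the
doubled sequence with product length capped at one circumference
(single-pass products; the ladder handles concatemers).

## Quantification

* **2^−ΔΔCt.** Replicate Cts are averaged arithmetically before
  ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator's ΔCt, so
  the calibrator's fold is exactly 1. Undetermined wells are dropped by
  default; an alternative policy imputes the cycle ceiling (40). They are
  never treated as zero.
* **RNase-R resistance.** 2^−(Ct_treated − Ct_mock) per target; values > 1
  are reported as-is (apparent enrichment of circles when equal RNA masses
  are loaded after digestion).
* **Molar mass.** Sum of NMP residue masses (A 329.21, C 305.18, G 345.21,
  U 306.17 g/mol). A circle adds nothing; a linear molecule adds one water
  (18.02) plus the 5'-end-group extra (OH +0, monophosphate +79.98,
  triphosphate +159.0 — the default, matching in-vitro-transcribed
  standards). Since a published standard's mass may come from an unstated
  convention, `composition_for_mass` searches a base composition of the
  printed length reproducing a printed mass under one fixed convention;
  agreement within 0.1% is the strongest consistency check available
  without the sequence itself.
* **Standard curve.** OLS of Ct on log₁₀(copies) over ≥ 3 points spanning
  ≥ 2 decades (the canonical series is 10¹¹…10⁷ copies);
  efficiency = 10^(−1/slope) − 1; a non-negative slope is a
  "non-amplifying curve" error.
* **Copies per cell.** copies/µg × pg RNA per cell × 10⁻⁶, with 7.72 pg per
  cell as the default total-RNA yield.
* **Exon-skip abundance.** max(total − canonical, 0); small negative
  differences are expected from measurement noise and are clamped with a
  warning rather than raised.
* **Gene copy number.** ΔCt against a centromeric reference corrects for
  aneuploidy; ΔΔCt against the parental line gives the fold; amplification
  is called at fold ≥ 2, inclusive.
* **Decay.** OLS of ln(fraction) on time; t½ = ln 2 / k; non-positive decay
  rates yield a missing half-life, non-positive fractions are excluded with
  a report.
* **Plasma conversion.** copies/µl of input cDNA × RT volume ÷ (fraction of
  eluate reverse-transcribed) ÷ plasma volume. With the default chain
  (1 ml plasma → 100 µl eluate, 15 µl into a 20 µl RT) the multiplier is
  133.3̅; the cDNA volume loaded into the dPCR cancels because the readout
  is already per µl of input.

## Cohort analysis

High/Low status comes from phospho-MET IHC when available (positive → High);
only a missing IHC call falls through to FISH amplification. The deciding
assay is recorded, and a FISH basis is never reported when an IHC call
exists.

The literal concordance formula — agreements over "positive by either plus
negative by either" — double-counts each discordant sample in the
denominator: (Npp+Nnn)/(Npp+Nnn+2Nd). It is the default because it is the
formula as stated; plain agreement (Npp+Nnn)/(Npp+Nnn+Nd) is exposed as
`mode="agreement"` and is always ≥ the literal value. Missing calls are
excluded pairwise; no imputation.

Continuous plasma values are binarized either at an explicit threshold or at
the midpoint of the exhaustive 1-D two-cluster split minimizing
within-cluster sum of squares — a deterministic, reproducible stand-in for
visual grouping of low vs high expressors.

Emergence in a longitudinal series is the first post-baseline timepoint at
≥ `fold_threshold` × baseline (mean of the pre-treatment window; a zero
baseline makes any positive value an emergence), sustained for
`persistence` consecutive points.

## Synthetic data

Generators draw from child streams `default_rng([seed, tag])` with one fixed
tag per generator, so each dataset regenerates independently and
byte-identically for a given config.

* **Catalogs.** ≥ 3 sources over a shared interval set; one spiked candidate
  present in all sources with dominant read counts (900/1000 junction
  reads), full conservation, and top abundance, mirroring how a genuinely
  dominant circRNA presents across databases. Files are written in two
  dialects (0-based BED-like; 1-based headered TSV) to exercise both
  readers.
* **Pan-cancer matrix.** Negative-binomial junction counts (mean 10,
  size 2 — overdispersed like capture-based counts); spiked circRNAs use
  mean 50 so the planted candidate is top-quartile abundant, as a dominant
  candidate is by construction. Correlated circ–gene pairs are coupled
  through a Gaussian copula with latent correlation 2·sin(πρ/6), the exact
  inverse of the copula's Spearman for continuous marginals; count
  discretization attenuates the realized ρ by < 0.002 at these parameters,
  so the planted value is recovered up to estimator noise. Marginals remain
  exactly negative-binomial and lognormal.
* **qPCR.** Ct = intercept − log₍₁₊E₎(copies) + N(0, σ); the intercept
  (default 40) is the Ct of a single copy, σ defaults to 0.15 cycles,
  E ∈ (0.7, 1.1]. The dilution series uses the canonical 10¹¹…10⁷ decades.
* **Cohort.** A latent High/Low status per patient (prevalence 0.5); each
  assay reports the status flipped with probability ε (default 0.05) and is
  missing at rate 0.1, independently. Mean pairwise agreement concordance
  converges to (1−ε)² + ε². Plasma concentrations are status-specific
  lognormals (medians 800 vs 60 copies/ml, σ_log 0.6).
* **Longitudinal.** A lognormal floor (20 copies/ml) before the programmed
  emergence timepoint, scaled 10-fold after it, with 20% CV multiplicative
  noise; one flat control patient. The decay-chase simulation uses 6
  timepoints over 20 h (~2.5 half-lives of the 8 h truth), the standard
  design for a transcription-block time course, which gives the slope
  estimator enough leverage for ±1.5 h recovery.

## What the simulations do and do not show

Passing tests demonstrate internal correctness — the statistics match
independent brute-force oracles, conversions match closed forms, and planted
parameters are recovered under the stated noise — on data whose error
structure is exactly the assumed one (Gaussian Ct noise, independent assay
flips, exact-match primer binding). They do not demonstrate robustness to
real-data pathologies: batch effects and library-size variation in count
matrices, probe cross-hybridization, PCR inhibitors in plasma, FFPE RNA
degradation, or inter-observer variability in IHC/FISH scoring. The
perfect-match PCR model in particular overstates specificity for primers
with near-match off-target sites.

## Numerical and design notes

* Sample Spearman at n = 250 has a standard error of ≈ 0.06 near ρ = 0.2, so
  single-replicate recovery within ±0.1 succeeds in only ~89% of draws at
  that target; recovery rates at ρ = 0.5 and 0.8 are comfortably higher.
  This is estimator variance, not generator bias.
* Gene-copy-number and half-life recoveries are assessed on means across
  seeded replicates; single-seed ΔΔCt estimates at σ_Ct = 0.2 scatter by
  ~±16% around the planted fold.
* Percentile and tie-break conventions (inclusive 75th percentile,
  lexicographic tie-break, average ranks) are fixed and documented so
  independent reimplementations can match outputs bit-for-bit.
* The concordance double-counting ambiguity and the compendium inclusion
  rule are the two places where a published description underdetermines the
  computation; both variants are implemented and the choice is explicit in
  the API.
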