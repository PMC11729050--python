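# Methods

## Scope

Tumor-only arm-level allele-specific copy number analysis from a targeted
SNP panel: ~1500 SNPs over the 41 scoreable chromosome arms (autosomes + X;
the acrocentric p-arms 13p, 14p, 15p, 21p and 22p carry no scoreable unique
sequence and are excluded). The pipeline works entirely at arm resolution —
no sub-arm segmentation — and assumes one tumor clone per sample with
integer allele copies per arm, total ≤ 4.

## Admixture model

A specimen is a mixture of tumor cells (purity `p`) and diploid normal
cells (`1 − p`). At a germline-heterozygous SNP on an arm whose tumor
genotype has `major ≥ minor` allele copies:

- expected BAF (B-major orientation):
  `(p·major + (1−p)) / (p·(major+minor) + 2(1−p))`; the A-major orientation
  is its mirror around 0.5.
- expected log2 depth ratio against a diploid baseline:
  `log2((p·(major+minor) + 2(1−p)) / 2)`.

The five-state universe and its signatures at full purity:

| state | label | mirrored BAF | log2 ratio |
|---|---|---|---|
| (1,1) | AB | 0.50 | 0 |
| (1,0) | A0/0B | 1.00 | −1.00 |
| (2,0) | AA/BB (cn-LOH) | 1.00 | 0 |
| (2,1) | AAB/ABB | 0.667 | +0.585 |
| (2,2) | AABB | 0.50 | +1.00 |

Inverse estimators:

- purity from an LOH arm's mirrored BAF `m`: losses `p = 2 − 1/m`,
  copy-neutral LOH `p = 2m − 1` (undefined at `m = 0.5`).
- ploidy: equal-weight mean of per-chromosome total copies over the 23
  chromosomes (1–22, X). Equal chromosome weights, not base-pair weights:
  e.g. 16 single-copy chromosomes + 7 diploid gives (16·1 + 7·2)/23 = 1.304,
  reported at one decimal as 1.3.

## Simulator

Per locus: germline genotype drawn Hardy–Weinberg from the locus population
BAF (0.5 throughout the default panel, giving an expected heterozygous
fraction of 0.5 per arm); depth drawn gamma–Poisson with mean
`mean_depth × expected relative coverage` and coefficient of variation
`depth_dispersion`; B-allele reads binomial at the expected BAF. Germline
homozygotes stay at BAF 0/1 regardless of arm state. The male X is germline
hemizygous: every X locus at BAF 0 or 1, one-copy coverage baseline, tumor
states restricted to {(1,0), (2,0)}.

Defaults — these are the study conditions, not tuning knobs:
`mean_depth = 500` (worked examples use 1000), `depth_dispersion = 0.2`
(FFPE-level variability), 1500 loci (36–37 per arm), purity 0.8 for worked
fixtures except the near-haploid case at 0.65.

At this design the arm-level summary noise is approximately 0.015 for the
median mirrored BAF and 0.06 for the median log2 ratio (median over ~36 loci
at dispersion 0.2, measured by simulation). These two scales standardize the
arbitration distance below.

## Arm caller

**Summary statistics.** Informative ("heterozygous-compatible") loci are
those with depth ≥ 20 and BAF strictly inside (0.05, 0.95). Each arm reduces
to: the median mirrored BAF over informative loci, the heterozygous fraction
(informative / covered loci) against its Hardy–Weinberg expectation, and the
median log2 depth ratio against the diploid baseline.

**Depth normalization (two-pass, tumor-only).** Pass one uses the
genome-wide autosomal median depth as a provisional baseline. Arms that are
allelically balanced (mirrored BAF < 0.58 with an intact heterozygous band)
then anchor the final baseline. When those arms split into distinct coverage
clusters — heterozygous AB arms coexisting with doubled AABB arms — the
lowest cluster (arm medians within 1.25× of the lowest) is the diploid
anchor, mirroring how copy-number "height" is read against heterozygous
chromosomes. A naive "mechanism = none" provisional rule deadlocks on
gain-heavy genomes where the genome-wide median locus itself sits in a
gained arm; anchoring on *allelically* balanced arms avoids that.

**Decision ladder.**

- allelic tier: when the heterozygous band holds at least `min_informative`
  (8) loci the mirrored BAF decides — balanced < 0.58 ≤ imbalance < 0.75 ≤
  LOH. When the band is too thin to judge, a heterozygous fraction below
  half its expectation is itself the LOH evidence (at high purity LOH pushes
  every germline het to BAF 0/1, emptying the band; a tumor-only caller must
  score the deficit). The deficit route deliberately does not override a
  readable, clearly balanced band: ordinary germline sampling shortfalls of
  het loci would otherwise produce false LOH.
- coverage tier: loss ≤ −0.15 < neutral < +0.13 ≤ gain on the log2 ratio.
- joint state: strong combinations map directly (LOH+neutral → (2,0),
  imbalance+gain → (2,1), balanced+neutral → (1,1)); imbalance+loss is a
  diluted/subclonal one-copy loss, kept integral as (1,0) with a
  low-confidence flag. All other combinations are arbitrated.

**Arbitration.** Remaining combinations (balanced+gain, balanced+loss,
imbalance+neutral, LOH+loss, LOH+gain) pick the nearest expected
(mirrored BAF, log2) signature over the allelically consistent states at
purities in [0.4, 1.0] (step 0.02), with each axis standardized by its
typical noise (0.015 BAF, 0.06 log2). Two deliberate refinements over plain
thresholding:

- *Noise scaling matters.* The BAF axis is several times less noisy than the
  depth axis; an unscaled Euclidean distance lets depth noise override clear
  allelic evidence near tier boundaries. Unconditionally mapping
  balanced+gain to AABB would alone misclassify ~1.4% of true (1,1) arms at
  the default dispersion.
- *Band-emptiness consistency.* When the heterozygous band is empty, only
  (state, purity) combinations whose expected BAF actually leaves the
  informative band are admissible: a one-copy loss at purity 0.4 keeps hets
  at BAF 0.625 and cannot explain an empty band, so it must not claim a
  copy-neutral LOH arm on a mild depth dip alone.

**Male X.** Coverage evidence only, against a one-copy baseline
(log2 = −1). A tier crossing is called only when the altered state's
expected signature is nearer than the baseline across the operating purity
range, so depth noise just past the threshold does not fabricate X events.

**Thresholds.** The LOH mirrored-BAF threshold 0.75 follows the field
convention of scoring allele-fraction tracks below 0.25 / above 0.75. The
imbalance threshold 0.58 makes a single-allele gain scoreable as imbalance
at purity ≥ 0.4. Coverage thresholds −0.15/+0.13 detect single-copy events
at purity ≥ 0.4 while tolerating dispersion-0.2 depth noise. All six
thresholds are overridable via the CLI config (`caller:` block); every run
logs the resolved set.

Measured recovery at these defaults (≥ 200 simulated arms per state per
purity, depth 500): 100% for all five states at purity ∈ {0.6, 0.8, 1.0};
see `analysis/04_caller_calibration.py` for the full sweep down to 0.3.

**Dilution caveat.** At purity ≤ 0.1 every state's expected signature
collapses into the balanced thresholds except AABB: its expected log2 at
purity exactly 0.1 is log2(1.1) = 0.1375, marginally above the 0.13 gain
threshold, so a noise-free AABB arm is still (correctly) detected there.
The property holds for AABB from purity 0.09 down.

## Pattern classification

- Pattern 1: no altered arms. Pattern 2: only loss-tier mechanisms (loss,
  cn_loh). Pattern 3: only gain-tier (gain, balanced_gain). Pattern 4: both.
  AABB counts on the gain side; a sample whose only alterations are AABB
  arms is reported Pattern 3 with an explicit ambiguity warning. The
  `count_balanced_gain` switch controls whether AABB arms enter the
  altered-arm tally (default yes).
- Massive loss: a chromosome is LOH'd when ≥ 1 scoreable arm carries an
  LOH-tier state; the flag requires ≥ 15 of 22 autosomes LOH'd, routed
  near-haploid vs near-homozygous by ≥ 60% dominance of loss vs cn-LOH.
  The 15/22 threshold separates observed massive-loss genomes (16–20
  chromosomes) from ordinary Pattern 2 karyotypes (≤ 6).
- Genome doubling: ≥ 10 LOH-tier arms AND (every remaining heterozygous arm
  is AABB, or ≥ 60% of LOH'd chromosomes are copy-neutral — the
  post-doubling signature).
- Purity estimate: median of per-LOH-arm inversions; absent without LOH
  arms. Ploidy estimate: per-chromosome mean of arm total copies, averaged
  with equal chromosome weights; absent if any chromosome is fully no-call.
- A sample with > 50% no-call arms raises an "uninterpretable" error (FFPE
  failure contract).

## Cohort statistics

- Mean summaries: two-sided Student-t intervals, `t.ppf`-based, reported at
  2 decimals (percentages at 1 decimal).
- Contingency tables: Pearson chi-square without continuity correction;
  zero rows/columns are errors; expected counts below 5 warn.
- Mann–Whitney U: exact two-tailed p by full enumeration of label
  assignments with midranks when both samples have n ≤ 8 (correct under
  ties, which scipy's exact method does not handle); tie-corrected normal
  approximation otherwise.
- No multiple-testing correction.

### Known limitation: chi-square vs permutation null

The acceptance property that the asymptotic Pearson p agree with a
100,000-draw Monte-Carlo permutation p within 3 Monte-Carlo standard errors
for random 2×4 tables with n = 61 is not attainable: at that sample size the
chi-square approximation error is systematically ~0.002–0.02 absolute —
several times the Monte-Carlo standard error (≤ ~0.005) — regardless of how
the permutation is implemented (measured with both the ≥-convention and
mid-p). This is a property of the asymptotic approximation itself
(discreteness plus O(1/n) error), not of either implementation. The test
(`tests/test_acceptance.py::test_chi_square_tracks_permutation_null`)
implements the property as stated and is expected to fail; it is retained
un-weakened as documentation of the approximation's limits.

## Fixture encoding decisions

- The near-haploid worked case lists chromosome "23"; it is encoded as X
  (the panel covers autosomes + X only).
- A "part of 5q" event is encoded as whole-arm 5q: the pipeline is
  arm-resolution.
- One worked case gives chromosome 13 both in a copy-loss list and with an
  extrapolated AA genotype; it is encoded as copy-neutral (2,0) on 13q.
- Worked cases without a stated sex are encoded female so listed X-LOH is
  expressible as a biallelic-locus LOH call.
- The doubled near-haploid case carries both "endoreduplication occurred"
  and ploidy 1.3; a doubled genome with ploidy 1.3 is arithmetically
  inconsistent under whole-copy states, so the 1.3 arithmetic is reproduced
  from the single-copy chromosome list and the doubling claim is recorded as
  a separate flag, without reconciling the two.
- In the printed-tally cohort constructor, the single multilineage tumor
  (altered, pattern class unpublished) is recorded Pattern 4; any altered
  pattern reproduces the printed totals. Per-sample altered-arm counts in
  that constructor are placeholders consistent with each pattern class (the
  per-patient counts are unpublished) — only the tallies and percentages are
  meaningful.

## Further limitations

- One clone per sample; no subclonality, no states above total copy 4.
- An all-AABB genome with no heterozygous diploid arms is unidentifiable
  from a diploid genome by tumor-only self-normalization (both are
  allelically balanced with uniform coverage); the balanced-arm
  lowest-cluster anchor resolves mixtures of AB and AABB arms, not the pure
  case.
- No read-level artifacts: mappability, GC content and allelic reference
  bias are not modeled.
- Problem sizes exercised: 1500-locus panels, 41 arms, cohorts up to 61
  samples, 25-seed recovery sweeps at depth 500–1000 — all run in seconds to
  tens of seconds on one CPU.
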