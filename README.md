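# karyopattern

Arm-level chromosomal alteration analysis for tumor-only targeted SNP panels,
modeled on pituitary neuroendocrine tumor (PitNET) molecular profiling.

A ~1500-SNP panel spread over all autosomes and the X chromosome yields, per
tumor, a B-allele frequency (BAF) and read depth at each locus. From these
two signals alone — no matched normal — the pipeline:

1. **Calls each of the 41 scoreable chromosome arms** (autosomes + X, minus
   the acrocentric p-arms 13p/14p/15p/21p/22p) into an allele-copy genotype
   state: `AB` (balanced), `A0/0B` (one-copy loss), `AA/BB` (copy-neutral
   LOH), `AAB/ABB` (single-allele gain), or `AABB` (balanced double gain).
2. **Classifies each sample** into one of four karyotype patterns —
   Pattern 1: no alterations; Pattern 2: losses/LOH only; Pattern 3: gains
   only; Pattern 4: mixed — and flags near-haploid / near-homozygous genomes
   and inferred endoreduplication (genome doubling).
3. **Estimates tumor purity** (from LOH-arm allele fractions) and **genome
   ploidy** (equal-weight mean copy number over the 23 chromosomes).
4. **Summarizes cohorts**: pattern-by-lineage contingency tables, per-group
   altered-arm confidence intervals, chi-square and Mann–Whitney tests.

Because raw patient data for this assay class is not publicly deposited, the
package includes a forward simulator that generates read counts with the
statistical structure the analysis assumes (Hardy–Weinberg germline
genotypes, purity dilution, gamma–Poisson depth noise, binomial allele
sampling), plus six worked-patient karyotype fixtures used as ground truth.

## The model

A specimen is a mixture of one tumor clone (purity `p`) and diploid normal
cells. At a germline-heterozygous SNP on an arm with `major`/`minor` allele
copies:

```
BAF  = (p·major + (1−p)) / (p·(major+minor) + 2(1−p))
logR = log2( (p·(major+minor) + 2(1−p)) / 2 )
```

The caller reduces each arm to a median mirrored BAF (over the heterozygous
band) and a median log2 depth ratio against the sample's own balanced arms,
then walks a two-tier ladder (allelic: balanced/imbalance/LOH at mirrored-BAF
0.58/0.75; coverage: loss/neutral/gain at log2 −0.15/+0.13). Weak or
contradictory tier combinations are arbitrated by the nearest expected
(BAF, logR) signature over the state universe. Purity is recovered by
inverting the BAF formula on LOH arms (`p = 2 − 1/m` for losses,
`p = 2m − 1` for copy-neutral LOH). See `docs/methods.md` for the full
derivations and design rationale.

## Worked example

Simulate a published near-haploid karyotype (16 chromosomes at single copy,
tumor purity 65%), call it, and classify it:

```bash
cat > spec56.yaml <<'EOF'
sample_id: patient_56
sex: female
purity: 0.65
arm_states:
  "1": "1,0"
  "2": "1,0"
  "3": "1,0"
  "4": "1,0"
  "6": "1,0"
  "8": "1,0"
  "10": "1,0"
  "11": "1,0"
  "13": "1,0"
  "15": "1,0"
  "17": "1,0"
  "19": "1,0"
  "20": "1,0"
  "21": "1,0"
  "22": "1,0"
  "X": "1,0"
EOF

karyopattern simulate --spec spec56.yaml --depth 1000 --seed 17 \
    --out obs.tsv --panel-out panel.tsv
karyopattern call --panel panel.tsv --obs obs.tsv --sex female --out calls.tsv
karyopattern classify --calls calls.tsv --sample-id patient_56 --out result.json
```

`result.json` reports pattern 2, 28 altered arms, `near_haploid: true`,
purity estimate ≈ 0.65 and ploidy 1.3 — the single-copy chromosomes sit at
mirrored BAF 1/1.35 ≈ 0.74 and log2 ≈ −0.29, exactly the diluted one-copy
signature.

The same pipeline is callable from Python:

```python
from karyopattern import (
    SimulationConfig, call_sample, classify_pattern, make_default_panel,
    simulate_sample,
)
from karyopattern.fixtures import fixture

panel = make_default_panel(seed=17)
spec = fixture(56)
obs = simulate_sample(spec, panel, SimulationConfig(mean_depth=1000, seed=17))
result = classify_pattern(call_sample(panel, obs, spec.sex), spec.sample_id)
print(result.pattern, result.near_haploid, result.ploidy_estimate.rounded)
# 2 True 1.3
```

## Repository layout

- `src/karyopattern/` — the library: `arms`, `model`, `panel`, `simulate`,
  `fixtures`, `caller`, `patterns`, `stats`, `cli`.
- `analysis/` — numbered result-generating drivers (see above).
- `tests/` — unit, property and acceptance tests (pytest + hypothesis).
- `scripts/acceptance.py` — recomputes the headline ploidy value.
- `docs/methods.md` — model derivations, thresholds, design decisions and
  limitations.
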