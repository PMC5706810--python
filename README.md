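# poolseq

Rare germline variant discovery from **pooled targeted sequencing** in
familial colorectal cancer (CRC), as a tested, reusable pipeline.

## The problem

Screening large familial case/control cohorts for rare, highly penetrant
germline variants by per-sample sequencing is expensive. An alternative is
to combine blood-derived DNA from a few individuals into **non-barcoded
equimolar pools** (~3 cases or ~8 controls per pool), sequence each pool to
high depth over a targeted panel — here 40 established and candidate CRC
susceptibility genes — and infer the *presence* of a variant in a pool from
its pooled alternate-allele fraction. For very rare variants presence is
what matters, not an accurate allele-frequency estimate, which makes the
design robust to modest pipetting imbalance. Carriers are then identified
by Sanger re-sequencing of the individual members of each positive pool.

## The model

One heterozygote among *n* equimolar diploid samples contributes an
expected alternate-allele fraction *f* = 1/(2*n*) — 1/6 ≈ 16.7% for a case
pool of three. With per-base substitution error *e* spread uniformly over
the three non-reference bases, observed alternate reads at a site of depth
*d* are

&nbsp;&nbsp;&nbsp;&nbsp;*X* ~ Binomial(*d*, *f*·(1−*e*) + (1−*f*)·*e*/3).

A variant is **called in a case pool** when *X*/*d* ≥ 2% (global screen),
10% ≤ *X*/*d* ≤ 50% (inclusive minor-allele window), and *d* ≥ 50 reads.
Detection power is the exact binomial sum of P(*X* = *k*) over accepted
*k* — at *d* = 1000, *f* = 1/6, *e* = 0.001 it is 0.9999999994, which is
why pool depths > 1000X (> 330X per case) make single-heterozygote
detection essentially certain.

Variants present in any control pool are removed; survivors are kept when
**rare** (reference-database MAF absent or < 0.001) and **likely
deleterious** (protein-truncating / consensus-splice-site, or
non-synonymous with ≥ 1 damaging call from SIFT / PolyPhen-2 /
MutationTaster). Cases are grouped into six recruitment tiers from
Amsterdam criteria I/II, diagnosis age, and tumor MSI status, and variants
are interpreted on the five-class ACMG scale by a rule-based evidence
combiner (PVS1/PM2/PP3/BA1 auto-assigned; segregation and functional codes
accepted as input flags only).

A synthetic-data generator reproduces the whole study's statistical
structure (cohort tiers and pedigrees, panel variants, Dirichlet pipetting
weights, negative-binomial depths) so every stage runs deterministically
from a seed with no external data.

## Worked example

```python
import json
from poolseq import SimulationConfig, run_pipeline, detection_power

print(detection_power(pool_size=3, n_carrier_alleles=1, depth=1000, error=0.001))
# 0.9999999993888945

cfg = SimulationConfig(n_cases=45, n_controls=32, n_background_variants=80,
                       n_spiked_variants=40, seed=99)
report = run_pipeline(cfg)
print(json.dumps(report["stage_counts"], indent=2))
```

prints

```json
{
  "pool_sites": 2280,
  "variants": 120,
  "detected_case_pool_sites": 224,
  "case_only": 53,
  "rare_deleterious": 40,
  "sanger_selected": 37,
  "validated": 37,
  "confirmed": 36,
  "unconfirmed": 0,
  "failed": 1
}
```

Read: 19 pools × 120 sites were simulated; 53 variants were detected in
cases and absent from controls; the rarity + deleteriousness cascade kept
40 (here exactly the 40 spiked rare case-only variants — the 80 background
variants are either too common or seen in controls); 37 met the Sanger
selection rule, 1 assay failed technically, and all 36 informative assays
confirmed the true carrier (`report["validation_sensitivity"] == 1.0`,
`report["end_to_end_sensitivity"] == 0.973` against an analytic detection
power of 1.000). The report also carries per-tier carrier frequencies and
ACMG class counts.

The same stages are exposed as a CLI:

```bash
poolseq simulate --config config.yaml --out work/
poolseq call --vcf work/pooled.vcf --pools work/pools.tsv --out work/calls.tsv
poolseq filter --calls work/calls.tsv --pools work/pools.tsv \
               --variants work/variants.tsv --out work/trace.tsv
poolseq power --pool-size 3 --depth 1000 --error 0.001
poolseq run --config config.yaml --seed 1 --out work/run
```

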