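# Methods

## Study design being modelled

The package implements the analysis of a pooled targeted-sequencing study
of familial colorectal cancer: 1046 CRC cases with a family history and
1006 older unrelated controls, pooled without barcodes in equimolar
proportions (~3 cases or ~8 controls per pool), sequenced over a 40-gene
panel to mean pool depths above 1000X (cases) and 700X (controls). The
pipeline starts from per-pool read counts at annotated variant sites;
alignment, variant calling and annotation are treated as upstream inputs
and are out of scope, as are CNV analysis and promoter-methylation assays.

## Pooled read-count model

For one pool of *m* members at one site:

* member contribution weights **w** ~ Dirichlet(α,…,α). α is the
  `pipette_concentration` (default 100, mild imbalance; α = ∞ gives exact
  equimolarity). A symmetric Dirichlet is the simplest exchangeable model
  of pipetting error with a single tunable parameter.
* true alternate-allele fraction *f* = Σ<sub>m</sub> w<sub>m</sub>·g<sub>m</sub>/2,
  with g<sub>m</sub> ∈ {0,1,2} the member's allele dosage.
* site depth *d* ~ NegativeBinomial with the configured pool mean and
  `depth_dispersion` (default 20; Poisson in the infinite-dispersion
  limit, and a `fixed` mode for exact depths). Targeted panels are
  over-dispersed relative to Poisson, hence the negative-binomial default.
* alternate reads *X* ~ Binomial(*d*, *f*(1−*e*) + (1−*f*)*e*/3) with
  per-base error *e* (default 0.001). Misincorporations are assumed
  uniform over the three non-reference bases, so only *e*/3 of errors
  produce the specific alternate allele.

## Calling thresholds

Case pools: alt fraction ≥ 2% (screen), inside the inclusive 10–50%
window, and site depth ≥ 50 reads. "≥ 50 reads" is interpreted as total
site depth (the standard coverage QC quantity; at study depths both
readings agree) with `min_reads_on_alt=True` switching to alternate-read
counting. The 2% screen is applied per pool. Window bounds are inclusive:
100/1000 reads passes, 99/1000 does not. At depth 0 the alt fraction is
defined as 0 so the rule is total.

Control pools carry no published decision rule; presence is declared at
alt fraction ≥ 2% (reusing the global screen) with ≥ 2 supporting reads to
guard against single-read errors. Both values are configurable.

`detection_power` sums the Binomial pmf over exactly the alternate-read
counts the scalar caller accepts, so the analytic power and the caller can
never disagree about the acceptance region; a seeded Monte-Carlo mode and
a depth-marginalised variant (Poisson or negative-binomial weights over
the exact fixed-depth power) support cross-checking against simulation.
At the design point (one heterozygote in a pool of three, 1000X, e=0.001)
power is 0.9999999994; the tests assert the >98% sensitivity regime and
exact/Monte-Carlo agreement within 3 standard errors on a grid of depths
{100, 300, 1000} and pool sizes {3, 8}.

## Filter cascade and Sanger validation

The cascade is a pure conjunction — case-only (detected in ≥1 case pool,
present in 0 control pools), rare (reference MAF absent or < 0.001,
strict), likely deleterious (truncating/splice ±1,2 unconditionally;
non-synonymous with ≥1 damaging in-silico call). The ≥1-tool reading is
the default because the study's own later clarification uses "at least
one" tool; a strict all-three mode exists. Stop-loss is grouped with the
truncating classes for the deleteriousness filter but does not trigger
automatic Sanger selection, which names only stop-gain besides damaging
predictions and ClinVar-pathogenic entries.

Sanger deconvolution reads the truth genotype matrix: the first pool
member with dosage ≥ 1 is the confirmed carrier; a call with no carrier is
unconfirmed (false positive); assays fail technically with configurable
probability (default 0.056, matching a 6/108 failure rate). Validation
sensitivity is confirmed/(confirmed + unconfirmed), failed assays
excluded from the denominator. (The source study's own arithmetic around
this quantity is internally inconsistent by one variant — 108 selected − 6
failed − 2 unconfirmed = 100, yet sensitivity is quoted as 99/101; the
stated 99/101 convention is implemented.) A variant detected in several
pools yields one validation record per pool.

## Tier engine

Amsterdam I is coded as the 3-2-1 rule: ≥3 affected relatives (proband
included), one first-degree of the other two, spanning ≥2 successive
generations, ≥1 diagnosis before 50 (droppable), FAP excluded via a
boolean family flag (default false). Amsterdam II widens the affected set
to CRC + endometrial + small-bowel + urothelial cancers and keeps the age
clause. Pedigree records store relation-to-proband and a generation
number rather than a full relationship graph, so first-degree links
between two non-proband members are presumed from generations (two FDRs
within one generation; an FDR and an SDR in adjacent generations). This
covers the intended family structures — e.g. an affected parent linking
the proband and an affected grandparent — but cannot represent arbitrary
pedigrees; families whose linking member is not adjacent to the proband's
kernel may be under-called.

Tier assignment is first-match in the recruitment priority order: MSS
group (MSS + MSI-Low, per the study's tabulation) → AC-I = Tier 1, AC-I
without age = Tier 3, AC-II = Tier 4, first CRC < 60 with ≥1 FDR/SDR with
CRC = Tier 5; MSI-High with no MMR mutation / MLH1 promoter methylation →
AC-I or AC-II = Tier 2, ≥1 FDR/SDR with CRC = Tier 6; otherwise
unassigned. Tier 5's age clause is applied to the proband's first CRC.
Missing diagnosis ages raise an error only when the age clause actually
needs them.

## ACMG combiner

Only computable database/population/in-silico codes are auto-assigned:
PVS1 (truncating consequence in a gene with an established
loss-of-function mechanism — default the 17 established CRC genes,
configurable), PM2 (absent from reference populations), PP3 (≥1 damaging
call, none benign), BA1 (MAF ≥ 0.05, configurable). PS4 (case-control
prevalence) is never auto-assigned because it is uninformative for
private variants; segregation/functional/de-novo codes enter only as
explicit overrides. The combining rules follow the 2015 five-class
guideline verbatim (no point system). Contradictory evidence — a rule
firing on one side while any evidence exists on the other — yields VUS.
Totality and pathogenic-side monotonicity are verified by exhaustive
enumeration over a 12-code vocabulary (4096 evidence sets).

## Synthetic cohort generator

Each case draws a recruitment tier from the configured proportions
(defaults are the study's tier mix 139/202/36/501/64/104 of 1046) and
receives the smallest pedigree that places it in exactly that tier, which
gives the tier round-trip property used in testing. Diagnosis ages are
tier-constrained normals (e.g. Tier 5 < 60; Tier 3 ≥ 50 so the AC-I age
clause genuinely fails); controls are tumor-free and older (mean 61,
range 43–84 vs case mean ~56). Background panel variants draw a
reference MAF from a log-uniform spectrum on [1e-4, 0.5] and
Hardy–Weinberg genotypes in both arms; spiked variants — the detection
target — are heterozygous in one case each (drawn with replacement across
variants, so a case may carry several), absent from all controls, novel
with probability 0.34 or else MAF < 0.001, and annotated from a
likely-deleterious profile. Default variant counts (9721 background + 264
spiked) mirror the study's scale; tests and the acceptance script use
smaller configurations (tens of subjects, 20,000 replicate pool-sites for
the sensitivity figure) chosen to exercise the same code paths at high
statistical resolution.

What the generator does **not** emulate: linkage disequilibrium and
population structure, mapping/alignment artifacts, indel realignment,
strand bias, batch effects between sequencing runs, and relatedness
between cases. Passing tests therefore demonstrate the correctness of the
decision rules and their calibration under the stated noise model, not
performance on real sequencing data.

## Numerical conventions and edge cases

* Pool-partition: subjects are chunked in order; the last pool of an arm
  may be undersized (1046 cases at size 3 → 349 pools, one of size 2) and
  is retained rather than redistributed. The published pool total (480)
  is not targeted; pool sizes are configuration.
* Percentages round half-up to one decimal (Decimal arithmetic). Computed
  values are reported even where they differ from published rounding
  (14/139 = 10.07 → 10.1).
* All randomness flows from `numpy.random.default_rng` seeded with
  (stream-tag, seed[, pool-id hash]) tuples, so stages are reproducible
  independently of call order; identical configs give bit-identical
  output.
* Carrier counting: a case contributes once per (gene, tier) cell
  regardless of how many variants of that gene it carries, and once per
  tier carrier total regardless of how many genes are involved.

## Known limitations

* The pedigree encoding cannot express arbitrary family graphs (see tier
  engine above).
* The caller is a pure count-threshold rule by design: no genotype
  likelihoods, base-quality weighting, or strand-bias modelling.
* ACMG output has no gene-specific rule adaptations and no ClinGen
  calibration; per-variant agreement with any published classification is
  not claimed.
* Cohort-level variant totals reported for the original study (9,985
  candidate variants; 264 rare deleterious; 108 selected; 21
  ACMG-positive) depend on the unreleased patient data; the package
  reproduces their subset relations qualitatively, not the counts.
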