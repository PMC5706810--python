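"""Generator tests: determinism, cohort structure, pooling, and the read-count model."""

import numpy as np
import pandas as pd
import pytest

from poolseq import (
    ConfigError,
    SimulationConfig,
    Subject,
    build_pools,
    generate_cohort,
    generate_variants,
    simulate_pool_counts,
    spiked_truth_table,
)
from poolseq.synthetic_data import DEFAULT_TIER_COUNTS, counts_to_frame

from conftest import make_variant, one_carrier_genotypes


def test_cohort_deterministic_by_seed():
    cfg = SimulationConfig(n_cases=40, n_controls=30, seed=1)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert a == b


def test_cohort_structure_invariants():
    cfg = SimulationConfig(n_cases=120, n_controls=100, seed=3)
    subjects, pedigree = generate_cohort(cfg)
    cases = [s for s in subjects if s.is_case]
    controls = [s for s in subjects if not s.is_case]
    assert len(cases) == 120 and len(controls) == 100
    assert len({s.subject_id for s in subjects}) == len(subjects)
    for c in controls:
        assert not c.tumors and c.age_at_diagnosis is None
    for c in cases:
        assert 18 <= c.age_at_diagnosis <= 100
        assert c.crc_tumors
    # every case has exactly one proband record in its family
    by_family = {}
    for m in pedigree:
        by_family.setdefault(m.family_id, []).append(m)
    for c in cases:
        fam = by_family[c.family_id]
        assert sum(m.relation_to_proband == "self" for m in fam) == 1


def test_controls_older_than_cases_on_average():
    # controls are recruited to be older (mean 61) than cases (dx mean ~56)
    cfg = SimulationConfig(n_cases=300, n_controls=300, seed=5)
    subjects, _ = generate_cohort(cfg)
    case_ages = [s.age_at_recruitment for s in subjects if s.is_case]
    ctrl_ages = [s.age_at_recruitment for s in subjects if not s.is_case]
    assert np.mean(ctrl_ages) > np.mean(case_ages)
    assert all(43 <= a <= 84 for a in ctrl_ages)


def test_tier_mix_matches_configured_proportions():
    """Tier draws are multinomial; counts stay within sampling error."""
    cfg = SimulationConfig(n_cases=1046, n_controls=2, seed=11)
    subjects, _ = generate_cohort(cfg)
    counts = {t: 0 for t in DEFAULT_TIER_COUNTS}
    for s in subjects:
        if s.is_case:
            counts[s.target_tier] += 1
    n = 1046
    for tier, expected in DEFAULT_TIER_COUNTS.items():
        p = expected / n
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts[tier] - expected) <= 4 * sd, (tier, counts[tier])


def test_forced_tier_one_proportion():
    cfg = SimulationConfig(n_cases=25, n_controls=2, seed=2,
                           tier_proportions={1: 1.0}, msi_low_fraction=0.0)
    subjects, pedigree = generate_cohort(cfg)
    from poolseq import amsterdam_I
    by_family = {}
    for m in pedigree:
        by_family.setdefault(m.family_id, []).append(m)
    for s in subjects:
        if s.is_case:
            assert s.target_tier == 1
            assert all(t.msi_status == "MSS" for t in s.crc_tumors)
            assert amsterdam_I(by_family[s.family_id])


def test_nonpositive_cohort_rejected():
    with pytest.raises(ConfigError):
        generate_cohort(SimulationConfig(n_cases=0, n_controls=5))


def test_background_variant_frequency():
    """Observed cohort allele frequency tracks the reference MAF (binomial)."""
    cfg = SimulationConfig(
        n_cases=500, n_controls=500, seed=13,
        maf_spectrum={"dist": "uniform", "low": 0.2, "high": 0.2},
    )
    variants, genotypes = generate_variants(cfg, n_background=5, n_spiked=0)
    n_alleles = 2 * 1000
    se = np.sqrt(0.2 * 0.8 / n_alleles)
    for v in variants:
        af = genotypes[v.variant_id].sum() / n_alleles
        assert abs(af - 0.2) <= 3 * se


def test_spiked_variants_case_only_single_het():
    cfg = SimulationConfig(n_cases=50, n_controls=40, seed=4)
    variants, genotypes = generate_variants(cfg, n_background=10, n_spiked=20)
    truth = spiked_truth_table(genotypes)
    assert set(truth["variant_id"]) == {f"spike{k:04d}" for k in range(20)}
    for v in variants:
        if v.variant_id.startswith("spike"):
            col = genotypes[v.variant_id]
            ctrl = col[col.index.str.startswith("ctrl")]
            assert (ctrl == 0).all()
            assert col.sum() == 1  # one heterozygous carrier
            assert v.ref_db_maf is None or v.ref_db_maf < 0.001


def test_zero_spiked_means_no_case_only_truth():
    cfg = SimulationConfig(n_cases=20, n_controls=20, seed=4)
    _, genotypes = generate_variants(cfg, n_background=15, n_spiked=0)
    assert spiked_truth_table(genotypes).empty


def _subjects(n_cases, n_controls):
    cases = [Subject(f"case{i:05d}", "case", age_at_diagnosis=50)
             for i in range(n_cases)]
    ctrls = [Subject(f"ctrl{i:05d}", "control") for i in range(n_controls)]
    return cases + ctrls


def test_build_pools_ceiling_arithmetic():
    cfg = SimulationConfig(n_cases=1046, n_controls=1006)
    pools = build_pools(_subjects(1046, 1006), cfg)
    case_pools = [p for p in pools if p.arm == "case"]
    ctrl_pools = [p for p in pools if p.arm == "control"]
    assert len(case_pools) == 349
    assert sorted(p.size for p in case_pools) == [2] + [3] * 348
    assert len(ctrl_pools) == 126
    # partition: disjoint and exhaustive
    all_members = [m for p in pools for m in p.member_ids]
    assert len(all_members) == len(set(all_members)) == 2052


def test_build_pools_empty_rejected():
    with pytest.raises(ConfigError):
        build_pools([], SimulationConfig())


def test_pool_counts_closed_form_mean(trio_pool):
    """Mean observed alt fraction = f(1-e) + (1-f)e/3 for one het of three."""
    n = 10_000
    e = 0.001
    vids = [f"s{i}" for i in range(n)]
    variants = [make_variant(vid=v, pos=i + 1) for i, v in enumerate(vids)]
    genotypes = one_carrier_genotypes(["A", "B", "C"], vids, "B")
    cfg = SimulationConfig(
        n_cases=3, n_controls=1, base_error_rate=e,
        pipette_concentration=np.inf, depth_distribution="fixed",
        mean_case_pool_depth=1000, seed=21,
    )
    counts = simulate_pool_counts(trio_pool, variants, genotypes, cfg)
    fracs = np.array([c.alt_fraction for c in counts])
    expected = (1 / 6) * (1 - e) + (5 / 6) * (e / 3)
    mc_se = fracs.std() / np.sqrt(n)
    assert abs(fracs.mean() - expected) <= 4 * mc_se
    assert all(0 <= c.alt_reads <= c.depth for c in counts)


def test_no_carrier_no_error_zero_alt(trio_pool):
    vids = [f"s{i}" for i in range(500)]
    variants = [make_variant(vid=v, pos=i + 1) for i, v in enumerate(vids)]
    genotypes = one_carrier_genotypes(["A", "B", "C"], vids, "B", dosage=0)
    cfg = SimulationConfig(n_cases=3, n_controls=1, base_error_rate=0.0,
                           seed=8)
    counts = simulate_pool_counts(trio_pool, variants, genotypes, cfg)
    assert all(c.alt_reads == 0 for c in counts)


def test_equimolar_limit_shrinks_alt_fraction_variance(trio_pool):
    vids = [f"s{i}" for i in range(3000)]
    variants = [make_variant(vid=v, pos=i + 1) for i, v in enumerate(vids)]
    genotypes = one_carrier_genotypes(["A", "B", "C"], vids, "B")
    base = dict(n_cases=3, n_controls=1, base_error_rate=0.0,
                depth_distribution="fixed", mean_case_pool_depth=2000, seed=9)
    noisy = SimulationConfig(**base, pipette_concentration=1.0)
    tight = SimulationConfig(**base, pipette_concentration=1e9)
    var_noisy = np.var([c.alt_fraction for c in
                        simulate_pool_counts(trio_pool, variants, genotypes, noisy)])
    var_tight = np.var([c.alt_fraction for c in
                        simulate_pool_counts(trio_pool, variants, genotypes, tight)])
    assert var_tight < var_noisy / 5


def test_counts_deterministic_by_seed(trio_pool):
    vids = ["x1", "x2", "x3"]
    variants = [make_variant(vid=v, pos=i + 1) for i, v in enumerate(vids)]
    genotypes = one_carrier_genotypes(["A", "B", "C"], vids, "A")
    cfg = SimulationConfig(n_cases=3, n_controls=1, seed=33)
    a = counts_to_frame(simulate_pool_counts(trio_pool, variants, genotypes, cfg))
    b = counts_to_frame(simulate_pool_counts(trio_pool, variants, genotypes, cfg))
    pd.testing.assert_frame_equal(a, b)
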