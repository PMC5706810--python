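"""Filter cascade, Sanger selection, and deconvolution tests."""

import numpy as np
import pandas as pd
import pytest

from poolseq import (
    MalformedInputError,
    Pool,
    SimulationConfig,
    apply_filter_cascade,
    filter_case_only,
    filter_consequence,
    filter_reference_frequency,
    run_pipeline,
    sanger_deconvolve,
    select_for_sanger,
    validation_sensitivity,
)
from poolseq.models import ValidationResult

from conftest import make_variant, one_carrier_genotypes


POOLS = [Pool("CP0", "case", ["a", "b", "c"]),
         Pool("CP1", "case", ["d", "e", "f"]),
         Pool("KP0", "control", list("ghijklmn"))]


def _calls(rows):
    df = pd.DataFrame(rows, columns=["pool_id", "variant_id", "detected"])
    df["depth"] = 1000
    df["alt_reads"] = 167
    df["alt_fraction"] = 0.167
    df["reason"] = np.where(df["detected"], "pass", "below_screen")
    return df


def test_case_only_set_logic():
    calls = _calls([
        ("CP0", "v_keep", True),
        ("CP0", "v_mixed", True), ("CP1", "v_mixed", True), ("KP0", "v_mixed", True),
        ("KP0", "v_ctrl", True),
        ("CP0", "v_none", False),
    ])
    assert filter_case_only(calls, POOLS) == {"v_keep"}


def test_case_only_unknown_pool_rejected():
    with pytest.raises(MalformedInputError):
        filter_case_only(_calls([("ZZ", "v", True)]), POOLS)


@pytest.mark.parametrize("maf,kept", [
    (None, True),        # never reported in reference databases
    (0.001, False),      # boundary is strict
    (0.0005, True),
    (0.01, False),
])
def test_reference_frequency_filter(maf, kept):
    out = filter_reference_frequency([make_variant(maf=maf)])
    assert bool(out) is kept


def test_reference_frequency_rejects_bad_maf():
    v = make_variant()
    v.ref_db_maf = 1.5  # bypass constructor validation
    with pytest.raises(MalformedInputError):
        filter_reference_frequency([v])


def test_consequence_filter_rules():
    stop_gain = make_variant(vid="sg", consequence="stop_gain")
    stop_loss = make_variant(vid="sl", consequence="stop_loss")
    benign_ns = make_variant(vid="ns0", sift="tolerated",
                             polyphen2="benign", mutation_taster="polymorphism")
    sift_only = make_variant(vid="ns1", sift="deleterious")
    syn = make_variant(vid="syn", consequence="synonymous")
    kept = {v.variant_id for v in
            filter_consequence([stop_gain, stop_loss, benign_ns, sift_only, syn])}
    assert kept == {"sg", "sl", "ns1"}
    # strict mode: all three tools must concur
    all3 = make_variant(vid="ns2", sift="deleterious", polyphen2="damaging",
                        mutation_taster="disease_causing")
    kept = {v.variant_id for v in
            filter_consequence([sift_only, all3], predictor_mode="all")}
    assert kept == {"ns2"}


def test_sanger_selection_rule():
    clinvar_only = make_variant(vid="cv", clinvar="pathogenic")
    bare_frameshift = make_variant(vid="fs", consequence="frameshift")
    mt_damaging = make_variant(vid="mt", mutation_taster="disease_causing")
    stop_gain = make_variant(vid="sg", consequence="stop_gain")
    selected = {v.variant_id for v in
                select_for_sanger([clinvar_only, bare_frameshift,
                                   mt_damaging, stop_gain])}
    assert selected == {"cv", "mt", "sg"}


def test_cascade_is_order_invariant_conjunction():
    variants = [
        make_variant(vid="spike_ok", sift="deleterious"),
        make_variant(vid="common", maf=0.05, sift="deleterious"),
        make_variant(vid="syn", consequence="synonymous"),
        make_variant(vid="in_ctrl", sift="deleterious"),
    ]
    calls = _calls([
        ("CP0", "spike_ok", True),
        ("CP0", "common", True),
        ("CP0", "syn", True),
        ("CP0", "in_ctrl", True), ("KP0", "in_ctrl", True),
    ])
    traces = apply_filter_cascade(calls, POOLS, variants)
    survivors = {v for v, t in traces.items() if t.passed_cascade}
    assert survivors == {"spike_ok"}
    # conjunction: the same survivors from stage sets intersected in any order
    case_only = filter_case_only(calls, POOLS)
    rare = {v.variant_id for v in filter_reference_frequency(variants)}
    deleterious = {v.variant_id for v in filter_consequence(variants)}
    for order in ([case_only, rare, deleterious],
                  [deleterious, case_only, rare],
                  [rare, deleterious, case_only]):
        acc = {v.variant_id for v in variants}
        for stage_set in order:
            acc &= stage_set
        assert acc == survivors
    # every trace lists the stages in the canonical order
    for t in traces.values():
        assert [s for s, _ in t.stages] == ["case_only", "reference_frequency",
                                            "consequence"]


def test_sanger_deconvolve_outcomes(trio_pool):
    genotypes = one_carrier_genotypes(["A", "B", "C"], ["v1", "v2"], "B")
    genotypes.loc[:, "v2"] = 0
    res = sanger_deconvolve("v1", trio_pool, genotypes)
    assert res.status == "confirmed" and res.carrier_id == "B"
    res = sanger_deconvolve("v2", trio_pool, genotypes)
    assert res.status == "unconfirmed" and res.carrier_id is None
    res = sanger_deconvolve("v1", trio_pool, genotypes, failure_prob=1.0,
                            rng=np.random.default_rng(0))
    assert res.status == "failed"
    with pytest.raises(MalformedInputError):
        sanger_deconvolve("missing", trio_pool, genotypes)


def test_validation_sensitivity_accounting():
    results = (
        [ValidationResult(f"v{i}", "p", "c", "confirmed") for i in range(99)]
        + [ValidationResult(f"u{i}", "p", None, "unconfirmed") for i in range(2)]
        + [ValidationResult(f"f{i}", "p", None, "failed") for i in range(6)]
    )
    # failed assays leave the denominator: 99 of 101
    assert validation_sensitivity(results) == pytest.approx(99 / 101)
    only_ok = [r for r in results if r.status == "confirmed"]
    assert validation_sensitivity(only_ok) == 1.0
    with pytest.raises(MalformedInputError):
        validation_sensitivity([ValidationResult("f", "p", None, "failed")])


def test_noise_free_run_confirms_every_spiked_carrier():
    """No sequencing error + perfect equimolarity: sensitivity 1.0 and every
    annotation-eligible spiked variant deconvolves to its true carrier."""
    cfg = SimulationConfig(
        n_cases=30, n_controls=24, n_background_variants=30,
        n_spiked_variants=30, base_error_rate=0.0,
        pipette_concentration=np.inf, depth_distribution="fixed",
        sanger_failure_rate=0.0, seed=17,
        maf_spectrum={"dist": "loguniform", "low": 0.01, "high": 0.5},
    )
    report = run_pipeline(cfg)
    assert report["validation_sensitivity"] == 1.0
    assert report["end_to_end_sensitivity"] == 1.0
    # background variants here all have MAF >= 0.001: none survives
    assert report["stage_counts"]["rare_deleterious"] <= 30


def test_end_to_end_sensitivity_tracks_analytic_power():
    cfg = SimulationConfig(
        n_cases=90, n_controls=24, n_background_variants=0,
        n_spiked_variants=90, base_error_rate=0.001,
        pipette_concentration=np.inf, depth_distribution="fixed",
        sanger_failure_rate=0.0, seed=23,
    )
    report = run_pipeline(cfg)
    power = report["analytic_detection_power"]
    observed = report["end_to_end_sensitivity"]
    n = 90
    se = max(np.sqrt(power * (1 - power) / n), 1.0 / n)
    assert abs(observed - power) <= 3 * se
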