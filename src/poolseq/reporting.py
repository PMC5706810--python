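"""Carrier aggregation by gene and tier, and the end-to-end pipeline driver.

The carrier table counts, for every (gene, recruitment tier) cell, the
distinct cases confirmed to carry >= 1 identified variant in that gene.
A case with confirmed variants in two genes appears in both gene rows but
only once in its tier's carrier total, so per-tier carrier frequencies
(carrier cases / tier case count, as a percentage rounded half-up to one
decimal) never double-count a patient.

``run_pipeline`` chains every stage — simulate, pool, call, filter, tier,
classify, validate, aggregate — deterministically from the configured
seed and returns a JSON-serialisable report bundle.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import variant_filter
from .acmg_classifier import classify_variant
from .models import (
    MalformedInputError,
    PanelVariant,
    Pool,
    PANEL_GENES,
    Subject,
    TierLabel,
    ValidationResult,
)
from .pooled_caller import call_all, detection_power
from .synthetic_data import (
    DEFAULT_TIER_COUNTS,
    SimulationConfig,
    build_pools,
    counts_to_frame,
    generate_cohort,
    generate_variants,
    simulate_all_pool_counts,
)
from .tier_engine import assign_tier

__all__ = [
    "CarrierTable",
    "build_carrier_table",
    "tier_frequencies",
    "round_half_up",
    "load_reference_carrier_counts",
    "carriers_from_count_table",
    "run_pipeline",
    "TIER_ORDER",
]

#: Presentation order of tiers (FCCTX-like MSS tiers, then Lynch-like MSI-H).
TIER_ORDER = (1, 3, 4, 5, 2, 6)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 10.05 -> 10.1."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CarrierTable:
    """Per-(gene, tier) distinct-carrier counts with tier denominators."""

    counts: pd.DataFrame           # index: gene, columns: tier, values: carriers
    tier_case_counts: dict[int, int]
    tier_carrier_cases: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tier_carrier_cases:
            # without case identities, a tier's carriers is its column sum
            self.tier_carrier_cases = {
                t: int(self.counts[t].sum()) for t in self.counts.columns
            }

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def gene_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def tier_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_carrier_table(
    results: Iterable[ValidationResult],
    variant_genes: Mapping[str, str],
    tiers: Mapping[str, TierLabel | int | str],
    genes: Iterable[str] = PANEL_GENES,
    tier_case_counts: Mapping[int, int] | None = None,
) -> CarrierTable:
    """Aggregate confirmed carriers into a gene x tier table.

    Only confirmed validation results contribute.  A carrier counts once
    per (gene, tier) cell regardless of how many distinct variants of
    that gene it carries, and once per tier in the tier carrier totals.
    Genes without carriers appear with zeros.
    """
    genes = list(genes)
    tier_of: dict[str, int | str] = {}
    for sid, label in tiers.items():
        tier_of[sid] = label.tier if isinstance(label, TierLabel) else label

    cell_cases: dict[tuple[str, int], set[str]] = {}
    tier_cases: dict[int, set[str]] = {}
    for r in results:
        if r.status != "confirmed":
            continue
        if r.carrier_id not in tier_of:
            raise MalformedInputError(
                f"carrier {r.carrier_id} has no tier label"
            )
        tier = tier_of[r.carrier_id]
        if tier == "unassigned":
            continue
        gene = variant_genes.get(r.variant_id)
        if gene is None:
            raise MalformedInputError(f"variant {r.variant_id} has no gene")
        cell_cases.setdefault((gene, int(tier)), set()).add(r.carrier_id)
        tier_cases.setdefault(int(tier), set()).add(r.carrier_id)

    cols = list(TIER_ORDER)
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=cols)
    for (gene, tier), cases in cell_cases.items():
        if gene in counts.index and tier in counts.columns:
            counts.loc[gene, tier] = len(cases)
    case_counts = dict(tier_case_counts or DEFAULT_TIER_COUNTS)
    return CarrierTable(
        counts=counts,
        tier_case_counts=case_counts,
        tier_carrier_cases={t: len(s) for t, s in tier_cases.items()},
    )


def tier_frequencies(table: CarrierTable) -> dict[int, float]:
    """Per-tier carrier percentage, rounded half-up to one decimal."""
    out = {}
    for tier in table.counts.columns:
        n_cases = table.tier_case_counts.get(int(tier), 0)
        if n_cases <= 0:
            raise MalformedInputError(f"tier {tier}: case count must be > 0")
        carriers = table.tier_carrier_cases.get(int(tier), 0)
        out[int(tier)] = round_half_up(100.0 * carriers / n_cases, 1)
    return out


def load_reference_carrier_counts() -> pd.DataFrame:
    """Reference gene x tier carrier-count table shipped as package data.

    106 variant-carrying cases distributed over the 40-gene panel and the
    six recruitment tiers; columns tier1..tier6 plus a gene-group label.
    """
    ref = importlib.resources.files("poolseq.data") / "reference_carrier_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def carriers_from_count_table(counts: pd.DataFrame) -> tuple[
    list[ValidationResult], dict[str, str], dict[str, int]
]:
    """Expand a gene x tier count table into per-carrier validation records.

    Constructs one synthetic confirmed carrier (distinct case, distinct
    variant) per counted unit, so ``build_carrier_table`` can be exercised
    against a published-style summary table.  Returns
    ``(results, variant_genes, tiers)``.
    """
    results: list[ValidationResult] = []
    variant_genes: dict[str, str] = {}
    tiers: dict[str, int] = {}
    i = 0
    for _, row in counts.iterrows():
        gene = row["gene"]
        for tier in TIER_ORDER:
            for _ in range(int(row[f"tier{tier}"])):
                vid, cid = f"rv{i:04d}", f"rc{i:04d}"
                results.append(ValidationResult(vid, f"rp{i:04d}", cid, "confirmed"))
                variant_genes[vid] = gene
                tiers[cid] = tier
                i += 1
    return results, variant_genes, tiers


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _annotation_eligible(variants: list[PanelVariant]) -> set[str]:
    """Spiked variants whose annotations alone would carry them to Sanger."""
    rare = variant_filter.filter_reference_frequency(variants)
    deleterious = variant_filter.filter_consequence(rare)
    selected = variant_filter.select_for_sanger(deleterious)
    return {v.variant_id for v in selected}


def run_pipeline(config: SimulationConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> pool -> call -> filter -> tier -> classify ->
    validate -> aggregate and return the report bundle.

    The report contains per-stage record counts, Sanger validation
    sensitivity, the end-to-end detection sensitivity of annotation-
    eligible spiked variants (comparable to the analytic single-pool
    detection power), tier carrier frequencies, and ACMG class counts.
    Fully reproducible from ``config.seed``; artifacts are written as TSV
    under ``out_dir`` when given.
    """
    from . import io as pio  # local import to avoid cycle at module load

    config.validate()
    subjects, pedigree = generate_cohort(config)
    variants, genotypes = generate_variants(
        config, config.n_background_variants, config.n_spiked_variants
    )
    pools = build_pools(subjects, config)
    counts = counts_to_frame(simulate_all_pool_counts(pools, variants, genotypes, config))
    calls = call_all(counts, pools)

    traces = variant_filter.apply_filter_cascade(calls, pools, variants)
    case_only = {v for v, t in traces.items() if t.stages[0][1]}
    survivors = {v for v, t in traces.items() if t.passed_cascade}
    sanger_ids = {v for v, t in traces.items() if t.final == "sanger_selected"}

    by_family: dict[str, list] = {}
    for m in pedigree:
        by_family.setdefault(m.family_id, []).append(m)
    tiers = {
        s.subject_id: assign_tier(s, by_family[s.family_id])
        for s in subjects if s.is_case
    }

    classifications = {}
    variant_by_id = {v.variant_id: v for v in variants}
    for vid in sorted(survivors):
        cls, evidence = classify_variant(variant_by_id[vid])
        classifications[vid] = {"class": cls, "evidence": evidence}

    pool_by_id = {p.pool_id: p for p in pools}
    arm_of = {p.pool_id: p.arm for p in pools}
    det = calls[calls["detected"]]
    det_case = det[det["pool_id"].map(arm_of) == "case"]
    rng = np.random.default_rng([4, config.seed])
    results: list[ValidationResult] = []
    for _, row in det_case.sort_values(["variant_id", "pool_id"]).iterrows():
        if row["variant_id"] in sanger_ids:
            results.append(variant_filter.sanger_deconvolve(
                row["variant_id"], pool_by_id[row["pool_id"]], genotypes,
                failure_prob=config.sanger_failure_rate, rng=rng,
            ))

    try:
        sensitivity = variant_filter.validation_sensitivity(results)
    except MalformedInputError:
        sensitivity = None

    eligible_spiked = {
        v for v in _annotation_eligible(variants) if v.startswith("spike")
    }
    confirmed_spiked = {
        r.variant_id for r in results
        if r.status == "confirmed" and r.variant_id.startswith("spike")
    }
    end_to_end = (
        len(confirmed_spiked & eligible_spiked) / len(eligible_spiked)
        if eligible_spiked else None
    )
    analytic_power = detection_power(
        config.case_pool_size, 1, config.mean_case_pool_depth,
        config.base_error_rate,
    )

    variant_genes = {v.variant_id: v.gene for v in variants}
    tier_case_counts: dict[int, int] = {}
    for s in subjects:
        if s.is_case:
            t = tiers[s.subject_id].tier
            if t != "unassigned":
                tier_case_counts[int(t)] = tier_case_counts.get(int(t), 0) + 1
    table = build_carrier_table(
        results, variant_genes, tiers,
        tier_case_counts={t: tier_case_counts.get(t, 0) or 1 for t in TIER_ORDER},
    )

    class_counts: dict[str, int] = {}
    for rec in classifications.values():
        class_counts[rec["class"]] = class_counts.get(rec["class"], 0) + 1

    report = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_pools": len(pools),
        "stage_counts": {
            "pool_sites": int(len(counts)),
            "variants": len(variants),
            "detected_case_pool_sites": int(len(det_case)),
            "case_only": len(case_only),
            "rare_deleterious": len(survivors),
            "sanger_selected": len(sanger_ids),
            "validated": len(results),
            "confirmed": sum(r.status == "confirmed" for r in results),
            "unconfirmed": sum(r.status == "unconfirmed" for r in results),
            "failed": sum(r.status == "failed" for r in results),
        },
        "validation_sensitivity": sensitivity,
        "end_to_end_sensitivity": end_to_end,
        "analytic_detection_power": analytic_power,
        "tier_counts": {str(t): tier_case_counts.get(t, 0) for t in TIER_ORDER},
        "tier_frequencies_pct": {
            str(t): v for t, v in tier_frequencies(table).items()
        },
        "carrier_grand_total": table.grand_total,
        "acmg_class_counts": class_counts,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_subjects_tsv(out / "subjects.tsv", subjects)
        pio.write_pools_tsv(out / "pools.tsv", pools)
        pio.write_pedigree(out / "pedigree.ped", pedigree)
        pio.write_variants_tsv(out / "variants.tsv", variants)
        pio.write_pooled_vcf(out / "pooled.vcf", variants, counts, pools)
        pio.write_calls_tsv(out / "calls.tsv", calls)
        pio.write_filter_traces_tsv(out / "filter_trace.tsv", traces.values())
        pio.write_validation_tsv(out / "validation.tsv", results)
        pio.write_tiers_tsv(out / "tiers.tsv", tiers)
        pio.write_classifications_tsv(out / "classifications.tsv", classifications)
        pio.write_report_json(out / "report.json", report)
    return report
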