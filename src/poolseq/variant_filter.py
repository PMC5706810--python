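"""Case-only rare-deleterious filter cascade and simulated Sanger validation.

The cascade is a conjunction of three stages applied to pooled calls:

1. **case_only** — detected in >= 1 case pool and present in 0 control
   pools;
2. **reference_frequency** — reference-database MAF absent (never
   reported) or strictly below 0.001;
3. **consequence** — protein-truncating / consensus-splice-site variants
   pass unconditionally; non-synonymous variants pass when predicted
   deleterious by at least one of SIFT / PolyPhen-2 / MutationTaster
   (a strict all-three mode is available); synonymous and other classes
   are removed.

Survivors are "rare, likely deleterious".  A subset is then selected for
Sanger confirmation: >= 1 damaging in-silico call, or listed pathogenic in
ClinVar, or a stop-gain.  Sanger deconvolution re-sequences each pool
member individually; in simulation mode it reads the truth genotype matrix
and identifies the carrier (or exposes a false-positive pooled call).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import (
    ConfigError,
    FilterTrace,
    MalformedInputError,
    PanelVariant,
    Pool,
    ValidationResult,
)

__all__ = [
    "filter_case_only",
    "filter_reference_frequency",
    "filter_consequence",
    "select_for_sanger",
    "apply_filter_cascade",
    "sanger_deconvolve",
    "validation_sensitivity",
]

CASCADE_STAGES = ("case_only", "reference_frequency", "consequence")


def filter_case_only(calls: pd.DataFrame, pools: list[Pool]) -> set[str]:
    """Variants detected in >= 1 case pool and present in no control pool."""
    arm_of = {p.pool_id: p.arm for p in pools}
    unknown = set(calls["pool_id"]) - set(arm_of)
    if unknown:
        raise MalformedInputError(f"unknown pool ids: {sorted(unknown)[:5]}")
    det = calls[calls["detected"]]
    arms = det["pool_id"].map(arm_of)
    in_cases = set(det.loc[arms == "case", "variant_id"])
    in_controls = set(det.loc[arms == "control", "variant_id"])
    return in_cases - in_controls


def filter_reference_frequency(
    variants: Iterable[PanelVariant], maf_cutoff: float = 0.001
) -> list[PanelVariant]:
    """Keep variants never reported in reference databases or with MAF < cutoff.

    The inequality is strict: a variant at exactly the cutoff is removed.
    """
    kept = []
    for v in variants:
        maf = v.ref_db_maf
        if maf is not None and not 0.0 <= maf <= 1.0:
            raise MalformedInputError(f"{v.variant_id}: MAF {maf} outside [0,1]")
        if maf is None or maf < maf_cutoff:
            kept.append(v)
    return kept


def filter_consequence(
    variants: Iterable[PanelVariant], predictor_mode: str = "any"
) -> list[PanelVariant]:
    """Keep likely-deleterious consequence classes.

    Truncating / consensus-splice-site variants pass unconditionally.
    Non-synonymous variants pass when called damaging by at least one
    in-silico tool (``predictor_mode="any"``, the default) or by all three
    (``predictor_mode="all"``).
    """
    if predictor_mode not in ("any", "all"):
        raise ConfigError(f"unknown predictor_mode {predictor_mode!r}")
    need = 1 if predictor_mode == "any" else 3
    kept = []
    for v in variants:
        if v.is_truncating:
            kept.append(v)
        elif v.consequence == "nonsynonymous" and v.n_damaging_predictions >= need:
            kept.append(v)
    return kept


def select_for_sanger(variants: Iterable[PanelVariant]) -> list[PanelVariant]:
    """Select rare-deleterious variants for Sanger confirmation.

    Criteria (any of): >= 1 damaging in-silico prediction; listed
    pathogenic in ClinVar; stop-gain.  Note the rule names only stop-gain
    among the truncating classes, so e.g. an unannotated frameshift is not
    auto-selected.
    """
    return [
        v for v in variants
        if v.n_damaging_predictions >= 1
        or v.clinvar == "pathogenic"
        or v.consequence == "stop_gain"
    ]


def apply_filter_cascade(
    calls: pd.DataFrame,
    pools: list[Pool],
    variants: Iterable[PanelVariant],
    maf_cutoff: float = 0.001,
    predictor_mode: str = "any",
) -> dict[str, FilterTrace]:
    """Run the full cascade and record every stage decision per variant.

    The cascade is a conjunction, so the surviving set does not depend on
    stage order; the trace records the fixed canonical order.  ``final``
    is ``sanger_selected`` for survivors that also meet the Sanger
    selection rule, ``rare_deleterious`` for the remaining survivors, and
    ``rejected`` otherwise.
    """
    variants = list(variants)
    case_only = filter_case_only(calls, pools)
    rare_ids = {v.variant_id for v in filter_reference_frequency(variants, maf_cutoff)}
    deleterious_ids = {
        v.variant_id for v in filter_consequence(variants, predictor_mode)
    }
    sanger_ids = {v.variant_id for v in select_for_sanger(variants)}

    traces: dict[str, FilterTrace] = {}
    for v in variants:
        stages = [
            ("case_only", v.variant_id in case_only),
            ("reference_frequency", v.variant_id in rare_ids),
            ("consequence", v.variant_id in deleterious_ids),
        ]
        if all(ok for _, ok in stages):
            final = (
                "sanger_selected" if v.variant_id in sanger_ids
                else "rare_deleterious"
            )
        else:
            final = "rejected"
        traces[v.variant_id] = FilterTrace(v.variant_id, stages, final)
    return traces


def sanger_deconvolve(
    variant_id: str,
    pool: Pool,
    genotypes: pd.DataFrame,
    failure_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ValidationResult:
    """Simulate Sanger sequencing of each pool member at one variant.

    Returns the first member (in pool order) with allele dosage >= 1 as
    the confirmed carrier; ``unconfirmed`` when no member carries the
    allele (a false-positive pooled call); ``failed`` with the configured
    per-assay probability (primer design / technical failures).
    """
    if variant_id not in genotypes.columns:
        raise MalformedInputError(f"variant {variant_id} absent from genotypes")
    missing = [m for m in pool.member_ids if m not in genotypes.index]
    if missing:
        raise MalformedInputError(
            f"pool {pool.pool_id} members absent from genotypes: {missing}"
        )
    if not 0.0 <= failure_prob <= 1.0:
        raise ConfigError("failure_prob must lie in [0,1]")
    if failure_prob > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        if rng.random() < failure_prob:
            return ValidationResult(variant_id, pool.pool_id, None, "failed")
    dosages = genotypes.loc[pool.member_ids, variant_id]
    carriers = [m for m in pool.member_ids if dosages[m] >= 1]
    if carriers:
        return ValidationResult(variant_id, pool.pool_id, carriers[0], "confirmed")
    return ValidationResult(variant_id, pool.pool_id, None, "unconfirmed")


def validation_sensitivity(results: Iterable[ValidationResult]) -> float:
    """Fraction of non-failed Sanger assays that confirmed the pooled call.

    ``confirmed / (confirmed + unconfirmed)``; assays that failed for
    technical reasons are excluded from the denominator.
    """
    confirmed = unconfirmed = 0
    for r in results:
        if r.status == "confirmed":
            confirmed += 1
        elif r.status == "unconfirmed":
            unconfirmed += 1
    if confirmed + unconfirmed == 0:
        raise MalformedInputError("no non-failed validation results")
    return confirmed / (confirmed + unconfirmed)
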