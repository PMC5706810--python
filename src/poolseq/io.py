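"""Readers and writers for the pipeline's on-disk formats.

Pooled read counts travel as a multi-sample VCF with one sample column
per pool and per-pool FORMAT fields ``DP`` (site depth) and ``AD``
(ref,alt read counts), handled with pysam.  Subjects, pools, variants,
calls, tiers, traces and truth tables are plain TSV; pedigrees use a
PED-like table extended with relation, generation, cancer type and
diagnosis age; configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .models import (
    CallThresholds,
    FilterTrace,
    PanelVariant,
    PedigreeMember,
    Pool,
    Subject,
    TierLabel,
    Tumor,
    ValidationResult,
)
from .synthetic_data import SimulationConfig

__all__ = [
    "write_pooled_vcf", "read_pooled_vcf",
    "write_subjects_tsv", "read_subjects_tsv",
    "write_pools_tsv", "read_pools_tsv",
    "write_pedigree", "read_pedigree",
    "write_variants_tsv", "read_variants_tsv",
    "write_truth_tsv",
    "write_calls_tsv", "read_calls_tsv",
    "write_filter_traces_tsv", "write_validation_tsv",
    "write_tiers_tsv", "write_classifications_tsv",
    "write_report_json",
    "load_config", "save_config", "load_thresholds",
]


# ---------------------------------------------------------------------------
# Pooled VCF
# ---------------------------------------------------------------------------

def write_pooled_vcf(path: str | Path, variants: list[PanelVariant],
                     counts: pd.DataFrame, pools: list[Pool]) -> None:
    """Write per-pool depths/alt reads as a multi-sample VCF (DP and AD)."""
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom)
    header.info.add("GENE", 1, "String", "Panel gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence class")
    header.formats.add("DP", 1, "Integer", "Pool read depth at the site")
    header.formats.add("AD", "R", "Integer", "Pool read counts (ref, alt)")
    pool_ids = [p.pool_id for p in pools]
    for pid in pool_ids:
        header.add_sample(pid)

    lut = {
        (r.pool_id, r.variant_id): (int(r.depth), int(r.alt_reads))
        for r in counts.itertuples()
    }
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), id=v.variant_id,
            )
            rec.info["GENE"] = v.gene
            rec.info["CSQ"] = v.consequence
            for pid in pool_ids:
                depth, alt = lut.get((pid, v.variant_id), (0, 0))
                rec.samples[pid]["DP"] = depth
                rec.samples[pid]["AD"] = (depth - alt, alt)
            vcf.write(rec)


def read_pooled_vcf(path: str | Path) -> pd.DataFrame:
    """Read a pooled VCF into a (pool_id, variant_id, depth, alt_reads) table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.alts[0]}"
            for pid, sample in rec.samples.items():
                ad = sample.get("AD")
                depth = sample.get("DP")
                alt = int(ad[1]) if ad is not None and ad[1] is not None else 0
                rows.append((pid, vid, int(depth or 0), alt))
    return pd.DataFrame(rows, columns=["pool_id", "variant_id", "depth", "alt_reads"])


# ---------------------------------------------------------------------------
# Subjects / pools / pedigree / variants
# ---------------------------------------------------------------------------

def _tumors_str(tumors: list[Tumor]) -> str:
    return ";".join(f"{t.site}:{t.age}:{t.msi_status}" for t in tumors)


def _parse_tumors(s: str) -> list[Tumor]:
    if not s or pd.isna(s):
        return []
    out = []
    for part in str(s).split(";"):
        site, age, msi = part.split(":")
        out.append(Tumor(site, int(age), msi))
    return out


def write_subjects_tsv(path: str | Path, subjects: list[Subject]) -> None:
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id, "arm": s.arm, "sex": s.sex,
            "age_at_diagnosis": s.age_at_diagnosis,
            "age_at_recruitment": s.age_at_recruitment, "race": s.race,
            "tumors": _tumors_str(s.tumors), "family_id": s.family_id,
            "mmr_mutation": int(s.mmr_mutation),
            "mlh1_promoter_methylation": int(s.mlh1_promoter_methylation),
            "target_tier": s.target_tier,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subjects_tsv(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, sep="\t", dtype={"tumors": str})
    subjects = []
    for r in df.itertuples():
        age = None if pd.isna(r.age_at_diagnosis) else int(r.age_at_diagnosis)
        rec = None if pd.isna(r.age_at_recruitment) else int(r.age_at_recruitment)
        tier = None if pd.isna(r.target_tier) else int(r.target_tier)
        subjects.append(Subject(
            subject_id=r.subject_id, arm=r.arm, sex=r.sex,
            age_at_diagnosis=age, age_at_recruitment=rec, race=r.race,
            tumors=_parse_tumors(r.tumors), family_id=r.family_id,
            mmr_mutation=bool(r.mmr_mutation),
            mlh1_promoter_methylation=bool(r.mlh1_promoter_methylation),
            target_tier=tier,
        ))
    return subjects


def write_pools_tsv(path: str | Path, pools: list[Pool]) -> None:
    pd.DataFrame(
        [(p.pool_id, p.arm, ",".join(p.member_ids)) for p in pools],
        columns=["pool_id", "arm", "member_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_pools_tsv(path: str | Path) -> list[Pool]:
    df = pd.read_csv(path, sep="\t")
    return [Pool(r.pool_id, r.arm, r.member_ids.split(",")) for r in df.itertuples()]


_PED_COLS = ["family_id", "member_id", "father_id", "mother_id", "sex",
             "phenotype", "relation_to_proband", "generation",
             "cancer_type", "age_at_diagnosis"]


def write_pedigree(path: str | Path, members: list[PedigreeMember]) -> None:
    """Six-column PED-like layout extended with relation/cancer columns.

    Parent links and sex are not modelled, so father/mother are 0 and sex
    unknown; phenotype is 2 (affected) for members with any cancer.
    """
    rows = []
    for m in members:
        rows.append({
            "family_id": m.family_id, "member_id": m.member_id,
            "father_id": 0, "mother_id": 0, "sex": 0,
            "phenotype": 2 if m.cancer_type != "none" else 1,
            "relation_to_proband": m.relation_to_proband,
            "generation": m.generation, "cancer_type": m.cancer_type,
            "age_at_diagnosis": m.age_at_diagnosis,
        })
    pd.DataFrame(rows, columns=_PED_COLS).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> list[PedigreeMember]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        age = None if pd.isna(r.age_at_diagnosis) else int(r.age_at_diagnosis)
        out.append(PedigreeMember(
            member_id=r.member_id, family_id=r.family_id,
            relation_to_proband=r.relation_to_proband,
            generation=int(r.generation), cancer_type=r.cancer_type,
            age_at_diagnosis=age,
        ))
    return out


def write_variants_tsv(path: str | Path, variants: list[PanelVariant]) -> None:
    df = pd.DataFrame([dataclasses.asdict(v) for v in variants])
    df["ref_db_maf"] = df["ref_db_maf"].astype(float)  # None -> NaN, full precision
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_variants_tsv(path: str | Path) -> list[PanelVariant]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        maf = d["ref_db_maf"]
        d["ref_db_maf"] = None if pd.isna(maf) else float(maf)
        d["conserved"] = bool(d["conserved"])
        out.append(PanelVariant(**d))
    return out


def write_truth_tsv(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stage outputs
# ---------------------------------------------------------------------------

def write_calls_tsv(path: str | Path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_filter_traces_tsv(path: str | Path,
                            traces: Iterable[FilterTrace]) -> None:
    rows = []
    for t in traces:
        for stage, ok in t.stages:
            rows.append({"variant_id": t.variant_id, "stage": stage,
                         "passed": int(ok), "final": t.final})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_validation_tsv(path: str | Path,
                         results: Iterable[ValidationResult]) -> None:
    pd.DataFrame(
        [(r.variant_id, r.pool_id, r.carrier_id or "", r.status)
         for r in results],
        columns=["variant_id", "pool_id", "carrier_id", "status"],
    ).to_csv(path, sep="\t", index=False)


def write_tiers_tsv(path: str | Path, tiers: dict[str, TierLabel]) -> None:
    rows = []
    for sid, label in tiers.items():
        rows.append({"subject_id": sid, "tier": label.tier, **label.basis})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_classifications_tsv(path: str | Path,
                              classifications: dict[str, dict]) -> None:
    rows = []
    for vid, rec in classifications.items():
        codes = ",".join(sorted(rec["evidence"]))
        rows.append({"variant_id": vid, "acmg_class": rec["class"],
                     "evidence_codes": codes})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report_json(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    config = SimulationConfig(**data)
    config.validate()
    return config


def save_config(path: str | Path, config: SimulationConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_thresholds(path: str | Path) -> CallThresholds:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return CallThresholds(**data)
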