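"""Synthetic cohort, variant, pool, and pooled-read-count generation.

The generator emulates the statistical structure the pooled-sequencing
analysis assumes: a familial-CRC case/control cohort recruited into six
family-history tiers, a 40-gene panel carrying a background of population
variants plus rare case-only "spiked" variants (one heterozygous carrier
each, the detection target of the design), equimolar DNA pools of ~3 cases
or ~8 controls, and per-pool read counts at every variant site.

Noise model for one pool at one site
------------------------------------
Member contribution weights ``w ~ Dirichlet(alpha)`` (symmetric; large
``alpha`` approaches exact equimolarity, ``alpha = inf`` is exact), the
true pooled alternate-allele fraction is ``f = sum_m w_m * dosage_m / 2``,
site depth is negative-binomial around the configured pool mean (Poisson
in the infinite-dispersion limit, or exactly fixed), and alternate reads
are ``Binomial(depth, f*(1-e) + (1-f)*e/3)`` where ``e`` is the per-base
substitution error rate, spread uniformly over the three non-reference
bases.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ConfigError,
    PanelVariant,
    PedigreeMember,
    Pool,
    PoolSiteCounts,
    PANEL_GENES,
    Subject,
    Tumor,
)

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_variants",
    "build_pools",
    "simulate_pool_counts",
    "simulate_all_pool_counts",
    "counts_to_frame",
    "spiked_truth_table",
]

# Stream tags keep the per-stage random substreams independent of call order.
_COHORT_STREAM = 1
_VARIANT_STREAM = 2
_COUNTS_STREAM = 3

#: Tier sizes of the emulated study sample (1046 cases): tier -> count.
DEFAULT_TIER_COUNTS = {1: 139, 2: 64, 3: 202, 4: 36, 5: 501, 6: 104}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated study's conditions: 1046 cases / 1006
    controls, pools of 3 cases or 8 controls sequenced to mean pool depths
    of 1000X (cases) and 700X (controls), per-base error 0.001, tier mix
    as recruited, and a panel-wide variant background alongside 264 rare
    case-only spiked variants.
    """

    n_cases: int = 1046
    n_controls: int = 1006
    case_pool_size: int = 3
    control_pool_size: int = 8
    mean_case_pool_depth: int = 1000
    mean_control_pool_depth: int = 700
    depth_dispersion: float = 20.0
    depth_distribution: str = "negative_binomial"  # negative_binomial | poisson | fixed
    base_error_rate: float = 0.001
    pipette_concentration: float = 100.0
    maf_spectrum: dict = field(
        default_factory=lambda: {"dist": "loguniform", "low": 1e-4, "high": 0.5}
    )
    tier_proportions: dict = field(
        default_factory=lambda: {
            t: c / sum(DEFAULT_TIER_COUNTS.values())
            for t, c in DEFAULT_TIER_COUNTS.items()
        }
    )
    n_background_variants: int = 9721
    n_spiked_variants: int = 264
    spike_novel_fraction: float = 0.34
    sanger_failure_rate: float = 0.056
    msi_low_fraction: float = 0.16
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("cohort sizes must be positive")
        if self.case_pool_size < 1 or self.control_pool_size < 1:
            raise ConfigError("pool sizes must be >= 1")
        for name in ("base_error_rate", "spike_novel_fraction",
                     "sanger_failure_rate", "msi_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        if self.depth_dispersion <= 0:
            raise ConfigError("depth_dispersion must be positive")
        if self.pipette_concentration <= 0:
            raise ConfigError("pipette_concentration must be positive")
        if self.depth_distribution not in ("negative_binomial", "poisson", "fixed"):
            raise ConfigError(
                f"unknown depth_distribution {self.depth_distribution!r}"
            )
        tot = sum(self.tier_proportions.values())
        if self.tier_proportions and not np.isclose(tot, 1.0, atol=1e-6):
            raise ConfigError("tier_proportions must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _stream(tag: int, seed: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed, *extra])


# ---------------------------------------------------------------------------
# Cohort and pedigrees
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator, mean: float, sd: float,
              low: int, high: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), low, high))


def _case_msi(rng: np.random.Generator, tier: int, msi_low_fraction: float) -> str:
    if tier in (2, 6):
        return "MSI_H"
    return "MSI_L" if rng.random() < msi_low_fraction else "MSS"


def _crc_site(rng: np.random.Generator) -> str:
    return rng.choice(
        ["large_intestine", "rectum", "appendix"], p=[0.76, 0.23, 0.01]
    )


def _build_family(tier: int, proband: Subject,
                  rng: np.random.Generator) -> list[PedigreeMember]:
    """Construct the smallest pedigree that places ``proband`` in ``tier``.

    Tier structures (proband generation 2, parents 1, grandparents 0):
      1/2: Amsterdam-I with the age clause — affected parent (dx < 50) and
           affected sibling, both FDR, two successive generations.
      3:   Amsterdam-I structure, every diagnosis >= 50.
      4:   Amsterdam-II only — mother with endometrial cancer (dx < 50),
           sibling with urothelial cancer; only one CRC so AC-I fails.
      5:   no Amsterdam structure; one SDR (uncle) with CRC.
      6:   no Amsterdam structure; one FDR (sibling) with CRC.
    """
    fid = proband.family_id
    pdx = proband.age_at_diagnosis
    members = [
        PedigreeMember(f"{fid}_self", fid, "self", 2, "CRC", pdx)
    ]
    if tier in (1, 2):
        members += [
            PedigreeMember(f"{fid}_p", fid, "FDR", 1, "CRC",
                           int(rng.integers(38, 50))),
            PedigreeMember(f"{fid}_s", fid, "FDR", 2, "CRC",
                           int(rng.integers(50, 72))),
        ]
    elif tier == 3:
        members += [
            PedigreeMember(f"{fid}_p", fid, "FDR", 1, "CRC",
                           int(rng.integers(50, 75))),
            PedigreeMember(f"{fid}_s", fid, "FDR", 2, "CRC",
                           int(rng.integers(50, 72))),
        ]
    elif tier == 4:
        members += [
            PedigreeMember(f"{fid}_m", fid, "FDR", 1, "endometrial",
                           int(rng.integers(40, 50))),
            PedigreeMember(f"{fid}_s", fid, "FDR", 2, "urothelial",
                           int(rng.integers(50, 70))),
        ]
    elif tier == 5:
        members.append(
            PedigreeMember(f"{fid}_u", fid, "SDR", 1, "CRC",
                           int(rng.integers(50, 76)))
        )
    elif tier == 6:
        members.append(
            PedigreeMember(f"{fid}_s", fid, "FDR", 2, "CRC",
                           int(rng.integers(40, 76)))
        )
    # an unaffected relative so pedigrees are not purely affected members
    members.append(PedigreeMember(f"{fid}_r", fid, "FDR", 2, "none", None))
    return members


# Diagnosis-age windows per tier: Tier 3 requires every CRC dx >= 50 (the
# AC-I age clause must fail); Tier 5 requires proband dx < 60.
_TIER_AGE = {
    1: (55, 10, 26, 87),
    2: (55, 10, 20, 87),
    3: (63, 9, 50, 92),
    4: (58, 8, 39, 76),
    5: (53, 7, 29, 59),
    6: (58, 9, 29, 84),
}


def generate_cohort(config: SimulationConfig) -> tuple[list[Subject], list[PedigreeMember]]:
    """Generate cases (with tier-consistent pedigrees) and older controls.

    Each case is assigned a target tier by a draw from
    ``config.tier_proportions`` and receives a pedigree constructed so the
    tier rules recover exactly that tier (round-trip property).  Controls
    carry no tumors and are older on average (mean 61 vs 56 years).
    """
    config.validate()
    rng = _stream(_COHORT_STREAM, config.seed)
    tiers = sorted(config.tier_proportions)
    probs = np.array([config.tier_proportions[t] for t in tiers], dtype=float)
    probs = probs / probs.sum()

    subjects: list[Subject] = []
    pedigree: list[PedigreeMember] = []
    for i in range(config.n_cases):
        tier = int(rng.choice(tiers, p=probs))
        mean, sd, lo, hi = _TIER_AGE[tier]
        dx = _draw_age(rng, mean, sd, lo, hi)
        sex = "M" if rng.random() < 0.49 else "F"
        race = rng.choice(
            ["white", "black", "asian", "american_indian", "other"],
            p=[0.89, 0.01, 0.07, 0.005, 0.025],
        )
        msi = _case_msi(rng, tier, config.msi_low_fraction)
        tumor = Tumor(_crc_site(rng), dx, msi)
        subj = Subject(
            subject_id=f"case{i:05d}",
            arm="case",
            sex=sex,
            age_at_diagnosis=dx,
            age_at_recruitment=min(dx + int(rng.integers(0, 4)), 100),
            race=str(race),
            tumors=[tumor],
            family_id=f"F{i:05d}",
            target_tier=tier,
        )
        subjects.append(subj)
        pedigree.extend(_build_family(tier, subj, rng))

    for i in range(config.n_controls):
        subjects.append(
            Subject(
                subject_id=f"ctrl{i:05d}",
                arm="control",
                sex="M" if rng.random() < 0.39 else "F",
                age_at_recruitment=_draw_age(rng, 61, 8, 43, 84),
                race=str(rng.choice(
                    ["white", "black", "asian", "other"],
                    p=[0.86, 0.02, 0.10, 0.02],
                )),
                family_id=f"C{i:05d}",
            )
        )
    return subjects, pedigree


# ---------------------------------------------------------------------------
# Variants and genotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))

_BG_CONSEQ = (
    ("nonsynonymous", 0.74), ("synonymous", 0.18), ("other", 0.03),
    ("stop_gain", 0.02), ("frameshift", 0.015), ("splice_site", 0.01),
    ("stop_loss", 0.005),
)
_SPIKE_CONSEQ = (
    ("nonsynonymous", 0.93), ("stop_gain", 0.03), ("frameshift", 0.02),
    ("splice_site", 0.02),
)


def _draw_maf(rng: np.random.Generator, spectrum: dict, size: int) -> np.ndarray:
    dist = spectrum.get("dist", "loguniform")
    low = float(spectrum.get("low", 1e-4))
    high = float(spectrum.get("high", 0.5))
    if dist == "loguniform":
        return np.exp(rng.uniform(np.log(low), np.log(high), size=size))
    if dist == "uniform":
        return rng.uniform(low, high, size=size)
    raise ConfigError(f"unknown maf_spectrum dist {dist!r}")


def _site(rng: np.random.Generator, gene: str, index: int) -> tuple[str, int, str, str]:
    gi = PANEL_GENES.index(gene)
    chrom = f"chr{gi % 22 + 1}"
    pos = 1_000_000 * (gi + 1) + 137 * index + 101
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return chrom, pos, ref, alt


def _predictor_calls(rng, damaging_p, benign_p):
    r = rng.random()
    if r < damaging_p:
        return "damaging"
    if r < damaging_p + benign_p:
        return "benign"
    return "absent"


_TOOL_LABELS = {
    "sift": {"damaging": "deleterious", "benign": "tolerated", "absent": "absent"},
    "polyphen2": {"damaging": "damaging", "benign": "benign", "absent": "absent"},
    "mutation_taster": {
        "damaging": "disease_causing", "benign": "polymorphism", "absent": "absent",
    },
}


def generate_variants(
    config: SimulationConfig, n_background: int, n_spiked: int
) -> tuple[list[PanelVariant], pd.DataFrame]:
    """Generate panel variants and the truth genotype matrix.

    Background variants carry a reference-database MAF drawn from the
    configured spectrum and Hardy-Weinberg genotypes at that frequency in
    both arms.  Spiked variants are the detection target: heterozygous in
    one case each, absent from every control, reference MAF either absent
    (novel) or < 0.001, and annotated from a likely-deleterious profile
    (every spiked non-synonymous variant has >= 1 damaging in-silico call).

    Returns ``(variants, genotypes)`` where ``genotypes`` is an int8
    DataFrame of allele dosages indexed by subject_id with one column per
    variant_id.  Carriers of each spiked variant are recoverable from the
    matrix (see :func:`spiked_truth_table`).
    """
    config.validate()
    if n_background < 0 or n_spiked < 0:
        raise ConfigError("variant counts must be >= 0")
    rng = _stream(_VARIANT_STREAM, config.seed)

    case_ids = [f"case{i:05d}" for i in range(config.n_cases)]
    ctrl_ids = [f"ctrl{i:05d}" for i in range(config.n_controls)]
    subject_ids = case_ids + ctrl_ids
    n_subjects = len(subject_ids)
    if n_spiked > 0 and not case_ids:
        raise ConfigError("spiked variants require at least one case")

    variants: list[PanelVariant] = []
    dosage = np.zeros((n_subjects, n_background + n_spiked), dtype=np.int8)

    bg_conseq, bg_p = zip(*_BG_CONSEQ)
    mafs = _draw_maf(rng, config.maf_spectrum, n_background)
    for j in range(n_background):
        gene = str(rng.choice(PANEL_GENES))
        chrom, pos, ref, alt = _site(rng, gene, j)
        conseq = str(rng.choice(bg_conseq, p=bg_p))
        calls = {}
        for tool in _TOOL_LABELS:
            cls = (
                _predictor_calls(rng, 0.25, 0.55)
                if conseq == "nonsynonymous" else "absent"
            )
            calls[tool] = _TOOL_LABELS[tool][cls]
        clinvar = str(rng.choice(
            ["absent", "VUS", "benign", "pathogenic"], p=[0.80, 0.12, 0.06, 0.02]
        ))
        variants.append(PanelVariant(
            variant_id=f"bg{j:05d}", chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=gene, consequence=conseq, ref_db_maf=float(mafs[j]),
            sift=calls["sift"], polyphen2=calls["polyphen2"],
            mutation_taster=calls["mutation_taster"], clinvar=clinvar,
            conserved=bool(rng.random() < 0.3),
        ))
        dosage[:, j] = rng.binomial(2, mafs[j], size=n_subjects)

    sp_conseq, sp_p = zip(*_SPIKE_CONSEQ)
    replace = n_spiked > len(case_ids)
    carrier_rows = rng.choice(len(case_ids), size=n_spiked, replace=replace)
    for k in range(n_spiked):
        j = n_background + k
        gene = str(rng.choice(PANEL_GENES))
        chrom, pos, ref, alt = _site(rng, gene, 100_000 + k)
        conseq = str(rng.choice(sp_conseq, p=sp_p))
        maf = (
            None if rng.random() < config.spike_novel_fraction
            else float(rng.uniform(1e-6, 0.00099))
        )
        calls = {t: "absent" for t in _TOOL_LABELS}
        if conseq == "nonsynonymous":
            tools = list(_TOOL_LABELS)
            anchor = tools[int(rng.integers(3))]
            for tool in tools:
                if tool == anchor:
                    cls = "damaging"
                else:
                    cls = _predictor_calls(rng, 0.5, 0.2)
                calls[tool] = _TOOL_LABELS[tool][cls]
        clinvar = str(rng.choice(["absent", "VUS", "pathogenic"], p=[0.62, 0.30, 0.08]))
        variants.append(PanelVariant(
            variant_id=f"spike{k:04d}", chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=gene, consequence=conseq, ref_db_maf=maf,
            sift=calls["sift"], polyphen2=calls["polyphen2"],
            mutation_taster=calls["mutation_taster"], clinvar=clinvar,
            conserved=bool(rng.random() < 0.8),
        ))
        dosage[int(carrier_rows[k]), j] = 1

    genotypes = pd.DataFrame(
        dosage, index=pd.Index(subject_ids, name="subject_id"),
        columns=[v.variant_id for v in variants],
    )
    return variants, genotypes


def spiked_truth_table(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Truth table of spiked variants: one row per (variant_id, carrier_id)."""
    spike_cols = [c for c in genotypes.columns if c.startswith("spike")]
    rows = []
    for vid in spike_cols:
        col = genotypes[vid]
        for sid in col.index[col.to_numpy() > 0]:
            rows.append({"variant_id": vid, "carrier_id": sid,
                         "dosage": int(col[sid])})
    return pd.DataFrame(rows, columns=["variant_id", "carrier_id", "dosage"])


# ---------------------------------------------------------------------------
# Pools and pooled read counts
# ---------------------------------------------------------------------------

def build_pools(subjects: list[Subject], config: SimulationConfig) -> list[Pool]:
    """Partition subjects into arm-homogeneous equimolar pools.

    Cases are chunked into pools of ``case_pool_size`` and controls into
    pools of ``control_pool_size`` in subject order; the last pool of each
    arm may be smaller.  Every subject lands in exactly one pool.
    """
    if not subjects:
        raise ConfigError("cannot pool an empty subject list")
    pools: list[Pool] = []
    for arm, size in (("case", config.case_pool_size),
                      ("control", config.control_pool_size)):
        ids = [s.subject_id for s in subjects if s.arm == arm]
        prefix = "CP" if arm == "case" else "KP"
        for i in range(0, len(ids), size):
            pools.append(Pool(f"{prefix}{i // size:04d}", arm, ids[i:i + size]))
    return pools


def _draw_depths(rng: np.random.Generator, mean: int, dispersion: float,
                 distribution: str, size: int) -> np.ndarray:
    if distribution == "fixed":
        return np.full(size, mean, dtype=np.int64)
    if distribution == "poisson" or np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    # NB with mean m and size r: var = m + m^2/r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_pool_counts(
    pool: Pool,
    variants: list[PanelVariant],
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[PoolSiteCounts]:
    """Simulate read counts for one pool at every variant site.

    Per site: Dirichlet member weights (exact 1/n at infinite
    concentration), true alt fraction from member dosages, depth from the
    configured distribution, alt reads binomial with the error-adjusted
    success probability ``f*(1-e) + (1-f)*e/3``.
    """
    missing = [m for m in pool.member_ids if m not in genotypes.index]
    if missing:
        raise ConfigError(f"pool {pool.pool_id}: members absent from genotypes: {missing}")
    if rng is None:
        rng = _stream(_COUNTS_STREAM, config.seed, zlib.crc32(pool.pool_id.encode()))

    vids = [v.variant_id for v in variants]
    dos = genotypes.loc[pool.member_ids, vids].to_numpy(dtype=float)  # (m, V)
    n_var = len(vids)
    m = pool.size
    if np.isinf(config.pipette_concentration):
        weights = np.full((n_var, m), 1.0 / m)
    else:
        weights = rng.dirichlet([config.pipette_concentration] * m, size=n_var)
    f = np.einsum("vm,mv->v", weights, dos) / 2.0

    mean = (config.mean_case_pool_depth if pool.arm == "case"
            else config.mean_control_pool_depth)
    depths = _draw_depths(rng, mean, config.depth_dispersion,
                          config.depth_distribution, n_var)
    e = config.base_error_rate
    p = f * (1.0 - e) + (1.0 - f) * e / 3.0
    alts = rng.binomial(depths, p)
    return [
        PoolSiteCounts(pool.pool_id, vids[j], int(depths[j]), int(alts[j]))
        for j in range(n_var)
    ]


def simulate_all_pool_counts(
    pools: list[Pool],
    variants: list[PanelVariant],
    genotypes: pd.DataFrame,
    config: SimulationConfig,
) -> list[PoolSiteCounts]:
    """Simulate read counts for every pool; deterministic given the config seed."""
    out: list[PoolSiteCounts] = []
    for pool in pools:
        out.extend(simulate_pool_counts(pool, variants, genotypes, config))
    return out


def counts_to_frame(counts: list[PoolSiteCounts]) -> pd.DataFrame:
    """Tabulate PoolSiteCounts as a DataFrame (pool_id, variant_id, depth, alt_reads)."""
    return pd.DataFrame(
        [(c.pool_id, c.variant_id, c.depth, c.alt_reads) for c in counts],
        columns=["pool_id", "variant_id", "depth", "alt_reads"],
    )
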