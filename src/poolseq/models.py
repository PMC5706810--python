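"""Domain records shared across the pooled-sequencing pipeline.

The pipeline screens a fixed 40-gene panel (17 established hereditary CRC
genes plus 23 candidate susceptibility genes) in non-barcoded DNA pools of
cases and controls.  Everything downstream of alignment is expressed in
terms of the records defined here: study subjects with their tumors and
pedigrees, panel variants with reference-database annotations, pools, and
per-pool read counts at each variant site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ESTABLISHED_GENES",
    "CANDIDATE_GENES",
    "PANEL_GENES",
    "CRC_SITES",
    "TRUNCATING_CONSEQUENCES",
    "CONSEQUENCES",
    "Tumor",
    "Subject",
    "PedigreeMember",
    "PanelVariant",
    "Pool",
    "PoolSiteCounts",
    "CallThresholds",
    "PoolCall",
    "FilterTrace",
    "ValidationResult",
    "TierLabel",
    "ConfigError",
    "MalformedInputError",
    "IncompletePedigreeError",
]


class ConfigError(ValueError):
    """Invalid simulation or threshold configuration."""


class MalformedInputError(ValueError):
    """An input table/record violates its documented invariants."""


class IncompletePedigreeError(ValueError):
    """A pedigree lacks the information needed to evaluate a criterion."""


# The 40-gene targeted panel: established hereditary-CRC genes first, then
# candidate susceptibility genes.
ESTABLISHED_GENES: tuple[str, ...] = (
    "APC", "AXIN2", "BMPR1A", "EPCAM", "MLH1", "MLH3", "MSH2", "MSH6",
    "MUTYH", "PMS2", "POLD1", "POLE", "PTEN", "SMAD4", "STK11", "TGFBR2",
    "TP53",
)
CANDIDATE_GENES: tuple[str, ...] = (
    "ALPK2", "BAP1", "BLM", "BRAP", "CDH1", "CHEK2", "CTNNB1", "ENG",
    "ENTPD7", "FZD7", "GREM1", "HELQ", "LAMA2", "LRIG1", "MET", "MSH3",
    "NOS1", "PALB2", "POLQ", "PREX1", "PTCH1", "SH2B3", "WDR78",
)
PANEL_GENES: tuple[str, ...] = ESTABLISHED_GENES + CANDIDATE_GENES

CRC_SITES = frozenset({"large_intestine", "rectum", "appendix"})

CONSEQUENCES = (
    "nonsynonymous", "stop_gain", "stop_loss", "frameshift",
    "splice_site", "synonymous", "other",
)

#: Consequence classes expected to truncate the protein or disrupt a
#: consensus splice site (+/- 1,2); these pass the deleteriousness filter
#: unconditionally.
TRUNCATING_CONSEQUENCES = frozenset(
    {"stop_gain", "stop_loss", "frameshift", "splice_site"}
)

_DAMAGING_CALLS = {
    "sift": "deleterious",
    "polyphen2": "damaging",
    "mutation_taster": "disease_causing",
}
_BENIGN_CALLS = {
    "sift": "tolerated",
    "polyphen2": "benign",
    "mutation_taster": "polymorphism",
}


@dataclass
class Tumor:
    """A single tumor diagnosis; MSI status is only meaningful for CRC sites."""

    site: str  # large_intestine | rectum | appendix | other_cancer
    age: int
    msi_status: str = "untested"  # MSS | MSI_L | MSI_H | untested

    @property
    def is_crc(self) -> bool:
        return self.site in CRC_SITES


@dataclass
class Subject:
    """A study participant (CRC case or unrelated healthy control).

    ``target_tier``, ``mmr_mutation`` and ``mlh1_promoter_methylation`` are
    simulation-truth / screening flags: the generated recruitment tier (for
    round-trip validation) and prior germline-MMR / MLH1-promoter test
    outcomes that exclude a case from the Lynch-like tiers.
    """

    subject_id: str
    arm: str  # case | control
    sex: str = "unknown"  # M | F | unknown
    age_at_diagnosis: int | None = None
    age_at_recruitment: int | None = None
    race: str = "unknown"
    tumors: list[Tumor] = field(default_factory=list)
    family_id: str = ""
    mmr_mutation: bool = False
    mlh1_promoter_methylation: bool = False
    target_tier: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("case", "control"):
            raise MalformedInputError(f"unknown arm {self.arm!r}")
        if self.arm == "control" and self.tumors:
            raise MalformedInputError("controls have no tumors")
        if self.arm == "case" and self.age_at_diagnosis is not None:
            if not 18 <= self.age_at_diagnosis <= 100:
                raise MalformedInputError(
                    f"case age_at_diagnosis {self.age_at_diagnosis} outside [18,100]"
                )

    @property
    def is_case(self) -> bool:
        return self.arm == "case"

    @property
    def crc_tumors(self) -> list[Tumor]:
        return [t for t in self.tumors if t.is_crc]

    @property
    def first_crc_age(self) -> int | None:
        ages = [t.age for t in self.crc_tumors]
        return min(ages) if ages else None

    @property
    def msi_high(self) -> bool:
        return any(t.msi_status == "MSI_H" for t in self.crc_tumors)


@dataclass
class PedigreeMember:
    """One member of a case's family, recorded relative to the proband."""

    member_id: str
    family_id: str
    relation_to_proband: str  # self | FDR | SDR | other
    generation: int
    cancer_type: str = "none"  # CRC | endometrial | small_bowel | urothelial | other | none
    age_at_diagnosis: int | None = None


@dataclass
class PanelVariant:
    """A variant on the 40-gene panel with its annotation fields.

    Annotations (reference-database MAF, in-silico predictor calls, ClinVar
    label, conservation) are inputs to the pipeline, not looked up live.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    ref_db_maf: float | None = None
    sift: str = "absent"            # deleterious | tolerated | absent
    polyphen2: str = "absent"       # damaging | benign | absent
    mutation_taster: str = "absent"  # disease_causing | polymorphism | absent
    clinvar: str = "absent"         # pathogenic | benign | VUS | absent
    conserved: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedInputError(f"{self.variant_id}: pos must be >= 1")
        if self.ref == self.alt:
            raise MalformedInputError(f"{self.variant_id}: ref == alt")
        if self.gene not in PANEL_GENES:
            raise MalformedInputError(
                f"{self.variant_id}: gene {self.gene!r} not on the 40-gene panel"
            )
        if self.consequence not in CONSEQUENCES:
            raise MalformedInputError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.ref_db_maf is not None and not 0.0 <= self.ref_db_maf <= 1.0:
            raise MalformedInputError(
                f"{self.variant_id}: ref_db_maf {self.ref_db_maf} outside [0,1]"
            )

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING_CONSEQUENCES

    @property
    def n_damaging_predictions(self) -> int:
        return sum(
            getattr(self, tool) == call for tool, call in _DAMAGING_CALLS.items()
        )

    @property
    def n_benign_predictions(self) -> int:
        return sum(
            getattr(self, tool) == call for tool, call in _BENIGN_CALLS.items()
        )


@dataclass
class Pool:
    """A non-barcoded, arm-homogeneous DNA pool."""

    pool_id: str
    arm: str  # case | control
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.arm not in ("case", "control"):
            raise MalformedInputError(f"pool {self.pool_id}: unknown arm {self.arm!r}")
        if not self.member_ids:
            raise MalformedInputError(f"pool {self.pool_id}: empty membership")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class PoolSiteCounts:
    """Read depth and alternate-allele reads for one pool at one site."""

    pool_id: str
    variant_id: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise MalformedInputError("negative read counts")
        if self.alt_reads > self.depth:
            raise MalformedInputError(
                f"{self.pool_id}/{self.variant_id}: alt_reads > depth"
            )

    @property
    def alt_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass
class CallThresholds:
    """Read-count thresholds of the pooled calling rule.

    Case pools require the alternate-allele fraction to clear a global 2%
    screen, fall inside the 10-50% minor-allele window expected for one or
    a few heterozygotes among ~3 pooled diploid samples, and have >= 50
    reads at the site.  Control pools only establish presence/absence of
    the allele (any pool passing the screen with >= 2 supporting reads).

    ``min_reads_on_alt`` switches the >=50-reads requirement from total
    site depth (default) to alternate-allele reads.
    """

    min_alt_fraction_screen: float = 0.02
    case_window_low: float = 0.10
    case_window_high: float = 0.50
    min_reads: int = 50
    control_presence_fraction: float = 0.02
    control_min_alt_reads: int = 2
    min_reads_on_alt: bool = False

    def __post_init__(self) -> None:
        ok = (
            0.0
            <= self.min_alt_fraction_screen
            <= self.case_window_low
            < self.case_window_high
            <= 1.0
        )
        if not ok:
            raise ConfigError(
                "thresholds must satisfy 0 <= screen <= window_low < window_high <= 1"
            )
        if self.min_reads < 0:
            raise ConfigError("min_reads must be >= 0")
        if not 0.0 <= self.control_presence_fraction <= 1.0:
            raise ConfigError("control_presence_fraction outside [0,1]")


@dataclass
class PoolCall:
    """The decision record for one pool at one variant site."""

    pool_id: str
    variant_id: str
    detected: bool
    alt_fraction: float
    reason: str  # pass | below_screen | below_window | above_window | insufficient_reads

    def __post_init__(self) -> None:
        if self.detected != (self.reason == "pass"):
            raise MalformedInputError("detected must hold exactly when reason == 'pass'")


@dataclass
class FilterTrace:
    """Audit record of every cascade decision for one variant."""

    variant_id: str
    stages: list[tuple[str, bool]]
    final: str  # rare_deleterious | sanger_selected | rejected

    @property
    def passed_cascade(self) -> bool:
        return self.final in ("rare_deleterious", "sanger_selected")


@dataclass
class ValidationResult:
    """Outcome of Sanger deconvolution of one pooled call."""

    variant_id: str
    pool_id: str
    carrier_id: str | None
    status: str  # confirmed | unconfirmed | failed

    def __post_init__(self) -> None:
        if self.status == "confirmed" and self.carrier_id is None:
            raise MalformedInputError("confirmed result requires a carrier_id")


@dataclass
class TierLabel:
    """Recruitment tier of a case plus the family-history facts behind it."""

    tier: int | str  # 1..6 or "unassigned"
    basis: dict = field(default_factory=dict)
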