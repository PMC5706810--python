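"""Five-class ACMG/AMP variant interpretation from combined evidence codes.

Evidence codes carry one of seven strengths — pathogenic-side
``very_strong`` (PVS), ``strong`` (PS), ``moderate`` (PM), ``supporting``
(PP) and benign-side ``stand_alone_benign`` (BA), ``strong_benign`` (BS),
``supporting_benign`` (BP).  ``combine`` applies the published combining
rules to yield exactly one of pathogenic / likely_pathogenic / VUS /
likely_benign / benign; whenever pathogenic-side and benign-side rules
both fire the result is VUS (conflicting evidence).

``assign_evidence`` auto-assigns only the computable database /
population / in-silico codes:

* **PVS1** (very strong) — protein-truncating consequence in a gene where
  loss of function is an established disease mechanism;
* **PM2** (moderate) — absent from reference population databases;
* **PP3** (supporting) — >= 1 damaging in-silico prediction and no benign
  ones;
* **BA1** (stand-alone benign) — reference MAF above 5% (configurable).

Case-control prevalence (PS4) is deliberately never auto-assigned: with
very rare or private variants the comparison is uninformative.
Segregation, functional and de-novo codes are accepted only as explicit
input overrides.
"""

from __future__ import annotations

from collections.abc import Mapping

from .models import MalformedInputError, PanelVariant, ESTABLISHED_GENES

__all__ = [
    "STRENGTHS",
    "DEFAULT_LOF_GENES",
    "assign_evidence",
    "combine",
    "classify_variant",
]

STRENGTHS = frozenset({
    "very_strong", "strong", "moderate", "supporting",
    "stand_alone_benign", "strong_benign", "supporting_benign",
})

_TRUNCATING_FOR_PVS1 = frozenset({"stop_gain", "frameshift", "splice_site"})

#: Genes where loss of function is an established disease mechanism
#: (the panel's established hereditary-CRC genes); configurable.
DEFAULT_LOF_GENES = frozenset(ESTABLISHED_GENES)


def assign_evidence(
    variant: PanelVariant,
    lof_genes: frozenset[str] = DEFAULT_LOF_GENES,
    ba1_maf: float = 0.05,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Deterministically map annotations to evidence codes.

    Returns ``{code: strength}``.  ``overrides`` merges additional codes
    (e.g. segregation PP1 or functional PS3 supplied as input flags);
    overrides win on code collisions.
    """
    codes: dict[str, str] = {}
    if variant.consequence in _TRUNCATING_FOR_PVS1 and variant.gene in lof_genes:
        codes["PVS1"] = "very_strong"
    if variant.ref_db_maf is None or variant.ref_db_maf == 0.0:
        codes["PM2"] = "moderate"
    if variant.n_damaging_predictions >= 1 and variant.n_benign_predictions == 0:
        codes["PP3"] = "supporting"
    if variant.ref_db_maf is not None and variant.ref_db_maf >= ba1_maf:
        codes["BA1"] = "stand_alone_benign"
    if overrides:
        for code, strength in overrides.items():
            if strength not in STRENGTHS:
                raise MalformedInputError(
                    f"unknown evidence strength {strength!r} for {code}"
                )
            codes[code] = strength
    return codes


def _counts(evidence: Mapping[str, str]) -> dict[str, int]:
    counts = {s: 0 for s in STRENGTHS}
    for code, strength in evidence.items():
        if strength not in STRENGTHS:
            raise MalformedInputError(
                f"unknown evidence strength {strength!r} for {code}"
            )
        counts[strength] += 1
    return counts


def combine(evidence: Mapping[str, str]) -> str:
    """Combine evidence codes into one of the five ACMG classes.

    Pathogenic-side and benign-side rule sets are evaluated independently.
    Contradictory evidence — a rule firing on one side while the other
    side holds any evidence — yields VUS, as does no rule firing at all.
    """
    c = _counts(evidence)
    vs, st, mo, su = (c["very_strong"], c["strong"], c["moderate"],
                      c["supporting"])
    ba, bs, bp = (c["stand_alone_benign"], c["strong_benign"],
                  c["supporting_benign"])

    pathogenic = (
        (vs >= 2)
        or (vs >= 1 and (
            st >= 1
            or mo >= 2
            or (mo >= 1 and su >= 1)
            or su >= 2
        ))
        or (st >= 2)
        or (st == 1 and (
            mo >= 3
            or (mo == 2 and su >= 2)
            or (mo == 1 and su >= 4)
        ))
    )
    likely_pathogenic = (
        (vs >= 1 and mo >= 1)
        or (st == 1 and 1 <= mo <= 2)
        or (st == 1 and su >= 2)
        or (mo >= 3)
        or (mo == 2 and su >= 2)
        or (mo == 1 and su >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_rule = pathogenic or likely_pathogenic
    benign_rule = benign or likely_benign
    path_evidence = vs + st + mo + su > 0
    benign_evidence = ba + bs + bp > 0
    # contradictory evidence: a rule fires on one side while the other
    # side holds any evidence at all (e.g. {BA1, PVS1})
    if (path_rule and benign_evidence) or (benign_rule and path_evidence):
        return "VUS"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "VUS"


def classify_variant(
    variant: PanelVariant,
    lof_genes: frozenset[str] = DEFAULT_LOF_GENES,
    ba1_maf: float = 0.05,
    overrides: Mapping[str, str] | None = None,
) -> tuple[str, dict[str, str]]:
    """Assign evidence and combine it; returns ``(class, evidence)``."""
    evidence = assign_evidence(variant, lof_genes, ba1_maf, overrides)
    return combine(evidence), evidence
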