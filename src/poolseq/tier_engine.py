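"""Recruitment-tier assignment from pedigree, age, and tumor MSI status.

Cases were recruited into six prioritized family-history tiers.  MSS-group
tumors (MSS or MSI-Low) populate the FCCTX-like tiers and MSI-High tumors
(with no known MMR germline mutation or MLH1 promoter methylation) the
Lynch-like tiers:

====  =========  =======================================================
Tier  MSI group  Family-history criterion
====  =========  =======================================================
1     MSS        Amsterdam I (with the <50-years age clause)
3     MSS        Amsterdam I structure, age clause not met
4     MSS        Amsterdam II
5     MSS        first CRC diagnosed < 60 and >= 1 FDR/SDR with CRC
2     MSI-High   Amsterdam I or II
6     MSI-High   >= 1 FDR/SDR with CRC (no Amsterdam criteria)
====  =========  =======================================================

Amsterdam I: >= 3 relatives with CRC (proband included), one a
first-degree relative of the other two, spanning >= 2 successive
generations, >= 1 diagnosed before 50, FAP excluded.  Amsterdam II widens
the affected set to the HNPCC tumor spectrum (CRC, endometrial,
small-bowel, urothelial).

Pedigree records encode each member's relation to the proband (plus a
generation number), not the full relationship graph, so first-degree
links between two non-proband members are inferred: two FDRs of the
proband within one generation of each other (parent/child or siblings),
or an FDR and an SDR in adjacent generations (e.g. an affected parent and
that parent's own parent), are presumed first-degree of one another.
"""

from __future__ import annotations

from .models import (
    IncompletePedigreeError,
    MalformedInputError,
    PedigreeMember,
    Subject,
    TierLabel,
)

__all__ = ["amsterdam_I", "amsterdam_II", "assign_tier", "AC2_SPECTRUM"]

AC1_SPECTRUM = frozenset({"CRC"})
#: HNPCC tumor spectrum used by Amsterdam II.
AC2_SPECTRUM = frozenset({"CRC", "endometrial", "small_bowel", "urothelial"})


def _proband(pedigree: list[PedigreeMember]) -> PedigreeMember:
    selves = [m for m in pedigree if m.relation_to_proband == "self"]
    if len(selves) != 1:
        raise MalformedInputError(
            f"pedigree must contain exactly one proband, found {len(selves)}"
        )
    return selves[0]


def _presumed_first_degree(a: PedigreeMember, b: PedigreeMember) -> bool:
    """Whether two family members are (presumed) first-degree relatives.

    Exact for pairs involving the proband; inferred from generations for
    pairs of relatives (see module docstring).
    """
    ra, rb = a.relation_to_proband, b.relation_to_proband
    gap = abs(a.generation - b.generation)
    if "self" in (ra, rb):
        return (rb if ra == "self" else ra) == "FDR"
    if ra == "FDR" and rb == "FDR":
        return gap <= 1
    if {ra, rb} == {"FDR", "SDR"}:
        return gap == 1
    return False


def _amsterdam(
    pedigree: list[PedigreeMember],
    spectrum: frozenset[str],
    require_age: bool,
    fap_family: bool,
) -> bool:
    if fap_family:
        return False
    _proband(pedigree)  # structural check: exactly one proband
    affected = [m for m in pedigree if m.cancer_type in spectrum]
    if len(affected) < 3:
        return False
    # 3-2-1 link clause: one affected member first-degree of >= 2 others
    linked = any(
        sum(_presumed_first_degree(pivot, other)
            for other in affected if other is not pivot) >= 2
        for pivot in affected
    )
    if not linked:
        return False
    generations = {m.generation for m in affected}
    if max(generations) - min(generations) < 1:
        return False
    if not require_age:
        return True
    ages = [m.age_at_diagnosis for m in affected]
    if any(a is not None and a < 50 for a in ages):
        return True
    if any(a is None for a in ages):
        raise IncompletePedigreeError(
            "affected member without diagnosis age; cannot evaluate the age clause"
        )
    return False


def amsterdam_I(pedigree: list[PedigreeMember], require_age: bool = True,
                fap_family: bool = False) -> bool:
    """Amsterdam criteria I; ``require_age=False`` drops the <50-years clause."""
    return _amsterdam(pedigree, AC1_SPECTRUM, require_age, fap_family)


def amsterdam_II(pedigree: list[PedigreeMember], require_age: bool = True,
                 fap_family: bool = False) -> bool:
    """Amsterdam criteria II (affected set widened to the HNPCC spectrum)."""
    return _amsterdam(pedigree, AC2_SPECTRUM, require_age, fap_family)


def assign_tier(subject: Subject, pedigree: list[PedigreeMember],
                fap_family: bool = False) -> TierLabel:
    """Assign a CRC case to its recruitment tier (first match in priority order).

    MSS and MSI-Low tumors form the MSS group; an MSI-High case with a
    known MMR germline mutation or MLH1 promoter methylation is left
    unassigned (these explain the tumor phenotype and exclude the case
    from the Lynch-like tiers).
    """
    if not subject.is_case or not subject.crc_tumors:
        raise MalformedInputError(
            f"{subject.subject_id}: tier assignment requires a CRC case"
        )
    ac1 = amsterdam_I(pedigree, require_age=True, fap_family=fap_family)
    ac1_no_age = amsterdam_I(pedigree, require_age=False, fap_family=fap_family)
    ac2 = amsterdam_II(pedigree, require_age=True, fap_family=fap_family)
    fdr_sdr_crc = any(
        m.relation_to_proband in ("FDR", "SDR") and m.cancer_type == "CRC"
        for m in pedigree
    )
    first_crc = subject.first_crc_age
    crc_lt60 = first_crc is not None and first_crc < 60 and fdr_sdr_crc
    msi_group = "MSI_H" if subject.msi_high else "MSS_group"
    basis = {
        "ac1": ac1,
        "ac1_no_age": ac1_no_age,
        "ac2": ac2,
        "crc_lt60_with_fdr_sdr": crc_lt60,
        "fdr_sdr_crc": fdr_sdr_crc,
        "msi_group": msi_group,
    }

    if msi_group == "MSI_H":
        if subject.mmr_mutation or subject.mlh1_promoter_methylation:
            return TierLabel("unassigned", basis)
        if ac1 or ac2:
            return TierLabel(2, basis)
        if fdr_sdr_crc:
            return TierLabel(6, basis)
        return TierLabel("unassigned", basis)

    if ac1:
        return TierLabel(1, basis)
    if ac1_no_age:
        return TierLabel(3, basis)
    if ac2:
        return TierLabel(4, basis)
    if crc_lt60:
        return TierLabel(5, basis)
    return TierLabel("unassigned", basis)
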