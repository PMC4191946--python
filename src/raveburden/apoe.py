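"""APOE epsilon-diplotype calling and stratified phenotype associations.

The three common APOE alleles are haplotypes of two coding SNPs:
p.C130R (rs429358) and p.R176C (rs7412).  Epsilon-3 is wild type at both
positions, epsilon-4 carries C130R, and epsilon-2 carries R176C.  From the
two allele dosages (count of the C130R change, count of the R176C change)
the diplotype follows uniquely for every combination except the double
heterozygote, which is phase-resolved to e2/e4 (the overwhelmingly likely
phase; the rare e1 allele carrying both changes is not modelled) and
flagged ambiguous.  Dosage pairs that would force both changes onto one
haplotype — (2,1), (1,2), (2,2) — are data errors.
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

from .model import (
    ApoeDiplotype,
    DataError,
    FisherResult,
    Group,
    OnsetSite,
    Sample,
    Sex,
    TestMethod,
)
from .association import fisher_exact

__all__ = ["call_apoe", "apoe_strata_test", "apoe_strata_tests", "age_of_onset_by_carrier"]

_DIPLOTYPE_MAP = {
    (0, 0): ("e3", "e3", False),
    (0, 1): ("e2", "e3", False),
    (0, 2): ("e2", "e2", False),
    (1, 0): ("e3", "e4", False),
    (2, 0): ("e4", "e4", False),
    (1, 1): ("e2", "e4", True),  # double heterozygote: phase ambiguous
}


def call_apoe(
    genotype_130: int, genotype_176: int, sample_id: str = ""
) -> ApoeDiplotype:
    """Call an epsilon diplotype from the two SNP dosages.

    ``genotype_130`` is the dosage of the C130R change (rs429358, the e4
    tag), ``genotype_176`` the dosage of the R176C change (rs7412, the e2
    tag).  Missing dosage (negative or None) yields an uncallable result,
    excluded from all denominators.
    """
    if genotype_130 is None or genotype_176 is None or genotype_130 < 0 or genotype_176 < 0:
        return ApoeDiplotype(sample_id=sample_id, allele1=None, allele2=None, called=False)
    key = (int(genotype_130), int(genotype_176))
    if key not in _DIPLOTYPE_MAP and key in {(2, 1), (1, 2), (2, 2)}:
        raise DataError(
            f"dosage pair {key} requires a haplotype carrying both changes "
            "(the e1 allele, not modelled)"
        )
    if key not in _DIPLOTYPE_MAP:
        raise DataError(f"invalid APOE dosage pair {key}")
    a1, a2, amb = _DIPLOTYPE_MAP[key]
    return ApoeDiplotype(sample_id=sample_id, allele1=a1, allele2=a2, ambiguous=amb)


def _field_value(sample: Sample, field: str):
    v = getattr(sample, field)
    return v.value if hasattr(v, "value") else v


def apoe_strata_test(
    diplotypes: Sequence[ApoeDiplotype],
    samples: Sequence[Sample],
    allele: str,
    field: str,
    level,
    subset: Optional[dict] = None,
    method: TestMethod | str = TestMethod.MINLIKE,
) -> FisherResult:
    """Carrier x stratum exact test.

    Rows: carriers of ``allele`` (>= 1 copy) vs non-carriers; columns:
    samples at ``field == level`` vs the rest.  ``subset`` optionally
    restricts the analysis (e.g. ``{"group": "case"}`` or
    ``{"onset_site": "limb"}``).  Uncallable diplotypes are dropped.
    An empty stratum level yields a degenerate result, not an error.
    """
    if allele not in ("e2", "e3", "e4"):
        raise DataError(f"unknown APOE allele {allele!r}")
    by_id = {d.sample_id: d for d in diplotypes}
    table = [[0, 0], [0, 0]]
    for s in samples:
        d = by_id.get(s.sample_id)
        if d is None or not d.called:
            continue
        if subset and any(_field_value(s, f) != str(v) for f, v in subset.items()):
            continue
        row = 0 if d.carries(allele) else 1
        col = 0 if _field_value(s, field) == str(level) else 1
        table[row][col] += 1
    return fisher_exact(table, method=method)


def apoe_strata_tests(
    diplotypes: Sequence[ApoeDiplotype],
    samples: Sequence[Sample],
    method: TestMethod | str = TestMethod.MINLIKE,
) -> dict[str, FisherResult]:
    """The standard battery of stratified APOE associations.

    Within cases: e2 vs upper-limb onset, e4 vs bulbar onset, e2 vs the
    long-survivor panel; within limb-onset cases: e4 carriage by sex; and
    e4 carriage case vs control.
    """
    cases = {"group": Group.CASE.value}
    return {
        "e2_upper_limb_onset": apoe_strata_test(
            diplotypes, samples, "e2", "onset_site", OnsetSite.UPPER_LIMB.value,
            subset=cases, method=method,
        ),
        "e4_bulbar_onset": apoe_strata_test(
            diplotypes, samples, "e4", "onset_site", OnsetSite.BULBAR.value,
            subset=cases, method=method,
        ),
        "e2_long_survivor": apoe_strata_test(
            diplotypes, samples, "e2", "long_survivor", True,
            subset=cases, method=method,
        ),
        "e4_female_limb_onset": apoe_strata_test(
            diplotypes, samples, "e4", "sex", Sex.FEMALE.value,
            subset={"group": Group.CASE.value, "onset_site": OnsetSite.LIMB.value},
            method=method,
        ),
        "e4_case_control": apoe_strata_test(
            diplotypes, samples, "e4", "group", Group.CASE.value, method=method
        ),
    }


def age_of_onset_by_carrier(
    diplotypes: Sequence[ApoeDiplotype],
    samples: Sequence[Sample],
    allele: str,
) -> dict[str, Optional[float]]:
    """Median age of onset for carriers vs non-carriers (cases only).

    Reported as group medians only; no test statistic is attached.
    """
    by_id = {d.sample_id: d for d in diplotypes}
    carrier_ages, noncarrier_ages = [], []
    for s in samples:
        if s.group is not Group.CASE or s.age_of_onset is None:
            continue
        d = by_id.get(s.sample_id)
        if d is None or not d.called:
            continue
        (carrier_ages if d.carries(allele) else noncarrier_ages).append(s.age_of_onset)
    return {
        "carrier_median": statistics.median(carrier_ages) if carrier_ages else None,
        "noncarrier_median": statistics.median(noncarrier_ages) if noncarrier_ages else None,
        "n_carriers": len(carrier_ages),
        "n_noncarriers": len(noncarrier_ages),
    }
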