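"""Site-quality filtering and novel/rare variant classification.

Classification rules, in the order the pipeline applies them:

1. *Quality*: a site fails the hard filters iff any of DP < 5, QUAL < 30,
   QD < 2, FS > 50, HaplotypeScore > 13, MQ < 30, MQRankSum < -12.5,
   ReadPosRankSum < -8 holds (strict comparators; absent annotations never
   fail their rule).
2. *Functional restriction*: only nonsynonymous, stopgain, stoploss and
   frameshift changes enter the novel/rare analysis.
3. *Novelty*: absent from dbSNP, ESP6500 and 1000 Genomes.
4. *Rarity* (database-known variants only): ESP6500 frequency <= the cutoff
   (inclusive), or a dbSNP entry without a listed frequency that is absent
   from ESP6500 and absent from (or below 1% in) 1000 Genomes.
5. *Shared exclusion*: a novel or rare variant carried by at least one case
   AND at least one control is treated as a likely benign polymorphism and
   excluded; otherwise it is attributed to the group that carries it.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .model import (
    AnalysisConfig,
    AnnotatedVariant,
    Classification,
    CohortData,
    DataError,
    FUNCTIONAL_CLASSES,
    Group,
    SiteQuality,
    VariantStatus,
)

__all__ = [
    "apply_quality_filters",
    "is_novel",
    "is_rare",
    "restrict_functional",
    "classify_cohort",
    "classify_variant",
]


def apply_quality_filters(
    q: SiteQuality, cfg: Optional[AnalysisConfig] = None
) -> tuple[bool, list[str]]:
    """Return (passed, failed_rules) for one site's quality annotations."""
    cfg = cfg or AnalysisConfig()
    failed = []
    if q.dp is not None and q.dp < cfg.dp_min:
        failed.append("DP")
    if q.qual is not None and q.qual < cfg.qual_min:
        failed.append("QUAL")
    if q.qd is not None and q.qd < cfg.qd_min:
        failed.append("QD")
    if q.fs is not None and q.fs > cfg.fs_max:
        failed.append("FS")
    if q.haplotype_score is not None and q.haplotype_score > cfg.haplotype_score_max:
        failed.append("HaplotypeScore")
    if q.mq is not None and q.mq < cfg.mq_min:
        failed.append("MQ")
    if q.mq_rank_sum is not None and q.mq_rank_sum < cfg.mq_rank_sum_min:
        failed.append("MQRankSum")
    if q.read_pos_rank_sum is not None and q.read_pos_rank_sum < cfg.read_pos_rank_sum_min:
        failed.append("ReadPosRankSum")
    return (not failed, failed)


def is_novel(v: AnnotatedVariant) -> bool:
    """True iff the variant is absent from dbSNP, ESP6500 and 1000 Genomes.

    Membership, not frequency, decides: a database entry listing frequency 0
    still makes the variant non-novel.
    """
    return not v.in_dbsnp and v.esp_freq is None and v.kg_freq is None


def is_rare(v: AnnotatedVariant, cfg: Optional[AnalysisConfig] = None) -> bool:
    """Rarity for a database-known variant.

    Raises if called on a novel variant: novelty and rarity are mutually
    exclusive by construction.
    """
    cfg = cfg or AnalysisConfig()
    if is_novel(v):
        raise DataError(f"is_rare called on novel variant {v.key}")
    if v.esp_freq is not None:
        return v.esp_freq <= cfg.rarity_cutoff
    # absent from ESP6500: rare only as an unfrequencied dbSNP entry that
    # 1000 Genomes does not contradict
    if v.in_dbsnp and not v.dbsnp_has_freq:
        return v.kg_freq is None or v.kg_freq < cfg.kg_cutoff
    return False


def restrict_functional(
    variants: Sequence[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Keep nonsynonymous/stopgain/stoploss/frameshift variants only."""
    return [v for v in variants if v.functional_class in FUNCTIONAL_CLASSES]


def classify_variant(
    v: AnnotatedVariant,
    case_carriers: int,
    control_carriers: int,
    cfg: Optional[AnalysisConfig] = None,
) -> Classification:
    """Status of one quality-passing, functional variant given carrier counts."""
    cfg = cfg or AnalysisConfig()
    if is_novel(v):
        base, reason = VariantStatus.NOVEL, "absent_all_databases"
    elif is_rare(v, cfg):
        base, reason = VariantStatus.RARE, "below_frequency_cutoff"
    else:
        return Classification(
            status=VariantStatus.COMMON,
            reasons=("database_frequency_above_cutoff",),
            case_carriers=case_carriers,
            control_carriers=control_carriers,
        )
    if case_carriers >= 1 and control_carriers >= 1:
        return Classification(
            status=VariantStatus.EXCLUDED_SHARED,
            reasons=(reason, "carried_in_both_groups"),
            case_carriers=case_carriers,
            control_carriers=control_carriers,
        )
    attributed = None
    if case_carriers >= 1:
        attributed = Group.CASE
    elif control_carriers >= 1:
        attributed = Group.CONTROL
    return Classification(
        status=base,
        reasons=(reason,),
        case_carriers=case_carriers,
        control_carriers=control_carriers,
        attributed_to=attributed,
    )


def classify_cohort(
    data: CohortData,
    cfg: Optional[AnalysisConfig] = None,
    apply_quality: bool = True,
    apply_functional: bool = True,
) -> list[Classification]:
    """Classify every variant of a cohort.

    Returns one :class:`Classification` per variant, aligned with
    ``data.variants``.  Quality filtering and the functional restriction can
    be disabled when the caller has already applied them; the final
    novel/rare/shared partition is unaffected by the order of those two
    steps.
    """
    cfg = cfg or AnalysisConfig()
    case_mask = data.group_mask(Group.CASE)
    control_mask = data.group_mask(Group.CONTROL)
    out: list[Classification] = []
    for j, v in enumerate(data.variants):
        if apply_quality:
            ok, failed = apply_quality_filters(data.site_quality[j], cfg)
            if not ok:
                out.append(
                    Classification(
                        status=VariantStatus.FILTERED_QUALITY, reasons=tuple(failed)
                    )
                )
                continue
        if apply_functional and v.functional_class not in FUNCTIONAL_CLASSES:
            out.append(
                Classification(
                    status=VariantStatus.NON_FUNCTIONAL,
                    reasons=(v.functional_class.value,),
                )
            )
            continue
        col = data.genotypes[:, j]
        carrier = col >= 1
        cc = int((carrier & case_mask).sum())
        tc = int((carrier & control_mask).sum())
        out.append(classify_variant(v, cc, tc, cfg))
    return out


def qualifying_variant_indices(
    classifications: Sequence[Classification],
) -> list[int]:
    """Indices of variants with final status novel or rare."""
    return [
        j
        for j, c in enumerate(classifications)
        if c.status in (VariantStatus.NOVEL, VariantStatus.RARE)
    ]
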