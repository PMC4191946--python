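"""PolyPhen-weighted allele binning and the deleterious-carrier burden test.

Each sample's qualifying (novel or rare, functional) variants within a gene
set are collapsed into a single deleteriousness score.  Rare variants are
not in linkage disequilibrium with one another, so no LD weighting applies;
instead every variant carries its PolyPhen-2 score and the per-sample score
is the maximum (default) or the sum of those.  A sample whose score reaches
the "probably damaging" threshold (0.85) counts as a deleterious-variant
carrier, and carrier counts are compared between cases and controls with
the exact conditional test.

Score policies for variants without a PolyPhen-2 score:

* ordinary missing scores contribute 0 by default (the binning deliberately
  downweights variation not predicted deleterious), or can be excluded;
* stopgain/frameshift changes structurally lack PolyPhen-2 scores and are
  assigned 1.0 (maximally damaging) by default, configurable to 0.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    AggregationMode,
    AnalysisConfig,
    BurdenResult,
    Classification,
    CohortData,
    DataError,
    Group,
    LOF_CLASSES,
    PanelGene,
    VariantStatus,
)
from .association import fisher_exact

__all__ = ["individual_score", "variant_weight", "burden_test"]


def individual_score(
    scores: Iterable[float], mode: AggregationMode | str = AggregationMode.MAX
) -> float:
    """Collapse one sample's variant scores into a single value.

    max: the worst single variant (0 for a sample with none).
    sum: total deleteriousness, which can cross the carrier threshold
    through several moderate variants.
    """
    mode = AggregationMode(mode)
    scores = list(scores)
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise DataError(f"variant score {s} outside [0, 1]")
    if not scores:
        return 0.0
    return max(scores) if mode is AggregationMode.MAX else float(sum(scores))


def variant_weight(variant, cfg: AnalysisConfig) -> Optional[float]:
    """Score contributed by one variant, or None if excluded by policy."""
    if variant.functional_class in LOF_CLASSES and variant.polyphen_score is None:
        return 1.0 if cfg.lof_score_policy == "one" else 0.0
    if variant.polyphen_score is None:
        return 0.0 if cfg.missing_score_policy == "zero" else None
    return float(variant.polyphen_score)


def burden_test(
    data: CohortData,
    classifications: Sequence[Classification],
    gene_set: Optional[Sequence[PanelGene]] = None,
    cfg: Optional[AnalysisConfig] = None,
    panel: Optional[Sequence[PanelGene]] = None,
    gene_set_name: Optional[str] = None,
) -> BurdenResult:
    """Case/control deleterious-carrier test over a gene set.

    ``gene_set`` defaults to the panel genes in the known-ALS or associated
    categories (the genes with the highest prior for involvement); supply
    ``panel`` for that default to be computable.  The full per-sample score
    vector is retained in the result for audit.
    """
    cfg = cfg or AnalysisConfig()
    if gene_set is None:
        if panel is None:
            raise DataError("burden_test needs a gene_set or a panel")
        gene_set = [
            g for g in panel if g.categories & {"known_als", "associated"}
        ]
        gene_set_name = gene_set_name or "known_als+associated"
    if not gene_set:
        raise DataError("empty gene set")
    genes = {g.gene for g in gene_set}
    name = gene_set_name or "+".join(sorted(genes))

    cols: list[int] = []
    weights: list[float] = []
    for j, (v, c) in enumerate(zip(data.variants, classifications)):
        if c.status not in (VariantStatus.NOVEL, VariantStatus.RARE):
            continue
        if v.gene not in genes:
            continue
        w = variant_weight(v, cfg)
        if w is None:
            continue
        cols.append(j)
        weights.append(w)

    n_samples = len(data.samples)
    if cols:
        carried = (data.genotypes[:, cols] >= 1).astype(float)
        wmat = carried * np.asarray(weights)[None, :]
        if cfg.aggregation_mode is AggregationMode.MAX:
            sample_scores = wmat.max(axis=1)
        else:
            sample_scores = wmat.sum(axis=1)
    else:
        sample_scores = np.zeros(n_samples)

    carrier = sample_scores >= cfg.polyphen_threshold
    case_mask = data.group_mask(Group.CASE)
    control_mask = data.group_mask(Group.CONTROL)
    a = int((carrier & case_mask).sum())
    c = int((carrier & control_mask).sum())
    n_case = int(case_mask.sum())
    n_control = int(control_mask.sum())
    fr = fisher_exact(
        [[a, n_case - a], [c, n_control - c]], method=cfg.test_method
    )
    return BurdenResult(
        gene_set=name,
        scores={s.sample_id: float(v) for s, v in zip(data.samples, sample_scores)},
        case_carriers=a,
        control_carriers=c,
        n_cases=n_case,
        n_controls=n_control,
        fisher=fr,
    )
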