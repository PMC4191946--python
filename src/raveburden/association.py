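"""Exact 2x2 inference and prevalence/enrichment computations.

The engine works in the conditional framework: with both margins of the
2x2 table fixed, the top-left cell follows Fisher's noncentral
hypergeometric distribution with odds-ratio parameter psi.  From that one
distribution we derive

* the two-sided exact p-value, either ``minlike`` (sum of all outcome
  probabilities not exceeding the observed one, the convention of R's
  ``fisher.test``) or ``central`` (twice the smaller one-sided tail);
* the conditional maximum-likelihood odds ratio (CMLE), the root of the
  conditional score equation E_psi[X] = x;
* an exact 95% confidence interval — tail inversion
  (P_psi(X >= x) = alpha/2 / P_psi(X <= x) = alpha/2) for the central
  method, and inversion of the minlike p-value function (the "matching"
  interval of two-sided exact tests) for the minlike method.

Tables with a zero margin are degenerate: p = 1 and OR is reported as 1
with the ``degenerate`` flag set, never an exception.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .model import (
    Classification,
    CohortData,
    DataError,
    FisherResult,
    Group,
    PanelGene,
    PrevalenceRow,
    TestMethod,
    VariantStatus,
    AnalysisConfig,
)

__all__ = [
    "fisher_exact",
    "snp_carrier_test",
    "gene_prevalence",
    "prevalence_total",
    "adjust_control_count",
    "category_enrichment",
]

# relative slack when comparing point probabilities for the minlike rule;
# guards against ties being broken by floating-point noise (same device as
# R's fisher.test)
_TIE_RELTOL = 1e-7


def _margins(table: np.ndarray) -> tuple[int, int, int, int]:
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    return a + b, c + d, a + c, b + d


def _support_logweights(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support of the conditional distribution and log hypergeometric weights.

    The weight of k successes in row 1 is C(r1, k) * C(r2, c1 - k); the
    noncentral pmf at parameter psi is proportional to weight * psi^k.
    """
    lo, hi = max(0, c1 - r2), min(c1, r1)
    k = np.arange(lo, hi + 1)
    lw = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
    )
    return k, lw


def _pmf(log_psi: float, k: np.ndarray, lw: np.ndarray) -> np.ndarray:
    z = lw + k * log_psi
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def _p_minlike(log_psi: float, x: int, k: np.ndarray, lw: np.ndarray) -> float:
    p = _pmf(log_psi, k, lw)
    px = p[k == x][0]
    return float(p[p <= px * (1.0 + _TIE_RELTOL)].sum())


def _p_central(log_psi: float, x: int, k: np.ndarray, lw: np.ndarray) -> float:
    p = _pmf(log_psi, k, lw)
    lower = float(p[k <= x].sum())
    upper = float(p[k >= x].sum())
    return min(1.0, 2.0 * min(lower, upper))


def _cmle(x: int, k: np.ndarray, lw: np.ndarray) -> float:
    """Conditional MLE: solve E_psi[X] = x; 0 / +inf at the support bounds."""
    if x == k[0]:
        return 0.0 if len(k) > 1 else 1.0
    if x == k[-1]:
        return math.inf if len(k) > 1 else 1.0
    score = lambda t: float((_pmf(t, k, lw) * k).sum()) - x
    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2
        if lo < -500:  # pragma: no cover - untriggerable for interior x
            return 0.0
    while score(hi) < 0:
        hi *= 2
        if hi > 500:  # pragma: no cover
            return math.inf
    return float(np.exp(brentq(score, lo, hi, xtol=1e-12)))


def _invert_monotone(f, target: float, t_start: float, direction: int) -> float:
    """Root of f(t) = target moving from t_start in +-1 direction.

    f must approach values beyond target monotonically in that direction.
    """
    step = 1.0
    t0 = t_start
    t1 = t_start + direction * step
    while (f(t1) - target) * (f(t0) - target) > 0:
        t0 = t1
        step *= 2
        t1 = t_start + direction * step
        if abs(t1) > 700:  # psi out of double range; effectively 0 / inf
            return -math.inf if direction < 0 else math.inf
    lo, hi = sorted((t0, t1))
    return float(brentq(lambda t: f(t) - target, lo, hi, xtol=1e-10))


def _solve_increasing(f, target: float, t0: float = 0.0) -> float:
    """Root of increasing f(t) = target, expanding the bracket from t0."""
    lo = hi = t0
    step = 1.0
    while f(lo) > target:
        lo -= step
        step *= 2
        if lo < -700:
            return -math.inf
    step = 1.0
    while f(hi) < target:
        hi += step
        step *= 2
        if hi > 700:
            return math.inf
    return float(brentq(lambda t: f(t) - target, lo, hi, xtol=1e-10))


def _ci_central(
    x: int, k: np.ndarray, lw: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Exact tail-inversion interval (the convention of R's fisher.test)."""
    half = alpha / 2.0
    if x == k[0]:
        low = 0.0
    else:
        # P(X >= x) increases with psi; the lower limit makes it alpha/2
        upper_tail = lambda t: float(_pmf(t, k, lw)[k >= x].sum())
        t = _solve_increasing(upper_tail, half)
        low = 0.0 if t == -math.inf else float(np.exp(t))
    if x == k[-1]:
        high = math.inf
    else:
        # P(X <= x) decreases with psi; negate to reuse the increasing solver
        lower_tail = lambda t: -float(_pmf(t, k, lw)[k <= x].sum())
        t = _solve_increasing(lower_tail, -half)
        high = math.inf if t == math.inf else float(np.exp(t))
    return low, high


def _ci_minlike(
    x: int, k: np.ndarray, lw: np.ndarray, alpha: float, cmle: float
) -> tuple[float, float]:
    """Matching interval of the minlike test: bounds of {psi : p(psi) >= alpha}.

    The minlike p-value function of psi has jump discontinuities where the
    inclusion set changes; after root-finding from the CMLE outward we scan a
    log-grid beyond each root and push the bound outward if the p-value pops
    back above alpha (Fay-style matching interval).
    """
    t_mid = 0.0 if cmle in (0.0, math.inf) else math.log(cmle)
    p_at = lambda t: _p_minlike(t, x, k, lw)

    def _extend(t_root: float, direction: int) -> float:
        t = t_root
        for _ in range(6):
            probe = [t + direction * d for d in np.linspace(0.05, 3.0, 40)]
            above = [tp for tp in probe if p_at(tp) >= alpha]
            if not above:
                return t
            t_far = above[-1]
            t = _invert_monotone(p_at, alpha, t_far, direction)
            if not math.isfinite(t):
                return t
        return t  # pragma: no cover - pathological oscillation

    if x == k[0]:
        low = 0.0
    elif x == k[-1]:
        # p rises towards 1 as psi -> inf: the lower bound is the increasing
        # crossing of alpha
        t = _solve_increasing(p_at, alpha)
        t = _extend(t, -1) if math.isfinite(t) else t
        low = 0.0 if t == -math.inf else float(np.exp(t))
    else:
        t = _invert_monotone(p_at, alpha, t_mid, -1)
        t = _extend(t, -1) if math.isfinite(t) else t
        low = 0.0 if t == -math.inf else float(np.exp(t))
    if x == k[-1]:
        high = math.inf
    elif x == k[0]:
        # p rises towards 1 as psi -> 0: -p is increasing in t
        t = _solve_increasing(lambda t_: -p_at(t_), -alpha)
        t = _extend(t, +1) if math.isfinite(t) else t
        high = math.inf if t == math.inf else float(np.exp(t))
    else:
        t = _invert_monotone(p_at, alpha, t_mid, +1)
        t = _extend(t, +1) if math.isfinite(t) else t
        high = math.inf if t == math.inf else float(np.exp(t))
    return low, high


def fisher_exact(
    table: Sequence[Sequence[int]],
    method: TestMethod | str = TestMethod.MINLIKE,
    alpha: float = 0.05,
    compute_ci: bool = True,
) -> FisherResult:
    """Exact conditional inference for a 2x2 table.

    Parameters
    ----------
    table
        ``[[a, b], [c, d]]`` of non-negative integers; rows are groups
        (e.g. cases / controls), columns are outcomes (carrier / non-carrier).
    method
        ``minlike`` (default) or ``central`` two-sided p-value; the CI follows
        the same convention (matching interval for minlike, tail inversion
        for central).
    compute_ci
        Skip the (comparatively expensive) CI inversion when False.
    """
    method = TestMethod(method)
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError(f"not a non-negative 2x2 table: {table!r}")
    tbl = ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1])))
    r1, r2, c1, c2 = _margins(t)
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(
            table=tbl, p_two_sided=1.0, method=method, or_cmle=1.0,
            ci_low=0.0, ci_high=math.inf, degenerate=True,
        )
    x = int(t[0, 0])
    k, lw = _support_logweights(r1, r2, c1)
    if method is TestMethod.MINLIKE:
        p = _p_minlike(0.0, x, k, lw)
    else:
        p = _p_central(0.0, x, k, lw)
    p = min(1.0, p)
    cm = _cmle(x, k, lw)
    if compute_ci:
        if method is TestMethod.MINLIKE:
            lo, hi = _ci_minlike(x, k, lw, alpha, cm)
        else:
            lo, hi = _ci_central(x, k, lw, alpha)
    else:
        lo, hi = math.nan, math.nan
    return FisherResult(
        table=tbl, p_two_sided=p, method=method, or_cmle=cm,
        ci_low=lo, ci_high=hi, degenerate=False,
    )


def snp_carrier_test(
    carriers_case: int,
    carriers_control: int,
    n_case: int,
    n_control: int,
    method: TestMethod | str = TestMethod.MINLIKE,
) -> FisherResult:
    """Carrier-count association for one SNP against cohort denominators."""
    if carriers_case > n_case or carriers_control > n_control:
        raise DataError(
            f"carrier counts ({carriers_case}, {carriers_control}) exceed "
            f"cohort sizes ({n_case}, {n_control})"
        )
    if min(carriers_case, carriers_control) < 0:
        raise DataError("negative carrier count")
    table = [
        [carriers_case, n_case - carriers_case],
        [carriers_control, n_control - carriers_control],
    ]
    return fisher_exact(table, method=method)


# ---------------------------------------------------------------------------
# prevalence computations
# ---------------------------------------------------------------------------

_QUALIFYING = (VariantStatus.NOVEL, VariantStatus.RARE)


def _carrier_ids(
    data: CohortData,
    classifications: Sequence[Classification],
    genes: Iterable[str],
    group: Group,
) -> set[str]:
    """Distinct samples in *group* carrying >=1 qualifying variant in *genes*."""
    genes = set(genes)
    cols = [
        j
        for j, (v, c) in enumerate(zip(data.variants, classifications))
        if c.status in _QUALIFYING and v.gene in genes
    ]
    carriers: set[str] = set()
    if not cols:
        return carriers
    sub = data.genotypes[:, cols]
    has = (sub >= 1).any(axis=1)
    for s, h in zip(data.samples, has):
        if h and s.group is group:
            carriers.add(s.sample_id)
    return carriers


def gene_prevalence(
    data: CohortData,
    classifications: Sequence[Classification],
    gene: str,
    group: Group,
    cohort_n: Optional[int] = None,
) -> PrevalenceRow:
    """Carrier prevalence of one gene in one group (percent of cohort_n)."""
    known_genes = {v.gene for v in data.variants}
    if gene not in known_genes:
        raise DataError(f"unknown gene {gene!r}")
    if cohort_n is None:
        cohort_n = data.n_cases if group is Group.CASE else data.n_controls
    carriers = _carrier_ids(data, classifications, [gene], group)
    return PrevalenceRow(gene=gene, carriers=len(carriers), cohort_n=cohort_n)


def prevalence_total(
    data: CohortData,
    classifications: Sequence[Classification],
    genes: Iterable[str],
    group: Group,
    cohort_n: Optional[int] = None,
) -> PrevalenceRow:
    """Union prevalence over a gene list: distinct carriers of any listed gene.

    A sample carrying qualifying variants in two listed genes counts once,
    so the total is a union, never a sum of per-gene percentages.
    """
    genes = list(genes)
    if cohort_n is None:
        cohort_n = data.n_cases if group is Group.CASE else data.n_controls
    carriers = _carrier_ids(data, classifications, genes, group)
    return PrevalenceRow(gene="+".join(genes), carriers=len(carriers), cohort_n=cohort_n)


def adjust_control_count(count: float, n_cases: int, n_controls: int) -> float:
    """Rescale a control-group count to a control cohort of case-cohort size."""
    return count * n_cases / n_controls


def category_enrichment(
    data: CohortData,
    classifications: Sequence[Classification],
    panel: Sequence[PanelGene],
    subset_tag: str,
    cfg: Optional[AnalysisConfig] = None,
) -> tuple[FisherResult, dict[str, float]]:
    """Carrier enrichment of a tagged gene subset between cases and controls.

    Returns the Fisher result on the carrier x group table plus the carrier
    percentages per group.
    """
    cfg = cfg or AnalysisConfig()
    genes = [g.gene for g in panel if subset_tag in g.subsets]
    if not genes:
        raise DataError(f"no panel gene carries subset tag {subset_tag!r}")
    n_case, n_control = data.n_cases, data.n_controls
    case_carriers = len(_carrier_ids(data, classifications, genes, Group.CASE))
    control_carriers = len(_carrier_ids(data, classifications, genes, Group.CONTROL))
    fr = snp_carrier_test(
        case_carriers, control_carriers, n_case, n_control, method=cfg.test_method
    )
    pct = {
        "case_pct": round(100.0 * case_carriers / n_case, 2),
        "control_pct": round(100.0 * control_carriers / n_control, 2),
    }
    return fr, pct
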