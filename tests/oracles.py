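"""Independent brute-force oracles used by the test suite.

Everything here is derived from first principles with exact integer
arithmetic (``math.comb`` / ``fractions``), deliberately sharing no code
with the package's inference engine.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

# the engine treats point probabilities within 1e-7 relative slack as tied;
# the oracle applies the same rule exactly, in integer arithmetic
_TIE_NUM = 10**7 + 1
_TIE_DEN = 10**7


def hypergeom_weights(r1: int, r2: int, c1: int) -> tuple[list[int], list[int]]:
    """Support and integer weights of the conditional distribution."""
    lo, hi = max(0, c1 - r2), min(c1, r1)
    ks = list(range(lo, hi + 1))
    w = [comb(r1, k) * comb(r2, c1 - k) for k in ks]
    return ks, w


def two_sided_ps(r1: int, r2: int, c1: int) -> dict[int, tuple[float, float]]:
    """Exact (minlike, central) two-sided p for every possible top-left cell."""
    ks, w = hypergeom_weights(r1, r2, c1)
    total = sum(w)
    out = {}
    for i, x in enumerate(ks):
        wx = w[i]
        num = sum(wj for wj in w if wj * _TIE_DEN <= wx * _TIE_NUM)
        minlike = Fraction(num, total)
        lower = sum(w[: i + 1])
        upper = sum(w[i:])
        central = min(Fraction(1), 2 * Fraction(min(lower, upper), total))
        out[x] = (float(minlike), float(central))
    return out


def minlike_p(a: int, b: int, c: int, d: int) -> float:
    return two_sided_ps(a + b, c + d, a + c)[a][0]


def central_p(a: int, b: int, c: int, d: int) -> float:
    return two_sided_ps(a + b, c + d, a + c)[a][1]


def brute_force_classify(variants, genotypes, case_index, control_index, cfg):
    """First-principles novel/rare/shared re-derivation via set operations.

    Returns dict key -> status string for quality-passing functional
    variants supplied by the caller; mirrors the published rules, written
    independently of the package's classifier.
    """
    out = {}
    functional = {"nonsynonymous", "stopgain", "stoploss", "frameshift"}
    for j, v in enumerate(variants):
        if v.functional_class.value not in functional:
            out[v.key] = "non_functional"
            continue
        case_carriers = {i for i in case_index if genotypes[i, j] >= 1}
        control_carriers = {i for i in control_index if genotypes[i, j] >= 1}
        novel = (not v.in_dbsnp) and v.esp_freq is None and v.kg_freq is None
        if novel:
            base = "novel"
        else:
            if v.esp_freq is not None:
                rare = v.esp_freq <= cfg.rarity_cutoff
            elif v.in_dbsnp and not v.dbsnp_has_freq:
                rare = v.kg_freq is None or v.kg_freq < cfg.kg_cutoff
            else:
                rare = False
            base = "rare" if rare else "common"
        if base in ("novel", "rare") and case_carriers and control_carriers:
            out[v.key] = "excluded_shared"
        else:
            out[v.key] = base
    return out
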