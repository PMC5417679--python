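"""Fisher's exact test of association between gene lists and HERV characteristics.

For a user gene list L, a gene universe U (all symbols in the loaded
annotation) and the set K of genes bearing a queried HERV characteristic,
the 2x2 table is::

            in K     not in K
    in L      a          b
    not L     c          d

The odds ratio is (a*d)/(b*c); the p-value is Fisher's exact, computed by
hypergeometric enumeration.  Tables up to N = a+b+c+d = 2000 use exact
integer arithmetic (probabilities compared as integer numerators over the
common denominator C(N, a+c), so ties are resolved exactly and the returned
float is correct to one ulp); larger tables delegate to
``scipy.stats.fisher_exact``.

The decision rule follows common practice for this kind of screen: an
association is called when the p-value is below alpha (default 0.001) and
the odds ratio exceeds 1.  The two-sided p is the headline statistic — the
OR > 1 gate supplies the direction — with the one-sided (greater) p
available for power studies.  Benjamini-Hochberg correction is offered for
batch mode but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_OR_MIN = 1.0

#: Largest table total handled by the exact integer-arithmetic path.
EXACT_MAX_N = 2000

#: Relative tie tolerance of the float fallback (matches scipy's rule).
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # list & characteristic
    b: int  # list without characteristic
    c: int  # non-list & characteristic
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    query: str
    list_name: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float  # two-sided
    p_greater: float  # one-sided, enrichment direction
    significant: bool
    continuity_corrected: bool
    hits: tuple  # gene symbols in cell a
    p_adjusted: float | None = None
    direction: str = "up"
    n_dropped: int = 0  # list symbols outside the universe


# ---------------------------------------------------------------------------
# exact Fisher p-value

@lru_cache(maxsize=200_000)
def _margin_stats(n: int, r: int, c: int):
    """Cached per-margin enumeration for the exact path.

    Returns (lo, numerators, sorted numerators, prefix sums of sorted
    numerators, suffix sums in support order, denominator C(n, c)) where
    numerators[i] = C(r, lo+i) * C(n-r, c-lo-i).
    """
    lo = max(0, r + c - n)
    hi = min(r, c)
    num = math.comb(r, lo) * math.comb(n - r, c - lo)
    nums = [num]
    for a in range(lo, hi):
        num = num * (r - a) * (c - a) // ((a + 1) * (n - r - c + a + 1))
        nums.append(num)
    order = sorted(range(len(nums)), key=nums.__getitem__)
    sorted_nums = [nums[i] for i in order]
    prefix = []
    acc = 0
    for v in sorted_nums:
        acc += v
        prefix.append(acc)
    suffix = []
    acc = 0
    for v in reversed(nums):
        acc += v
        suffix.append(acc)
    suffix.reverse()
    return lo, tuple(nums), tuple(sorted_nums), tuple(prefix), tuple(suffix), math.comb(n, c)


def _exact_pvalues(table: ContingencyTable) -> tuple[float, float]:
    import bisect

    n, r, c = table.n, table.a + table.b, table.a + table.c
    lo, nums, sorted_nums, prefix, suffix, denom = _margin_stats(n, r, c)
    i = table.a - lo
    obs = nums[i]
    # two-sided: total probability of tables as or less likely than observed
    j = bisect.bisect_right(sorted_nums, obs)
    two = prefix[j - 1] if j else 0
    greater = suffix[i]
    return _ratio(two, denom), _ratio(greater, denom)


def _ratio(num: int, denom: int) -> float:
    """Correctly rounded float of a (possibly huge) integer ratio."""
    if num >= denom:
        return 1.0
    from fractions import Fraction

    return float(Fraction(num, denom))


def fisher_pvalue(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for one table.

    ``alternative`` is "two-sided" (probability mass of all tables with the
    same margins whose probability does not exceed the observed table's) or
    "greater" (upper tail on cell a).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if table.n <= EXACT_MAX_N:
        two, greater = _exact_pvalues(table)
        return two if alternative == "two-sided" else greater
    from scipy.stats import fisher_exact

    return float(
        fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative=alternative
        ).pvalue
    )


def odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """(a*d)/(b*c); Haldane-Anscombe +0.5 on every cell when any cell is 0.

    Returns (odds ratio, continuity-correction flag).  Raw counts are kept
    on the result object, so the uncorrected table is never lost.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


# ---------------------------------------------------------------------------
# enrichment

def _normalize(symbols: Iterable[str]) -> set[str]:
    return {s.upper() for s in symbols if s.strip()}


def fisher_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    characteristic_set: Iterable[str],
    list_name: str = "list",
    query: str = "characteristic",
    direction: str = "up",
) -> EnrichmentResult:
    """Test a gene list for enrichment of a characteristic within a universe.

    Symbols are uppercased; list symbols outside the universe are dropped
    with a logged count.  Raises on an empty universe or an empty list
    after normalisation.
    """
    uni = _normalize(universe)
    if not uni:
        raise ValueError("empty gene universe")
    raw_list = _normalize(gene_list)
    lst = raw_list & uni
    dropped = len(raw_list) - len(lst)
    if dropped:
        log.info("%s: %d list symbol(s) outside the universe dropped", list_name, dropped)
    if not lst:
        raise ValueError(f"gene list {list_name!r} empty after normalisation")
    charset = _normalize(characteristic_set) & uni

    a_set = lst & charset
    table = ContingencyTable(
        a=len(a_set),
        b=len(lst) - len(a_set),
        c=len(charset) - len(a_set),
        d=len(uni) - len(lst) - len(charset) + len(a_set),
    )
    or_, corrected = odds_ratio(table)
    p_two = fisher_pvalue(table, "two-sided")
    p_greater = fisher_pvalue(table, "greater")
    return EnrichmentResult(
        query=query,
        list_name=list_name,
        table=table,
        odds_ratio=or_,
        p_value=p_two,
        p_greater=p_greater,
        significant=(p_two < DEFAULT_ALPHA and or_ > DEFAULT_OR_MIN),
        continuity_corrected=corrected,
        hits=tuple(sorted(a_set)),
        direction=direction,
        n_dropped=dropped,
    )


class HervProfile:
    """A neighbor profile queryable for characteristic gene sets.

    Wraps the defragmented elements, the (element, isoform) neighbor
    records and the gene universe (all symbols of the loaded annotation,
    overridable with a custom universe list).
    """

    def __init__(self, elements, records, genes=None, universe=None):
        from .neighbor_map import genes_with_characteristic

        self.elements = list(elements)
        self.records = list(records)
        if universe is not None:
            self.universe = sorted(_normalize(universe))
        elif genes is not None:
            self.universe = sorted(_normalize(g.symbol for g in genes))
        else:
            self.universe = sorted(_normalize(r.symbol for r in self.records))
        self._gwc = genes_with_characteristic

    def characteristic_set(self, query) -> set[str]:
        return _normalize(self._gwc(self.records, self.elements, query))


def batch_enrichment(
    gene_lists: Mapping[str, Sequence[str]],
    queries: Sequence,
    profile: HervProfile,
    directions: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """One result per (list, query), list-major order, deterministic.

    ``queries`` holds :class:`~hervkit.neighbor_map.CharacteristicQuery`
    objects; ``directions`` optionally tags lists "up"/"down" (the sign
    used by :func:`results_matrix`).
    """
    if not gene_lists or not queries:
        raise ValueError("need >= 1 gene list and >= 1 query")
    results = []
    charsets = [(q, profile.characteristic_set(q)) for q in queries]
    for list_name, genes in gene_lists.items():
        direction = (directions or {}).get(list_name, "up")
        for q, charset in charsets:
            results.append(
                fisher_enrichment(
                    genes,
                    profile.universe,
                    charset,
                    list_name=list_name,
                    query=q.label(),
                    direction=direction,
                )
            )
    return results


def results_matrix(results: Sequence[EnrichmentResult]):
    """-log10(p) matrix (lists x queries), signed by the list's direction
    tag: positive for up-regulated lists, negative for down-regulated."""
    import pandas as pd

    rows: dict[str, dict[str, float]] = {}
    for r in results:
        sign = -1.0 if r.direction == "down" else 1.0
        val = sign * (-math.log10(r.p_value) if r.p_value > 0 else math.inf)
        rows.setdefault(r.list_name, {})[r.query] = val
    return pd.DataFrame(rows).T


def apply_significance(
    results: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    or_min: float = DEFAULT_OR_MIN,
    correction: str = "none",
) -> list[EnrichmentResult]:
    """Re-flag results under a significance rule.

    Default: raw p < alpha AND odds ratio > or_min (no correction).  With
    ``correction="benjamini_hochberg"`` the BH-adjusted p (across the whole
    batch) is compared as adjusted <= alpha instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "none":
        return [
            replace(r, significant=(r.p_value < alpha and r.odds_ratio > or_min), p_adjusted=None)
            for r in results
        ]
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        replace(r, significant=(pa <= alpha and r.odds_ratio > or_min), p_adjusted=float(pa))
        for r, pa in zip(results, p_adj)
    ]


def write_results(results: Sequence[EnrichmentResult], stream) -> None:
    from .rmsk_io import _open_text

    out, needs_close = _open_text(stream, "wt")
    try:
        out.write(
            "list\tquery\tdirection\ta\tb\tc\td\toddsRatio\tpValue\tpGreater\t"
            "pAdjusted\tsignificant\tcontinuityCorrected\thits\n"
        )
        for r in results:
            t = r.table
            out.write(
                "\t".join(
                    [
                        r.list_name, r.query, r.direction,
                        str(t.a), str(t.b), str(t.c), str(t.d),
                        f"{r.odds_ratio:.6g}", f"{r.p_value:.6g}", f"{r.p_greater:.6g}",
                        "NA" if r.p_adjusted is None else f"{r.p_adjusted:.6g}",
                        str(int(r.significant)), str(int(r.continuity_corrected)),
                        ",".join(r.hits),
                    ]
                )
                + "\n"
            )
    finally:
        if needs_close:
            out.close()
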