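"""Join RepeatMasker fragments into HERV elements and classify their structure.

A full-length provirus has the structure 5'-LTR1-Internal-LTR2-3'.
RepeatMasker reports it as several fragments because insertions and
deletions interrupt the alignment, so the annotation must be
*defragmented*: fragments close together on the same strand that belong to
the same HERV family (an LTR model and its internal partner, or pieces of
one model) are chained back into a single element.

The chaining rule is deterministic and greedy.  Within each
(chromosome, strand, family) stream, fragments sorted by start are joined
whenever the genomic gap to the running chain end is at most
``max_distance`` and, when consecutive fragments match the same consensus
model, their consensus intervals are colinear with the genomic order
(strand-aware, non-strict, so the two identical LTRs of a complete element
are not rejected).  Fragments of *other* families interleaved inside a gap
live in their own stream and neither join nor break the chain — this
nested-insertion tolerance is the main reason defragmentation exists.

Each element then gets:

* components: runs of adjacent fragments of the same model, merged;
* an intactness ratio per component — the fraction of the consensus model
  covered by the union of matched consensus intervals — plus a
  length-weighted aggregate;
* one of five truncation labels read strand-aware from the component roles:
  complete, 5'-truncated, 3'-truncated, both-truncated, or solo LTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .rmsk_io import RepeatFragment, _chrom_sort_key
from .taxonomy import Taxonomy, load_taxonomy

#: Default join window, in bp.
DEFAULT_MAX_DISTANCE = 500

TRUNCATION_TYPES = (
    "complete",
    "five_prime_truncated",
    "three_prime_truncated",
    "both_truncated",
    "solo_ltr",
)


@dataclass(frozen=True)
class ComponentMatch:
    """A merged run of fragments matching one repeat model."""

    role: str  # "ltr" | "internal"
    rep_name: str
    start: int
    end: int
    consensus_intervals: tuple  # union of 1-based inclusive (start, end); () if absent
    consensus_length: int | None
    fragments: int

    @property
    def consensus_span(self) -> tuple | None:
        if not self.consensus_intervals:
            return None
        return (self.consensus_intervals[0][0], self.consensus_intervals[-1][1])


@dataclass(frozen=True)
class HERVElement:
    """A defragmented element: ordered components plus classification."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    group: str
    superfamily: str
    components: tuple  # ComponentMatch, genomic order
    n_fragments: int
    truncation: str
    intactness: float | None  # length-weighted mean of component ratios

    @property
    def component_intactness(self) -> tuple:
        return tuple(intactness_ratio(c) for c in self.components)


@dataclass(frozen=True)
class SweepRow:
    max_distance: int
    n_defragmented: int  # elements merged from >1 fragment
    n_non_defragmented: int  # single-fragment elements
    n_total: int
    coverage: float  # n_defragmented / max n_defragmented over the sweep


def _union_intervals(intervals: Iterable[tuple]) -> tuple:
    """Union of 1-based inclusive intervals, sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def intactness_ratio(component: ComponentMatch) -> float | None:
    """Fraction of the consensus model covered by the matched intervals.

    Merged fragments union their consensus intervals before measuring, so
    overlapping pieces are not double counted.  Returns None when consensus
    data are absent; such components are excluded from element aggregates.
    """
    if component.consensus_length is None or not component.consensus_intervals:
        return None
    if component.consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    covered = sum(e - s + 1 for s, e in component.consensus_intervals)
    return min(1.0, covered / component.consensus_length)


def _colinear(prev: RepeatFragment, frag: RepeatFragment) -> bool:
    """Advisory strand-aware consensus colinearity between consecutive
    fragments of the same model; skipped when either lacks consensus data.

    Non-strict, so the 5' and 3' LTRs of one element (which cover the same
    consensus span) are allowed to chain.
    """
    if prev.rep_name != frag.rep_name:
        return True
    a, b = prev.consensus_start, frag.consensus_start
    if a is None or b is None:
        return True
    return b >= a if frag.strand == "+" else b <= a


def _joins(prev: RepeatFragment, frag: RepeatFragment, chain_end: int, max_distance: int) -> bool:
    gap = frag.start - chain_end
    return gap <= max_distance and _colinear(prev, frag)


def _build_components(chain: Sequence[RepeatFragment], taxonomy: Taxonomy) -> tuple:
    components: list[ComponentMatch] = []
    run: list[RepeatFragment] = []

    def flush():
        if not run:
            return
        name = run[0].rep_name
        cons = [
            (f.consensus_start, f.consensus_end)
            for f in run
            if f.consensus_start is not None
        ]
        lengths = [f.consensus_length for f in run if f.consensus_length is not None]
        components.append(
            ComponentMatch(
                role=taxonomy.role_of(name),
                rep_name=name,
                start=min(f.start for f in run),
                end=max(f.end for f in run),
                consensus_intervals=_union_intervals(cons) if cons else (),
                consensus_length=max(lengths) if lengths else None,
                fragments=len(run),
            )
        )
        run.clear()

    for f in chain:
        if run and f.rep_name != run[-1].rep_name:
            flush()
        run.append(f)
    flush()
    return tuple(components)


def classify_truncation(element_or_components, taxonomy: Taxonomy | None = None, strand: str = "+") -> str:
    """Label an element's truncation pattern from its component roles.

    The component list is read in element (5'->3') orientation: genomic
    order for plus-strand elements, reversed for minus-strand.  Rules:
    no internal component -> solo LTR (also when two LTRs merged with no
    internal sequence left between them); internal flanked by LTRs on both
    sides -> complete; LTR only 3' of the internal -> 5'-truncated; LTR
    only 5' -> 3'-truncated; no LTR at all -> both-truncated.
    """
    if isinstance(element_or_components, HERVElement):
        components = element_or_components.components
        strand = element_or_components.strand
    else:
        components = tuple(element_or_components)
    roles = [c.role for c in components]
    if strand == "-":
        roles = roles[::-1]
    internal_idx = [i for i, r in enumerate(roles) if r == "internal"]
    if not internal_idx:
        return "solo_ltr"
    has_5 = any(r == "ltr" for r in roles[: internal_idx[0]])
    has_3 = any(r == "ltr" for r in roles[internal_idx[-1] + 1 :])
    if has_5 and has_3:
        return "complete"
    if has_3:
        return "five_prime_truncated"
    if has_5:
        return "three_prime_truncated"
    return "both_truncated"


def _aggregate_intactness(components: Sequence[ComponentMatch]) -> float | None:
    num = den = 0.0
    for c in components:
        r = intactness_ratio(c)
        if r is None:
            continue
        w = c.end - c.start
        num += r * w
        den += w
    return num / den if den else None


def _element_identity(chain: Sequence[RepeatFragment], taxonomy: Taxonomy):
    """(family, group, superfamily) for a chain. Group prefers the LTR name."""
    family = taxonomy.family_of(chain[0].rep_name)
    ltr = next((f for f in chain if taxonomy.role_of(f.rep_name) == "ltr"), None)
    group = taxonomy.canonical_group((ltr or chain[0]).rep_name)
    superfamily = "Unclassified"
    for f in chain:
        sf = taxonomy.superfamily_of(f.rep_name)
        if sf == "Unclassified":
            from .taxonomy import classify_superfamily

            sf = classify_superfamily(f.rep_class, f.rep_family)
        if sf != "Unclassified":
            superfamily = sf
            break
    return family, group, superfamily


def defragment(
    fragments: Iterable[RepeatFragment],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    taxonomy: Taxonomy | None = None,
) -> list[HERVElement]:
    """Chain HERV fragments into elements; every fragment lands in exactly
    one element.

    Ties in the per-stream sort break by lower start, then longer fragment,
    then input order, making the output a pure function of the input.
    Elements are returned sorted by (chrom, start, end) with sequential ids.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if taxonomy is None:
        taxonomy = load_taxonomy()

    streams: dict[tuple, list] = {}
    for idx, f in enumerate(fragments):
        key = (f.chrom, f.strand, taxonomy.family_of(f.rep_name))
        streams.setdefault(key, []).append((f.start, -(f.end - f.start), idx, f))

    chains: list[list[RepeatFragment]] = []
    for key in streams:
        stream = sorted(streams[key])
        chain: list[RepeatFragment] = []
        chain_end = None
        for _, _, _, f in stream:
            if chain and _joins(chain[-1], f, chain_end, max_distance):
                chain.append(f)
                chain_end = max(chain_end, f.end)
            else:
                if chain:
                    chains.append(chain)
                chain = [f]
                chain_end = f.end
        if chain:
            chains.append(chain)

    elements = []
    for chain in chains:
        family, group, superfamily = _element_identity(chain, taxonomy)
        components = _build_components(chain, taxonomy)
        strand = chain[0].strand
        elements.append(
            HERVElement(
                element_id="",
                chrom=chain[0].chrom,
                start=min(f.start for f in chain),
                end=max(f.end for f in chain),
                strand=strand,
                family=family,
                group=group,
                superfamily=superfamily,
                components=components,
                n_fragments=len(chain),
                truncation=classify_truncation(components, taxonomy, strand),
                intactness=_aggregate_intactness(components),
            )
        )
    elements.sort(key=lambda e: (_chrom_sort_key(e.chrom), e.start, e.end, e.strand, e.family))
    return [
        replace(e, element_id=f"E{i:06d}") for i, e in enumerate(elements, start=1)
    ]


def sweep_distance(
    fragments: Iterable[RepeatFragment],
    distances: Sequence[int],
    taxonomy: Taxonomy | None = None,
) -> list[SweepRow]:
    """Run the defragmentation at each distance and tabulate the outcome.

    Coverage is each distance's defragmented-element count normalised by the
    maximum count observed across the sweep (1.0 at the optimum).
    """
    if not distances:
        raise ValueError("distances must be non-empty")
    if taxonomy is None:
        taxonomy = load_taxonomy()
    fragments = list(fragments)
    raw = []
    for d in distances:
        elements = defragment(fragments, d, taxonomy)
        n_def = sum(1 for e in elements if e.n_fragments > 1)
        raw.append((d, n_def, len(elements) - n_def))
    max_def = max(n for _, n, _ in raw)
    return [
        SweepRow(
            max_distance=d,
            n_defragmented=n_def,
            n_non_defragmented=n_non,
            n_total=n_def + n_non,
            coverage=(n_def / max_def) if max_def else 0.0,
        )
        for d, n_def, n_non in raw
    ]
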