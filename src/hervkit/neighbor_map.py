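"""Relate HERV elements to gene isoforms.

An element is *intragenic* for an isoform when it overlaps the transcript
span — sub-classified exonic (intersects any exon), intronic (wholly inside
the span with no exon intersection) or boundary (straddles a transcript
edge without touching an exon) — and *intergenic* when it lies within a
distance window upstream of the transcription start site or downstream of
the transcription termination site (windows measured in the gene's
orientation, default 100,000 bp each side).  Orientation is *sense* when
element and gene strands agree, *antisense* otherwise.

One record is emitted per qualifying (element, isoform) pair; an element
near several isoforms or genes yields several records — there is no
nearest-gene exclusivity, matching how per-gene HERV content is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .defragment import HERVElement, TRUNCATION_TYPES
from .rmsk_io import GeneModel

log = logging.getLogger(__name__)

MAX_WINDOW = 100_000
RELATIONS = ("upstream", "downstream", "exonic", "intronic", "boundary")
INTRAGENIC_RELATIONS = frozenset(["exonic", "intronic", "boundary"])


@dataclass(frozen=True)
class NeighborRecord:
    element_id: str
    isoform_id: str
    symbol: str
    relation: str
    distance: int  # bp; 0 when overlapping
    orientation: str  # "sense" | "antisense"


def _classify_overlap(element: HERVElement, gene: GeneModel) -> str:
    if any(element.start < e and s < element.end for s, e in gene.exons):
        return "exonic"
    if gene.tx_start <= element.start and element.end <= gene.tx_end:
        return "intronic"
    return "boundary"


def map_neighbors(
    elements: Iterable[HERVElement],
    genes: Sequence[GeneModel],
    window_up: int = MAX_WINDOW,
    window_down: int = MAX_WINDOW,
) -> list[NeighborRecord]:
    """One record per (element, isoform) pair in contact or proximity.

    ``window_up``/``window_down`` bound the intergenic search upstream of
    the TSS and downstream of the TTS respectively, in the gene's
    orientation; both must lie in [0, 100,000].
    """
    for name, w in (("window_up", window_up), ("window_down", window_down)):
        if not 0 <= w <= MAX_WINDOW:
            raise ValueError(f"{name} must be in [0, {MAX_WINDOW}], got {w}")

    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        left = window_up if g.strand == "+" else window_down
        right = window_down if g.strand == "+" else window_up
        # +1 so that elements at distance exactly == window still hit the
        # tree; the explicit distance filter below draws the real boundary.
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.tx_start - left - 1, g.tx_end + right + 1, gi
        )

    records = []
    for e in elements:
        tree = trees.get(e.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(e.start, e.end):
            g = genes[hit.data]
            if e.start < g.tx_end and g.tx_start < e.end:
                relation = _classify_overlap(e, g)
                distance = 0
            elif e.end <= g.tx_start:
                distance = g.tx_start - e.end
                relation = "upstream" if g.strand == "+" else "downstream"
            else:
                distance = e.start - g.tx_end
                relation = "downstream" if g.strand == "+" else "upstream"
            if relation == "upstream" and distance > window_up:
                continue
            if relation == "downstream" and distance > window_down:
                continue
            records.append(
                NeighborRecord(
                    element_id=e.element_id,
                    isoform_id=g.isoform_id,
                    symbol=g.symbol,
                    relation=relation,
                    distance=distance,
                    orientation="sense" if e.strand == g.strand else "antisense",
                )
            )
    records.sort(key=lambda r: (r.element_id, r.isoform_id, r.relation))
    return records


def profile_summary(records: Sequence[NeighborRecord], elements: Sequence[HERVElement]) -> dict:
    """Summary statistics of the element/gene integration.

    Location counts are reported both per record (one per (element,
    isoform) pair) and per distinct element, since an element may relate
    differently to different isoforms.
    """
    by_id = {e.element_id: e for e in elements}
    with_neighbor = {r.element_id for r in records}
    isoforms = {r.isoform_id for r in records}
    n_elements = len(elements)

    def records_with(pred):
        return sum(1 for r in records if pred(r))

    def elements_with(pred):
        return len({r.element_id for r in records if pred(r)})

    summary = {
        "n_elements": n_elements,
        "n_records": len(records),
        "n_elements_with_neighbor": len(with_neighbor),
        "pct_elements_with_neighbor": 100.0 * len(with_neighbor) / n_elements if n_elements else 0.0,
        "n_isoforms_with_element": len(isoforms),
        "sense_records": records_with(lambda r: r.orientation == "sense"),
        "antisense_records": records_with(lambda r: r.orientation == "antisense"),
        "upstream_records": records_with(lambda r: r.relation == "upstream"),
        "downstream_records": records_with(lambda r: r.relation == "downstream"),
        "intragenic_records": records_with(lambda r: r.relation in INTRAGENIC_RELATIONS),
        "upstream_elements": elements_with(lambda r: r.relation == "upstream"),
        "downstream_elements": elements_with(lambda r: r.relation == "downstream"),
        "intragenic_elements": elements_with(lambda r: r.relation in INTRAGENIC_RELATIONS),
    }
    for t in TRUNCATION_TYPES:
        summary[f"neighboring_{t}"] = sum(
            1
            for eid in with_neighbor
            if by_id.get(eid) is not None and by_id[eid].truncation == t
        )
    return summary


@dataclass(frozen=True)
class CharacteristicQuery:
    """A conjunctive filter over the seven queryable HERV characteristics.

    Unset fields are wildcards.  ``location`` is one of intragenic,
    upstream, downstream or intergenic (either side); boundary relations
    count as intragenic.  ``max_distance`` applies to intergenic records
    only, so combining it with ``location="intragenic"`` is contradictory.
    """

    superfamily: str | None = None
    family: str | None = None
    name: str | None = None
    orientation: str | None = None
    max_distance: int | None = None
    location: str | None = None
    completeness: str | None = None

    def validate(self) -> None:
        if self.location is not None and self.location not in (
            "intragenic", "upstream", "downstream", "intergenic",
        ):
            raise ValueError(f"unknown location {self.location!r}")
        if self.orientation is not None and self.orientation not in ("sense", "antisense"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.completeness is not None and self.completeness not in TRUNCATION_TYPES:
            raise ValueError(f"unknown completeness {self.completeness!r}")
        if self.max_distance is not None:
            if self.max_distance < 0:
                raise ValueError("max_distance must be >= 0")
            if self.location == "intragenic":
                raise ValueError(
                    "contradictory query: intragenic location with a distance bound"
                )

    def label(self) -> str:
        parts = [
            f"{k}={v}"
            for k, v in (
                ("superfamily", self.superfamily),
                ("family", self.family),
                ("name", self.name),
                ("orientation", self.orientation),
                ("distance", self.max_distance),
                ("location", self.location),
                ("completeness", self.completeness),
            )
            if v is not None
        ]
        return ",".join(parts) if parts else "any"

    def matches(self, record: NeighborRecord, element: HERVElement) -> bool:
        if self.superfamily is not None and element.superfamily != self.superfamily:
            return False
        if self.family is not None and element.family != self.family:
            return False
        if self.name is not None:
            if element.group != self.name and all(
                c.rep_name != self.name for c in element.components
            ):
                return False
        if self.orientation is not None and record.orientation != self.orientation:
            return False
        if self.completeness is not None and element.truncation != self.completeness:
            return False
        intragenic = record.relation in INTRAGENIC_RELATIONS
        if self.location == "intragenic" and not intragenic:
            return False
        if self.location == "intergenic" and intragenic:
            return False
        if self.location in ("upstream", "downstream") and record.relation != self.location:
            return False
        if self.max_distance is not None:
            if intragenic or record.distance > self.max_distance:
                return False
        return True


def genes_with_characteristic(
    records: Sequence[NeighborRecord],
    elements: Sequence[HERVElement],
    query: CharacteristicQuery,
) -> set[str]:
    """Gene symbols with >= 1 isoform bearing >= 1 record matching the query.

    Adding a constraint can only shrink the result (the filter is a
    conjunction over records).
    """
    query.validate()
    by_id = {e.element_id: e for e in elements}
    hits = set()
    for r in records:
        e = by_id.get(r.element_id)
        if e is not None and query.matches(r, e):
            hits.add(r.symbol)
    return hits


def write_neighbors(records: Sequence[NeighborRecord], stream) -> None:
    from .rmsk_io import _open_text

    out, needs_close = _open_text(stream, "wt")
    try:
        out.write("elementId\tisoformId\tsymbol\trelation\tdistance\torientation\n")
        for r in records:
            out.write(
                f"{r.element_id}\t{r.isoform_id}\t{r.symbol}\t{r.relation}\t{r.distance}\t{r.orientation}\n"
            )
    finally:
        if needs_close:
            out.close()


def read_neighbors(source) -> list[NeighborRecord]:
    from .rmsk_io import _iter_lines

    records = []
    for lineno, line in _iter_lines(source):
        if lineno == 1 or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise ValueError(f"malformed neighbors line {lineno}")
        records.append(
            NeighborRecord(
                element_id=cols[0], isoform_id=cols[1], symbol=cols[2],
                relation=cols[3], distance=int(cols[4]), orientation=cols[5],
            )
        )
    return records
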