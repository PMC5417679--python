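"""Readers and writers for the formats the pipeline touches.

All genomic intervals are normalised to 0-based half-open coordinates (the
UCSC table convention) at the read boundary; the 1-based inclusive
RepeatMasker ``.out`` dialect is converted on the way in and restored on the
way out.  RepeatMasker consensus coordinates are kept verbatim in the UCSC
signed encoding (the "remaining" field is negative) and exposed normalised
so that ``consensus_start < consensus_end`` for both strands.

Supported inputs: UCSC ``rmsk`` table dumps (with or without the leading
``bin`` column), classic RepeatMasker ``.out`` files, genePred transcript
tables (knownGene-style), BED12, a minimal GTF subset, 2-column
isoform->symbol cross-reference TSVs (kgXref-style), and one-symbol-per-line
gene lists.  Gzip-compressed files are accepted transparently by filename.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: "Main chromosomes": the 24 assembled human chromosomes.
MAIN_CHROMOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)

RMSK_DIALECTS = ("ucsc_table", "rm_out", "auto")


@dataclass(frozen=True)
class RepeatFragment:
    """One RepeatMasker annotation line.

    ``rep_start``/``rep_end``/``rep_left`` follow the UCSC signed encoding:
    for a plus-strand hit rep_start is the 1-based consensus begin and
    rep_left the (non-positive) remaining bases past rep_end; for a
    minus-strand hit the roles of rep_start and rep_left are exchanged.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # half-open exclusive
    strand: str  # "+" | "-"
    rep_name: str
    rep_class: str
    rep_family: str
    sw_score: int = 0
    rep_start: int = 0
    rep_end: int = 0
    rep_left: int = 0
    source_line: int = field(default=-1, compare=False)
    extras: tuple = field(default=(), compare=False)  # (milliDiv, milliDel, milliIns, genoLeft, linkId)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    # -- normalised consensus coordinates ---------------------------------
    @property
    def consensus_start(self) -> int | None:
        """1-based consensus begin, orientation-normalised; None if absent."""
        cs = self.rep_start if self.strand == "+" else self.rep_left
        return cs if cs >= 1 and self.rep_end >= cs else None

    @property
    def consensus_end(self) -> int | None:
        return self.rep_end if self.consensus_start is not None else None

    @property
    def consensus_length(self) -> int | None:
        """Full consensus model length: matched end + remaining bases."""
        if self.consensus_start is None:
            return None
        remaining = self.rep_left if self.strand == "+" else self.rep_start
        return self.rep_end + abs(remaining)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """One transcript isoform with exon structure and a gene symbol."""

    isoform_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple  # ordered ((start, end), ...), 0-based half-open

    def __post_init__(self):
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"transcript {self.isoform_id}: exon [{s},{e}) outside span "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.isoform_id}: exons unsorted or overlapping"
                )
            prev_end = e


# ---------------------------------------------------------------------------
# helpers

def _open_text(source, mode="rt"):
    """Return (stream, needs_close). Accepts paths (gzip by suffix) or streams."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    p = Path(source)
    if p.suffix == ".gz":
        return gzip.open(p, mode), True
    return open(p, mode), True


def _iter_lines(source):
    stream, needs_close = _open_text(source)
    try:
        for i, line in enumerate(stream, start=1):
            yield i, line.rstrip("\n")
    finally:
        if needs_close:
            stream.close()


# ---------------------------------------------------------------------------
# RepeatMasker annotations

def _parse_ucsc_row(cols: Sequence[str], lineno: int, has_bin: bool) -> RepeatFragment:
    off = 1 if has_bin else 0
    try:
        return RepeatFragment(
            chrom=cols[off + 4],
            start=int(cols[off + 5]),
            end=int(cols[off + 6]),
            strand=cols[off + 8],
            rep_name=cols[off + 9],
            rep_class=cols[off + 10],
            rep_family=cols[off + 11],
            sw_score=int(cols[off + 0]),
            rep_start=int(cols[off + 12]),
            rep_end=int(cols[off + 13]),
            rep_left=int(cols[off + 14]),
            source_line=lineno,
            extras=(
                int(cols[off + 1]),
                int(cols[off + 2]),
                int(cols[off + 3]),
                int(cols[off + 7]),
                int(cols[off + 15]) if len(cols) > off + 15 else 0,
            ),
        )
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed rmsk table line {lineno}: {exc}") from exc


def _strip_parens(tok: str) -> tuple[int, bool]:
    if tok.startswith("(") and tok.endswith(")"):
        return int(tok[1:-1]), True
    return int(tok), False


def _parse_out_row(cols: Sequence[str], lineno: int) -> RepeatFragment:
    # score div del ins query qbegin qend (qleft) strand name class/family
    # and position-in-repeat columns: + strand: begin end (left)
    #                                 C strand: (left) end begin
    try:
        strand_sym = cols[8]
        strand = "-" if strand_sym in ("C", "-") else "+"
        cls_fam = cols[10]
        rep_class, _, rep_family = cls_fam.partition("/")
        p1, _ = _strip_parens(cols[11])
        p2, _ = _strip_parens(cols[12])
        p3, _ = _strip_parens(cols[13])
        if strand == "+":
            rep_start, rep_end, rep_left = p1, p2, -p3
        else:
            rep_start, rep_end, rep_left = -p1, p2, p3
        geno_left, _ = _strip_parens(cols[7])
        return RepeatFragment(
            chrom=cols[4],
            start=int(cols[5]) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(cols[6]),
            strand=strand,
            rep_name=cols[9],
            rep_class=rep_class,
            rep_family=rep_family,
            sw_score=int(cols[0]),
            rep_start=rep_start,
            rep_end=rep_end,
            rep_left=rep_left,
            source_line=lineno,
            extras=(
                int(round(float(cols[1]) * 10)),
                int(round(float(cols[2]) * 10)),
                int(round(float(cols[3]) * 10)),
                -geno_left,
                int(cols[14]) if len(cols) > 14 else 0,
            ),
        )
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed RepeatMasker .out line {lineno}: {exc}") from exc


def _looks_like_out_header(line: str) -> bool:
    s = line.strip()
    return s.startswith(("SW", "score", "There were no")) or not s


def read_rmsk(
    source,
    dialect: str = "auto",
    chrom_allowlist: Iterable[str] | None = MAIN_CHROMOSOMES,
) -> list[RepeatFragment]:
    """Read RepeatMasker annotations into :class:`RepeatFragment` records.

    Parameters
    ----------
    source : path or text stream
    dialect : "ucsc_table", "rm_out" or "auto"
        ``auto`` sniffs: ``.out`` headers/whitespace separation vs. a TSV.
    chrom_allowlist : iterable of chromosome names or None
        Records on other chromosomes are dropped.  Pass ``None`` or an
        empty iterable to keep everything (haplotype/unplaced contigs).
    """
    if dialect not in RMSK_DIALECTS:
        raise ValueError(f"unknown rmsk dialect {dialect!r}; expected one of {RMSK_DIALECTS}")
    allow = frozenset(chrom_allowlist) if chrom_allowlist else None

    fragments: list[RepeatFragment] = []
    for lineno, line in _iter_lines(source):
        if not line.strip():
            continue
        if dialect == "auto":
            if _looks_like_out_header(line):
                dialect = "rm_out"
                continue
            dialect = "rm_out" if ("\t" not in line and len(line.split()) >= 14) else "ucsc_table"
        if dialect == "rm_out":
            if _looks_like_out_header(line):
                continue
            frag = _parse_out_row(line.split(), lineno)
        else:
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            has_bin = len(cols) >= 17
            frag = _parse_ucsc_row(cols, lineno, has_bin)
        if allow is not None and frag.chrom not in allow:
            continue
        fragments.append(frag)
    return fragments


def write_rmsk(fragments: Iterable[RepeatFragment], stream, dialect: str = "ucsc_table") -> None:
    """Serialise fragments back to an rmsk dialect (inverse of :func:`read_rmsk`)."""
    out, needs_close = _open_text(stream, "wt")
    try:
        for f in fragments:
            ex = f.extras if len(f.extras) == 5 else (0, 0, 0, 0, 0)
            if dialect == "ucsc_table":
                out.write(
                    "\t".join(
                        str(x)
                        for x in (
                            f.sw_score, ex[0], ex[1], ex[2], f.chrom, f.start, f.end,
                            ex[3], f.strand, f.rep_name, f.rep_class, f.rep_family,
                            f.rep_start, f.rep_end, f.rep_left, ex[4],
                        )
                    )
                    + "\n"
                )
            elif dialect == "rm_out":
                cls_fam = f.rep_class if not f.rep_family else f"{f.rep_class}/{f.rep_family}"
                if f.strand == "+":
                    pos = (str(f.rep_start), str(f.rep_end), f"({-f.rep_left})")
                    strand_sym = "+"
                else:
                    pos = (f"({-f.rep_start})", str(f.rep_end), str(f.rep_left))
                    strand_sym = "C"
                out.write(
                    " ".join(
                        str(x)
                        for x in (
                            f.sw_score, ex[0] / 10, ex[1] / 10, ex[2] / 10,
                            f.chrom, f.start + 1, f.end, f"({-ex[3]})",
                            strand_sym, f.rep_name, cls_fam, *pos, ex[4],
                        )
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown rmsk dialect {dialect!r}")
    finally:
        if needs_close:
            out.close()


def is_ltr_class(rep_class: str) -> bool:
    """LTR retroelement classes: "LTR", "LTR?" and any "LTR/..." subclass."""
    return rep_class == "LTR" or rep_class.startswith(("LTR/", "LTR?"))


def filter_herv(fragments: Iterable[RepeatFragment], taxonomy=None) -> list[RepeatFragment]:
    """Retain exactly the LTR-retroelement (HERV) fragments, order preserved.

    Idempotent; the optional taxonomy argument is accepted for interface
    symmetry but classification is by rmsk repClass alone.
    """
    return [f for f in fragments if is_ltr_class(f.rep_class)]


# ---------------------------------------------------------------------------
# gene models

def read_xref(source) -> dict[str, str]:
    """2-column isoform -> symbol TSV (kgXref-style; extra columns ignored)."""
    xref: dict[str, str] = {}
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValueError(f"malformed xref line {lineno}: need >= 2 columns")
        xref[cols[0]] = cols[1]
    return xref


def read_gene_list(source) -> list[str]:
    """One symbol per line; blank lines and # comments ignored."""
    symbols = []
    for _, line in _iter_lines(source):
        s = line.strip()
        if s and not s.startswith("#"):
            symbols.append(s)
    return symbols


def _gene_from_genepred(cols, lineno, xref):
    if len(cols) < 10:
        raise ValueError(f"malformed genePred line {lineno}: {len(cols)} columns")
    name = cols[0]
    starts = [int(x) for x in cols[8].split(",") if x]
    ends = [int(x) for x in cols[9].split(",") if x]
    if len(starts) != len(ends) or len(starts) != int(cols[7]):
        raise ValueError(f"transcript {name}: exon count mismatch on line {lineno}")
    return GeneModel(
        isoform_id=name,
        symbol=(xref or {}).get(name, name),
        chrom=cols[1],
        strand=cols[2],
        tx_start=int(cols[3]),
        tx_end=int(cols[4]),
        exons=tuple(zip(starts, ends)),
    )


def _gene_from_bed12(cols, lineno, xref):
    if len(cols) < 12:
        raise ValueError(f"malformed BED12 line {lineno}: {len(cols)} columns")
    name = cols[3]
    start = int(cols[1])
    sizes = [int(x) for x in cols[10].split(",") if x]
    offsets = [int(x) for x in cols[11].split(",") if x]
    if len(sizes) != len(offsets) or len(sizes) != int(cols[9]):
        raise ValueError(f"transcript {name}: block count mismatch on line {lineno}")
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return GeneModel(
        isoform_id=name,
        symbol=(xref or {}).get(name, name),
        chrom=cols[0],
        strand=cols[5],
        tx_start=start,
        tx_end=int(cols[2]),
        exons=exons,
    )


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _genes_from_gtf(source, xref):
    exons: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    declared: set[str] = set()
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ValueError(f"malformed GTF line {lineno}")
        feature = cols[2]
        attrs = _parse_gtf_attrs(cols[8])
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        if feature == "transcript":
            declared.add(tid)
            meta.setdefault(tid, (cols[0], cols[6], attrs.get("gene_name", attrs.get("gene_id", tid))))
        elif feature == "exon":
            meta.setdefault(tid, (cols[0], cols[6], attrs.get("gene_name", attrs.get("gene_id", tid))))
            exons.setdefault(tid, []).append((int(cols[3]) - 1, int(cols[4])))
    missing = declared - set(exons)
    if missing:
        raise ValueError(f"GTF transcript(s) lacking exon lines: {sorted(missing)}")
    genes = []
    for tid, (chrom, strand, symbol) in meta.items():
        ex = tuple(sorted(exons[tid]))
        genes.append(
            GeneModel(
                isoform_id=tid,
                symbol=(xref or {}).get(tid, symbol),
                chrom=chrom,
                strand=strand,
                tx_start=ex[0][0],
                tx_end=ex[-1][1],
                exons=ex,
            )
        )
    return genes


def read_genes(source, format: str = "genepred", xref: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Read transcript models; one :class:`GeneModel` per isoform.

    Symbols resolve through ``xref`` when given, else symbol = isoform id.
    Duplicate isoform ids: last record wins with a logged warning.
    """
    if format not in ("genepred", "bed12", "gtf"):
        raise ValueError(f"unknown gene format {format!r}")
    if format == "gtf":
        genes = _genes_from_gtf(source, xref)
    else:
        parse = _gene_from_genepred if format == "genepred" else _gene_from_bed12
        genes = []
        for lineno, line in _iter_lines(source):
            if not line.strip() or line.startswith("#"):
                continue
            genes.append(parse(line.split("\t"), lineno, xref))
    by_id: dict[str, GeneModel] = {}
    for g in genes:
        if g.isoform_id in by_id:
            log.warning("duplicate isoform id %s: keeping last record", g.isoform_id)
        by_id[g.isoform_id] = g
    return list(by_id.values())


# ---------------------------------------------------------------------------
# element tables (written by defragment, read back for annotate/enrich)

_ELEMENT_COLUMNS = [
    "elementId", "chrom", "start", "end", "strand", "family", "group",
    "superfamily", "truncation", "nFragments", "intactness", "components",
]


def _encode_component(c) -> str:
    if c.consensus_length is None:
        cons, clen = ".", "."
    else:
        cons = ",".join(f"{s}-{e}" for s, e in c.consensus_intervals)
        clen = str(c.consensus_length)
    return "|".join([c.role, c.rep_name, str(c.start), str(c.end), cons, clen, str(c.fragments)])


def _decode_component(text: str):
    from .defragment import ComponentMatch

    role, rep_name, start, end, cons, clen, nfrag = text.split("|")
    if cons == ".":
        intervals: tuple = ()
        length = None
    else:
        intervals = tuple(
            tuple(int(x) for x in part.split("-")) for part in cons.split(",")
        )
        length = int(clen)
    return ComponentMatch(
        role=role,
        rep_name=rep_name,
        start=int(start),
        end=int(end),
        consensus_intervals=intervals,
        consensus_length=length,
        fragments=int(nfrag),
    )


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def write_elements(elements, stream, format: str = "tsv") -> None:
    """Write an element table as TSV (lossless) or BED (0-based half-open).

    BED name field carries ``elementId|truncation``; lines sorted by
    (chrom, start).
    """
    if format not in ("tsv", "bed"):
        raise ValueError(f"unknown element format {format!r}")
    out, needs_close = _open_text(stream, "wt")
    try:
        if format == "tsv":
            out.write("\t".join(_ELEMENT_COLUMNS) + "\n")
            for e in elements:
                intact = "NA" if e.intactness is None else repr(e.intactness)
                out.write(
                    "\t".join(
                        [
                            e.element_id, e.chrom, str(e.start), str(e.end), e.strand,
                            e.family, e.group, e.superfamily, e.truncation,
                            str(e.n_fragments), intact,
                            ";".join(_encode_component(c) for c in e.components),
                        ]
                    )
                    + "\n"
                )
        else:
            for e in sorted(elements, key=lambda e: (_chrom_sort_key(e.chrom), e.start, e.end)):
                out.write(
                    "\t".join(
                        [
                            e.chrom, str(e.start), str(e.end),
                            f"{e.element_id}|{e.truncation}",
                            str(e.n_fragments), e.strand,
                        ]
                    )
                    + "\n"
                )
    finally:
        if needs_close:
            out.close()


def read_elements(source) -> list:
    """Read back a TSV element table; inverse of ``write_elements(fmt="tsv")``."""
    from .defragment import HERVElement

    elements = []
    lines = list(_iter_lines(source))
    if not lines:
        return elements
    header = lines[0][1].split("\t")
    if header != _ELEMENT_COLUMNS:
        raise ValueError(f"unexpected element table header: {header}")
    for lineno, line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_ELEMENT_COLUMNS):
            raise ValueError(f"malformed element table line {lineno}")
        comps = tuple(_decode_component(t) for t in cols[11].split(";") if t)
        elements.append(
            HERVElement(
                element_id=cols[0],
                chrom=cols[1],
                start=int(cols[2]),
                end=int(cols[3]),
                strand=cols[4],
                family=cols[5],
                group=cols[6],
                superfamily=cols[7],
                truncation=cols[8],
                n_fragments=int(cols[9]),
                intactness=None if cols[10] == "NA" else float(cols[10]),
                components=comps,
            )
        )
    return elements
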