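"""Seeded synthetic fixtures: planted proviruses, gene models and gene lists.

The generator emulates what the pipeline consumes from a genome annotation:
a UCSC-dialect rmsk fragment table derived from *planted* HERV elements
(each with a chosen family, truncation pattern, strand and fragmentation
plan), a genePred transcript table, an isoform->symbol cross-reference, and
a truth table recording exactly what was planted.  Fragment consensus
coordinates are derived from the planted model geometry — fragments carve
contiguous chunks out of the consensus while genomic gaps model inserted
sequence — so intactness ratios have exact expected values and
defragmentation at any distance >= the largest planted gap must reconstruct
every element with its exact span and truncation label.

Genes are laid out on a fixed grid with inter-gene spacing comfortably
larger than twice the neighbor-mapping window, so an element planted
relative to one host gene has a provable relation to that gene and no
accidental relation to any other.

Everything is driven by a single ``numpy.random.default_rng(seed)`` stream;
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .taxonomy import Taxonomy, load_taxonomy

#: (ltr model, ltr consensus bp, internal model, internal consensus bp)
#: Model lengths are typical for each family's consensus.
MODEL_GEOMETRY = {
    "HERVH": ("LTR7", 450, "HERVH-int", 5800),
    "HERVK10": ("LTR5_Hs", 968, "HERVK-int", 7000),
    "ERV9": ("LTR12", 1577, "HERV9-int", 6300),
    "HERV16": ("LTR16A1", 450, "HERV16-int", 4500),
    "THE1": ("THE1B", 350, "THE1-int", 1600),
    "MLT": ("MLT1D", 500, "MLT-int", 1500),
    "HERVW": ("LTR2", 590, "HERV17-int", 6900),
    "MST": ("MSTD", 420, "MST-int", 1800),
}

TRUNCATION_COMPONENTS = {
    "complete": ("ltr", "internal", "ltr"),
    "five_prime_truncated": ("internal", "ltr"),
    "three_prime_truncated": ("ltr", "internal"),
    "both_truncated": ("internal",),
    "solo_ltr": ("ltr",),
}

RELATION_CHOICES = ("intronic", "exonic", "upstream", "downstream", "intergenic_far")


@dataclass(frozen=True)
class PlantedElement:
    """Specification of one element to plant."""

    family: str = "HERVH"
    truncation: str = "solo_ltr"
    strand: str = "+"
    chrom: str | None = None  # auto-assigned round-robin when None
    pieces_per_component: int = 2
    max_gap: int = 300  # largest genomic gap inserted between fragments
    relation: str = "intergenic_far"  # relation to its host gene
    distance: int = 5_000  # planted intergenic distance (upstream/downstream)
    decoy: bool = False  # drop a fragment of another family into one gap


@dataclass(frozen=True)
class PlantSpec:
    """Whole-fixture specification."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 6_000_000}
    )
    elements: tuple = ()
    n_genes: int = 12
    exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 15_000
    gene_spacing: int = 450_000  # slot pitch; >> 2 * neighbor window
    decoy_family: str = "MLT"

    @staticmethod
    def default(n_per_type: int = 4, max_gap: int = 300, seed_families=None) -> "PlantSpec":
        """The standard 20-element fixture: n_per_type per truncation type,
        families rotated, mixed relations, nested decoys on a few elements."""
        families = list(seed_families or ("HERVH", "HERVK10", "ERV9", "HERV16"))
        elements = []
        i = 0
        for trunc in TRUNCATION_COMPONENTS:
            for k in range(n_per_type):
                elements.append(
                    PlantedElement(
                        family=families[i % len(families)],
                        truncation=trunc,
                        strand="+" if i % 2 == 0 else "-",
                        pieces_per_component=2 if trunc != "solo_ltr" else 2,
                        max_gap=max_gap,
                        relation=RELATION_CHOICES[i % len(RELATION_CHOICES)],
                        distance=2_000 + 7_000 * (i % 3),
                        decoy=(i % 5 == 0),
                    )
                )
                i += 1
        return PlantSpec(elements=tuple(elements))

    @staticmethod
    def from_yaml(source) -> "PlantSpec":
        import yaml

        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        elements = tuple(PlantedElement(**e) for e in data.get("elements", []))
        kwargs = {k: v for k, v in data.items() if k != "elements"}
        if "chrom_sizes" in kwargs:
            kwargs["chrom_sizes"] = dict(kwargs["chrom_sizes"])
        return PlantSpec(elements=elements, **kwargs)


@dataclass(frozen=True)
class TruthElement:
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    truncation: str
    n_fragments: int
    n_components: int
    max_gap_used: int
    relation: str  # planted relation to host gene ("none" for far elements)
    host_symbol: str | None
    distance: int  # planted intergenic distance; 0 for intragenic/none


@dataclass(frozen=True)
class TruthTable:
    elements: tuple  # planted TruthElement, in planting order
    decoys: tuple  # TruthElement for decoy solo fragments
    gene_symbols: tuple
    isoform_ids: tuple

    def genes_with(self, relation=None, family=None, truncation=None) -> set[str]:
        out = set()
        for e in self.elements:
            if e.host_symbol is None:
                continue
            if relation is not None and e.relation != relation:
                continue
            if family is not None and e.family != family:
                continue
            if truncation is not None and e.truncation != truncation:
                continue
            out.add(e.host_symbol)
        return out


@dataclass(frozen=True)
class SyntheticFixture:
    rmsk_text: str
    genepred_text: str
    xref_text: str
    truth: TruthTable

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "rmsk": out / "rmsk.tsv",
            "genes": out / "genes.genepred.tsv",
            "xref": out / "xref.tsv",
        }
        paths["rmsk"].write_text(self.rmsk_text)
        paths["genes"].write_text(self.genepred_text)
        paths["xref"].write_text(self.xref_text)
        return paths


# ---------------------------------------------------------------------------

def _plan_fragments(plant: PlantedElement, rng) -> tuple[list, int, int]:
    """Lay out fragments in element orientation starting at offset 0.

    Returns (fragments, total span, largest gap used); each fragment is
    (rel_start, rel_end, model, consensus_start, consensus_end, model_len).
    """
    geom = MODEL_GEOMETRY.get(plant.family)
    if geom is None:
        raise ValueError(f"no model geometry for family {plant.family!r}")
    ltr_name, ltr_len, int_name, int_len = geom
    roles = TRUNCATION_COMPONENTS[plant.truncation]

    frags = []
    pos = 0
    max_gap_used = 0
    for ci, role in enumerate(roles):
        model, mlen = (ltr_name, ltr_len) if role == "ltr" else (int_name, int_len)
        pieces = max(1, plant.pieces_per_component)
        # contiguous consensus chunks; genomic gaps model inserted sequence
        cuts = np.linspace(0, mlen, pieces + 1).astype(int)
        for pi in range(pieces):
            c0, c1 = int(cuts[pi]) + 1, int(cuts[pi + 1])
            if c1 < c0:
                continue
            if frags and not (ci == 0 and pi == 0):
                gap = int(rng.integers(50, max(51, plant.max_gap + 1)))
                gap = min(gap, plant.max_gap) if plant.max_gap >= 50 else plant.max_gap
                max_gap_used = max(max_gap_used, gap)
                pos += gap
            length = c1 - c0 + 1
            frags.append((pos, pos + length, model, c0, c1, mlen))
            pos += length
    return frags, pos, max_gap_used


def _encode_ucsc_row(chrom, start, end, strand, name, rep_class, rep_family,
                     cs, ce, mlen, sw, link_id):
    remaining = mlen - ce
    if strand == "+":
        rep_start, rep_left = cs, -remaining
    else:
        rep_start, rep_left = -remaining, cs
    return "\t".join(
        str(x)
        for x in (
            sw, 0, 0, 0, chrom, start, end, 0, strand, name,
            rep_class, rep_family, rep_start, ce, rep_left, link_id,
        )
    )


def generate_genome_fixture(spec: PlantSpec, seed: int, taxonomy: Taxonomy | None = None) -> SyntheticFixture:
    """Emit rmsk + genePred + xref text and the matching truth table.

    Raises when a planted element cannot fit its target region (intron,
    window or chromosome bounds).
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    rng = np.random.default_rng(seed)
    chroms = list(spec.chrom_sizes)

    # --- genes on a fixed grid -------------------------------------------
    gene_len = spec.exons_per_gene * spec.exon_length + (spec.exons_per_gene - 1) * spec.intron_length
    genes = []  # (isoform, symbol, chrom, strand, tx_start, tx_end, exons)
    slots: dict[str, int] = {ch: 0 for ch in chroms}
    for gi in range(spec.n_genes):
        chrom = chroms[gi % len(chroms)]
        slot = slots[chrom]
        slots[chrom] += 1
        tx_start = 150_000 + slot * spec.gene_spacing
        tx_end = tx_start + gene_len
        if tx_end + 110_000 > spec.chrom_sizes[chrom]:
            raise ValueError(f"gene {gi} does not fit on {chrom}; enlarge chrom_sizes")
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        exons = tuple(
            (
                tx_start + k * (spec.exon_length + spec.intron_length),
                tx_start + k * (spec.exon_length + spec.intron_length) + spec.exon_length,
            )
            for k in range(spec.exons_per_gene)
        )
        genes.append((f"uc{gi + 1:04d}.1", f"GENE{gi + 1:04d}", chrom, strand, tx_start, tx_end, exons))

    genes_by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        genes_by_chrom.setdefault(g[2], []).append(i)

    # --- plant elements ---------------------------------------------------
    rows = []  # (chrom, start, line fields...) for sorting
    truth_elements = []
    truth_decoys = []
    host_cursor: dict[str, int] = {ch: 0 for ch in chroms}
    used_introns: dict[int, int] = {}
    link_id = 0

    for pi, plant in enumerate(spec.elements):
        if plant.truncation not in TRUNCATION_COMPONENTS:
            raise ValueError(f"unknown truncation {plant.truncation!r}")
        chrom = plant.chrom or chroms[pi % len(chroms)]
        frags, span, max_gap_used = _plan_fragments(plant, rng)

        host = None
        relation = plant.relation
        distance = 0
        if relation == "intergenic_far":
            # mid-point between gene slots: > window from every gene
            slot = pi // len(chroms) % max(1, slots[chrom])
            anchor = 150_000 + slot * spec.gene_spacing + gene_len + 160_000
            host_sym = None
            relation = "none"
        else:
            cand = genes_by_chrom.get(chrom, [])
            if not cand:
                raise ValueError(f"no genes on {chrom} to host element {pi}")
            host = genes[cand[host_cursor[chrom] % len(cand)]]
            host_cursor[chrom] += 1
            iso, host_sym, _, gstrand, tx_start, tx_end, exons = host
            if relation == "intronic":
                which = used_introns.get(id(host), 0)
                used_introns[id(host)] = which + 1
                intron_start = exons[which % (len(exons) - 1)][1]
                intron_end = exons[which % (len(exons) - 1) + 1][0]
                if span + 400 > intron_end - intron_start:
                    raise ValueError(
                        f"element {pi} (span {span}) does not fit intron of {host_sym}"
                    )
                anchor = intron_start + 200
            elif relation == "exonic":
                # overlap the second exon's start
                anchor = exons[1][0] - min(span // 2, exons[1][0] - tx_start - 1)
            elif relation == "upstream":
                distance = plant.distance
                if gstrand == "+":
                    anchor = tx_start - distance - span
                else:
                    anchor = tx_end + distance
            elif relation == "downstream":
                distance = plant.distance
                if gstrand == "+":
                    anchor = tx_end + distance
                else:
                    anchor = tx_start - distance - span
            else:
                raise ValueError(f"unknown relation {plant.relation!r}")

        if anchor < 0 or anchor + span > spec.chrom_sizes[chrom]:
            raise ValueError(f"element {pi} exceeds {chrom} bounds")

        link_id += 1
        decoy_row = None
        gaps = []
        prev_end = None
        for rel_start, rel_end, model, c0, c1, mlen in frags:
            if prev_end is not None and rel_start > prev_end:
                gaps.append((prev_end, rel_start))
            prev_end = rel_end
        if plant.strand == "-":
            # mirror the layout so genomic order reverses element order
            frags = [
                (span - rel_end, span - rel_start, model, c0, c1, mlen)
                for rel_start, rel_end, model, c0, c1, mlen in frags
            ][::-1]
            gaps = [(span - ge, span - gs) for gs, ge in gaps][::-1]

        taxa_family = taxonomy.family_of(frags[0][2])
        for rel_start, rel_end, model, c0, c1, mlen in frags:
            taxon = taxonomy.lookup(model)
            rows.append(
                (
                    chrom,
                    anchor + rel_start,
                    _encode_ucsc_row(
                        chrom, anchor + rel_start, anchor + rel_end, plant.strand,
                        model, "LTR", taxon.superfamily if taxon.superfamily != "Unclassified" else "ERV1",
                        c0, c1, mlen, int(rng.integers(300, 5000)), link_id,
                    ),
                )
            )

        if plant.decoy and gaps:
            gs, ge = max(gaps, key=lambda g: g[1] - g[0])
            if ge - gs >= 120:
                dec_fam = spec.decoy_family if spec.decoy_family != plant.family else "MST"
                dl_name, dl_len, _, _ = MODEL_GEOMETRY[dec_fam]
                dstart = anchor + gs + (ge - gs - 80) // 2
                dtaxon = taxonomy.lookup(dl_name)
                link_id += 1
                rows.append(
                    (
                        chrom,
                        dstart,
                        _encode_ucsc_row(
                            chrom, dstart, dstart + 80, plant.strand, dl_name, "LTR",
                            dtaxon.superfamily, 1, 80, dl_len,
                            int(rng.integers(300, 5000)), link_id,
                        ),
                    )
                )
                truth_decoys.append(
                    TruthElement(
                        chrom=chrom, start=dstart, end=dstart + 80, strand=plant.strand,
                        family=dec_fam, truncation="solo_ltr", n_fragments=1,
                        n_components=1, max_gap_used=0, relation="decoy",
                        host_symbol=None, distance=0,
                    )
                )

        n_components = len(TRUNCATION_COMPONENTS[plant.truncation])
        truth_elements.append(
            TruthElement(
                chrom=chrom, start=anchor, end=anchor + span, strand=plant.strand,
                family=taxa_family, truncation=plant.truncation,
                n_fragments=len(frags), n_components=n_components,
                max_gap_used=max_gap_used, relation=relation,
                host_symbol=host_sym, distance=distance,
            )
        )

    rows.sort(key=lambda r: (r[0], r[1]))
    rmsk_text = "".join(line + "\n" for _, _, line in rows)

    gp_lines = []
    xref_lines = []
    for iso, sym, chrom, strand, tx_start, tx_end, exons in genes:
        starts = ",".join(str(s) for s, _ in exons) + ","
        ends = ",".join(str(e) for _, e in exons) + ","
        gp_lines.append(
            "\t".join(
                [iso, chrom, strand, str(tx_start), str(tx_end),
                 str(tx_start), str(tx_end), str(len(exons)), starts, ends]
            )
        )
        xref_lines.append(f"{iso}\t{sym}")

    return SyntheticFixture(
        rmsk_text=rmsk_text,
        genepred_text="".join(l + "\n" for l in gp_lines),
        xref_text="".join(l + "\n" for l in xref_lines),
        truth=TruthTable(
            elements=tuple(truth_elements),
            decoys=tuple(truth_decoys),
            gene_symbols=tuple(g[1] for g in genes),
            isoform_ids=tuple(g[0] for g in genes),
        ),
    )


# ---------------------------------------------------------------------------

def generate_gene_lists(
    universe: Sequence[str],
    characteristic_set: Sequence[str],
    odds_ratio: float,
    list_size: int,
    seed: int,
) -> list[str]:
    """Sample a gene list whose *expected* 2x2 table against the
    characteristic set has the planted odds ratio.

    Each gene enters the list independently with probability p1 (inside the
    characteristic set) or p0 (outside), where p1/(1-p1) = OR * p0/(1-p0)
    and m*p1 + (N-m)*p0 = list_size.  The realised list size therefore
    fluctuates around ``list_size``.
    """
    universe = list(universe)
    n_total = len(universe)
    if list_size <= 0:
        raise ValueError("list_size must be positive")
    if list_size > n_total:
        raise ValueError("list_size exceeds the universe")
    if odds_ratio < 0:
        raise ValueError("odds_ratio must be >= 0")
    charset = set(characteristic_set)
    m = sum(1 for g in universe if g in charset)

    def expected_size(p0: float) -> float:
        if odds_ratio == 0:
            p1 = 0.0
        else:
            odds0 = p0 / (1 - p0)
            p1 = odds_ratio * odds0 / (1 + odds_ratio * odds0)
        return m * p1 + (n_total - m) * p0, p1

    lo, hi = 1e-12, 1 - 1e-12
    for _ in range(200):
        mid = (lo + hi) / 2
        size, _ = expected_size(mid)
        if size < list_size:
            lo = mid
        else:
            hi = mid
    p0 = (lo + hi) / 2
    _, p1 = expected_size(p0)

    rng = np.random.default_rng(seed)
    draws = rng.random(n_total)
    return [
        g for g, u in zip(universe, draws) if u < (p1 if g in charset else p0)
    ]
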