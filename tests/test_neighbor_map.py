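"""Element-to-gene mapping: relations, distances, orientation, queries."""

from dataclasses import replace

import numpy as np
import pytest

import hervkit as hk
from hervkit.neighbor_map import INTRAGENIC_RELATIONS, CharacteristicQuery

from conftest import make_fragment, random_fragments


def element(chrom="chr1", start=0, end=450, strand="+", eid="E1",
            family="HERVH", group="LTR7", superfamily="ERV1",
            truncation="solo_ltr"):
    comp = hk.ComponentMatch("ltr", group, start, end, ((1, end - start),), end - start, 1)
    return hk.HERVElement(
        element_id=eid, chrom=chrom, start=start, end=end, strand=strand,
        family=family, group=group, superfamily=superfamily,
        components=(comp,), n_fragments=1, truncation=truncation,
        intactness=1.0,
    )


def gene(chrom="chr1", strand="+", tx_start=10_000, tx_end=20_000,
         exons=None, iso="iso1", symbol="SYM1"):
    exons = exons or ((tx_start, tx_start + 500), (tx_end - 500, tx_end))
    return hk.GeneModel(iso, symbol, chrom, strand, tx_start, tx_end, tuple(exons))


class TestMapNeighbors:
    def test_upstream_distance_arithmetic(self):
        g = gene(tx_start=10_000, tx_end=20_000)
        e = element(start=9_900, end=9_950)
        (r,) = hk.map_neighbors([e], [g])
        assert (r.relation, r.distance) == ("upstream", 50)
        assert hk.map_neighbors([e], [g], window_up=40) == []
        (r,) = hk.map_neighbors([e], [g], window_up=50)
        assert r.distance == 50

    def test_downstream_of_minus_gene_is_genomic_left(self):
        g = gene(strand="-", tx_start=10_000, tx_end=20_000)
        e = element(start=9_900, end=9_950)
        (r,) = hk.map_neighbors([e], [g])
        assert (r.relation, r.distance) == ("downstream", 50)

    def test_intronic_element_distance_zero(self):
        g = gene()
        e = element(start=12_000, end=12_450)  # between the two exons
        (r,) = hk.map_neighbors([e], [g])
        assert (r.relation, r.distance) == ("intronic", 0)

    def test_exonic_beats_intronic(self):
        g = gene()
        e = element(start=10_400, end=10_850)  # overlaps first exon end
        (r,) = hk.map_neighbors([e], [g])
        assert r.relation == "exonic"

    def test_boundary_straddles_transcript_edge(self):
        g = gene(exons=((12_000, 12_100), (19_000, 19_100)),
                 tx_start=12_000, tx_end=19_100)
        e = element(start=11_900, end=12_050)
        (r,) = hk.map_neighbors([e], [g])
        assert r.relation == "exonic"  # touches the first exon
        g2 = gene(exons=((12_500, 12_600), (19_000, 19_100)),
                  tx_start=12_000, tx_end=19_100)
        e2 = element(start=11_900, end=12_200)
        (r2,) = hk.map_neighbors([e2], [g2])
        assert (r2.relation, r2.distance) == ("boundary", 0)

    def test_orientation_sense_iff_strands_equal(self):
        g = gene(strand="-")
        (r,) = hk.map_neighbors([element(start=12_000, end=12_450, strand="-")], [g])
        assert r.orientation == "sense"
        (r,) = hk.map_neighbors([element(start=12_000, end=12_450, strand="+")], [g])
        assert r.orientation == "antisense"

    def test_window_out_of_range_errors(self):
        with pytest.raises(ValueError):
            hk.map_neighbors([], [], window_up=100_001)
        with pytest.raises(ValueError):
            hk.map_neighbors([], [], window_down=-1)

    def test_element_pairs_with_every_nearby_isoform(self):
        g1 = gene(iso="a", symbol="A")
        g2 = gene(iso="b", symbol="B", tx_start=12_500, tx_end=22_000,
                  exons=((12_500, 13_000), (21_500, 22_000)))
        e = element(start=13_500, end=13_950)
        recs = hk.map_neighbors([e], [g1, g2])
        assert {r.symbol for r in recs} == {"A", "B"}


def brute_force_records(elements, genes, window_up=100_000, window_down=100_000):
    """All-pairs oracle for map_neighbors."""
    out = set()
    for e in elements:
        for g in genes:
            if g.chrom != e.chrom:
                continue
            if e.start < g.tx_end and g.tx_start < e.end:
                if any(e.start < xe and xs < e.end for xs, xe in g.exons):
                    rel = "exonic"
                elif g.tx_start <= e.start and e.end <= g.tx_end:
                    rel = "intronic"
                else:
                    rel = "boundary"
                dist = 0
            elif e.end <= g.tx_start:
                dist = g.tx_start - e.end
                rel = "upstream" if g.strand == "+" else "downstream"
            else:
                dist = e.start - g.tx_end
                rel = "downstream" if g.strand == "+" else "upstream"
            if rel == "upstream" and dist > window_up:
                continue
            if rel == "downstream" and dist > window_down:
                continue
            ori = "sense" if e.strand == g.strand else "antisense"
            out.add((e.element_id, g.isoform_id, rel, dist, ori))
    return out


class TestOracleAndProperties:
    def _random_scene(self, seed, n_frags=40, n_genes=8):
        rng = np.random.default_rng(seed)
        elements = hk.defragment(random_fragments(rng, n_frags), 500)
        genes = []
        for i in range(n_genes):
            chrom = ["chr1", "chr2"][int(rng.integers(2))]
            tx_start = int(rng.integers(0, 60_000))
            tx_end = tx_start + int(rng.integers(2_000, 30_000))
            mid = (tx_start + tx_end) // 2
            genes.append(
                gene(chrom=chrom, strand="+-"[int(rng.integers(2))],
                     tx_start=tx_start, tx_end=tx_end,
                     exons=((tx_start, tx_start + 500), (mid, mid + 300), (tx_end - 500, tx_end)),
                     iso=f"iso{i}", symbol=f"S{i}")
            )
        return elements, genes

    @pytest.mark.parametrize("seed", range(6))
    def test_interval_index_matches_all_pairs_scan(self, seed):
        elements, genes = self._random_scene(seed)
        recs = hk.map_neighbors(elements, genes, 50_000, 30_000)
        got = {(r.element_id, r.isoform_id, r.relation, r.distance, r.orientation) for r in recs}
        assert got == brute_force_records(elements, genes, 50_000, 30_000)

    @pytest.mark.parametrize("seed", range(6))
    def test_shrinking_windows_never_add_records(self, seed):
        elements, genes = self._random_scene(seed)
        big = hk.map_neighbors(elements, genes, 80_000, 80_000)
        small = hk.map_neighbors(elements, genes, 20_000, 10_000)
        assert set(small) <= set(big)
        for r in small:
            if r.relation == "upstream":
                assert r.distance <= 20_000
            elif r.relation == "downstream":
                assert r.distance <= 10_000
            else:
                assert r.distance == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_strand_flip_swaps_sense_antisense(self, seed):
        elements, genes = self._random_scene(seed)
        flipped = [replace(e, strand="-" if e.strand == "+" else "+") for e in elements]
        before = hk.map_neighbors(elements, genes)
        after = hk.map_neighbors(flipped, genes)
        n_sense = sum(r.orientation == "sense" for r in before)
        n_anti = sum(r.orientation == "antisense" for r in before)
        assert sum(r.orientation == "sense" for r in after) == n_anti
        assert sum(r.orientation == "antisense" for r in after) == n_sense


class TestProfileSummary:
    def test_empty_records_all_zero(self):
        s = hk.profile_summary([], [])
        assert s["n_records"] == 0
        assert s["pct_elements_with_neighbor"] == 0.0

    def test_planted_fixture_counts(self, default_fixture, fixture_elements, fixture_records):
        s = hk.profile_summary(fixture_records, fixture_elements)
        truth = default_fixture.truth
        hosted = [t for t in truth.elements if t.host_symbol is not None]
        # planted hosted elements + decoys (which sit inside hosted elements)
        decoys_near = sum(1 for d in truth.decoys)
        assert s["n_elements_with_neighbor"] >= len(hosted)
        assert s["upstream_records"] == sum(1 for t in hosted if t.relation == "upstream")
        assert s["downstream_records"] == sum(1 for t in hosted if t.relation == "downstream")
        planted_intragenic = sum(1 for t in hosted if t.relation in ("intronic", "exonic"))
        assert s["intragenic_records"] >= planted_intragenic
        assert s["n_isoforms_with_element"] <= len(truth.isoform_ids)


class TestGenesWithCharacteristic:
    def test_empty_query_returns_all_neighbored_symbols(self, fixture_records, fixture_elements):
        got = hk.genes_with_characteristic(fixture_records, fixture_elements, CharacteristicQuery())
        assert got == {r.symbol for r in fixture_records}

    def test_planted_conjunctive_match(self):
        e1 = element(eid="E1", superfamily="ERVK", family="HERVK10", group="LTR5_Hs",
                     start=12_000, end=12_450, strand="-")
        e2 = element(eid="E2", superfamily="ERV1", start=30_000, end=30_450)
        g1 = gene(iso="a", symbol="TARGET")
        g2 = gene(iso="b", symbol="OTHER", tx_start=28_000, tx_end=38_000,
                  exons=((28_000, 28_500), (37_500, 38_000)))
        recs = hk.map_neighbors([e1, e2], [g1, g2])
        q = CharacteristicQuery(superfamily="ERVK", location="intragenic", orientation="antisense")
        assert hk.genes_with_characteristic(recs, [e1, e2], q) == {"TARGET"}

    def test_name_filter_soundness(self, fixture_records, fixture_elements):
        got = hk.genes_with_characteristic(
            fixture_records, fixture_elements, CharacteristicQuery(name="LTR5_Hs")
        )
        by_id = {e.element_id: e for e in fixture_elements}
        with_name = {
            r.symbol
            for r in fixture_records
            if any(c.rep_name == "LTR5_Hs" for c in by_id[r.element_id].components)
            or by_id[r.element_id].group == "LTR5_Hs"
        }
        assert got <= with_name

    def test_adding_constraints_never_enlarges(self, fixture_records, fixture_elements):
        queries = [
            CharacteristicQuery(),
            CharacteristicQuery(superfamily="ERV1"),
            CharacteristicQuery(superfamily="ERV1", orientation="sense"),
            CharacteristicQuery(superfamily="ERV1", orientation="sense", location="intragenic"),
        ]
        sets = [
            hk.genes_with_characteristic(fixture_records, fixture_elements, q)
            for q in queries
        ]
        for smaller, larger in zip(sets[1:], sets):
            assert smaller <= larger

    def test_contradictory_query_errors(self, fixture_records, fixture_elements):
        with pytest.raises(ValueError, match="contradictory"):
            hk.genes_with_characteristic(
                fixture_records, fixture_elements,
                CharacteristicQuery(location="intragenic", max_distance=1000),
            )

    def test_distance_filter_selects_close_intergenic(self):
        g = gene()
        near = element(eid="N", start=9_800, end=9_950)  # upstream 50
        far = element(eid="F", start=0, end=450)  # upstream 9550
        recs = hk.map_neighbors([near, far], [g])
        got = hk.genes_with_characteristic(
            recs, [near, far], CharacteristicQuery(max_distance=100)
        )
        assert got == {"SYM1"}
        got_none = hk.genes_with_characteristic(
            recs, [far], CharacteristicQuery(max_distance=100)
        )
        assert got_none == set()
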