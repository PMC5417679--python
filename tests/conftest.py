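import io

import numpy as np
import pytest

import hervkit as hk
from hervkit.synthetic import MODEL_GEOMETRY


@pytest.fixture(scope="session")
def taxonomy():
    return hk.load_taxonomy()


@pytest.fixture(scope="session")
def default_fixture():
    """The standard 20-element planted fixture (4 per truncation type,
    gaps <= 300 bp, nested decoys)."""
    return hk.generate_genome_fixture(hk.PlantSpec.default(), seed=7)


@pytest.fixture(scope="session")
def fixture_fragments(default_fixture):
    return hk.filter_herv(hk.read_rmsk(io.StringIO(default_fixture.rmsk_text)))


@pytest.fixture(scope="session")
def fixture_elements(fixture_fragments, taxonomy):
    return hk.defragment(fixture_fragments, 500, taxonomy)


@pytest.fixture(scope="session")
def fixture_genes(default_fixture):
    xref = dict(
        line.split("\t") for line in default_fixture.xref_text.splitlines()
    )
    return hk.read_genes(
        io.StringIO(default_fixture.genepred_text), "genepred", xref
    )


@pytest.fixture(scope="session")
def fixture_records(fixture_elements, fixture_genes):
    return hk.map_neighbors(fixture_elements, fixture_genes)


def make_fragment(
    chrom="chr1",
    start=1000,
    end=1500,
    strand="+",
    rep_name="LTR7",
    rep_class="LTR",
    rep_family="ERV1",
    cs=None,
    ce=None,
    mlen=None,
    sw=1000,
):
    """Build a RepeatFragment with UCSC-style signed consensus encoding."""
    if cs is None:
        rep_start = rep_end = rep_left = 0
    else:
        remaining = mlen - ce
        if strand == "+":
            rep_start, rep_end, rep_left = cs, ce, -remaining
        else:
            rep_start, rep_end, rep_left = -remaining, ce, cs
    return hk.RepeatFragment(
        chrom=chrom, start=start, end=end, strand=strand,
        rep_name=rep_name, rep_class=rep_class, rep_family=rep_family,
        sw_score=sw, rep_start=rep_start, rep_end=rep_end, rep_left=rep_left,
    )


def random_fragments(rng, n=30, chroms=("chr1", "chr2"), families=("HERVH", "THE1", "ERV9")):
    """Random HERV fragments with model-consistent consensus coordinates."""
    frags = []
    pos = {c: 0 for c in chroms}
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        fam = families[int(rng.integers(len(families)))]
        ltr, ltr_len, internal, int_len = MODEL_GEOMETRY[fam]
        if rng.random() < 0.6:
            name, mlen = ltr, ltr_len
        else:
            name, mlen = internal, int_len
        cs = int(rng.integers(1, mlen))
        ce = int(rng.integers(cs, mlen + 1))
        length = ce - cs + 1
        pos[chrom] += int(rng.integers(0, 1200))
        start = pos[chrom]
        pos[chrom] += length
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append(
            make_fragment(
                chrom=chrom, start=start, end=start + length, strand=strand,
                rep_name=name, cs=cs, ce=ce, mlen=mlen,
            )
        )
    return frags
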