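import pytest

from semiperm.data_io import (
    LocusAlignment,
    SampleRecord,
    SampleTable,
    build_sympatry_map,
)


def make_samples(rows):
    """rows: (sample_id, species, basin) triples."""
    return SampleTable(
        [SampleRecord(sid, sp, ba, f"{ba}-river", "test") for sid, sp, ba in rows]
    )


def make_alignment(locus, pairs):
    """pairs: (haplotype_id, sequence)."""
    ids, seqs = zip(*pairs)
    return LocusAlignment(locus, tuple(ids), tuple(seqs))


@pytest.fixture
def two_pop_dataset():
    """Two species in one basin plus one allopatric basin each; one locus."""
    samples = make_samples(
        [
            ("A1", "alpha", "G"), ("A2", "alpha", "G"),
            ("A3", "alpha", "T"), ("A4", "alpha", "T"),
            ("B1", "beta", "G"), ("B2", "beta", "G"),
            ("B3", "beta", "S"), ("B4", "beta", "S"),
        ]
    )
    aln = make_alignment(
        "loc1",
        [
            ("A1_a", "AAAA"), ("A1_b", "AAAT"),
            ("A2_a", "AAAA"), ("A2_b", "GGGG"),
            ("A3_a", "AAAA"), ("A3_b", "AAAT"),
            ("A4_a", "AAAA"), ("A4_b", "AAAT"),
            ("B1_a", "GGGG"), ("B1_b", "GGGC"),
            ("B2_a", "GGGG"), ("B2_b", "GGGC"),
            ("B3_a", "GGGG"), ("B3_b", "GGGC"),
            ("B4_a", "GGGG"), ("B4_b", "GGGC"),
        ],
    )
    samples.bind_alignment(aln)
    smap = build_sympatry_map(samples)
    return aln, samples, smap
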