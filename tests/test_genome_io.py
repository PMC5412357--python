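"""genome_io: GenBank round trips, name normalization, gene-order and
strand accounting, region extraction."""

import io
import warnings

import pytest

from mitocomp import genome_io
from mitocomp.model import AnnotatedGenome, GeneFeature, reverse_complement


def _feature_tuple(f):
    return (f.name, f.type, f.strand, tuple(f.spans), f.anticodon)


def test_genbank_round_trip_preserves_feature_table(genome):
    buf = io.StringIO()
    genome_io.write_genbank(genome, buf)
    buf.seek(0)
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # no unknown-gene warnings expected
        again = genome_io.read_genbank(buf)
    assert again.sequence == genome.sequence
    assert again.topology == "circular"
    assert [_feature_tuple(f) for f in again.features] == \
        [_feature_tuple(f) for f in genome.features]
    assert len([f for f in again.features if f.name != "CR"]) == 37


def test_feature_table_round_trip(genome, tmp_path):
    path = str(tmp_path / "features.tsv")
    genome_io.write_feature_table(genome, path)
    feats = genome_io.read_feature_table(path)
    assert {_feature_tuple(f)[:4] for f in feats} == \
        {_feature_tuple(f)[:4] for f in genome.features}


def test_origin_wrapping_feature_round_trips():
    g = AnnotatedGenome(id="wrap", sequence="ACGTACGTAC",
                        features=[GeneFeature(name="ND2", type="PCG", strand="J",
                                              spans=[(8, 10), (0, 2)])])
    buf = io.StringIO()
    genome_io.write_genbank(g, buf)
    buf.seek(0)
    again = genome_io.read_genbank(buf)
    assert again.features[0].spans == [(8, 10), (0, 2)]
    assert genome_io.extract_region(again, again.features[0]) == "ACAC"


@pytest.mark.parametrize("raw, anticodon, expected", [
    ("COX1", None, "CO1"), ("COI", None, "CO1"), ("NAD2", None, "ND2"),
    ("12S ribosomal RNA", None, "srRNA"), ("tRNA-Leu", "TAA", "tRNA-Leu(UUR)"),
    ("tRNA-Ser", "GCT", "tRNA-Ser(AGN)"), ("trnL1", None, "tRNA-Leu(CUN)"),
    ("D-loop", None, "CR"), ("totally-unknown", None, None),
])
def test_gene_name_normalization(raw, anticodon, expected):
    assert genome_io.normalize_gene_name(raw, anticodon) == expected


def test_strand_census_matches_ancestral_order(genome):
    census = genome_io.strand_census(genome)
    assert (census["J"], census["N"]) == (23, 14)
    assert census["missing"] == []


def test_strand_census_all_j_and_partial(genome):
    flipped = AnnotatedGenome(
        id="allJ", sequence=genome.sequence,
        features=[GeneFeature(name=f.name, type=f.type, strand="J",
                              spans=f.spans) for f in genome.features])
    c = genome_io.strand_census(flipped)
    assert (c["J"], c["N"]) == (37, 0)
    drop = {"tRNA-Ile", "tRNA-Cys", "tRNA-Val"}
    partial = AnnotatedGenome(
        id="partial", sequence=genome.sequence,
        features=[f for f in genome.features if f.name not in drop])
    c = genome_io.strand_census(partial)
    assert c["J"] + c["N"] == 34
    assert set(c["missing"]) == drop


def test_gene_order_matches_packaged_table(genome):
    equal, idx = genome_io.compare_gene_order(genome)
    assert equal and idx is None


def test_gene_order_rotation_invariance(genome):
    shift = 5000
    L = len(genome.sequence)
    rotated_seq = genome.sequence[shift:] + genome.sequence[:shift]

    def rot(span):
        s, e = (span[0] - shift) % L, (span[1] - shift) % L or L
        return [(s, e)] if s < e else [(s, L), (0, e)]

    feats = []
    for f in genome.features:
        spans = []
        for sp in f.spans:
            spans.extend(rot(sp))
        feats.append(GeneFeature(name=f.name, type=f.type, strand=f.strand,
                                 spans=spans))
    rotated = AnnotatedGenome(id="rot", sequence=rotated_seq, features=feats)
    equal, _ = genome_io.compare_gene_order(rotated)
    assert equal


def test_gene_order_detects_swap(genome):
    order = genome_io.ancestral_gene_order()
    swapped = list(order)
    # swap the two tRNAs at indices 4 and 5 (tRNA-Trp / tRNA-Cys)
    swapped[4], swapped[5] = swapped[5], swapped[4]
    equal, idx = genome_io.compare_gene_order(genome, reference=swapped)
    assert not equal and idx == 4


def test_duplicated_gene_raises(genome):
    dup = AnnotatedGenome(
        id="dup", sequence=genome.sequence,
        features=list(genome.features) + [GeneFeature(
            name="ND2", type="PCG", strand="J", spans=[(0, 9)])])
    with pytest.raises(ValueError, match="duplicated"):
        genome_io.gene_order_signature(dup)


def test_extract_region_orientations():
    seq = "AAAACGTAAATTTTTTTTTT"
    g = AnnotatedGenome(id="x", sequence=seq, features=[])
    j = GeneFeature(name="a", type="spacer", strand="J", spans=[(10, 13)])
    assert genome_io.extract_region(g, j) == seq[10:13]
    n = GeneFeature(name="b", type="spacer", strand="N", spans=[(4, 7)])
    assert genome_io.extract_region(g, n) == "ACG"  # revcomp of CGT
    # double reverse-complement is the identity
    assert reverse_complement(reverse_complement(seq[4:7])) == seq[4:7]
    wrap = GeneFeature(name="c", type="spacer", strand="J",
                       spans=[(18, 20), (0, 2)])
    assert genome_io.extract_region(g, wrap) == "TTAA"


def test_feature_and_gap_lengths_tile_genome(genome):
    feats = genome.features_sorted()
    total = sum(f.length for f in feats)
    gaps = 0
    for a, b in zip(feats, feats[1:]):
        gaps += b.start - a.end
    gaps += len(genome.sequence) - feats[-1].end + feats[0].start
    assert total + gaps == len(genome.sequence)


def test_infer_control_region_flags_provenance(genome):
    stripped = AnnotatedGenome(
        id="nocr", sequence=genome.sequence,
        features=[f for f in genome.features if f.type != "control_region"])
    cr = genome_io.infer_control_region(stripped)
    assert cr.inferred
    annotated = next(f for f in genome.features if f.type == "control_region")
    assert cr.spans[0][0] == annotated.spans[0][0]


def test_malformed_genbank_raises(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("not a genbank record\n")
    with pytest.raises(ValueError, match="[Gg]en[Bb]ank|record"):
        genome_io.read_genbank(str(bad))
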