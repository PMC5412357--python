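"""spacer_consensus: spacer extraction, progressive alignment (checked
against an exhaustive enumeration oracle), IUPAC consensus motifs."""

from functools import lru_cache

import pytest
from hypothesis import given, strategies as st

from mitocomp import spacer_consensus as sc
from mitocomp import synthetic_data as sd
from mitocomp.model import AnnotatedGenome, GeneFeature

MOTIF_HIS_ND5 = "GTGAAWWWTTTATCM"
MOTIF_ND1_S2 = "TATBAAWWWWWWWTAGTA"
MOTIF_GLU_PHE = "ACTWAWWWWAWTTMWHWA"


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extract_planted_spacers(genome, truth):
    for spt in truth.spacers:
        got = sc.extract_spacer(genome, spt.up, spt.down)
        assert got.sequence == spt.sequence
        assert got.orientation == spt.orientation
        assert got.span == spt.genomic_span


def test_his_nd5_spacer_is_n_oriented(genome, truth):
    got = sc.extract_spacer(genome, "tRNA-His", "ND5")
    assert got.orientation == "N"
    assert len(got.sequence) == 15


def test_abutting_genes_give_empty_spacer():
    g = AnnotatedGenome(id="x", sequence="ACGTACGTACGT", features=[
        GeneFeature(name="a", type="tRNA", strand="J", spans=[(0, 4)]),
        GeneFeature(name="b", type="tRNA", strand="J", spans=[(4, 8)])])
    assert sc.extract_spacer(g, "a", "b").sequence == ""


def test_non_adjacent_flanks_raise():
    g = AnnotatedGenome(id="x", sequence="ACGTACGTACGTACGT", features=[
        GeneFeature(name="a", type="tRNA", strand="J", spans=[(0, 2)]),
        GeneFeature(name="b", type="tRNA", strand="J", spans=[(4, 6)]),
        GeneFeature(name="c", type="tRNA", strand="J", spans=[(8, 10)]),
        GeneFeature(name="d", type="tRNA", strand="J", spans=[(12, 14)])])
    with pytest.raises(ValueError, match="not adjacent"):
        sc.extract_spacer(g, "a", "c")


# ---------------------------------------------------------------------------
# alignment vs exhaustive oracle
# ---------------------------------------------------------------------------

def _enumerate_alignments(a, b):
    """All global alignments of two short strings as (rowA, rowB) pairs."""
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return [("", "")]
        out = []
        if i < len(a) and j < len(b):
            out += [(a[i] + x, b[j] + y) for x, y in rec(i + 1, j + 1)]
        if i < len(a):
            out += [(a[i] + x, "-" + y) for x, y in rec(i + 1, j)]
        if j < len(b):
            out += [("-" + x, b[j] + y) for x, y in rec(i, j + 1)]
        return out
    return rec(0, 0)


def _score(rowA, rowB):
    """Match +1, mismatch -1, gap -2, terminal gaps free."""
    score = 0.0
    for row_self in (rowA, rowB):
        gaps = [k for k, c in enumerate(row_self) if c == "-"]
        first = next((k for k, c in enumerate(row_self) if c != "-"), len(row_self))
        last = len(row_self) - 1 - next(
            (k for k, c in enumerate(reversed(row_self)) if c != "-"), len(row_self))
        score += sum(-2 for k in gaps if first <= k <= last)
    for x, y in zip(rowA, rowB):
        if x != "-" and y != "-":
            score += 1 if x == y else -1
    return score


def _pairwise(a, b):
    """align_to_profile against a single-row profile, mask mapped back."""
    mask, q = sc.align_to_profile([a], b)
    it = iter(a)
    t = "".join("-" if c == "-" else next(it) for c in mask)
    return t, q


def _ident(t, q):
    return sum(1 for x, y in zip(t, q) if x == y and x != "-")


@pytest.mark.parametrize("a, b", [
    ("ACGT", "AGT"), ("ACGT", "ACGT"), ("AATT", "ATT"),
    ("GATTA", "GTA"), ("ACACA", "CAC"), ("TATATA", "TATA"),
])
def test_pairwise_alignment_matches_exhaustive_oracle(a, b):
    alns = _enumerate_alignments(a, b)
    best_score = max(_score(x, y) for x, y in alns)
    best_ident = max(_ident(x, y) for x, y in alns
                     if _score(x, y) == best_score)
    ta, tb = _pairwise(a, b)
    assert _score(ta, tb) == best_score
    assert _ident(ta, tb) == best_ident


def test_gap_placed_opposite_the_unmatched_residue():
    assert _pairwise("ACGT", "AGT") == ("ACGT", "A-GT")


def test_identical_sequences_align_gap_free():
    rows = sc.align_spacers(["ACGTACGT"] * 4)
    assert rows == ["ACGTACGT"] * 4


def test_equal_length_panel_aligns_gap_free():
    rows = sc.align_spacers(["ACGTAA", "ACGTTA", "ACCTAA"])
    assert all("-" not in r for r in rows)
    assert [len(r) for r in rows] == [6, 6, 6]


def test_length_ratio_guard():
    with pytest.raises(ValueError, match="manual review"):
        sc.align_spacers(["ACGTACGTACGT", "ACG"])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_column_residue_sets_map_to_iupac():
    m = sc.iupac_consensus(["AT", "TT", "AC"])  # col1 {A,T}=W, col2 {T,C}=Y
    assert m.consensus == "WY"
    m = sc.iupac_consensus(["C", "G", "T"])
    assert m.consensus == "B"


def test_single_sequence_consensus_is_identity():
    assert sc.iupac_consensus(["ACGT"]).consensus == "ACGT"


def test_consensus_idempotent_and_order_invariant():
    rows = sd.generate_spacer_panel(MOTIF_GLU_PHE, 5, seed=11)
    m1 = sc.iupac_consensus(rows)
    m2 = sc.iupac_consensus(list(reversed(rows)))
    assert m1.consensus == m2.consensus
    assert sc.iupac_consensus([m1.consensus]).consensus == m1.consensus


def test_every_input_matches_consensus():
    rows = sd.generate_spacer_panel(MOTIF_ND1_S2, 5, seed=3)
    m = sc.iupac_consensus(rows)
    assert all(sc.consensus_matches(r, m) for r in rows)


def test_majority_gap_columns_trimmed():
    rows = ["TTACGT--", "--ACGT--", "--ACGTAA"]
    m = sc.iupac_consensus(rows)
    assert m.consensus == "ACGT"
    assert m.kept_columns == [2, 3, 4, 5]


def test_empty_alignment_raises():
    with pytest.raises(ValueError):
        sc.iupac_consensus([])


@pytest.mark.parametrize("motif, length", [
    (MOTIF_HIS_ND5, 15), (MOTIF_ND1_S2, 18), (MOTIF_GLU_PHE, 18)])
def test_planted_panels_regenerate_motifs(motif, length):
    rows = sc.align_spacers(sd.generate_spacer_panel(motif, 5, seed=7))
    m = sc.iupac_consensus(rows)
    assert len(m) == length
    assert m.consensus == motif


@pytest.mark.parametrize("seed", range(10))
def test_flanking_extensions_trimmed_to_core(seed):
    """A lineage-specific 5' extension aligns as a terminal overhang and
    is trimmed, leaving the conserved core motif."""
    rows = sd.generate_spacer_panel(
        MOTIF_ND1_S2, 5, seed=seed, extensions={1: ("TAAACT", "")})
    m = sc.iupac_consensus(sc.align_spacers(rows))
    assert m.consensus == MOTIF_ND1_S2


@given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=9),
                min_size=2, max_size=5))
def test_alignment_rows_restore_inputs(seqs):
    rows = sc.align_spacers(seqs)
    assert [r.replace("-", "") for r in rows] == [s for s in seqs]
    assert len({len(r) for r in rows}) == 1
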