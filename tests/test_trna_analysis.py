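"""trna_analysis: cloverleaf parsing, mismatch detection, and the six-way
pair-change classification (checked exhaustively against an independent
oracle over all 256 ordered pair comparisons)."""

import itertools

import pytest

from mitocomp import trna_analysis as ta
from mitocomp import synthetic_data as sd

RNA = "ACGU"
ALL_PAIRS = list(itertools.product(RNA, RNA))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _toy_hairpin():
    #  7-pair acceptor stem, 4 nt loop, 1 nt discriminator
    seq = "GGGAAAC" + "UUUA" + "GUUUCCC" + "A"
    struct = "(((((((" + "...." + ")))))))" + "."
    arm_map = {
        "acceptor": {"stem5": (0, 7), "stem3": (11, 18), "loop": (0, 0)},
        "DHU": {"stem5": (7, 7), "stem3": (7, 7), "loop": (7, 7)},
        "anticodon": {"stem5": (7, 7), "stem3": (7, 7), "loop": (7, 11)},
        "TPSIC": {"stem5": (7, 7), "stem3": (7, 7), "loop": (7, 7)},
    }
    return seq, struct, arm_map


def test_toy_acceptor_hairpin_has_seven_pairs():
    seq, struct, arm_map = _toy_hairpin()
    leaf = ta.parse_cloverleaf(seq, struct, arm_map)
    assert leaf.arms["acceptor"].depth == 7
    assert leaf.arms["DHU"].depth == 0


def test_serine_agn_template_lacks_dhu_arm(templates):
    t = templates["tRNA-Ser(AGN)"]
    leaf = ta.parse_cloverleaf(t["sequence"], t["structure"], t["arms"],
                               name="tRNA-Ser(AGN)")
    assert leaf.arms["DHU"].depth == 0
    assert leaf.arms["acceptor"].depth == 7


def test_all_dot_structure_zero_drawn_pairs():
    seq, _, arm_map = _toy_hairpin()
    empty_map = {arm: {"stem5": (0, 0), "stem3": (0, 0), "loop": (0, 0)}
                 for arm in ta.ARM_NAMES}
    empty_map["anticodon"]["loop"] = (7, 11)
    leaf = ta.parse_cloverleaf(seq, "." * len(seq), empty_map)
    assert all(leaf.arms[a].depth == 0 for a in ta.ARM_NAMES)


@pytest.mark.parametrize("structure, err", [
    ("(((", "unbalanced"), (")..", "unbalanced"), ("..", "length")])
def test_parse_errors(structure, err):
    seq, _, arm_map = _toy_hairpin()
    bad = structure + "." * (len(seq) - len(structure)) if err != "length" else structure
    with pytest.raises(ValueError, match=err):
        ta.parse_cloverleaf(seq if err != "length" else seq, bad, arm_map)


def test_anticodon_located_in_loop(templates):
    for name, t in templates.items():
        leaf = ta.parse_cloverleaf(t["sequence"], t["structure"], t["arms"],
                                   name=name)
        expected = t["anticodon"].replace("T", "U")
        assert leaf.anticodon == expected
        lo, hi = leaf.arms["anticodon"].loop
        assert lo <= leaf.anticodon_span[0] and leaf.anticodon_span[1] <= hi


# ---------------------------------------------------------------------------
# mismatches
# ---------------------------------------------------------------------------

def test_all_watson_crick_cloverleaf_has_no_mismatches(templates):
    t = templates["tRNA-Met"]
    leaf = ta.parse_cloverleaf(t["sequence"], t["structure"], t["arms"])
    assert ta.find_mismatches(leaf) == []


def test_planted_uu_mismatch_found(truth):
    seq, struct, arms = truth.trna_structures["tRNA-Arg"]
    leaf = ta.parse_cloverleaf(seq, struct, arms, name="tRNA-Arg")
    assert ta.find_mismatches(leaf) == [("acceptor", 5, ("U", "U"))]


def test_two_uu_pairs_in_tpsic_stem(templates):
    t = templates["tRNA-Val"]
    seq, struct = list(t["sequence"]), list(t["structure"])
    for pos in (2, 3):
        i, j = sd._arm_pair_indices(t["arms"], "TPSIC", pos)
        sd._apply_pair(seq, struct, i, j, ("T", "T"))
    leaf = ta.parse_cloverleaf("".join(seq), "".join(struct), t["arms"])
    assert ta.find_mismatches(leaf) == [("TPSIC", 2, ("U", "U")),
                                        ("TPSIC", 3, ("U", "U"))]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

WORKED_EXAMPLES = [
    (("G", "C"), ("A", "U"), "cbc"),
    (("G", "U"), ("A", "U"), "hemi_cbc"),
    (("A", "A"), ("A", "U"), "rbc"),
    (("A", "U"), ("U", "A"), "mbc"),
    (("U", "U"), ("U", "C"), "nrbc"),
    (("G", "C"), ("G", "C"), "identity"),
]


@pytest.mark.parametrize("a, b, expected", WORKED_EXAMPLES)
def test_classifier_worked_examples(a, b, expected):
    assert ta.classify_pair_change(a, b) == expected
    assert ta.classify_pair_change(b, a) == expected  # undirected


def _oracle_category(a, b):
    """Independent restatement of the category definitions."""
    canonical = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                 ("G", "U"), ("U", "G")}
    if a == b:
        return "identity"
    n_canonical = (a in canonical) + (b in canonical)
    if n_canonical == 0:
        return "nrbc"
    if n_canonical == 1:
        return "rbc"
    hamming = (a[0] != b[0]) + (a[1] != b[1])
    if hamming == 1:
        return "hemi_cbc"
    return "mbc" if (b[0], b[1]) == (a[1], a[0]) else "cbc"


def test_classifier_matches_oracle_on_all_256_comparisons():
    seen = set()
    for a in ALL_PAIRS:
        for b in ALL_PAIRS:
            cat = ta.classify_pair_change(a, b)
            assert cat == _oracle_category(a, b), (a, b)
            assert cat == ta.classify_pair_change(b, a)
            assert cat in ("identity", "cbc", "hemi_cbc", "mbc", "rbc", "nrbc")
            seen.add(cat)
    assert len(seen) == 6  # every category realized: the six classes partition


def test_classifier_rejects_non_nucleotides():
    with pytest.raises(ValueError):
        ta.classify_pair_change(("X", "U"), ("A", "U"))


# ---------------------------------------------------------------------------
# pairwise tRNA comparison
# ---------------------------------------------------------------------------

def test_identical_cloverleaves_all_identity(templates):
    t = templates["tRNA-Phe"]
    leaf = ta.parse_cloverleaf(t["sequence"], t["structure"], t["arms"],
                               name="tRNA-Phe")
    cmp_res = ta.compare_trnas(leaf, leaf)
    assert cmp_res.changes and all(c.category == "identity" for c in cmp_res.changes)
    assert not cmp_res.surplus_ref and not cmp_res.surplus_other


def test_identity_mismatch_raises(templates):
    a = templates["tRNA-Phe"]
    b = templates["tRNA-Met"]
    la = ta.parse_cloverleaf(a["sequence"], a["structure"], a["arms"], name="tRNA-Phe")
    lb = ta.parse_cloverleaf(b["sequence"], b["structure"], b["arms"], name="tRNA-Met")
    with pytest.raises(ValueError, match="identity mismatch"):
        ta.compare_trnas(la, lb)


def test_unequal_stem_depths_reported_as_surplus():
    seq, struct, arm_map = _toy_hairpin()
    shallow = {k: dict(v) for k, v in arm_map.items()}
    shallow["acceptor"] = {"stem5": (0, 5), "stem3": (13, 18), "loop": (0, 0)}
    deep = ta.parse_cloverleaf(seq, struct, arm_map)
    shal = ta.parse_cloverleaf(seq, "." * len(seq), shallow)
    cmp_res = ta.compare_trnas(deep, shal)
    assert len([c for c in cmp_res.changes if c.arm == "acceptor"]) == 5
    assert [s[0] for s in cmp_res.surplus_ref] == ["acceptor", "acceptor"]


def test_planted_pattern_histogram_recovered():
    plants = [
        sd.PatternPlant("tRNA-Leu(UUR)", "acceptor", 1, "cbc", 1),
        sd.PatternPlant("tRNA-Leu(UUR)", "anticodon", 2, "cbc", 2),
        sd.PatternPlant("tRNA-Lys", "TPSIC", 3, "cbc", 3),
        sd.PatternPlant("tRNA-Asp", "DHU", 1, "hemi_cbc", 1),
        sd.PatternPlant("tRNA-Gly", "acceptor", 4, "hemi_cbc", 4),
        sd.PatternPlant("tRNA-Leu(CUN)", "anticodon", 2, "rbc", 1),
        sd.PatternPlant("tRNA-Ser(AGN)", "acceptor", 3, "mbc", 2),
        sd.PatternPlant("tRNA-Arg", "acceptor", 5, "nrbc", 1),
    ]
    panel = sd.generate_panel(sd.PanelConfig(seed=13, pattern_plants=plants))
    ref = panel.taxa[0]
    hist = {}
    for taxon in panel.taxa[1:]:
        for trna in panel.cloverleaves[taxon]:
            sr, dr, arms = panel.cloverleaves[ref][trna]
            sv, dv, _ = panel.cloverleaves[taxon][trna]
            lr = ta.parse_cloverleaf(sr, dr, arms, name=trna)
            lv = ta.parse_cloverleaf(sv, dv, arms, name=trna)
            for ch in ta.compare_trnas(lr, lv).changes:
                if ch.category != "identity":
                    hist[ch.category] = hist.get(ch.category, 0) + 1
    assert hist == {"cbc": 3, "hemi_cbc": 2, "rbc": 1, "mbc": 1, "nrbc": 1}
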