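"""control_region: homopolymer/(TA)n/macro-repeat/stem-loop detectors,
checked against brute-force oracles on seeded random sequences."""

import numpy as np
import pytest

from mitocomp import control_region as cr
from mitocomp import synthetic_data as sd
from mitocomp.control_region import PAIRS


def _random_seq(n, seed, p_at=0.5):
    rng = np.random.default_rng(seed)
    p = [p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# homopolymers and (TA)n
# ---------------------------------------------------------------------------

def test_planted_polyt_in_random_background():
    bg = list(_random_seq(400, 3))
    bg[200:200] = list("T" * 15)
    seq = "".join(bg)
    seq = seq[:199] + "C" + seq[200:215] + "C" + seq[216:]  # guard flanks
    found = cr.find_homopolymer(seq, "T", 10)
    assert [(e.spans[0], e.length) for e in found] == [((200, 215), 15)]


def test_no_long_run_returns_empty():
    assert cr.find_homopolymer("ACGTACGTACGT", "T", 5) == []


def test_run_abutting_sequence_end():
    found = cr.find_homopolymer("ACG" + "A" * 12, "A", 10)
    assert found[0].spans == [(3, 15)]


def test_homopolymer_invariant_under_appended_tail():
    seq = "ACG" + "T" * 11 + "GCA"
    a = cr.find_homopolymer(seq, "T", 10)
    b = cr.find_homopolymer(seq + "CAGCAG", "T", 10)
    assert [(e.spans, e.length) for e in a] == [(e.spans, e.length) for e in b]


def test_ta_stretch_examples():
    found = cr.find_ta_stretch("GGCTATATATAGGC", 3)
    assert [(e.spans[0], e.length) for e in found] == [((3, 11), 8)]
    assert cr.find_ta_stretch("TATG", 3) == []
    two = cr.find_ta_stretch("CCTATATACCATATATCC", 3)
    assert len(two) == 2 and two[0].start < two[1].start
    for e in two:
        assert e.length % 2 == 0 and e.length >= 6


# ---------------------------------------------------------------------------
# macro repeats
# ---------------------------------------------------------------------------

def _brute_macro(s, min_len):
    """All-substring-pairs oracle: maximal repeated substrings, then the
    same non-tandem qualification and nesting suppression as the API."""
    n = len(s)
    maximal = {}
    L = min_len
    while L <= n // 2 + 1:
        subs = {}
        for i in range(n - L + 1):
            subs.setdefault(s[i:i + L], []).append(i)
        repeated = {k: v for k, v in subs.items() if len(v) >= 2}
        if not repeated:
            break
        for sub, occ in repeated.items():
            lefts = {s[i - 1] if i > 0 else None for i in occ}
            rights = {s[i + L] if i + L < n else None for i in occ}
            if len(lefts) > 1 and len(rights) > 1:
                maximal[sub] = occ
        L += 1
    out = []
    for sub in sorted(maximal, key=lambda x: (-len(x), x)):
        occ, L = maximal[sub], len(sub)
        chosen = []
        for p in occ:
            if not chosen or p >= chosen[-1] + L + 1:
                chosen.append(p)
        if len(chosen) >= 2:
            out.append((sub, tuple((p, p + L) for p in chosen)))
    kept = []
    for sub, spans in out:
        nested = any(all(any(S <= s0 and e0 <= E for S, E in kspans)
                         for s0, e0 in spans) for _, kspans in kept)
        if not nested:
            kept.append((sub, spans))
    return sorted((spans, len(sub)) for sub, spans in kept)


def _embed(background, inserts):
    """Place (position, sequence) inserts into a mutable background copy,
    forcing distinct flanking characters between copies of the same
    sequence so each planted repeat is exactly maximal."""
    s = list(background)
    by_seq = {}
    for pos, ins in inserts:
        s[pos:pos + len(ins)] = list(ins)
        by_seq.setdefault(ins, []).append(pos)
    for ins, positions in by_seq.items():
        for k, pos in enumerate(positions):
            flank = "CG"[k % 2]
            if pos > 0:
                s[pos - 1] = flank
            if pos + len(ins) < len(s):
                s[pos + len(ins)] = flank
    return "".join(s)


def test_planted_repeat_recovered_with_exact_length():
    rep = _random_seq(50, 11, p_at=0.8)
    seq = _embed(_random_seq(900, 12), [(100, rep), (500, rep)])
    found = cr.find_macro_repeats(seq, 30)
    assert [(e.length, e.spans) for e in found] == \
        [(50, [(100, 150), (500, 550)])]


@pytest.mark.parametrize("seed, n, min_len, p_at", [
    (1, 400, 10, 0.8), (2, 400, 10, 0.85), (3, 600, 11, 0.8)])
def test_macro_repeats_match_brute_force(seed, n, min_len, p_at):
    seq = _random_seq(n, seed, p_at)
    got = sorted((tuple(e.spans), e.length)
                 for e in cr.find_macro_repeats(seq, min_len))
    assert got == _brute_macro(seq, min_len)


def test_macro_repeats_random_1500mer_matches_oracle():
    rep = _random_seq(40, 21)
    seq = _embed(_random_seq(1500, 20), [(200, rep), (900, rep)])
    got = sorted((tuple(e.spans), e.length)
                 for e in cr.find_macro_repeats(seq, 30))
    assert got == _brute_macro(seq, 30)


def test_tandem_copies_reported_separately():
    unit = _random_seq(15, 31, p_at=0.7)
    seq = "CAG" + unit + unit + "GTC" + _random_seq(100, 32)
    macros, tandem = cr.scan_repeats(seq, 10)
    assert macros == []
    assert len(tandem) == 1 and tandem[0].length == 15


def test_repeat_occurrences_are_identical_substrings(truth, genome):
    from mitocomp import genome_io
    crf = genome_io.infer_control_region(genome)
    seq = genome_io.extract_region(genome, crf)
    for el in cr.find_macro_repeats(seq, 30):
        copies = {seq[s:e] for s, e in el.spans}
        assert len(copies) == 1


# ---------------------------------------------------------------------------
# stem-loops
# ---------------------------------------------------------------------------

def _brute_stem_loops(s, min_stem, loop_range):
    """Exhaustive (position, stem, loop) enumeration with the maximality
    definition applied literally."""
    lo, hi = loop_range
    n = len(s)
    out = []
    for i in range(n):
        for l in range(lo, hi + 1):  # noqa: E741
            for stem in range(min_stem, n):
                a, b = i + stem, i + stem + l  # loop bounds
                end = b + stem
                if end > n:
                    break
                if not all((s[i + k], s[end - 1 - k]) in PAIRS for k in range(stem)):
                    continue
                out_ok = (i == 0 or end == n or (s[i - 1], s[end]) not in PAIRS)
                in_ok = not (l - 2 >= lo and (s[a], s[b - 1]) in PAIRS)
                if out_ok and in_ok:
                    out.append(((i, end), stem, l))
    return sorted(out)


def test_planted_hairpin_detected():
    hp = sd._stem_loop_seq(10, 6)
    seq = "A" * 30 + hp + "C" + "A" * 30
    found = cr.find_stem_loops(seq, 6, (3, 20))
    assert any(e.spans == [(30, 30 + len(hp))]
               and e.detail["stem"] == 10 and e.detail["loop"] == 6
               for e in found)


def test_polya_sequence_has_no_hairpins():
    assert cr.find_stem_loops("A" * 120, 6, (3, 20)) == []


@pytest.mark.parametrize("seed, n, p_at", [(5, 400, 0.7), (6, 800, 0.6)])
def test_stem_loops_match_brute_force(seed, n, p_at):
    seq = _random_seq(n, seed, p_at)
    got = sorted((tuple(e.spans[0]), e.detail["stem"], e.detail["loop"])
                 for e in cr.find_stem_loops(seq, 6, (3, 20)))
    assert got == _brute_stem_loops(seq, 6, (3, 20))


def test_stem_loops_ranked_by_stem_then_3prime():
    seq = _random_seq(600, 9, 0.7)
    found = cr.find_stem_loops(seq, 6, (3, 20))
    keys = [(-e.detail["stem"], -e.spans[0][1]) for e in found]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# whole-control-region report
# ---------------------------------------------------------------------------

def test_cr_report_recovers_all_planted_elements(genome, truth):
    rep = cr.cr_report(genome)
    assert rep.presence == {"polyT": True, "TA_stretch": True,
                            "polyA": True, "stem_loop": True}
    detected = {(el.kind, tuple(el.spans)) for el in rep.elements}
    for el in truth.cr_elements:
        assert (el.kind, tuple(el.spans)) in detected


def test_cr_report_elements_in_genomic_order(genome):
    rep = cr.cr_report(genome)
    starts = [el.start for el in rep.elements]
    assert starts == sorted(starts)


def test_genome_without_stem_loop_reports_absent():
    cfg = sd.GeneratorConfig(
        seed=8, cr=sd.CRPlantConfig(stem_loop=None))
    g, _ = sd.generate_genome(cfg)
    rep = cr.cr_report(g)
    assert rep.presence["stem_loop"] is False
    assert rep.presence["polyT"] and rep.presence["polyA"]


def test_cr_report_requires_control_region(genome):
    from mitocomp.model import AnnotatedGenome
    bare = AnnotatedGenome(
        id="bare", sequence=genome.sequence,
        features=[f for f in genome.features
                  if f.type not in ("control_region",) and
                  f.name not in ("srRNA",)])
    with pytest.raises(ValueError, match="control region"):
        cr.cr_report(bare)
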