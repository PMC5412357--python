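"""Detection of conserved structural elements in the mitochondrial
control region (A+T-rich region).

The insect control region conventionally carries four conserved
structural elements — a poly-T stretch, a (TA)n-like stretch, a poly-A
stretch and a 3'-end stem-loop — plus, in some taxa, long non-tandem
macro repeats.  All detectors are exact (no mismatches) and return
coordinates relative to the scanned sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .model import AnnotatedGenome
from . import genome_io

__all__ = ["CRElement", "find_homopolymer", "find_ta_stretch",
           "find_macro_repeats", "scan_repeats", "find_stem_loops",
           "cr_report", "CRReport", "PAIRS"]

#: Stem pairing alphabet: Watson-Crick plus the G-T (G-U) wobble.
PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                   ("G", "T"), ("T", "G")})


@dataclass
class CRElement:
    """One structural element, zero-based half-open span(s)."""

    kind: str  # polyT | polyA | TA_stretch | stem_loop | macro_repeat | tandem_repeat
    spans: list[tuple[int, int]]
    length: int
    detail: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.spans[0][0]


def find_homopolymer(seq: str, base: str, min_len: int = 10) -> list[CRElement]:
    """Maximal runs of ``base`` (A or T) of length >= min_len, left to right."""
    if base not in ("A", "T"):
        raise ValueError("base must be 'A' or 'T'")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    s = seq.upper()
    out = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] == base:
            j = i
            while j < n and s[j] == base:
                j += 1
            if j - i >= min_len:
                kind = "polyT" if base == "T" else "polyA"
                out.append(CRElement(kind=kind, spans=[(i, j)], length=j - i))
            i = j
        else:
            i += 1
    return out


def find_ta_stretch(seq: str, min_units: int = 3) -> list[CRElement]:
    """Maximal exact (TA)n or (AT)n runs with n >= min_units."""
    if min_units < 3:
        raise ValueError("min_units must be >= 3")
    s = seq.upper()
    n = len(s)
    out = []
    i = 0
    while i < n - 1:
        if {s[i], s[i + 1]} == {"T", "A"} and s[i] != s[i + 1]:
            j = i + 2
            while j < n and s[j] == s[j - 2]:
                j += 1
            run = j - i
            units = run // 2
            if units >= min_units:
                end = i + 2 * units  # even length by definition
                out.append(CRElement(kind="TA_stretch", spans=[(i, end)],
                                     length=2 * units,
                                     detail={"units": units, "phase": s[i]}))
            i = j - 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Non-tandem macro repeats
# ---------------------------------------------------------------------------

def _maximal_repeat_strings(s: str, min_len: int) -> set[str]:
    """Candidate maximal repeated substrings via pairwise maximal extensions.

    For every shift d, runs of agreement between s and s shifted by d are
    maximal common substrings for that occurrence pair; any maximal repeat
    of length >= min_len appears as such a run.
    """
    n = len(s)
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    found: set[str] = set()
    for d in range(1, n - min_len + 1):
        eq = a[:-d] == a[d:]
        if not eq.any():
            continue
        # run-length encode the boolean agreement vector
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):
            if stop - start >= min_len:
                found.add(s[start:stop])
    return found


def _occurrences(s: str, sub: str) -> list[int]:
    out = []
    i = s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


def scan_repeats(seq: str, min_len: int = 30) -> tuple[list[CRElement], list[CRElement]]:
    """(non-tandem macro repeats, tandem repeats) of length >= min_len.

    A macro repeat is a maximal exact repeated substring with at least
    two occurrences separated by >= 1 nt; abutting copies (gap 0) are a
    different phenomenon and land in the tandem list.  Nested sub-repeats
    whose every occurrence lies inside a longer reported repeat's
    occurrences are suppressed.
    """
    if min_len < 10:
        raise ValueError("min_len must be >= 10")
    s = seq.upper()
    macro_raw, tandem_raw = [], []
    for sub in sorted(_maximal_repeat_strings(s, min_len), key=lambda x: (-len(x), x)):
        occ = _occurrences(s, sub)
        if len(occ) < 2:
            continue
        L = len(sub)
        # greedy selection of non-overlapping occurrences with gap >= 1
        chosen: list[int] = []
        for p in occ:
            if not chosen or p >= chosen[-1] + L + 1:
                chosen.append(p)
        abutting = any(q - p == L for p, q in zip(occ, occ[1:]))
        if len(chosen) >= 2:
            macro_raw.append(CRElement(
                kind="macro_repeat", spans=[(p, p + L) for p in chosen],
                length=L, detail={"n_copies": len(chosen),
                                  "all_occurrences": occ}))
        elif abutting:
            tandem_raw.append(CRElement(
                kind="tandem_repeat", spans=[(p, p + L) for p in occ],
                length=L, detail={"n_copies": len(occ)}))
    # suppress repeats fully nested inside a longer reported repeat
    kept: list[CRElement] = []
    for el in macro_raw:  # already sorted longest-first
        nested = any(
            all(any(S <= s0 and e0 <= E for S, E in k.spans) for s0, e0 in el.spans)
            for k in kept)
        if not nested:
            kept.append(el)
    kept.sort(key=lambda e: e.start)
    tandem_raw.sort(key=lambda e: e.start)
    return kept, tandem_raw


def find_macro_repeats(seq: str, min_len: int = 30) -> list[CRElement]:
    """Non-tandem macro repeats (see :func:`scan_repeats`)."""
    return scan_repeats(seq, min_len)[0]


# ---------------------------------------------------------------------------
# Stem-loops (perfect inverted repeats)
# ---------------------------------------------------------------------------

def _pairs_ok(s: str, i: int, j: int) -> bool:
    return (s[i], s[j]) in PAIRS


def find_stem_loops(seq: str, min_stem: int = 6,
                    loop_range: tuple[int, int] = (3, 20)) -> list[CRElement]:
    """All maximal perfect hairpins (Watson-Crick + G-U, zero mismatches).

    A hairpin with stem s and loop l spans 2s + l nt.  Maximality: the
    stem can be extended neither outward (flanking bases do not pair or
    the sequence ends) nor inward (the innermost loop bases do not pair,
    or shrinking the loop would violate the minimum).  Results are ranked
    by stem length, ties broken by proximity to the 3' end.
    """
    loop_min, loop_max = loop_range
    if min_stem < 1 or loop_min < 1 or loop_max < loop_min:
        raise ValueError("invalid stem/loop constraints")
    s = seq.upper()
    n = len(s)
    found = []
    for a in range(n):  # loop start
        for l in range(loop_min, loop_max + 1):  # noqa: E741
            b = a + l  # loop end (exclusive)
            if b >= n:
                break
            # grow the stem outward from (a-1, b)
            m = 0
            while a - 1 - m >= 0 and b + m < n and _pairs_ok(s, a - 1 - m, b + m):
                m += 1
            if m < min_stem:
                continue
            # inward extension possible? then a deeper hairpin covers this center
            if l - 2 >= loop_min and _pairs_ok(s, a, b - 1):
                continue
            start, end = a - m, b + m
            found.append(CRElement(
                kind="stem_loop", spans=[(start, end)], length=end - start,
                detail={"stem": m, "loop": l, "loop_span": (a, b)}))
    found.sort(key=lambda e: (-e.detail["stem"], -e.spans[0][1]))
    return found


def _flank_motifs(seq: str, el: CRElement) -> dict:
    """Optional conserved flank checks around a stem-loop: a 5' 'TATA' box
    and a 3' 'G(A)nT' motif, as described for insect control regions."""
    s = seq.upper()
    start, end = el.spans[0]
    five = s[max(0, start - 4):start]
    has_tata = five == "TATA"
    has_gant = False
    tail = s[end:end + 12]
    if len(tail) >= 3 and tail[0] == "G":
        k = 1
        while k < len(tail) and tail[k] == "A":
            k += 1
        has_gant = k > 1 and k < len(tail) and tail[k] == "T"
    return {"tata_5prime": has_tata, "gant_3prime": has_gant}


# ---------------------------------------------------------------------------
# Whole-control-region report
# ---------------------------------------------------------------------------

CONSERVED_KINDS = ("polyT", "TA_stretch", "polyA", "stem_loop")


@dataclass
class CRReport:
    genome_id: str
    cr_span: list[tuple[int, int]]
    elements: list[CRElement]
    tandem: list[CRElement]
    presence: dict[str, bool]
    inferred_cr: bool = False


def _contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def cr_report(genome: AnnotatedGenome, polyt_min: int = 10, polya_min: int = 10,
              ta_min_units: int = 3, repeat_min_len: int = 30,
              min_stem: int = 6, loop_range: tuple[int, int] = (3, 20)) -> CRReport:
    """Run all control-region detectors and flag the four conserved elements.

    Coordinates are control-region-relative.  Stem-loops contained inside
    another reported element (a (TA)n stretch or a macro-repeat copy is
    itself foldable) are not listed as separate stem-loop elements.
    """
    cr = genome_io.infer_control_region(genome)
    seq = genome_io.extract_region(genome, cr)
    elements: list[CRElement] = []
    elements += find_homopolymer(seq, "T", polyt_min)
    elements += find_ta_stretch(seq, ta_min_units)
    elements += find_homopolymer(seq, "A", polya_min)
    macros, tandem = scan_repeats(seq, repeat_min_len)
    elements += macros
    other_spans = [sp for el in elements for sp in el.spans]
    for sl in find_stem_loops(seq, min_stem, loop_range):
        if any(_contained(sl.spans[0], outer) for outer in other_spans):
            continue
        sl.detail.update(_flank_motifs(seq, sl))
        elements.append(sl)
    elements.sort(key=lambda e: (e.start, e.kind))
    presence = {kind: any(e.kind == kind for e in elements)
                for kind in CONSERVED_KINDS}
    return CRReport(genome_id=genome.id, cr_span=cr.spans, elements=elements,
                    tandem=tandem, presence=presence, inferred_cr=cr.inferred)
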