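"""Intergenic spacer extraction and IUPAC-ambiguity consensus motifs.

Insect mitochondrial genomes carry a handful of short intergenic spacers
that are conserved across large clades (e.g. between ND1 and
tRNA-Ser(UCN), between tRNA-Glu and tRNA-Phe, and between tRNA-His and
ND5).  This module extracts named spacers from a panel of annotated
genomes, aligns them, and derives a presence-set consensus: each column's
set of observed residues is written as the corresponding IUPAC ambiguity
letter, so every input sequence matches the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import AnnotatedGenome, iupac_code, reverse_complement, IUPAC_TO_SET

__all__ = ["Spacer", "SpacerSet", "ConsensusMotif", "extract_spacer",
           "align_spacers", "iupac_consensus", "consensus_matches"]


@dataclass
class Spacer:
    """One intergenic spacer in its reported orientation."""

    genome_id: str
    upstream: str
    downstream: str
    sequence: str
    orientation: str  # "J" or "N"
    span: tuple[int, int]  # genomic J-strand coordinates, half-open
    mixed_strand: bool = False


@dataclass
class SpacerSet:
    """A named spacer collected across a genome panel."""

    upstream: str
    downstream: str
    spacers: list[Spacer] = field(default_factory=list)

    @property
    def orientation(self) -> str:
        orients = {s.orientation for s in self.spacers}
        if len(orients) > 1:
            raise ValueError("inconsistent spacer orientations in set")
        return orients.pop() if orients else "J"

    def sequences(self) -> list[str]:
        return [s.sequence for s in self.spacers]


@dataclass
class ConsensusMotif:
    """IUPAC consensus of an aligned spacer panel."""

    consensus: str
    column_sets: list[frozenset]
    n_sequences: int
    kept_columns: list[int]  # alignment columns surviving gap-majority trimming

    def __len__(self) -> int:
        return len(self.consensus)


def extract_spacer(genome: AnnotatedGenome, up: str, down: str) -> Spacer:
    """The literal intergenic sequence between two adjacent features.

    The pair may be named in either genome order (spacers flanked by
    N-strand genes are conventionally named in N-strand reading order).
    When both flanking genes lie on the N strand the spacer is returned
    reverse-complemented; mixed-strand flanks are reported J-strand with
    ``mixed_strand=True``.  Abutting or overlapping features yield an
    empty spacer.
    """
    fa = genome.feature_by_name(up)
    fb = genome.feature_by_name(down)
    ordered = genome.features_sorted()
    ia, ib = ordered.index(fa), ordered.index(fb)
    n = len(ordered)
    if (ia + 1) % n == ib:
        first, second = fa, fb
    elif (ib + 1) % n == ia:
        first, second = fb, fa
    else:
        raise ValueError(f"{up} and {down} are not adjacent in {genome.id}")
    L = len(genome.sequence)
    gap_start, gap_end = first.end % L, second.start
    if first is ordered[-1] and second is ordered[0]:
        # gap wraps the origin
        if genome.topology != "circular":
            raise ValueError("origin-spanning spacer on a linear molecule")
        raw = genome.sequence[gap_start:] + genome.sequence[:gap_end]
    else:
        raw = genome.sequence[gap_start:gap_end] if gap_start < gap_end else ""
    both_n = fa.strand == "N" and fb.strand == "N"
    mixed = fa.strand != fb.strand
    seq = reverse_complement(raw) if both_n else raw
    return Spacer(genome_id=genome.id, upstream=up, downstream=down,
                  sequence=seq, orientation="N" if both_n else "J",
                  span=(gap_start, gap_end), mixed_strand=mixed)


#: Internal gaps cost twice the full match-to-mismatch swing, so a gap
#: pair must rescue more than two columns to beat a substitution — on
#: AT-rich low-complexity spacers anything laxer shreds the alignment
#: into spurious micro-shuffles.
GAP_SCORE = -4.0
#: Terminal gaps are half price: lineage-specific flanking residues hang
#: out of the profile, but a row cannot cheaply shed a deviant terminal
#: residue into an overhang.
END_GAP_SCORE = -2.0


def _profile_columns(rows: Sequence[str]) -> list[dict[str, float]]:
    """Per-column residue frequencies of the running profile (gaps ignored)."""
    cols = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        n = len(residues)
        freq: dict[str, float] = {}
        for r in residues:
            freq[r] = freq.get(r, 0.0) + 1.0 / n
        cols.append(freq)
    return cols


def _col_score(freq: dict[str, float], base: str) -> float:
    """Frequency-weighted profile score, +1 (unanimous match) to -1
    (residue absent); an all-gap column is neutral."""
    return 2.0 * freq.get(base, 0.0) - 1.0 if freq else 0.0


def align_to_profile(rows: Sequence[str], seq: str) -> tuple[str, str]:
    """Semi-global alignment of ``seq`` against the profile of ``rows``.

    Scoring: frequency-weighted column score in [-1, +1] (for a
    single-row profile this is match +1 / mismatch -1), internal gap -4,
    terminal gap -2.  Among score-optimal alignments the one with the
    most positively matched columns is chosen; remaining ties prefer the
    substitution over gap moves, deterministically.

    Returns (gap mask over profile columns with 'x' for a column, and the
    gapped sequence).
    """
    cols = _profile_columns(rows)
    m, n = len(cols), len(seq)
    NEG = (float("-inf"), 0)
    # dp[i][j]: best (score, matched columns) aligning cols[:i] with seq[:j]
    dp = [[NEG] * (n + 1) for _ in range(m + 1)]
    move = [[None] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        dp[i][0] = (END_GAP_SCORE * i, 0)
        move[i][0] = "U" if i else None
    for j in range(1, n + 1):
        dp[0][j] = (END_GAP_SCORE * j, 0)
        move[0][j] = "L"
    for i in range(1, m + 1):
        freq = cols[i - 1]
        for j in range(1, n + 1):
            s = _col_score(freq, seq[j - 1])
            hit = 1 if s > 0 else 0
            cand = [
                ((dp[i - 1][j - 1][0] + s, dp[i - 1][j - 1][1] + hit), "D"),
                ((dp[i - 1][j][0] + GAP_SCORE, dp[i - 1][j][1]), "U"),
                ((dp[i][j - 1][0] + GAP_SCORE, dp[i][j - 1][1]), "L"),
            ]
            dp[i][j], move[i][j] = max(cand, key=lambda c: c[0])
    # cheap terminal gaps: exit anywhere on the last row or column, paying
    # END_GAP_SCORE per remaining unmatched position
    best, bi, bj = NEG, m, n

    def consider(i, j):
        nonlocal best, bi, bj
        val = (dp[i][j][0] + END_GAP_SCORE * ((m - i) + (n - j)), dp[i][j][1])
        if val > best or (val == best and i + j > bi + bj):
            best, bi, bj = val, i, j

    for i in range(m + 1):
        consider(i, n)
    for j in range(n + 1):
        consider(m, j)
    t = ["x"] * (m - bi) + ["-"] * (n - bj)
    q = ["-"] * (m - bi) + list(seq[bj:])
    i, j = bi, bj
    path_t, path_q = [], []
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == "D":
            path_t.append("x")
            path_q.append(seq[j - 1])
            i, j = i - 1, j - 1
        elif mv == "U":
            path_t.append("x")
            path_q.append("-")
            i -= 1
        else:
            path_t.append("-")
            path_q.append(seq[j - 1])
            j -= 1
    return "".join(reversed(path_t)) + "".join(t), \
        "".join(reversed(path_q)) + "".join(q)


def align_spacers(spacer_set, max_length_ratio: float = 2.0) -> list[str]:
    """Progressive global alignment of a spacer panel.

    Spacers are extracted between annotated flanking genes, so
    equal-length panels are already positionally homologous and are kept
    as-is (these AT-rich, low-complexity stretches carry too little
    signal for similarity-based alignment to improve on the anchoring).
    When lengths differ, each sequence is added in input order against
    the running profile with frequency-weighted column scores (+1
    unanimous match to -1 absent residue; match +1 / mismatch -1 in the
    pairwise case), internal gap -4, terminal gap -2.  Gap columns
    propagate ("once a gap, always a gap"); the result is deterministic.
    Accepts a :class:`SpacerSet` or a plain list of sequences.
    """
    seqs = spacer_set.sequences() if isinstance(spacer_set, SpacerSet) else list(spacer_set)
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        return list(seqs)
    lens = [len(s) for s in seqs if s]
    if not lens or min(lens) == 0:
        raise ValueError("empty spacer in panel; review annotations")
    if max(lens) / min(lens) > max_length_ratio:
        raise ValueError(
            f"spacer lengths differ more than {max_length_ratio}x "
            f"({min(lens)}..{max(lens)} nt); manual review suggested")
    if len(set(lens)) == 1:  # anchored by extraction: positional homology
        return seqs
    rows = [seqs[0]]
    for seq in seqs[1:]:
        t, q = align_to_profile(rows, seq)
        # propagate new gap columns into existing rows
        merged = []
        for row in rows:
            it = iter(row)
            merged.append("".join("-" if c == "-" else next(it) for c in t))
        merged.append(q)
        rows = merged
    return rows


def iupac_consensus(alignment: Sequence[str]) -> ConsensusMotif:
    """Presence-set IUPAC consensus of a gapped alignment.

    Each column's set of distinct non-gap residues maps to its IUPAC
    ambiguity letter; columns that are gap in at least half the rows are
    dropped (trimming to the conserved core).
    """
    rows = [r.upper() for r in alignment]
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    n = len(rows)
    letters, sets, kept = [], [], []
    for j, col in enumerate(zip(*rows)):
        residues = [c for c in col if c != "-"]
        if (n - len(residues)) * 2 >= n:
            continue
        code = iupac_code(residues)
        letters.append(code)
        sets.append(frozenset().union(*(IUPAC_TO_SET[r.replace("U", "T")]
                                        for r in residues)))
        kept.append(j)
    return ConsensusMotif(consensus="".join(letters), column_sets=sets,
                          n_sequences=n, kept_columns=kept)


def consensus_matches(sequence: str, motif: ConsensusMotif) -> bool:
    """True when every residue of ``sequence`` lies in its column's set."""
    if len(sequence) != len(motif.consensus):
        return False
    return all(base.upper().replace("U", "T") in colset
               for base, colset in zip(sequence, motif.column_sets))
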