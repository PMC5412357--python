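"""Base composition, strand skews, start/stop codons and codon usage (RSCU).

Skews follow the standard strand-asymmetry definitions
``AT-skew = (A - T)/(A + T)`` and ``GC-skew = (G - C)/(G + C)``, computed
on whichever strand the caller supplies (whole-genome reports use the
deposited J-strand; per-gene reports use coding orientation).  Codon
statistics use the invertebrate mitochondrial genetic code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable

from .model import AnnotatedGenome
from . import genome_io

__all__ = ["SkewReport", "CodonUsageTable", "skew",
           "codon_position_composition", "start_stop_table", "rscu",
           "genome_skew_report", "INVERTEBRATE_MITO_TABLE"]

INVERTEBRATE_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]
_STOP_CODONS = set(INVERTEBRATE_MITO_TABLE.stop_codons)  # TAA, TAG
#: Start codons treated as canonical in insect mt genomes (reports always
#: list the literal codon; this set is informational only).
CANONICAL_STARTS = frozenset(
    {"ATA", "ATT", "ATG", "ATC", "TTG", "GTG", "TCG"})


@dataclass
class SkewReport:
    """Counts and skew statistics for one region."""

    label: str
    A: int
    C: int
    G: int
    T: int
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        return self.A + self.C + self.G + self.T + self.n_ambiguous

    @property
    def at_skew(self) -> Optional[float]:
        """(A - T)/(A + T); None when A + T == 0."""
        at = self.A + self.T
        return (self.A - self.T) / at if at else None

    @property
    def gc_skew(self) -> Optional[float]:
        gc = self.G + self.C
        return (self.G - self.C) / gc if gc else None

    @property
    def at_content(self) -> Optional[float]:
        """A+T percentage of unambiguous residues."""
        tot = self.A + self.C + self.G + self.T
        return 100.0 * (self.A + self.T) / tot if tot else None

    def as_row(self) -> dict:
        """Presentation row: percentages at 1 d.p., skews at 3 d.p."""
        return {
            "region": self.label, "A": self.A, "C": self.C, "G": self.G,
            "T": self.T,
            "AT%": None if self.at_content is None else round(self.at_content, 1),
            "AT_skew": None if self.at_skew is None else round(self.at_skew, 3),
            "GC_skew": None if self.gc_skew is None else round(self.gc_skew, 3),
        }


def skew(sequence: str, label: str = "") -> SkewReport:
    """Base counts and skews for a nucleotide string (N/ambiguity excluded)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper().replace("U", "T")
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return SkewReport(label=label, A=a, C=c, G=g, T=t,
                      n_ambiguous=len(s) - a - c - g - t)


def codon_position_composition(cds_set: Iterable[str],
                               label: str = "PCG") -> tuple[SkewReport, SkewReport, SkewReport]:
    """Per-codon-position composition aggregated over in-frame CDSs.

    Sequences must be in coding orientation, frame 0; trailing incomplete
    codons are dropped.  Returns SkewReports for positions 1, 2 and 3.
    """
    counts = [[0, 0, 0, 0] for _ in range(3)]  # A C G T per position
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ambiguous = [0, 0, 0]
    any_input = False
    for cds in cds_set:
        any_input = True
        s = cds.upper().replace("U", "T")
        n_codons = len(s) // 3
        if n_codons == 0:
            warnings.warn(f"sequence shorter than one codon skipped (length {len(s)})")
            continue
        for k in range(3 * n_codons):
            pos = k % 3
            j = idx.get(s[k])
            if j is None:
                ambiguous[pos] += 1
            else:
                counts[pos][j] += 1
    if not any_input:
        raise ValueError("no coding sequences supplied")
    return tuple(
        SkewReport(label=f"{label}_pos{p + 1}", A=counts[p][0], C=counts[p][1],
                   G=counts[p][2], T=counts[p][3], n_ambiguous=ambiguous[p])
        for p in range(3))


def _split_stop(cds: str, gene: str) -> tuple[str, str, bool]:
    """(start, stop, complete) for one coding sequence.

    Complete CDSs report their trailing codon; a length not divisible by
    three is legal only when the remainder is the incomplete stop "T" or
    "TA" (completed to TAA by polyadenylation).
    """
    s = cds.upper().replace("U", "T")
    if len(s) < 6:
        raise ValueError(f"{gene}: CDS too short ({len(s)} nt)")
    start = s[:3]
    rem = len(s) % 3
    if rem == 0:
        return start, s[-3:], True
    tail = s[-rem:]
    if tail in ("T", "TA"):
        return start, tail, False
    raise ValueError(
        f"{gene}: CDS length {len(s)} leaves trailing {tail!r}, "
        "not an incomplete stop (T/TA)")


def start_stop_table(genome: AnnotatedGenome) -> pd.DataFrame:
    """Start and stop codon per protein-coding gene.

    Stops of incomplete CDSs are reported as the literal residue(s)
    ("T" or "TA") with ``complete=False``.
    """
    rows = []
    for f in genome.features:
        if f.type != "PCG":
            continue
        cds = genome_io.extract_region(genome, f)
        start, stop, complete = _split_stop(cds, f.name)
        rows.append({"gene": f.name, "strand": f.strand, "start_codon": start,
                     "stop_codon": stop, "complete": complete,
                     "canonical_start": start in CANONICAL_STARTS})
    return pd.DataFrame(rows)


@dataclass
class CodonUsageTable:
    """Codon counts and relative synonymous codon usage.

    ``table`` holds one row per sense codon of the invertebrate
    mitochondrial code: codon, amino acid, count, rscu, absent.
    Within every synonymous family with a nonzero total the RSCU values
    average to 1; a codon has RSCU 0 iff it was never observed.
    """

    table: pd.DataFrame
    n_codons: int
    start_stop: Optional[pd.DataFrame] = field(default=None)

    def family(self, aa: str) -> pd.DataFrame:
        return self.table[self.table.aa == aa]


def rscu(cds_set: Iterable[str]) -> CodonUsageTable:
    """Relative synonymous codon usage over a set of in-frame CDSs.

    Stop codons and trailing incomplete codons are excluded from the
    counts.  RSCU(c) = count(c) * family_size / family_total.
    """
    counts: dict[str, int] = {}
    total = 0
    for cds in cds_set:
        s = cds.upper().replace("U", "T")
        for k in range(0, 3 * (len(s) // 3), 3):
            codon = s[k:k + 3]
            if codon in _STOP_CODONS or any(b not in "ACGT" for b in codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
            total += 1
    fwd = INVERTEBRATE_MITO_TABLE.forward_table
    families: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        families.setdefault(aa, []).append(codon)
    rows = []
    for aa in sorted(families):
        fam = sorted(families[aa])
        fam_total = sum(counts.get(c, 0) for c in fam)
        for codon in fam:
            n = counts.get(codon, 0)
            value = n * len(fam) / fam_total if fam_total else 0.0
            rows.append({"codon": codon, "aa": aa, "count": n,
                         "rscu": value, "absent": n == 0})
    return CodonUsageTable(table=pd.DataFrame(rows), n_codons=total)


def genome_skew_report(genome: AnnotatedGenome) -> pd.DataFrame:
    """Whole-genome plus per-region skew table (J-strand for the genome
    row, coding orientation for gene rows)."""
    reports = [skew(genome.sequence, label=f"{genome.id}:genome")]
    pcgs = [genome_io.extract_region(genome, f)
            for f in genome.features if f.type == "PCG"]
    if pcgs:
        reports.append(skew("".join(pcgs), label="PCG_all"))
        reports.extend(codon_position_composition(pcgs))
    return pd.DataFrame([r.as_row() for r in reports])
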