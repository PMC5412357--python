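"""Core data model for annotated mitochondrial genomes.

Coordinates are zero-based, half-open, on the majority (J) strand as
deposited.  A feature that wraps the origin of a circular molecule is
represented by an ordered pair of spans, never by rotating the sequence,
so deposited coordinates survive a read/write round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

COMPLEMENT = str.maketrans("ACGTUNRYKMSWBDHVacgtunrykmswbdhv",
                           "TGCAANYRMKSWVHDBtgcaanyrmkswvhdb")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control_region", "spacer")

#: IUPAC nucleotide ambiguity alphabet, residue set -> single letter.
IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_TO_SET = {v: set(k) for k, v in IUPAC_FROM_SET.items()}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (case preserved, U -> A)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated feature on a mitochondrial genome.

    ``spans`` is an ordered list of zero-based half-open intervals on the
    J-strand.  A single-interval feature has one span; an origin-wrapping
    feature on a circular genome has two, ``[(start, L), (0, end)]``.
    ``strand`` is ``"J"`` (majority) or ``"N"`` (minority).
    """

    name: str
    type: str
    strand: str
    spans: list[tuple[int, int]]
    anticodon: Optional[str] = None
    raw_name: Optional[str] = None
    inferred: bool = False  # set when the feature was deduced, not annotated

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be 'J' or 'N', got {self.strand!r}")
        if not self.spans:
            raise ValueError("feature needs at least one span")
        for s, e in self.spans:
            if e <= s:
                raise ValueError(f"empty or inverted span ({s}, {e})")

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    @property
    def wraps_origin(self) -> bool:
        return len(self.spans) > 1


@dataclass
class AnnotatedGenome:
    """A (typically circular) mitochondrial genome with its feature table."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.spans:
                if s < 0 or e > L:
                    raise ValueError(f"feature {f.name}: span ({s}, {e}) outside sequence of length {L}")
            if f.wraps_origin and self.topology != "circular":
                raise ValueError(f"feature {f.name} wraps the origin of a linear molecule")
            if f.length > L:
                raise ValueError(f"feature {f.name} longer than the genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in genome {self.id}")

    def features_sorted(self) -> list[GeneFeature]:
        """Features ordered by genomic start position."""
        return sorted(self.features, key=lambda f: (f.start, f.end))


def extract_region(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Feature sequence in coding orientation.

    J-strand features are returned as deposited; N-strand features are
    reverse-complemented.  Origin-wrapping spans are concatenated across
    the origin before orientation is applied.
    """
    L = len(genome.sequence)
    for s, e in feature.spans:
        if s < 0 or e > L:
            raise ValueError(f"span ({s}, {e}) outside sequence of length {L}")
    raw = "".join(genome.sequence[s:e] for s, e in feature.spans)
    return reverse_complement(raw) if feature.strand == "N" else raw


def iupac_code(residues: Iterable[str]) -> str:
    """IUPAC single-letter code for a set of nucleotide residues.

    Input letters may themselves be ambiguity codes; they are expanded
    to their residue sets first (so the operation is idempotent).
    U is treated as T.
    """
    expanded: set[str] = set()
    for r in residues:
        r = r.upper().replace("U", "T")
        try:
            expanded |= IUPAC_TO_SET[r]
        except KeyError:
            raise ValueError(f"not a nucleotide or IUPAC ambiguity code: {r!r}")
    if not expanded:
        raise ValueError("empty residue set")
    return IUPAC_FROM_SET[frozenset(expanded)]
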