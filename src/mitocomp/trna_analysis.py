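"""tRNA cloverleaf modeling, stem mismatch detection, and classification of
stem base-pair changes between homologous tRNAs.

Stem pairs are positional: the arm-boundary table fixes the expected stem
extents, and pair *k* of a stem couples the k-th base of the 5' strand
with the k-th base (from the outside) of the 3' strand, whether or not
the structure prediction drew a bond there.  Canonical pairs are the
Watson-Crick pairs plus the G-U wobble.  A change between two pairs at
the same stem position falls into exactly one of six categories:

identity   the same pair in both taxa
cbc        fully compensatory: both bases change, both pairs canonical
hemi_cbc   one base changes, both pairs canonical (e.g. G-U to A-U)
mbc        mirrored: the canonical pair is reversed (A-U to U-A), a cbc
           whose intermediate state is a non-canonical pair
rbc        reparative: exactly one of the two pairs is canonical
nrbc       non-reparative: neither pair is canonical

The comparison is undirected: category(a, b) == category(b, a).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO, Union

__all__ = ["Cloverleaf", "Arm", "StemPairChange", "TrnaComparison",
           "parse_cloverleaf", "find_mismatches", "classify_pair_change",
           "compare_trnas", "read_arm_table", "CANONICAL_PAIRS", "ARM_NAMES"]

ARM_NAMES = ("acceptor", "DHU", "anticodon", "TPSIC")
CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                             ("G", "U"), ("U", "G")})
_RNA = set("ACGU")


def _to_rna(base: str) -> str:
    b = base.upper().replace("T", "U")
    if b not in _RNA:
        raise ValueError(f"not a nucleotide: {base!r}")
    return b


@dataclass
class Arm:
    """One cloverleaf arm: ordered stem pair indices plus a loop range."""

    name: str
    stem_pairs: list[tuple[int, int]]  # (i, j), i < j, outermost first
    loop: tuple[int, int]  # half-open index range; empty for the acceptor

    @property
    def depth(self) -> int:
        return len(self.stem_pairs)


@dataclass
class Cloverleaf:
    """A tRNA with its arm-decomposed secondary structure (RNA alphabet)."""

    name: str
    sequence: str
    arms: dict[str, Arm]
    extra_arm: tuple[int, int] = (0, 0)
    anticodon: Optional[str] = None
    anticodon_span: Optional[tuple[int, int]] = None

    def stem_pair_bases(self, arm: str, k: int) -> tuple[str, str]:
        i, j = self.arms[arm].stem_pairs[k]
        return self.sequence[i], self.sequence[j]


@dataclass
class StemPairChange:
    """One positional stem comparison between a reference and another taxon."""

    trna: str
    arm: str
    position: int  # 1-based from the stem's 5' end
    pair_ref: tuple[str, str]
    pair_other: tuple[str, str]
    category: str
    canonical_in: str = ""  # "ref", "other", "both", "neither"


@dataclass
class TrnaComparison:
    changes: list[StemPairChange] = field(default_factory=list)
    surplus_ref: list[tuple[str, int, tuple[str, str]]] = field(default_factory=list)
    surplus_other: list[tuple[str, int, tuple[str, str]]] = field(default_factory=list)

    def histogram(self, include_identity: bool = False) -> dict[str, int]:
        h: dict[str, int] = {}
        for c in self.changes:
            if c.category == "identity" and not include_identity:
                continue
            h[c.category] = h.get(c.category, 0) + 1
        return h


def read_arm_table(path: Union[str, TextIO]) -> dict[str, dict]:
    """Parse an arm-boundary table (zero-based half-open coordinates).

    Columns: name, arm, stem5_start, stem5_end, stem3_start, stem3_end,
    loop_start, loop_end; the ``extra`` arm row carries only the loop
    range.  Returns {trna: {arm: row dict}}.
    """
    handle = open(path) if isinstance(path, str) else path
    try:
        rows = [r for r in csv.reader(handle, delimiter="\t")
                if r and not r[0].startswith("#")]
    finally:
        if isinstance(path, str):
            handle.close()
    table: dict[str, dict] = {}
    for name, arm, s5s, s5e, s3s, s3e, ls, le in rows:
        conv = lambda v: None if v == "." else int(v)
        table.setdefault(name, {})[arm] = dict(
            stem5=(conv(s5s), conv(s5e)), stem3=(conv(s3s), conv(s3e)),
            loop=(conv(ls), conv(le)))
    return table


def _parse_brackets(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def parse_cloverleaf(sequence: str, structure: str, arm_map: dict,
                     name: str = "tRNA") -> Cloverleaf:
    """Build a Cloverleaf from sequence, dot-bracket and an arm map.

    Stem pairs are taken positionally from the arm map's expected stem
    extents, so unpaired (mismatched) stem positions are retained as
    mismatch candidates.  The dot-bracket is validated: it must be
    balanced, match the sequence length, and every drawn bond must fall
    inside an expected stem.
    """
    if len(sequence) != len(structure):
        raise ValueError(
            f"{name}: sequence length {len(sequence)} != structure length {len(structure)}")
    seq = "".join(_to_rna(b) for b in sequence)
    drawn = _parse_brackets(structure)
    arms: dict[str, Arm] = {}
    for arm_name in ARM_NAMES:
        spec = arm_map[arm_name]
        (a5, b5), (a3, b3) = spec["stem5"], spec["stem3"]
        if (b5 - a5) != (b3 - a3):
            raise ValueError(f"{name}/{arm_name}: unequal stem strand lengths")
        pairs = [(a5 + k, b3 - 1 - k) for k in range(b5 - a5)]
        loop = spec["loop"] if spec["loop"][0] is not None else (0, 0)
        arms[arm_name] = Arm(name=arm_name, stem_pairs=pairs, loop=tuple(loop))
    expected = {p for arm in arms.values() for p in arm.stem_pairs}
    for p in drawn:
        if p not in expected:
            raise ValueError(f"{name}: drawn bond {p} outside expected stems")
    extra = arm_map.get("extra", {}).get("loop", (0, 0)) or (0, 0)
    ac_arm = arms["anticodon"]
    anticodon = anticodon_span = None
    if ac_arm.loop[1] - ac_arm.loop[0] >= 3:
        mid = (ac_arm.loop[0] + ac_arm.loop[1]) // 2
        anticodon_span = (mid - 1, mid + 2)
        anticodon = seq[anticodon_span[0]:anticodon_span[1]]
    return Cloverleaf(name=name, sequence=seq, arms=arms,
                      extra_arm=tuple(extra), anticodon=anticodon,
                      anticodon_span=anticodon_span)


def find_mismatches(cloverleaf: Cloverleaf) -> list[tuple[str, int, tuple[str, str]]]:
    """Every stem pair outside the canonical set {A-U, U-A, G-C, C-G, G-U, U-G}.

    Returns (arm, 1-based stem position, base pair) records in arm order.
    """
    out = []
    for arm_name in ARM_NAMES:
        arm = cloverleaf.arms[arm_name]
        for k in range(arm.depth):
            pair = cloverleaf.stem_pair_bases(arm_name, k)
            if pair not in CANONICAL_PAIRS:
                out.append((arm_name, k + 1, pair))
    return out


def classify_pair_change(pair_a: Sequence[str], pair_b: Sequence[str]) -> str:
    """Category of an undirected change between two stem base pairs."""
    a = (_to_rna(pair_a[0]), _to_rna(pair_a[1]))
    b = (_to_rna(pair_b[0]), _to_rna(pair_b[1]))
    if a == b:
        return "identity"
    can_a, can_b = a in CANONICAL_PAIRS, b in CANONICAL_PAIRS
    if can_a and can_b:
        changed = (a[0] != b[0]) + (a[1] != b[1])
        if changed == 1:
            return "hemi_cbc"
        if b == (a[1], a[0]):  # mirror test precedes the cbc fallback
            return "mbc"
        return "cbc"
    if can_a or can_b:
        return "rbc"
    return "nrbc"


def compare_trnas(ref: Cloverleaf, other: Cloverleaf) -> TrnaComparison:
    """Position-by-position stem comparison of two homologous cloverleaves.

    Stems are aligned by index from each stem's 5' end; positions beyond
    the shorter stem's depth are reported separately, never force-aligned.
    """
    if ref.name != other.name:
        raise ValueError(f"tRNA identity mismatch: {ref.name!r} vs {other.name!r}")
    result = TrnaComparison()
    for arm_name in ARM_NAMES:
        d_ref, d_other = ref.arms[arm_name].depth, other.arms[arm_name].depth
        for k in range(min(d_ref, d_other)):
            pa = ref.stem_pair_bases(arm_name, k)
            pb = other.stem_pair_bases(arm_name, k)
            cat = classify_pair_change(pa, pb)
            can_a, can_b = pa in CANONICAL_PAIRS, pb in CANONICAL_PAIRS
            canonical_in = {(True, True): "both", (True, False): "ref",
                            (False, True): "other", (False, False): "neither"}[(can_a, can_b)]
            result.changes.append(StemPairChange(
                trna=ref.name, arm=arm_name, position=k + 1, pair_ref=pa,
                pair_other=pb, category=cat, canonical_in=canonical_in))
        for k in range(min(d_ref, d_other), d_ref):
            result.surplus_ref.append((arm_name, k + 1, ref.stem_pair_bases(arm_name, k)))
        for k in range(min(d_ref, d_other), d_other):
            result.surplus_other.append((arm_name, k + 1, other.stem_pair_bases(arm_name, k)))
    return result
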