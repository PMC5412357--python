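"""Seeded generator of annotated mitochondrial genomes and alignment panels
with machine-readable truth sidecars.

The generator emulates a circular insect mt genome in the ancestral
37-gene order (23 J-strand / 14 N-strand): protein-coding genes are
sampled codon-wise from position-specific base frequencies (strongly
AT-biased third positions), tRNAs are instantiated from packaged
cloverleaf templates, conserved intergenic spacers are planted between
their flanking genes, and the control region carries planted poly-T /
(TA)n / poly-A stretches, non-tandem macro repeats and a 3' stem-loop.
Everything planted is recorded in a truth sidecar so downstream
detectors can be tested for exact recovery.  The seed fully determines
every emitted byte.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import AnnotatedGenome, GeneFeature, reverse_complement, IUPAC_TO_SET
from . import genome_io
from .control_region import CRElement, find_stem_loops, PAIRS

__all__ = ["GeneratorConfig", "SpacerPlant", "MismatchPlant", "PatternPlant",
           "CRPlantConfig", "TruthSidecar", "generate_genome",
           "generate_spacer_panel", "generate_inuc_alignment",
           "PanelConfig", "PanelResult", "generate_panel",
           "generate_group_panels", "load_cloverleaf_templates", "write_bundle"]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG"}

# Category -> (reference pair, variant pair) given a canonical WC template
# pair; nrbc requires the reference itself to hold a non-canonical pair.
_CBC = {("A", "T"): ("G", "C"), ("T", "A"): ("C", "G"),
        ("G", "C"): ("A", "T"), ("C", "G"): ("T", "A")}
_HEMI = {("A", "T"): ("G", "T"), ("T", "A"): ("T", "G"),
         ("G", "C"): ("G", "T"), ("C", "G"): ("T", "G")}


@dataclass
class SpacerPlant:
    """A conserved intergenic spacer to embed between two adjacent genes.

    ``sequence`` is given in the spacer's reported orientation (N when
    both flanking genes are N-strand, J otherwise); the generator places
    the appropriate strand on the genome.
    """

    up: str
    down: str
    sequence: str


@dataclass
class MismatchPlant:
    """A non-canonical stem pair planted into one genome's tRNA."""

    trna: str
    arm: str
    position: int  # 1-based from the stem's 5' end
    pair: tuple[str, str]  # DNA letters


@dataclass
class PatternPlant:
    """A stem base change of a given category planted into a panel taxon."""

    trna: str
    arm: str
    position: int
    category: str  # cbc | hemi_cbc | mbc | rbc | nrbc | identity
    taxon: int = 1  # index of the varying taxon (0 is the reference)


@dataclass
class CRPlantConfig:
    """Which structural elements to plant in the control region."""

    polyt_len: Optional[int] = 15
    ta_units: Optional[int] = 8
    polya_len: Optional[int] = 13
    stem_loop: Optional[tuple[int, int]] = (10, 6)  # (stem bp, loop nt)
    repeat_lens: tuple[int, ...] = (72, 36)
    repeat_seqs: Optional[tuple[str, ...]] = None  # overrides repeat_lens


@dataclass
class GeneratorConfig:
    seed: int = 0
    genome_length: int = 16300
    at_content: float = 0.765
    at_skew: Optional[float] = 0.0  # genome-wide J-strand target; None = free
    gc_skew: Optional[float] = None
    # per-codon-position composition of protein-coding genes (coding strand)
    codon_at: tuple[float, float, float] = (0.68, 0.66, 0.90)
    codon_at_skew: tuple[float, float, float] = (-0.09, -0.395, -0.03)
    codon_gc_skew: tuple[float, float, float] = (0.24, -0.15, -0.12)
    spacer_plants: Optional[list[SpacerPlant]] = None  # None = defaults
    mismatch_plants: list[MismatchPlant] = field(default_factory=lambda: [
        MismatchPlant("tRNA-Arg", "acceptor", 5, ("T", "T")),
        MismatchPlant("tRNA-Val", "TPSIC", 2, ("T", "T")),
    ])
    cr: CRPlantConfig = field(default_factory=CRPlantConfig)
    genome_id: str = "SYN0001"


#: Conserved spacer consensus motifs (IUPAC), reported orientation.
SPACER_MOTIFS = {
    ("tRNA-Glu", "tRNA-Phe"): "ACTWAWWWWAWTTMWHWA",
    ("tRNA-Ser(UCN)", "ND1"): "TATBAAWWWWWWWTAGTA",
    ("tRNA-His", "ND5"): "GTGAAWWWTTTATCM",
}


@dataclass
class SpacerTruth:
    up: str
    down: str
    sequence: str  # in reported orientation (what extract_spacer returns)
    orientation: str
    genomic_span: tuple[int, int]


@dataclass
class TruthSidecar:
    genome_id: str = ""
    targets: dict = field(default_factory=dict)
    spacers: list[SpacerTruth] = field(default_factory=list)
    cr_elements: list[CRElement] = field(default_factory=list)
    cr_span: Optional[tuple[int, int]] = None
    trna_mismatches: list[MismatchPlant] = field(default_factory=list)
    trna_structures: dict = field(default_factory=dict)  # trna -> (seq, struct, arm_map)
    pattern_plants: list[PatternPlant] = field(default_factory=list)
    gene_truth: dict = field(default_factory=dict)  # per-gene extras


# ---------------------------------------------------------------------------
# Packaged templates
# ---------------------------------------------------------------------------

def load_cloverleaf_templates() -> dict[str, dict]:
    """Packaged cloverleaf templates: {name: {sequence, structure, anticodon,
    arms}} with arm maps in the format parse_cloverleaf expects."""
    from .trna_analysis import read_arm_table
    from io import StringIO
    data = resources.files("mitocomp.data")
    arms = read_arm_table(StringIO(data.joinpath("cloverleaf_arms.tsv").read_text()))
    out: dict[str, dict] = {}
    for line in data.joinpath("cloverleaf_templates.tsv").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        name, anticodon, ac_start, seq, struct = line.split("\t")
        out[name] = dict(sequence=seq, structure=struct, anticodon=anticodon,
                         anticodon_start=int(ac_start), arms=arms[name])
    return out


def _arm_pair_indices(arm_map: dict, arm: str, position: int) -> tuple[int, int]:
    (a5, b5), (a3, b3) = arm_map[arm]["stem5"], arm_map[arm]["stem3"]
    depth = b5 - a5
    if not (1 <= position <= depth):
        raise ValueError(f"stem position {position} outside depth {depth} of {arm}")
    k = position - 1
    return a5 + k, b3 - 1 - k


def _apply_pair(seq: list[str], struct: list[str], i: int, j: int,
                pair: tuple[str, str]) -> None:
    seq[i], seq[j] = pair
    if (pair[0].replace("T", "U"), pair[1].replace("T", "U")) not in {
            ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}:
        struct[i], struct[j] = ".", "."


# ---------------------------------------------------------------------------
# Sequence sampling helpers
# ---------------------------------------------------------------------------

def _pos_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    gc = 1.0 - at
    p = np.array([at * (1 + at_skew) / 2, gc * (1 - gc_skew) / 2,
                  gc * (1 + gc_skew) / 2, at * (1 - at_skew) / 2])  # A C G T
    if (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("infeasible composition/skew targets")
    return p


def _sample_codons(n: int, probs: list[np.ndarray], rng: np.random.Generator) -> list[str]:
    cols = [rng.choice(_BASES, size=n, p=probs[k]) for k in range(3)]
    codons = ["".join(t) for t in zip(*cols)]
    # in-frame stops: redraw only the third base over the legal {C, T}
    # continuations, which barely perturbs the position-3 A+T target
    p3 = probs[2]
    p_ct = np.array([p3[1], p3[3]]) / (p3[1] + p3[3])
    for idx, c in enumerate(codons):
        if c in _STOPS:
            codons[idx] = c[:2] + rng.choice(["C", "T"], p=p_ct)
    return codons


def _spacer_realization(motif: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC_TO_SET[c])[rng.integers(len(IUPAC_TO_SET[c]))]
                   for c in motif)


def _random_seq(n: int, rng: np.random.Generator, p_at: float = 0.8) -> str:
    probs = np.array([p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2])
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _break_runs(s: list[str], rng: np.random.Generator,
                max_homopolymer: int = 7, max_ta: int = 5) -> None:
    """Break long A/T homopolymer runs and (TA)n runs in place (with C/G)."""
    changed = True
    while changed:
        changed = False
        run = 1
        for i in range(1, len(s) + 1):
            if i < len(s) and s[i] == s[i - 1] and s[i] in "AT":
                run += 1
            else:
                if run > max_homopolymer:
                    s[i - 1 - run // 2] = "C" if rng.integers(2) else "G"
                    changed = True
                run = 1
        run = 1
        for i in range(2, len(s)):
            if s[i] == s[i - 2] and s[i] != s[i - 1] and {s[i], s[i - 1]} == {"A", "T"}:
                run += 1
                if run > max_ta:
                    s[i] = "C" if rng.integers(2) else "G"
                    run = 1
                    changed = True
            else:
                run = 1


def _clean_repeat_unit(n: int, rng: np.random.Generator) -> str:
    s = list(_random_seq(n, rng, p_at=0.8))
    _break_runs(s, rng, max_homopolymer=5, max_ta=2)
    return "".join(s)


def _stem_loop_seq(stem: int, loop: int) -> str:
    """Deterministic planted hairpin: GC-biased stem, non-self-pairing loop."""
    fives = ([("G", "C"), ("C", "G"), ("G", "C"), ("A", "T")] * ((stem + 3) // 4))[:stem]
    stem5 = "".join(p[0] for p in fives)
    stem3 = "".join(p[1] for p in reversed(fives))
    loop_seq = ("AAC" * ((loop + 2) // 3))[:loop]
    if loop >= 2 and (loop_seq[0], loop_seq[-1]) in PAIRS:
        loop_seq = "A" + loop_seq[1:]
    return stem5 + loop_seq + stem3


# ---------------------------------------------------------------------------
# Control region assembly
# ---------------------------------------------------------------------------

def _build_control_region(length: int, cfg: CRPlantConfig, background: str,
                          rng: np.random.Generator) -> tuple[str, list[CRElement]]:
    """Assemble a control region of exactly ``length`` nt with planted
    elements at recorded coordinates; the rest comes from ``background``."""
    if cfg.repeat_seqs is not None:
        repeats = [r.upper() for r in cfg.repeat_seqs]
    else:
        repeats = [_clean_repeat_unit(n, rng) for n in cfg.repeat_lens]
    plants: list[tuple[str, str, dict]] = []  # (kind, sequence, detail)
    for k, r in enumerate(repeats):  # first copies
        plants.append((f"repeat{k}a", r, {}))
    if cfg.polyt_len:
        plants.append(("polyT", "T" * cfg.polyt_len, {}))
    if cfg.ta_units:
        plants.append(("TA_stretch", "TA" * cfg.ta_units,
                       {"units": cfg.ta_units, "phase": "T"}))
    for k, r in enumerate(repeats):  # second copies
        plants.append((f"repeat{k}b", r, {}))
    if cfg.polya_len:
        plants.append(("polyA", "A" * cfg.polya_len, {}))
    if cfg.stem_loop:
        stem, loop = cfg.stem_loop
        plants.append(("stem_loop", _stem_loop_seq(stem, loop),
                       {"stem": stem, "loop": loop}))
    total_plants = sum(len(p[1]) for p in plants)
    n_gaps = len(plants) + 1
    min_gap = 25
    bg_total = length - total_plants
    if bg_total < n_gaps * min_gap:
        raise ValueError(
            f"control region of {length} nt too short for planted elements "
            f"({total_plants} nt plants + {n_gaps * min_gap} nt spacing)")
    base, extra = divmod(bg_total, n_gaps)
    gap_lens = [base + (1 if i < extra else 0) for i in range(n_gaps)]
    bg = list(background[:bg_total])
    _break_runs(bg, rng)

    parts: list[str] = []
    elements: list[CRElement] = []
    pos = 0
    bg_i = 0
    repeat_spans: dict[str, list[tuple[int, int]]] = {}
    protected: set[int] = set()

    def take_bg(n: int) -> str:
        nonlocal bg_i
        chunk = "".join(bg[bg_i:bg_i + n])
        bg_i += n
        return chunk

    for gi, (kind, seq_p, detail) in enumerate(plants):
        gap = take_bg(gap_lens[gi])
        parts.append(gap)
        pos += len(gap)
        span = (pos, pos + len(seq_p))
        parts.append(seq_p)
        protected.update(range(*span))
        pos += len(seq_p)
        if kind.startswith("repeat"):
            repeat_spans.setdefault(kind[:-1], []).append(span)
        elif kind == "stem_loop":
            elements.append(CRElement(kind="stem_loop", spans=[span],
                                      length=len(seq_p), detail=dict(detail)))
        else:
            elements.append(CRElement(kind=kind, spans=[span],
                                      length=len(seq_p), detail=dict(detail)))
    parts.append(take_bg(gap_lens[-1]))
    cr = list("".join(parts))
    assert len(cr) == length

    for key in sorted(repeat_spans):
        spans = repeat_spans[key]
        elements.append(CRElement(kind="macro_repeat", spans=spans,
                                  length=spans[0][1] - spans[0][0],
                                  detail={"n_copies": len(spans)}))

    # guard characters so planted elements are exactly maximal
    def set_guard(i: int, avoid: set[str], prefer: str = "C") -> None:
        if 0 <= i < len(cr):
            if cr[i] in avoid:
                cr[i] = prefer if prefer not in avoid else "G"
            protected.add(i)

    for el in elements:
        for s, e in el.spans:
            if el.kind == "polyT":
                set_guard(s - 1, {"T"})
                set_guard(e, {"T"})
            elif el.kind == "polyA":
                set_guard(s - 1, {"A"})
                set_guard(e, {"A"})
            elif el.kind == "TA_stretch":
                set_guard(s - 1, {"A", "T"})
                set_guard(e, {"A", "T"})
            elif el.kind == "stem_loop":
                # same base never pairs with itself, so copying the 3' flank
                # into the 5' flank blocks outward stem extension
                if s - 1 >= 0 and e < len(cr) and (cr[s - 1], cr[e]) in PAIRS:
                    cr[s - 1] = cr[e]
                protected.update(i for i in (s - 1, e) if 0 <= i < len(cr))
        if el.kind == "macro_repeat":
            # differing flanks between copies keep the repeat maximal
            (s1, e1), (s2, e2) = el.spans[:2]
            if s1 - 1 >= 0:
                cr[s1 - 1] = "C"
                protected.add(s1 - 1)
            cr[s2 - 1] = "G"
            protected.add(s2 - 1)
            cr[e1] = "C"
            protected.add(e1)
            if e2 < len(cr):
                cr[e2] = "G"
                protected.add(e2)

    # scrub accidental hairpins from the background (planted elements keep
    # theirs; a hairpin inside a plant is reported as part of that element)
    sl_span = next((el.spans[0] for el in elements if el.kind == "stem_loop"), None)
    plant_spans = [sp for el in elements for sp in el.spans]
    for _ in range(300):
        dirty = False
        for hp in find_stem_loops("".join(cr), 6, (3, 20)):
            s, e = hp.spans[0]
            if (s, e) == sl_span:
                continue
            if any(ps <= s and e <= pe for ps, pe in plant_spans):
                continue
            stem = hp.detail["stem"]
            cand = [i for i in list(range(s, s + stem)) + list(range(e - stem, e))
                    if i not in protected]
            if not cand:
                continue
            i = cand[rng.integers(len(cand))]
            # partner index of i within this hairpin
            j = (e - 1) - (i - s) if i < s + stem else (s + (e - 1 - i))
            for b in "CGAT":
                if b != cr[i] and (b, cr[j]) not in PAIRS and (cr[j], b) not in PAIRS:
                    cr[i] = b
                    break
            dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("control-region hairpin scrub did not converge")
    return "".join(cr), elements


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _default_spacer_plants(rng: np.random.Generator) -> list[SpacerPlant]:
    return [SpacerPlant(up, down, _spacer_realization(motif, rng))
            for (up, down), motif in SPACER_MOTIFS.items()]


def _counts(seq: str) -> np.ndarray:
    return np.array([seq.count(b) for b in "ACGT"])


def generate_genome(cfg: GeneratorConfig) -> tuple[AnnotatedGenome, TruthSidecar]:
    """Generate one annotated genome plus its truth sidecar.

    The seed fully determines the output; identical configs give
    byte-identical genomes.  Composition targets are met by constructing
    the free (rRNA + control-region) background as an exact base multiset
    solving the genome-wide A+T and AT-skew targets, so the realized A+T
    content lands within about one percentage point of the target.
    """
    rng = np.random.default_rng(cfg.seed)
    order = genome_io.ancestral_order_table()
    templates = load_cloverleaf_templates()
    probs = [_pos_probs(cfg.codon_at[k], cfg.codon_at_skew[k], cfg.codon_gc_skew[k])
             for k in range(3)]

    # --- fixed parts -------------------------------------------------------
    gene_seqs: dict[str, str] = {}
    trna_structs: dict[str, tuple[str, str, dict]] = {}
    truth = TruthSidecar(genome_id=cfg.genome_id)
    for row in order:
        if row["type"] == "PCG":
            body_nt = row["length"] - 3 - len(row["stop"])
            codons = _sample_codons(body_nt // 3, probs, rng)
            gene_seqs[row["name"]] = row["start"] + "".join(codons) + row["stop"]
            truth.gene_truth[row["name"]] = {"start": row["start"], "stop": row["stop"]}
        elif row["type"] == "tRNA":
            t = templates[row["name"]]
            seq, struct = list(t["sequence"]), list(t["structure"])
            for mp in cfg.mismatch_plants:
                if mp.trna == row["name"]:
                    i, j = _arm_pair_indices(t["arms"], mp.arm, mp.position)
                    _apply_pair(seq, struct, i, j, mp.pair)
            gene_seqs[row["name"]] = "".join(seq)
            trna_structs[row["name"]] = ("".join(seq), "".join(struct), t["arms"])
    truth.trna_structures = trna_structs
    truth.trna_mismatches = list(cfg.mismatch_plants)

    spacer_plants = (cfg.spacer_plants if cfg.spacer_plants is not None
                     else _default_spacer_plants(rng))
    strand_of = {row["name"]: row["strand"] for row in order}
    order_names = [row["name"] for row in order]

    def genomic_spacer(plant: SpacerPlant) -> tuple[str, str, str]:
        """(genomic sequence, first flank in genome order, orientation)."""
        su, sd = strand_of[plant.up], strand_of[plant.down]
        both_n = su == "N" and sd == "N"
        iu, id_ = order_names.index(plant.up), order_names.index(plant.down)
        if (iu + 1) % len(order_names) == id_:
            first = plant.up
        elif (id_ + 1) % len(order_names) == iu:
            first = plant.down
        else:
            raise ValueError(f"spacer flanks {plant.up}/{plant.down} not adjacent")
        genomic = reverse_complement(plant.sequence) if both_n else plant.sequence
        return genomic, first, ("N" if both_n else "J")

    spacer_after: dict[str, tuple[SpacerPlant, str, str]] = {}
    for plant in spacer_plants:
        genomic, first, orient = genomic_spacer(plant)
        spacer_after[first] = (plant, genomic, orient)

    # repeats for the control region are drawn before the budget is solved
    cr_cfg = cfg.cr
    if cr_cfg.repeat_seqs is None and cr_cfg.repeat_lens:
        cr_cfg = replace(cr_cfg, repeat_seqs=tuple(
            _clean_repeat_unit(n, rng) for n in cr_cfg.repeat_lens))

    cr_plants_seq = ("".join(cr_cfg.repeat_seqs or ()) * 2
                     + "T" * (cr_cfg.polyt_len or 0) + "A" * (cr_cfg.polya_len or 0)
                     + "TA" * (cr_cfg.ta_units or 0)
                     + (_stem_loop_seq(*cr_cfg.stem_loop) if cr_cfg.stem_loop else ""))
    cr_plant_nt = len(cr_plants_seq)

    # --- fixed composition (genes, spacers, finished control region) -------
    fixed = np.zeros(4, dtype=int)  # A C G T as placed on the J-strand
    fixed_len = 0
    for row in order:
        name = row["name"]
        if row["type"] in ("PCG", "tRNA"):
            s = gene_seqs[name]
            c = _counts(s)
            if row["strand"] == "N":
                c = c[::-1]  # revcomp swaps A<->T and C<->G
            fixed += c
            fixed_len += len(s)
    for plant, genomic, _ in spacer_after.values():
        fixed += _counts(genomic)
        fixed_len += len(genomic)

    rrna_len = sum(row["length"] for row in order if row["type"] == "rRNA")
    cr_len = cfg.genome_length - fixed_len - rrna_len
    if cr_len < cr_plant_nt:
        raise ValueError("genome_length too small for the configured genes")
    # aim the control-region background at the overall A+T target so the
    # rRNA pool (solved exactly below) stays inside [0, 1]
    cr_bg_len = cr_len - cr_plant_nt
    free_at_needed = (cfg.at_content * cfg.genome_length
                      - float(fixed[0] + fixed[3]) - _counts(cr_plants_seq)[[0, 3]].sum())
    p_at_cr = float(np.clip(free_at_needed / max(cr_bg_len + rrna_len, 1),
                            0.05, 0.95))
    cr_background = _random_seq(cr_bg_len, rng, p_at=p_at_cr)
    cr_seq, cr_elements = _build_control_region(cr_len, cr_cfg, cr_background, rng)
    fixed += _counts(cr_seq)

    # --- rRNA background solves the genome-wide composition targets exactly
    R = rrna_len
    at_total = round(cfg.at_content * cfg.genome_length)
    n_at = at_total - int(fixed[0] + fixed[3])
    n_gc = R - n_at
    if not (0 <= n_at <= R):
        raise ValueError("infeasible A+T target for this gene complement")
    if cfg.at_skew is not None:
        delta = cfg.at_skew * at_total - int(fixed[0] - fixed[3])
        n_a = round((n_at + delta) / 2)
    else:
        n_a = n_at // 2
    if cfg.gc_skew is not None:
        gc_total = cfg.genome_length - at_total
        delta_gc = cfg.gc_skew * gc_total - int(fixed[2] - fixed[1])
        n_g = round((n_gc + delta_gc) / 2)
    else:
        n_g = n_gc // 2
    if not (0 <= n_a <= n_at and 0 <= n_g <= n_gc):
        raise ValueError("infeasible skew target for this gene complement")
    pool = np.concatenate([
        np.repeat("A", n_a), np.repeat("T", n_at - n_a),
        np.repeat("G", n_g), np.repeat("C", n_gc - n_g)])
    background = "".join(rng.permutation(pool))

    # rRNAs take the solved background (N-strand: the genome slice is the
    # background itself, so the solved J-strand counts apply directly)
    cursor = 0
    for row in order:
        if row["type"] == "rRNA":
            gene_seqs[row["name"]] = reverse_complement(
                background[cursor:cursor + row["length"]])
            cursor += row["length"]

    # --- assembly ----------------------------------------------------------
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for row in order:
        name = row["name"]
        if row["type"] == "control_region":
            seq_j = cr_seq
            features.append(GeneFeature(name="CR", type="control_region",
                                        strand="J", spans=[(pos, pos + len(seq_j))]))
            truth.cr_span = (pos, pos + len(seq_j))
        else:
            coding = gene_seqs[name]
            seq_j = reverse_complement(coding) if row["strand"] == "N" else coding
            anticodon = (templates[name]["anticodon"]
                         if row["type"] == "tRNA" else None)
            features.append(GeneFeature(name=name, type=row["type"],
                                        strand=row["strand"],
                                        spans=[(pos, pos + len(seq_j))],
                                        anticodon=anticodon))
        parts.append(seq_j)
        pos += len(seq_j)
        if name in spacer_after:
            plant, genomic, orient = spacer_after[name]
            truth.spacers.append(SpacerTruth(
                up=plant.up, down=plant.down, sequence=plant.sequence,
                orientation=orient, genomic_span=(pos, pos + len(genomic))))
            parts.append(genomic)
            pos += len(genomic)
    sequence = "".join(parts)
    assert len(sequence) == cfg.genome_length, (len(sequence), cfg.genome_length)
    truth.cr_elements = cr_elements
    truth.targets = {"at_content": cfg.at_content, "at_skew": cfg.at_skew,
                     "gc_skew": cfg.gc_skew, "codon_at": cfg.codon_at,
                     "genome_length": cfg.genome_length}
    genome = AnnotatedGenome(id=cfg.genome_id, sequence=sequence,
                             features=features, topology="circular",
                             description="synthetic mitochondrial genome")
    return genome, truth


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def generate_spacer_panel(motif: str, n_rows: int = 5, seed: int = 0,
                          extensions: Optional[dict[int, tuple[str, str]]] = None) -> list[str]:
    """Spacer sequences whose per-column residue sets equal the motif's
    IUPAC sets exactly (so the presence-set consensus reproduces the motif
    letter for letter).

    Columns are realized the way conserved spacer panels look in practice:
    one majority residue shared by most rows, with each alternative
    residue of the column's set carried by a single deviant row (an
    ambiguity letter usually reflects one deviant taxon).  ``extensions``
    optionally adds per-row terminal sequence, emulating lineage-specific
    flanking residues."""
    rng = np.random.default_rng(seed)
    sets = [sorted(IUPAC_TO_SET[c]) for c in motif.upper()]
    if n_rows < max(len(s) for s in sets):
        raise ValueError("not enough rows to cover every column's residue set")
    rows = [[""] * len(sets) for _ in range(n_rows)]
    for j, S in enumerate(sets):
        majority = S[rng.integers(len(S))]
        for r in range(n_rows):
            rows[r][j] = majority
        deviants = rng.choice(n_rows, size=len(S) - 1, replace=False)
        for r, residue in zip(deviants, [b for b in S if b != majority]):
            rows[r][j] = residue
    out = ["".join(r) for r in rows]
    if extensions:
        out = [(extensions.get(i, ("", ""))[0] + s + extensions.get(i, ("", ""))[1])
               for i, s in enumerate(out)]
    return out


def generate_inuc_alignment(n_rows: int, n_cols: int, n_identical: int,
                            seed: int = 0, at: float = 0.8,
                            taxa: Optional[Sequence[str]] = None) -> list[tuple[str, str]]:
    """Gap-free alignment with exactly ``n_identical`` conserved columns."""
    if not (0 <= n_identical <= n_cols):
        raise ValueError("n_identical outside [0, n_cols]")
    if n_rows < 2:
        raise ValueError("need >= 2 rows")
    rng = np.random.default_rng(seed)
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    ident_cols = set(rng.choice(n_cols, size=n_identical, replace=False).tolist())
    cols = []
    for j in range(n_cols):
        base = rng.choice(_BASES, p=probs)
        col = [base] * n_rows
        if j not in ident_cols:
            r = rng.integers(n_rows)
            others = [b for b in "ACGT" if b != base]
            col[r] = others[rng.integers(3)]
        cols.append(col)
    names = list(taxa) if taxa else [f"taxon{i + 1:02d}" for i in range(n_rows)]
    return [(names[i], "".join(cols[j][i] for j in range(n_cols)))
            for i in range(n_rows)]


@dataclass
class PanelConfig:
    seed: int = 0
    n_taxa: int = 5
    genes: Optional[list[tuple[str, str]]] = None  # (gene, strand); None = 22 tRNAs
    n_cols: int = 100
    inuc_at_correlation: float = 0.2
    inuc_mean: float = 55.0
    inuc_sd: float = 12.0
    at_mean: float = 80.0
    at_sd: float = 5.0
    pattern_plants: list[PatternPlant] = field(default_factory=list)


@dataclass
class PanelResult:
    taxa: list[str]
    alignments: dict[str, list[tuple[str, str]]]
    gene_strand: dict[str, str]
    cloverleaves: dict[str, dict[str, tuple[str, str, dict]]]  # taxon -> trna -> (seq, struct, arms)
    truth: TruthSidecar


def _planted_pairs(template_pair: tuple[str, str], category: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """(reference pair, variant pair) realizing a category from a WC pair."""
    p = template_pair
    if category == "identity":
        return p, p
    if category == "cbc":
        return p, _CBC[p]
    if category == "hemi_cbc":
        return p, _HEMI[p]
    if category == "mbc":
        return p, (p[1], p[0])
    if category == "rbc":
        return p, (p[0], p[0])
    if category == "nrbc":
        return ("T", "T"), ("T", "C")
    raise ValueError(f"unknown category {category!r}")


def generate_panel(cfg: PanelConfig) -> PanelResult:
    """Per-gene alignments with controlled conservation/composition plus a
    cloverleaf panel with planted stem changes of each requested category."""
    if cfg.n_taxa < 2:
        raise ValueError("panel needs >= 2 taxa")
    rng = np.random.default_rng(cfg.seed)
    templates = load_cloverleaf_templates()
    if cfg.genes is None:
        order = genome_io.ancestral_order_table()
        genes = [(r["name"], r["strand"]) for r in order if r["type"] == "tRNA"]
    else:
        genes = cfg.genes
    taxa = [f"taxon{i + 1:02d}" for i in range(cfg.n_taxa)]

    r = cfg.inuc_at_correlation
    cov = np.array([[cfg.inuc_sd ** 2, r * cfg.inuc_sd * cfg.at_sd],
                    [r * cfg.inuc_sd * cfg.at_sd, cfg.at_sd ** 2]])
    draws = rng.multivariate_normal([cfg.inuc_mean, cfg.at_mean], cov,
                                    size=len(genes))
    truth = TruthSidecar(genome_id="panel")
    alignments: dict[str, list[tuple[str, str]]] = {}
    gene_strand: dict[str, str] = {}
    for (gene, strand), (inuc_t, at_t) in zip(genes, draws):
        inuc_t = float(np.clip(inuc_t, 2.0, 99.0))
        at_t = float(np.clip(at_t, 55.0, 98.0))
        k = int(round(inuc_t / 100 * cfg.n_cols))
        alignments[gene] = generate_inuc_alignment(
            cfg.n_taxa, cfg.n_cols, k, seed=int(rng.integers(2 ** 31)),
            at=at_t / 100, taxa=taxa)
        gene_strand[gene] = strand
        truth.gene_truth[gene] = {"n_identical": k, "inuc_target": inuc_t,
                                  "at_target": at_t, "strand": strand}

    cloverleaves: dict[str, dict[str, tuple[str, str, dict]]] = {t: {} for t in taxa}
    for t_idx, taxon in enumerate(taxa):
        for name, tpl in templates.items():
            cloverleaves[taxon][name] = (tpl["sequence"], tpl["structure"],
                                         tpl["arms"])
    for plant in cfg.pattern_plants:
        tpl = templates[plant.trna]
        i, j = _arm_pair_indices(tpl["arms"], plant.arm, plant.position)
        ref_pair, var_pair = _planted_pairs(
            (tpl["sequence"][i], tpl["sequence"][j]), plant.category)
        for t_idx, taxon in enumerate(taxa):
            pair = var_pair if t_idx == plant.taxon else ref_pair
            seq, struct, arms = cloverleaves[taxon][plant.trna]
            s_l, d_l = list(seq), list(struct)
            _apply_pair(s_l, d_l, i, j, pair)
            cloverleaves[taxon][plant.trna] = ("".join(s_l), "".join(d_l), arms)
    truth.pattern_plants = list(cfg.pattern_plants)
    return PanelResult(taxa=taxa, alignments=alignments,
                       gene_strand=gene_strand, cloverleaves=cloverleaves,
                       truth=truth)


def generate_group_panels(group_specs: dict[str, tuple[int, float]],
                          n_genes: int = 6, n_cols: int = 100,
                          seed: int = 0) -> tuple[dict, dict[str, str]]:
    """Per-group alignment panels with exact planted mean %INUC.

    ``group_specs`` maps group name to (n_taxa, mean %INUC).  Returns
    ({(group, gene): alignment rows}, taxon->group map).  The per-gene
    identical-column counts are symmetric around the target so the group
    mean is exact (requires the mean to be a whole number of columns).
    """
    rng = np.random.default_rng(seed)
    panels = {}
    grouping: dict[str, str] = {}
    for g_idx, (group, (n_taxa, mean_inuc)) in enumerate(sorted(group_specs.items())):
        k_mean = mean_inuc / 100 * n_cols
        if abs(k_mean - round(k_mean)) > 1e-9:
            raise ValueError(f"group {group}: mean {mean_inuc} not representable "
                             f"in {n_cols} columns")
        k_mean = int(round(k_mean))
        taxa = [f"{group}_t{i + 1}" for i in range(n_taxa)]
        for t in taxa:
            grouping[t] = group
        offsets = [(i - (n_genes - 1) / 2) for i in range(n_genes)]
        ks = [int(k_mean + round(o)) for o in offsets]
        adjust = n_genes * k_mean - sum(ks)
        ks[0] += adjust
        for gene_i, k in enumerate(ks):
            if not (0 <= k <= n_cols):
                raise ValueError("planted mean too extreme for alignment length")
            panels[(group, f"gene{gene_i + 1}")] = generate_inuc_alignment(
                n_taxa, n_cols, k, seed=int(rng.integers(2 ** 31)), taxa=taxa)
    return panels, grouping


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(genome: AnnotatedGenome, truth: TruthSidecar, outdir) -> None:
    """Emit GenBank + FASTA + tRNA structure sidecars + truth TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome_io.write_genbank(genome, str(out / f"{genome.id}.gb"))
    genome_io.write_fasta([(genome.id, genome.sequence)],
                          str(out / f"{genome.id}.fasta"))
    with open(out / f"{genome.id}.trna_structures.tsv", "w") as fh:
        fh.write("# trna\tsequence\tstructure\n")
        for name, (seq, struct, _) in truth.trna_structures.items():
            fh.write(f"{name}\t{seq}\t{struct}\n")
    with open(out / f"{genome.id}.truth.tsv", "w") as fh:
        fh.write("# section\tname\tdetail\n")
        for key, val in truth.targets.items():
            fh.write(f"target\t{key}\t{val}\n")
        for sp in truth.spacers:
            fh.write(f"spacer\t{sp.up}|{sp.down}\t{sp.sequence}\t"
                     f"{sp.orientation}\t{sp.genomic_span[0]}\t{sp.genomic_span[1]}\n")
        for el in truth.cr_elements:
            spans = ";".join(f"{s}-{e}" for s, e in el.spans)
            fh.write(f"cr_element\t{el.kind}\t{spans}\n")
        for mp in truth.trna_mismatches:
            fh.write(f"trna_mismatch\t{mp.trna}\t{mp.arm}\t{mp.position}\t"
                     f"{mp.pair[0]}{mp.pair[1]}\n")
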