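"""Read/write annotated mitochondrial genomes and normalize annotations.

GenBank flat files are parsed with Biopython; 1-based inclusive GenBank
coordinates become zero-based half-open internally.  Gene names are
normalized to canonical symbols (13 protein-coding genes, 22 tRNAs with
isoacceptor suffixes for Leu and Ser, two rRNAs, ``CR`` for the control
region) via a packaged synonym table.
"""

from __future__ import annotations

import csv
import re
import warnings
from importlib import resources

from typing import Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import AnnotatedGenome, GeneFeature, extract_region  # noqa: F401

__all__ = [
    "read_genbank", "write_genbank", "read_fasta", "write_fasta",
    "read_feature_table", "write_feature_table", "normalize_gene_name",
    "strand_census", "gene_order_signature", "compare_gene_order",
    "ancestral_gene_order", "extract_region", "infer_control_region",
    "CANONICAL_GENES", "PCG_NAMES", "TRNA_NAMES", "RRNA_NAMES",
]

PCG_NAMES = ("ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND5",
             "ND4", "ND4L", "ND6", "CYTB", "ND1")
RRNA_NAMES = ("lrRNA", "srRNA")
TRNA_NAMES = (
    "tRNA-Ile", "tRNA-Gln", "tRNA-Met", "tRNA-Trp", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Leu(UUR)", "tRNA-Lys", "tRNA-Asp", "tRNA-Gly", "tRNA-Ala",
    "tRNA-Arg", "tRNA-Asn", "tRNA-Ser(AGN)", "tRNA-Glu", "tRNA-Phe",
    "tRNA-His", "tRNA-Thr", "tRNA-Pro", "tRNA-Ser(UCN)", "tRNA-Leu(CUN)",
    "tRNA-Val",
)
#: The 37 canonical mitochondrial genes (control region excluded).
CANONICAL_GENES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES

_FEATURE_KEY_TO_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                        "D-loop": "control_region"}
_TYPE_TO_FEATURE_KEY = {v: k for k, v in _FEATURE_KEY_TO_TYPE.items()}

# Anticodon -> Leu/Ser isoacceptor, for records that annotate plain "tRNA-Leu".
_ISOACCEPTOR_BY_ANTICODON = {
    ("tRNA-Leu", "TAA"): "tRNA-Leu(UUR)", ("tRNA-Leu", "TAG"): "tRNA-Leu(CUN)",
    ("tRNA-Ser", "GCT"): "tRNA-Ser(AGN)", ("tRNA-Ser", "TGA"): "tRNA-Ser(UCN)",
}


def _norm_key(raw: str) -> str:
    return re.sub(r"[\s\-_]+", "", raw).lower()


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")
        table[_norm_key(raw)] = canonical
    for name in CANONICAL_GENES + ("CR",):
        table.setdefault(_norm_key(name), name)
    return table


_SYNONYMS = _load_synonyms()


def normalize_gene_name(raw: str, anticodon: Optional[str] = None) -> Optional[str]:
    """Canonical gene symbol for ``raw``, or None if unrecognized.

    A bare Leu/Ser tRNA name is resolved to its isoacceptor via the
    anticodon when one is supplied.
    """
    key = _norm_key(raw)
    if key in ("trnaleu", "trnl", "trnaser", "trns") and anticodon:
        base = "tRNA-Leu" if "le" in key or key == "trnl" else "tRNA-Ser"
        iso = _ISOACCEPTOR_BY_ANTICODON.get((base, anticodon.upper().replace("U", "T")))
        if iso:
            return iso
    return _SYNONYMS.get(key)


def ancestral_gene_order(include_cr: bool = False) -> list[tuple[str, str]]:
    """Packaged ancestral insect gene order as (name, strand) pairs."""
    text = resources.files("mitocomp.data").joinpath("gene_order.tsv").read_text()
    order = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, ftype, strand = line.split("\t")[:3]
        if ftype == "control_region" and not include_cr:
            continue
        order.append((name, strand))
    return order


def ancestral_order_table() -> list[dict]:
    """Full packaged order table (generator defaults included)."""
    text = resources.files("mitocomp.data").joinpath("gene_order.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, ftype, strand, length, start, stop = line.split("\t")
        rows.append(dict(name=name, type=ftype, strand=strand,
                         length=None if length == "." else int(length),
                         start=None if start == "." else start,
                         stop=None if stop == "." else stop))
    return rows


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _location_to_spans(location, genome_length: int) -> list[tuple[int, int]]:
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    spans = [(int(p.start), int(p.end)) for p in parts]
    # normalize a join across the origin to (tail, head) order
    if len(spans) == 2 and spans[0][0] == 0 and spans[1][1] == genome_length:
        spans = [spans[1], spans[0]]
    return spans


def read_genbank(path: Union[str, TextIO]) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Unknown gene names are retained with their raw name (type inferred
    from the feature key) and a warning is issued.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path!r}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    seq = str(record.seq).upper()
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _FEATURE_KEY_TO_TYPE and feat.type != "misc_feature":
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        anticodon = None
        if "anticodon" in quals:
            m = re.search(r"seq:\s*([a-zA-Z]{3})", quals["anticodon"][0])
            anticodon = (m.group(1) if m else quals["anticodon"][0]).upper().replace("U", "T")
        ftype = _FEATURE_KEY_TO_TYPE.get(feat.type)
        if ftype is None:  # misc_feature: keep only control-region-like notes
            if not raw or _SYNONYMS.get(_norm_key(raw)) != "CR":
                continue
            ftype = "control_region"
        name = normalize_gene_name(raw, anticodon)
        if name is None:
            warnings.warn(f"unknown gene name {raw!r}; feature retained unnormalized")
            name = raw
        strand = "N" if feat.location.strand == -1 else "J"
        features.append(GeneFeature(
            name=name, type=ftype, strand=strand,
            spans=_location_to_spans(feat.location, len(seq)),
            anticodon=anticodon, raw_name=raw))
    return AnnotatedGenome(id=record.id or record.name, sequence=seq,
                           features=features, topology=topology,
                           description=record.description)


def write_genbank(genome: AnnotatedGenome, path: Union[str, TextIO]) -> None:
    """Emit an AnnotatedGenome as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description=genome.description)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.spans]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f"(seq:{f.anticodon.lower()})"]
        record.features.append(SeqFeature(location,
                                          type=_TYPE_TO_FEATURE_KEY[f.type],
                                          qualifiers=quals))
    SeqIO.write(record, path, "genbank")


def read_fasta(path: Union[str, TextIO]) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_fasta(records: list[tuple[str, str]], path: Union[str, TextIO]) -> None:
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")
    finally:
        if isinstance(path, str):
            handle.close()


# ---------------------------------------------------------------------------
# Feature tables (tab-separated, 1-based inclusive for interchange)
# ---------------------------------------------------------------------------

def write_feature_table(genome: AnnotatedGenome, path: Union[str, TextIO]) -> None:
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write("# name\ttype\tstrand\tstart\tend\n")
        for f in genome.features:
            for s, e in f.spans:
                handle.write(f"{f.name}\t{f.type}\t{f.strand}\t{s + 1}\t{e}\n")
    finally:
        if isinstance(path, str):
            handle.close()


def read_feature_table(path: Union[str, TextIO]) -> list[GeneFeature]:
    handle = open(path) if isinstance(path, str) else path
    try:
        rows = [r for r in csv.reader(handle, delimiter="\t")
                if r and not r[0].startswith("#")]
    finally:
        if isinstance(path, str):
            handle.close()
    grouped: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for name, ftype, strand, start, end in rows:
        grouped.setdefault((name, ftype, strand), []).append((int(start) - 1, int(end)))
    return [GeneFeature(name=k[0], type=k[1], strand=k[2], spans=v)
            for k, v in grouped.items()]


# ---------------------------------------------------------------------------
# Gene-level accounting
# ---------------------------------------------------------------------------

def strand_census(genome: AnnotatedGenome) -> dict:
    """J/N gene counts over the 37 canonical genes (control region excluded)."""
    j = n = 0
    present = set()
    for f in genome.features:
        if f.name in CANONICAL_GENES:
            present.add(f.name)
            if f.strand == "J":
                j += 1
            else:
                n += 1
    missing = [g for g in CANONICAL_GENES if g not in present]
    return {"J": j, "N": n, "missing": missing}


def gene_order_signature(genome: AnnotatedGenome, anchor: str = "tRNA-Ile") -> list[tuple[str, str]]:
    """Rotation-normalized gene order as (name, strand), anchored at tRNA-Ile.

    Falls back to the first annotated canonical gene if the anchor is
    absent.  The control region is excluded.  Raises on duplicated
    canonical genes.
    """
    ordered = [f for f in genome.features_sorted() if f.name in CANONICAL_GENES]
    names = [f.name for f in ordered]
    dupes = {g for g in names if names.count(g) > 1}
    if dupes:
        raise ValueError(f"duplicated canonical gene(s): {sorted(dupes)}")
    if not ordered:
        return []
    start = names.index(anchor) if anchor in names else 0
    rotated = ordered[start:] + ordered[:start]
    return [(f.name, f.strand) for f in rotated]


def compare_gene_order(genome: AnnotatedGenome,
                       reference: Optional[list[tuple[str, str]]] = None) -> tuple[bool, Optional[int]]:
    """Compare a genome's gene order to the ancestral table.

    Returns ``(equal, first_divergent_index)``; the index is None when
    the orders match.
    """
    if reference is None:
        reference = ancestral_gene_order()
    observed = gene_order_signature(genome)
    for i, (obs, ref) in enumerate(zip(observed, reference)):
        if obs != ref:
            return False, i
    if len(observed) != len(reference):
        return False, min(len(observed), len(reference))
    return True, None


def infer_control_region(genome: AnnotatedGenome) -> GeneFeature:
    """Return the annotated control region, or infer it.

    When no control region is annotated, the longest unannotated gap
    between srRNA and tRNA-Ile (its ancestral position) is labeled, with
    ``inferred=True`` as a provenance flag.
    """
    for f in genome.features:
        if f.type == "control_region":
            return f
    try:
        sr = genome.feature_by_name("srRNA")
        ile = genome.feature_by_name("tRNA-Ile")
    except KeyError as exc:
        raise ValueError(f"cannot infer control region for {genome.id}: {exc}") from exc
    L = len(genome.sequence)
    start, end = sr.end % L, ile.start
    if start == end:
        raise ValueError(f"no gap between srRNA and tRNA-Ile in {genome.id}")
    if start < end:
        spans = [(start, end)]
    elif end == 0:
        spans = [(start, L)]
    else:
        if genome.topology != "circular":
            raise ValueError("control region would wrap the origin of a linear molecule")
        spans = [(start, L), (0, end)]
    return GeneFeature(name="CR", type="control_region", strand="J",
                       spans=spans, inferred=True)
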