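"""Phylogenetic supermatrix assembly with codon-position partitions.

Aligned per-gene blocks (13 protein-coding genes, two rRNAs, a
configurable tRNA set) are concatenated into the four standard datasets:

P123   all codon positions of the PCGs
P123R  P123 plus the RNA gene blocks
P12    PCG columns with third codon positions excluded
P12R   P12 plus the RNA gene blocks

Codon-position partitions are interleaved column classes written in
stride notation (``start-end\\3`` / ``start-end\\2``, 1-based inclusive),
the dialect shared by RAxML and PartitionFinder.  Partition counts for a
full gene complement with 19 tRNAs are 39 (P123), 60 (P123R), 26 (P12)
and 47 (P12R).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

__all__ = ["GeneBlock", "Partition", "SupermatrixSpec", "concatenate",
           "exclude_third_positions", "build_dataset", "DATASET_NAMES",
           "DEFAULT_TRNA_EXCLUDE", "write_phylip", "read_phylip",
           "write_nexus", "write_raxml_partitions", "write_partitionfinder_cfg"]

DATASET_NAMES = ("P123", "P123R", "P12", "P12R")
DEFAULT_TRNA_EXCLUDE = ("tRNA-Ile", "tRNA-Gln", "tRNA-Met")


@dataclass
class GeneBlock:
    """One aligned gene block over a common taxon set.

    ``rows`` maps taxon to its aligned row (equal lengths).  ``frame``
    is the codon phase of column 0 for PCG blocks (0 means column 0 is a
    first codon position); None for RNA blocks.
    """

    name: str
    block_type: str  # PCG | tRNA | rRNA
    rows: dict[str, str]
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.block_type not in ("PCG", "tRNA", "rRNA"):
            raise ValueError(f"bad block type {self.block_type!r}")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.name}: ragged rows")
        if self.block_type == "PCG" and self.frame is None:
            raise ValueError(f"{self.name}: PCG block needs a frame")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def phases(self) -> list[int]:
        if self.frame is None:
            raise ValueError(f"{self.name}: not a codon block")
        return [(self.frame + j) % 3 for j in range(self.n_columns)]


@dataclass
class Partition:
    name: str
    start: int  # zero-based column of the concatenated matrix
    end: int  # half-open
    stride: int = 1

    def spec(self) -> str:
        """1-based inclusive range in RAxML/PartitionFinder dialect."""
        rng = f"{self.start + 1}-{self.end}"
        return rng if self.stride == 1 else f"{rng}\\{self.stride}"

    def columns(self) -> list[int]:
        return list(range(self.start, self.end, self.stride))


@dataclass
class SupermatrixSpec:
    """A concatenated matrix plus its partition scheme and column map."""

    name: str
    rows: dict[str, str]
    partitions: list[Partition]
    column_map: list[tuple[str, int, int]]
    excluded_trnas: tuple[str, ...] = ()
    third_positions_excluded: bool = False

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.rows)


def concatenate(blocks: Sequence[GeneBlock],
                order: Optional[Sequence[str]] = None) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Append block columns in the given order; taxon sets must agree.

    Returns (rows, column map of (block, start, end)).  Taxon order is
    preserved from the first block.
    """
    if order is not None:
        by_name = {b.name: b for b in blocks}
        blocks = [by_name[n] for n in order]
    if not blocks:
        raise ValueError("no blocks")
    taxa = blocks[0].taxa
    for b in blocks[1:]:
        if set(b.taxa) != set(taxa):
            diff = sorted(set(b.taxa) ^ set(taxa))
            raise ValueError(f"taxon mismatch at block {b.name!r}: {diff}")
    rows = {t: [] for t in taxa}
    column_map = []
    pos = 0
    for b in blocks:
        for t in taxa:
            rows[t].append(b.rows[t])
        column_map.append((b.name, pos, pos + b.n_columns))
        pos += b.n_columns
    return {t: "".join(parts) for t, parts in rows.items()}, column_map


def exclude_third_positions(block: GeneBlock) -> GeneBlock:
    """Drop every column whose codon phase is third.

    The returned block keeps the original frame and its phases are
    recomputed over the new column indices, so applying the operation
    twice removes the third phase of the *new* frame (the operation is
    deliberately not idempotent; dataset assembly tracks true codon
    positions itself).
    """
    if block.block_type != "PCG":
        raise ValueError(f"{block.name}: third-position exclusion applies to PCG blocks only")
    keep = [j for j, p in enumerate(block.phases()) if p != 2]
    rows = {t: "".join(r[j] for j in keep) for t, r in block.rows.items()}
    return GeneBlock(name=block.name, block_type="PCG", rows=rows,
                     frame=block.frame)


def _harmonize_taxa(blocks: Sequence[GeneBlock]) -> list[GeneBlock]:
    """Union the taxon sets; taxa missing from a block become all-gap rows."""
    taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in taxa:
                taxa.append(t)
    out = []
    for b in blocks:
        rows = {t: b.rows.get(t, "-" * b.n_columns) for t in taxa}
        out.append(GeneBlock(name=b.name, block_type=b.block_type, rows=rows,
                             frame=b.frame))
    return out


def build_dataset(blocks: Sequence[GeneBlock], name: str,
                  trna_exclude: Sequence[str] = DEFAULT_TRNA_EXCLUDE) -> SupermatrixSpec:
    """Assemble one of the four standard datasets from per-gene blocks.

    PCG blocks come first (input order), then rRNA, then tRNA blocks for
    the R datasets.  Third-position exclusion is tracked against each
    block's true codon phases, so P12/P12R partitions are the two
    surviving codon-position classes per gene (stride-2 ranges).
    """
    if name not in DATASET_NAMES:
        raise ValueError(f"unknown dataset {name!r}; expected one of {DATASET_NAMES}")
    with_rna = name.endswith("R")
    drop_third = name in ("P12", "P12R")
    pcgs = [b for b in blocks if b.block_type == "PCG"]
    rnas = [b for b in blocks if b.block_type == "rRNA"]
    trnas = [b for b in blocks if b.block_type == "tRNA"
             and b.name not in set(trna_exclude)]
    if not pcgs:
        raise ValueError("no PCG blocks supplied")
    if with_rna and not (rnas or trnas):
        raise ValueError(f"dataset {name} needs RNA blocks")
    selected = pcgs + (rnas + trnas if with_rna else [])
    selected = _harmonize_taxa(selected)

    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in selected[0].taxa}
    column_map: list[tuple[str, int, int]] = []
    pos = 0
    for b in selected:
        if b.block_type == "PCG":
            phases = b.phases()
            keep = [j for j, p in enumerate(phases) if not (drop_third and p == 2)]
            width = len(keep)
            n_classes = 2 if drop_third else 3
            # kept columns cycle through the surviving phase classes, so each
            # class is a stride-n_classes range offset by its first column
            for cls in range(n_classes):
                offsets = [k for k, j in enumerate(keep) if phases[j] == cls]
                if not offsets:
                    continue
                # conventional stride notation runs to the block end; the
                # stride selects the class members within the range
                parts.append(Partition(name=f"{b.name}_pos{cls + 1}",
                                       start=pos + offsets[0],
                                       end=pos + width,
                                       stride=n_classes))
            for t in chunks:
                row = b.rows[t]
                chunks[t].append("".join(row[j] for j in keep))
        else:
            width = b.n_columns
            parts.append(Partition(name=b.name, start=pos, end=pos + width))
            for t in chunks:
                chunks[t].append(b.rows[t])
        column_map.append((b.name, pos, pos + width))
        pos += width
    rows = {t: "".join(c) for t, c in chunks.items()}
    return SupermatrixSpec(name=name, rows=rows, partitions=parts,
                           column_map=column_map,
                           excluded_trnas=tuple(trna_exclude),
                           third_positions_excluded=drop_third)


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

def _open(path: Union[str, TextIO], mode: str = "w"):
    return (open(path, mode), True) if isinstance(path, str) else (path, False)


def write_phylip(spec_or_rows, path: Union[str, TextIO]) -> None:
    """Relaxed PHYLIP (taxon names of any length, space-separated)."""
    rows = spec_or_rows.rows if isinstance(spec_or_rows, SupermatrixSpec) else spec_or_rows
    handle, close = _open(path)
    try:
        n_cols = len(next(iter(rows.values())))
        handle.write(f" {len(rows)} {n_cols}\n")
        width = max(len(t) for t in rows) + 2
        for t, r in rows.items():
            handle.write(f"{t:<{width}}{r}\n")
    finally:
        if close:
            handle.close()


def read_phylip(path: Union[str, TextIO]) -> dict[str, str]:
    handle, close = _open(path, "r")
    try:
        header = handle.readline().split()
        n_taxa, n_cols = int(header[0]), int(header[1])
        rows = {}
        for line in handle:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            rows[name] = seq.strip()
    finally:
        if close:
            handle.close()
    if len(rows) != n_taxa or any(len(r) != n_cols for r in rows.values()):
        raise ValueError("PHYLIP header does not match matrix")
    return rows


def write_nexus(spec: SupermatrixSpec, path: Union[str, TextIO]) -> None:
    """NEXUS with a data block and a sets block listing the partitions."""
    handle, close = _open(path)
    try:
        handle.write("#NEXUS\n\nBEGIN DATA;\n")
        handle.write(f"  DIMENSIONS NTAX={spec.n_taxa} NCHAR={spec.n_columns};\n")
        handle.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        width = max(len(t) for t in spec.rows) + 2
        for t, r in spec.rows.items():
            handle.write(f"    {t:<{width}}{r}\n")
        handle.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for p in spec.partitions:
            handle.write(f"  CHARSET {p.name} = {p.spec()};\n")
        handle.write("END;\n")
    finally:
        if close:
            handle.close()


def write_raxml_partitions(spec: SupermatrixSpec, path: Union[str, TextIO]) -> None:
    handle, close = _open(path)
    try:
        for p in spec.partitions:
            handle.write(f"DNA, {p.name} = {p.spec()}\n")
    finally:
        if close:
            handle.close()


def write_partitionfinder_cfg(spec: SupermatrixSpec, path: Union[str, TextIO],
                              alignment_name: str = "supermatrix.phy") -> None:
    handle, close = _open(path)
    try:
        handle.write(f"alignment = {alignment_name};\n")
        handle.write("branchlengths = unlinked;\nmodels = all;\n")
        handle.write("model_selection = BIC;\n\n[data_blocks]\n")
        for p in spec.partitions:
            handle.write(f"{p.name} = {p.spec()};\n")
        handle.write("\n[schemes]\nsearch = greedy;\n")
    finally:
        if close:
            handle.close()
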