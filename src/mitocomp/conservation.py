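"""Alignment conservation profiling: %INUC, A+T content, group summaries
and the conservation-composition correlation.

%INUC is the percentage of alignment columns in which every row carries
the same unambiguous nucleotide; a gap or ambiguity code anywhere makes a
column variable.  Gap-containing columns stay in the denominator (an
alternative denominator excluding gap-only columns is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["AlignmentProfile", "profile_alignment", "correlate_profiles",
           "group_summary"]

_UNAMBIGUOUS = set("ACGT")


@dataclass
class AlignmentProfile:
    """Per-alignment conservation and composition summary."""

    gene: str
    n_rows: int
    n_columns: int
    n_identical_columns: int
    at_content: float  # percent, over non-gap residues
    strand: Optional[str] = None
    taxa: Optional[list[str]] = None
    n_gap_only_columns: int = 0
    domain_profiles: Optional[dict[str, "AlignmentProfile"]] = field(default=None)

    @property
    def percent_inuc(self) -> float:
        return 100.0 * self.n_identical_columns / self.n_columns

    @property
    def percent_inuc_nongap(self) -> float:
        """%INUC with gap-only columns removed from the denominator."""
        denom = self.n_columns - self.n_gap_only_columns
        return 100.0 * self.n_identical_columns / denom if denom else float("nan")


def _rows_and_taxa(alignment) -> tuple[list[str], Optional[list[str]]]:
    rows, taxa = [], []
    for item in alignment:
        if isinstance(item, str):
            rows.append(item)
        else:
            name, seq = item
            taxa.append(name)
            rows.append(seq)
    return rows, (taxa if taxa else None)


def profile_alignment(alignment: Sequence, gene: str = "",
                      domains: Optional[dict[str, tuple[int, int]]] = None,
                      strand: Optional[str] = None) -> AlignmentProfile:
    """Conservation/composition profile of a gapped multiple alignment.

    ``alignment`` is a sequence of row strings or (taxon, row) pairs of
    equal length (>= 2 rows).  ``domains`` maps names to half-open column
    ranges; sub-profiles are attached when supplied.
    """
    rows, taxa = _rows_and_taxa(alignment)
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    mat = np.array([list(r.upper().replace("U", "T")) for r in rows])
    n_rows, n_cols = mat.shape
    if n_cols == 0:
        raise ValueError("empty alignment")
    is_gap = (mat == "-") | (mat == ".")
    unamb = np.isin(mat, list(_UNAMBIGUOUS))
    identical = (mat == mat[0]).all(axis=0) & unamb.all(axis=0)
    gap_only = is_gap.all(axis=0)
    residues = mat[unamb]
    at = float(100.0 * np.isin(residues, ["A", "T"]).mean()) if residues.size else 0.0

    def _sub(name: str, start: int, end: int) -> AlignmentProfile:
        sub_unamb = unamb[:, start:end]
        sub_res = mat[:, start:end][sub_unamb]
        sub_at = float(100.0 * np.isin(sub_res, ["A", "T"]).mean()) if sub_res.size else 0.0
        return AlignmentProfile(
            gene=f"{gene}:{name}", n_rows=n_rows, n_columns=end - start,
            n_identical_columns=int(identical[start:end].sum()),
            at_content=sub_at, strand=strand, taxa=taxa,
            n_gap_only_columns=int(gap_only[start:end].sum()))

    domain_profiles = None
    if domains:
        for name, (s, e) in domains.items():
            if not (0 <= s < e <= n_cols):
                raise ValueError(f"domain {name!r} range ({s}, {e}) outside alignment")
        domain_profiles = {name: _sub(name, s, e) for name, (s, e) in domains.items()}
    return AlignmentProfile(gene=gene, n_rows=n_rows, n_columns=n_cols,
                            n_identical_columns=int(identical.sum()),
                            at_content=at, strand=strand, taxa=taxa,
                            n_gap_only_columns=int(gap_only.sum()),
                            domain_profiles=domain_profiles)


def correlate_profiles(profiles: Sequence[AlignmentProfile]) -> Optional[float]:
    """Pearson correlation between %INUC and A+T content across profiles.

    Returns None (flagged undefined) when either variable has zero
    variance.  Requires at least three profiles.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three profiles")
    x = np.array([p.percent_inuc for p in profiles])
    y = np.array([p.at_content for p in profiles])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def group_summary(profiles: Sequence[AlignmentProfile],
                  grouping: dict[str, str]) -> dict[str, dict]:
    """Per-group min/mean/max of %INUC and A+T content.

    Each profile is assigned to a group through its taxa; all taxa of a
    profile must map to the same group.  Groups represented by fewer
    than two genomes are flagged (``small_sample``).
    """
    by_group: dict[str, list[AlignmentProfile]] = {}
    group_taxa: dict[str, set] = {}
    for p in profiles:
        if not p.taxa:
            raise ValueError(f"profile {p.gene!r} carries no taxa; cannot group")
        unmapped = [t for t in p.taxa if t not in grouping]
        if unmapped:
            raise ValueError(f"unmapped taxa: {unmapped}")
        groups = {grouping[t] for t in p.taxa}
        if len(groups) != 1:
            raise ValueError(f"profile {p.gene!r} mixes groups {sorted(groups)}")
        g = groups.pop()
        by_group.setdefault(g, []).append(p)
        group_taxa.setdefault(g, set()).update(p.taxa)
    out = {}
    for g, plist in sorted(by_group.items()):
        inuc = [p.percent_inuc for p in plist]
        at = [p.at_content for p in plist]
        out[g] = {
            "n_profiles": len(plist), "n_genomes": len(group_taxa[g]),
            "inuc_min": min(inuc), "inuc_mean": sum(inuc) / len(inuc),
            "inuc_max": max(inuc),
            "at_min": min(at), "at_mean": sum(at) / len(at), "at_max": max(at),
            "small_sample": len(group_taxa[g]) < 2,
        }
    return out
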