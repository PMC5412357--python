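"""Derive IUPAC consensus motifs for conserved intergenic spacers.

Three short spacers are conserved across cyclorrhaphan flies: between
tRNA-His and ND5 (15 bp), between ND1 and tRNA-Ser(UCN) (18 bp) and
between tRNA-Glu and tRNA-Phe (18 bp).  A panel of spacer sequences is
reduced to a presence-set consensus: each column's set of observed
residues becomes one IUPAC ambiguity letter.
"""
from mitocomp import spacer_consensus as sc, synthetic_data as sd

for (up, down), motif in sd.SPACER_MOTIFS.items():
    rows = sd.generate_spacer_panel(motif, n_rows=5, seed=5)
    aligned = sc.align_spacers(rows)
    m = sc.iupac_consensus(aligned)
    print(f"{up} -- {down}:")
    for r in aligned:
        print(f"    {r}")
    print(f"    {m.consensus}   <- consensus, {len(m)} bp")
    assert all(sc.consensus_matches(r, m) for r in rows)
print("Every panel sequence matches its consensus (each residue lies in "
      "its column's IUPAC set); W marks A/T columns, M marks A/C, B marks "
      "C/G/T.")
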