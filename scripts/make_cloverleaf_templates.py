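"""One-off authoring script for the packaged cloverleaf template tables.

Builds 22 canonical cloverleaf tRNA templates (all Watson-Crick stems) with
standard insect mitochondrial anticodons; tRNA-Ser(AGN) lacks the DHU arm.
Outputs: src/mitocomp/data/cloverleaf_templates.tsv and cloverleaf_arms.tsv.
"""
import numpy as np
from pathlib import Path

ANTICODONS = [  # (canonical name, DNA anticodon)
    ("tRNA-Ile", "GAT"), ("tRNA-Gln", "TTG"), ("tRNA-Met", "CAT"),
    ("tRNA-Trp", "TCA"), ("tRNA-Cys", "GCA"), ("tRNA-Tyr", "GTA"),
    ("tRNA-Leu(UUR)", "TAA"), ("tRNA-Lys", "CTT"), ("tRNA-Asp", "GTC"),
    ("tRNA-Gly", "TCC"), ("tRNA-Ala", "TGC"), ("tRNA-Arg", "TCG"),
    ("tRNA-Asn", "GTT"), ("tRNA-Ser(AGN)", "GCT"), ("tRNA-Glu", "TTC"),
    ("tRNA-Phe", "GAA"), ("tRNA-His", "GTG"), ("tRNA-Thr", "TGT"),
    ("tRNA-Pro", "TGG"), ("tRNA-Ser(UCN)", "TGA"), ("tRNA-Leu(CUN)", "TAG"),
    ("tRNA-Val", "TAC"),
]
PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
PAIR_P = [0.35, 0.35, 0.15, 0.15]  # AT-biased stems, as in insect mt tRNAs
BASES = list("ACGT")
BASE_P = [0.40, 0.10, 0.10, 0.40]  # AT-biased loops


def build(name, anticodon, rng):
    has_dhu = name != "tRNA-Ser(AGN)"
    seq, struct = [], []
    arms = {}

    def stem_loop(arm, n_stem, loop_bases):
        s5_start = len(seq)
        fives, threes = [], []
        for _ in range(n_stem):
            a, b = PAIRS[rng.choice(len(PAIRS), p=PAIR_P)]
            fives.append(a)
            threes.append(b)
        seq.extend(fives); struct.extend("(" * n_stem)
        loop_start = len(seq)
        seq.extend(loop_bases); struct.extend("." * len(loop_bases))
        loop_end = len(seq)
        s3_start = len(seq)
        seq.extend(reversed(threes)); struct.extend(")" * n_stem)
        arms[arm] = dict(s5=(s5_start, s5_start + n_stem),
                         s3=(s3_start, s3_start + n_stem),
                         loop=(loop_start, loop_end))

    def fill(n):
        start = len(seq)
        seq.extend(rng.choice(BASES, n, p=BASE_P))
        struct.extend("." * n)
        return (start, start + n)

    # acceptor 5' side (7 bp); loop field unused for the acceptor arm
    acc5, acc3 = [], []
    for _ in range(7):
        a, b = PAIRS[rng.choice(len(PAIRS), p=PAIR_P)]
        acc5.append(a); acc3.append(b)
    seq.extend(acc5); struct.extend("(" * 7)
    fill(2)  # linker
    if has_dhu:
        stem_loop("DHU", 4, rng.choice(BASES, 8, p=BASE_P))
        fill(1)
    else:
        arms["DHU"] = dict(s5=(9, 9), s3=(9, 9), loop=(9, 9))
        fill(2)  # connector replacing the DHU arm
    ac_loop = list(rng.choice(BASES, 2, p=BASE_P)) + list(anticodon) + list(rng.choice(BASES, 2, p=BASE_P))
    stem_loop("anticodon", 5, ac_loop)
    extra = fill(4)
    stem_loop("TPSIC", 5, rng.choice(BASES, 7, p=BASE_P))
    acc3_start = len(seq)
    seq.extend(reversed(acc3)); struct.extend(")" * 7)
    fill(1)  # discriminator
    arms["acceptor"] = dict(s5=(0, 7), s3=(acc3_start, acc3_start + 7),
                            loop=(0, 0))
    ac = arms["anticodon"]["loop"]
    return "".join(seq), "".join(struct), arms, extra, (ac[0] + 2, ac[0] + 5)


def main():
    rng = np.random.default_rng(20170414)
    out = Path(__file__).resolve().parents[1] / "src" / "mitocomp" / "data"
    t_lines = ["# Cloverleaf tRNA templates: all-canonical Watson-Crick stems.",
               "# Coordinates in the arms table are zero-based half-open.",
               "# name\tanticodon\tanticodon_start\tsequence\tstructure"]
    a_lines = ["# Arm boundary table for the packaged cloverleaf templates.",
               "# Zero-based half-open coordinates; an empty stem/loop has start == end.",
               "# name\tarm\tstem5_start\tstem5_end\tstem3_start\tstem3_end\tloop_start\tloop_end"]
    for name, anticodon in ANTICODONS:
        s, db, arms, extra, ac_span = build(name, anticodon, rng)
        assert s[ac_span[0]:ac_span[1]] == anticodon
        t_lines.append(f"{name}\t{anticodon}\t{ac_span[0]}\t{s}\t{db}")
        for arm in ("acceptor", "DHU", "anticodon", "TPSIC"):
            d = arms[arm]
            a_lines.append(f"{name}\t{arm}\t{d['s5'][0]}\t{d['s5'][1]}\t{d['s3'][0]}\t{d['s3'][1]}\t{d['loop'][0]}\t{d['loop'][1]}")
        a_lines.append(f"{name}\textra\t.\t.\t.\t.\t{extra[0]}\t{extra[1]}")
    (out / "cloverleaf_templates.tsv").write_text("\n".join(t_lines) + "\n")
    (out / "cloverleaf_arms.tsv").write_text("\n".join(a_lines) + "\n")
    print("wrote", out)


if __name__ == "__main__":
    main()
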