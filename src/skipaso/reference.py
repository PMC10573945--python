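"""Published reference candidate sets used for validation.

Two well-characterized splice-junction candidate sets for clinically
relevant cancer exons serve as ground truth for the design geometry and
the physicochemical filters:

* the donor-site set for the third exon of the NRAS oncogene transcript
  (Ensembl exon ENSE00001751295.1) — six 25-mers that satisfy every
  physicochemical criterion;
* the full acceptor + donor set for the second exon of the VHL tumor
  suppressor (Ensembl exon ENSE00003504189.1) — fourteen 25-mers, all of
  which satisfy the criteria.

Names follow the Mann convention; sequences are antisense RNA, 5'->3'.
The synthetic VHL-like locus (:mod:`skipaso.fixtures`) embeds the exact
splice-junction context implied by these sequences, so regenerating them
verbatim exercises the whole design path.
"""
from __future__ import annotations

NRAS_EXON3_JUNCTION_ASOS: dict[str, str] = {
    "H3D (13, -12)": "UGCUCCUAGUACCUGUAGAGGUUAA",
    "H3D (12, -13)": "AUGCUCCUAGUACCUGUAGAGGUUA",
    "H3D (11, -14)": "AAUGCUCCUAGUACCUGUAGAGGUU",
    "H3D (10, -15)": "UAAUGCUCCUAGUACCUGUAGAGGU",
    "H3D (9, -16)": "AUAAUGCUCCUAGUACCUGUAGAGG",
    "H3D (8, -17)": "AAUAAUGCUCCUAGUACCUGUAGAG",
}

VHL_EXON2_JUNCTION_ASOS: dict[str, str] = {
    "H2A (-18, 7)": "AGGUGACCUAUCGGGACAAGCAAAG",
    "H2A (-17, 8)": "AAGGUGACCUAUCGGGACAAGCAAA",
    "H2A (-16, 9)": "AAAGGUGACCUAUCGGGACAAGCAA",
    "H2A (-15, 10)": "CAAAGGUGACCUAUCGGGACAAGCA",
    "H2A (-14, 11)": "CCAAAGGUGACCUAUCGGGACAAGC",
    "H2A (-13, 12)": "GCCAAAGGUGACCUAUCGGGACAAG",
    "H2A (-12, 13)": "AGCCAAAGGUGACCUAUCGGGACAA",
    "H2D (13, -12)": "AAACGUCAGUACCUGGCAGUGUGAU",
    "H2D (12, -13)": "AAAACGUCAGUACCUGGCAGUGUGA",
    "H2D (11, -14)": "UAAAACGUCAGUACCUGGCAGUGUG",
    "H2D (10, -15)": "GUAAAACGUCAGUACCUGGCAGUGU",
    "H2D (9, -16)": "AGUAAAACGUCAGUACCUGGCAGUG",
    "H2D (8, -17)": "AAGUAAAACGUCAGUACCUGGCAGU",
    "H2D (7, -18)": "AAAGUAAAACGUCAGUACCUGGCAG",
}
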