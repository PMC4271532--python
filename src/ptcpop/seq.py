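"""Low-level nucleotide and codon utilities.

All sequences are uppercase DNA strings. The standard nuclear genetic code
is hard-coded; translation of a stop codon yields ``*``.
"""

from __future__ import annotations

_BASES = "TCAG"

# Standard nuclear code, laid out in the classical TCAG order.
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")

#: IUPAC two-base ambiguity codes used to encode unresolved (heterozygous)
#: sites in pseudochromosomes.
HET_CODES = frozenset("RYSWKM")

IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


def complement(base: str) -> str:
    """Complement a single base (IUPAC-aware)."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS; stops become ``*``.

    Codons containing non-ACGT symbols translate to ``X``.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
    )


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
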