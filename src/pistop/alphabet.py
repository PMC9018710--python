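"""Trinucleotide alphabet shared across the package.

The internal alphabet is DNA (A, C, G, T); user-facing tables render T as U
so that piRNA 5' end sequences read as RNA (UAA, UAG, UGA, ...). All 64
trinucleotides are kept in a fixed lexicographic order so count vectors from
different libraries line up.
"""

from __future__ import annotations

from itertools import product

#: All 64 DNA trinucleotides in lexicographic order.
TRINUCLEOTIDES: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))

#: The three stop-codon trinucleotides (DNA alphabet).
STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

#: The 16 trinucleotides beginning with U (T in DNA).
UNN: tuple[str, ...] = tuple(k for k in TRINUCLEOTIDES if k[0] == "T")

#: The 13 Unn trinucleotides that are not stop codons.
OTHER_UNN: tuple[str, ...] = tuple(k for k in UNN if k not in STOP_CODONS)

#: Start codon (DNA alphabet).
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(kmer: str) -> str:
    """Render a DNA k-mer in the RNA alphabet (T -> U) for reporting."""
    return kmer.replace("T", "U").replace("t", "u")


def to_dna(kmer: str) -> str:
    """Convert an RNA k-mer back to the internal DNA alphabet (U -> T)."""
    return kmer.replace("U", "T").replace("u", "t")
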