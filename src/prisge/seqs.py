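"""Constant vector/scaffold sequences and small DNA helpers.

The lentiviral epegRNA cassette, as amplified for sequencing, reads

    [U6 tail] spacer [scaffold] extension [linker] ttttttt [8N barcode] [suffix]

on the plus strand.  Read 1 starts at the spacer; Read 2 enters from the
other end of the amplicon and therefore sees the reverse complement:
suffix', barcode', AAAAAAA (the poly-T terminator), linker', extension'.
The 7-A run on Read 2 anchors the barcode and the extension region.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: SpCas9 flip-and-extend scaffold used by every construct in the screens.
SCAFFOLDS = {
    "flip_extend": (
        "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGG"
        "GACCGAGTCGGTCC"
    ),
}

#: Constant sequence between the extension 3' end and the poly-T terminator
#: (tevopreQ1 stabilising motif plus cloning scar) on the plus strand.
LINKER = "TTGACGCGGTTCTATCTAGTTACGCGTTAAACCAACTAGAAA"

#: Poly-T Pol III terminator directly 5' of the clonal barcode.
TERMINATOR = "TTTTTTT"

#: Plus-strand sequence 3' of the barcode (read first on Read 2).
SUFFIX = "GGAGACGAAGCTTGGCG"

BARCODE_LEN = 8

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def random_distinct_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw ``n`` distinct random DNA ``length``-mers."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = random_dna(rng, length)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def hamming(a: str, b: str) -> int:
    """Hamming distance over the shared prefix length of two strings."""
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str) -> bool:
    return len(seq) > 0 and all(c in "ACGT" for c in seq)
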