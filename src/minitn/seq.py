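"""Small sequence utilities shared across modules.

All genome coordinates in this package are 1-based inclusive (GFF3
convention) unless a writer for another format (BED, WIG) says otherwise.
Translation uses NCBI genetic code 4 (mollicute code: UGA = Trp) via
Biopython's codon tables.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

VALID_NT = frozenset("ACGT")

#: stop codons under genetic code 4 (TGA codes for Trp)
STOPS_CODE4 = ("TAA", "TAG")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_code4(seq: str) -> str:
    """Translate a nucleotide sequence with genetic code 4 (UGA=Trp).

    The sequence is truncated to a whole number of codons; stop codons
    are rendered as '*'.
    """
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate(table=4))


def check_nucleotides(seq: str, context: str = "sequence") -> None:
    bad = set(seq.upper()) - VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide character(s) {sorted(bad)} in {context}")


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with the requested expected G+C fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def circular_slice(genome: str, start: int, length: int) -> str:
    """1-based slice of ``length`` bases starting at ``start``, wrapping
    past the origin of a circular genome."""
    G = len(genome)
    i = (start - 1) % G
    if i + length <= G:
        return genome[i : i + length]
    return genome[i:] + genome[: (i + length - G)]


def kmer_index(genome: str, k: int, circular: bool = True) -> dict[str, list[int]]:
    """Map every k-mer to the list of 1-based start positions where it
    occurs on the forward strand (wrapping past the origin if circular)."""
    G = len(genome)
    text = genome + (genome[: k - 1] if circular and G >= k else "")
    index: dict[str, list[int]] = {}
    for i in range(min(len(text) - k + 1, G)):
        index.setdefault(text[i : i + k], []).append(i + 1)
    return index
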