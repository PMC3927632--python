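"""Genetic-code lookup tables shared by the rate, scan, and simulation modules.

Everything here is derived once, at import time, from the standard nuclear
code as shipped with Biopython.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

#: all 64 codons in a fixed order
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: codon -> one-letter amino acid, stops mapped to '*'
AA_BY_CODON: dict[str, str] = {
    c: ("*" if c in STOP_CODONS else _STANDARD.forward_table[c]) for c in CODONS
}

#: amino acid -> tuple of synonymous codons
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _c, _aa in AA_BY_CODON.items():
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] += (_c,)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon`` ('*' for stops)."""
    return AA_BY_CODON[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def single_nt_neighbors(codon: str) -> list[str]:
    """The nine codons reachable from ``codon`` by one nucleotide change."""
    out = []
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[i]:
                out.append(codon[:i] + nt + codon[i + 1 :])
    return out


def gc_fraction_codon(codon: str) -> float:
    return sum(1 for nt in codon if nt in "GC") / 3.0


def iter_codons(seq: str):
    """Yield (index, codon) over the in-frame codons of ``seq`` (0-based index).

    Trailing bases that do not fill a codon are ignored.
    """
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield i // 3, seq[i : i + 3]
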