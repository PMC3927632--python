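"""Per-gene and windowed sequence features.

GC content, codon adaptation index (CAI), perfect-microsatellite (SSR)
content, fixed-width genomic windows, and intergenic interval lengths.

The SSR scanner reports maximal non-overlapping perfect tandem repeats of
primitive motifs of 1-6 bp; among overlapping candidates the longest run
wins, ties broken by leftmost start.  Mismatch-tolerant repeat models are
deliberately not implemented: perfect repeats are a reproducible lower bound
on repeat content and are all the downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import CODONS_BY_AA, STOP_CODONS, iter_codons

_ACGT = set("ACGT")

#: codons excluded from the CAI geometric mean: stops plus the single-codon
#: families Met (ATG) and Trp (TGG), which carry no usage information.
CAI_EXCLUDED = frozenset(STOP_CODONS) | {"ATG", "TGG"}


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); Ns and other ambiguity codes are ignored entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


class CodonUsageTable:
    """Codon usage frequencies and the derived relative adaptiveness w.

    w(codon) = freq(codon) / max frequency among the synonymous codons of its
    amino acid, so the preferred codon of every family has w = 1.  Codons
    with zero recorded usage are floored at w = 0.01 so the geometric mean
    stays defined.
    """

    W_FLOOR = 0.01

    def __init__(self, freqs: dict[str, float]):
        self.freqs = {c.upper(): float(f) for c, f in freqs.items()}
        self.w: dict[str, float] = {}
        for aa, codons in CODONS_BY_AA.items():
            if aa == "*":
                continue
            fam = {c: self.freqs.get(c, 0.0) for c in codons}
            fmax = max(fam.values())
            for c, f in fam.items():
                if fmax <= 0:
                    self.w[c] = 1.0
                else:
                    self.w[c] = max(f / fmax, self.W_FLOOR)

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["codon"], df["frequency"])))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            sorted(self.freqs.items()), columns=["codon", "frequency"]
        ).to_csv(path, sep="\t", index=False)


def cai(cds: str, table: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of w over informative codons.

    Stop codons, ATG and TGG are excluded; codons containing N are skipped.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    logs = []
    for _, codon in iter_codons(cds):
        if set(codon) - _ACGT or codon in CAI_EXCLUDED:
            continue
        logs.append(np.log(table.w[codon]))
    if not logs:
        raise ValueError("no informative codons for CAI")
    return float(np.exp(np.mean(logs)))


@dataclass(frozen=True)
class SSRHit:
    motif: str
    start: int  # 0-based
    end: int  # half-open
    repeat_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _is_primitive(motif: str) -> bool:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return False
    return True


def find_ssrs(
    seq: str,
    min_total_length: int = 15,
    min_repeats: int = 3,
    max_motif: int = 6,
) -> list[SSRHit]:
    """Perfect tandem repeats meeting both length and repeat-count thresholds.

    Candidates are maximal runs of a primitive motif; overlapping candidates
    are resolved greedily, longest first, then leftmost.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: set[SSRHit] = set()
    for mlen in range(1, max_motif + 1):
        i = 0
        while i + mlen <= n:
            motif = seq[i : i + mlen]
            if set(motif) - _ACGT or not _is_primitive(motif):
                i += 1
                continue
            j = i + mlen
            while j < n and seq[j] == seq[j - mlen]:
                j += 1
            reps = (j - i) // mlen
            if reps >= min_repeats and reps * mlen >= min_total_length:
                candidates.add(SSRHit(motif, i, i + reps * mlen, reps))
            i += 1
    chosen: list[SSRHit] = []
    occupied: list[tuple[int, int]] = []
    for hit in sorted(candidates, key=lambda h: (-h.length, h.start, h.motif)):
        if all(hit.end <= s or hit.start >= e for s, e in occupied):
            chosen.append(hit)
            occupied.append((hit.start, hit.end))
    chosen.sort(key=lambda h: h.start)
    return chosen


def ssr_fraction_of_cds(cds: str, hits: list[SSRHit]) -> float:
    """Fraction of CDS bp covered by (non-overlapping) SSR hits."""
    if not cds:
        raise ValueError("empty CDS")
    covered = np.zeros(len(cds), dtype=bool)
    for h in hits:
        if h.start < 0 or h.end > len(cds):
            raise ValueError("SSR hit outside CDS bounds")
        covered[h.start : h.end] = True
    return float(covered.sum()) / len(cds)


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    gc: float
    ssr_density: float


def windowed_features(
    chromosomes: dict[str, str], window: int = 100_000
) -> list[GenomicWindow]:
    """GC and SSR density in non-overlapping fixed-width windows.

    Windows start at position 0; a trailing partial window is dropped.
    """
    if window < 1000:
        raise ValueError("window must be >= 1000 bp")
    out = []
    for chrom in sorted(chromosomes):
        seq = chromosomes[chrom].upper()
        hits = find_ssrs(seq)
        cov = np.zeros(len(seq), dtype=bool)
        for h in hits:
            cov[h.start : h.end] = True
        for start in range(0, len(seq) - window + 1, window):
            sub = seq[start : start + window]
            acgt = sum(sub.count(b) for b in "ACGT")
            gc = (
                (sub.count("G") + sub.count("C")) / acgt if acgt else float("nan")
            )
            dens = float(cov[start : start + window].sum()) / window
            out.append(GenomicWindow(chrom, start, start + window, gc, dens))
    return out


def intergenic_lengths(
    intervals: list[tuple[int, int]], chrom_length: int
) -> list[int]:
    """Lengths of the complement of the union of gene intervals.

    Intervals are 0-based half-open; overlapping intervals are unioned and
    out-of-bounds intervals clipped rather than rejected.
    """
    clipped = [
        (max(0, s), min(chrom_length, e))
        for s, e in intervals
        if min(chrom_length, e) > max(0, s)
    ]
    clipped.sort()
    merged: list[list[int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    prev = 0
    for s, e in merged:
        if s > prev:
            out.append(s - prev)
        prev = e
    if chrom_length > prev:
        out.append(chrom_length - prev)
    return out


def default_codon_usage() -> CodonUsageTable:
    """A synthetic reference codon-usage table.

    Within each synonymous family, codons (sorted alphabetically) receive
    geometrically decreasing frequencies, GC-richer codons promoted first —
    a stand-in with a realistic spread of w values for simulation and tests;
    it does not reproduce any real organism's usage.
    """
    freqs: dict[str, float] = {}
    for aa, codons in CODONS_BY_AA.items():
        if aa == "*":
            continue
        ordered = sorted(
            codons, key=lambda c: (-sum(1 for b in c if b in "GC"), c)
        )
        for rank, c in enumerate(ordered):
            freqs[c] = 0.5 ** rank
    total = sum(freqs.values())
    return CodonUsageTable({c: f / total for c, f in freqs.items()})
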