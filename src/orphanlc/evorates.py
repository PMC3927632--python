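"""Evolutionary-rate estimation from pairwise codon alignments.

dN/dS is estimated with the Nei-Gojobori (1986) counting method with
Jukes-Cantor multiple-hit correction: fractional synonymous/nonsynonymous
site counts per codon, equal-weight averaging of substitution counts over
all minimal mutational pathways between differing codons (pathways through
stop codons excluded), and dX = -3/4 ln(1 - 4/3 pX).

This module also prepares raw alignments (5' truncation to a codon multiple,
internal stops masked to NNN), draws the length-matched intergenic null set,
and computes pN/pS from polymorphism tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd

from .codons import AA_BY_CODON, STOP_CODONS, iter_codons

_ACGT = set("ACGT")


@dataclass
class CodonAlignment:
    """A prepared pairwise codon alignment (equal lengths, multiple of 3)."""

    seq1: str
    seq2: str
    truncated_5prime_nt: int = 0
    n_internal_stops_masked: int = 0

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq1) % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")


@dataclass
class RateEstimate:
    dn: float
    ds: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    flags: list[str] = field(default_factory=list)

    @property
    def dnds(self) -> float | None:
        if self.ds is None or self.dn is None or not self.ds > 0:
            return None
        return self.dn / self.ds


@dataclass
class PolymorphismSummary:
    gene_id: str
    syn_count: int
    nonsyn_count: int
    syn_sites: float
    nonsyn_sites: float
    flags: list[str] = field(default_factory=list)

    def pnps(self, normalize: bool = True) -> float | None:
        """(pN/N)/(pS/S); with ``normalize=False`` the raw count ratio."""
        if self.syn_count == 0:
            return None
        if not normalize:
            return self.nonsyn_count / self.syn_count
        return (self.nonsyn_count / self.nonsyn_sites) / (
            self.syn_count / self.syn_sites
        )


def prepare_codon_alignment(row1: str, row2: str) -> CodonAlignment:
    """Apply the preparation rules to a raw pairwise alignment.

    Columns are removed from the 5' end until the length is a multiple of 3,
    then every internal (non-terminal) stop codon in either row is replaced
    by NNN.  Gap columns are left in place.
    """
    if len(row1) != len(row2):
        raise ValueError("alignment rows have different lengths")
    trunc = len(row1) % 3
    row1, row2 = row1[trunc:].upper(), row2[trunc:].upper()
    if len(row1) < 6:
        raise ValueError("prepared alignment shorter than two codons")
    n_codons = len(row1) // 3
    masked = 0
    out1, out2 = list(row1), list(row2)
    for i in range(n_codons - 1):  # terminal codon exempt
        for row, out in ((row1, out1), (row2, out2)):
            codon = row[3 * i : 3 * i + 3]
            if codon in STOP_CODONS:
                out[3 * i : 3 * i + 3] = "NNN"
                masked += 1
    return CodonAlignment(
        "".join(out1), "".join(out2), truncated_5prime_nt=trunc,
        n_internal_stops_masked=masked,
    )


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes one site, split by the fraction of its single
    nucleotide changes that are synonymous; changes creating stop codons are
    excluded from the denominator.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _ACGT:
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError("stop codon has no NG86 sites")
    aa = AA_BY_CODON[codon]
    syn = 0.0
    for i in range(3):
        n_syn = n_valid = 0
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if AA_BY_CODON[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) substitution counts between two sense
    codons, averaged with equal weight over all minimal mutational pathways.

    Pathways visiting a stop codon at an intermediate step are excluded; if
    every pathway is excluded (possible for 2-3 differences), all pathways
    are used as a fallback, counting steps into/out of stops as
    nonsynonymous.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order):
        cur = c1
        syn = non = 0.0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                ok = False
            if AA_BY_CODON[cur] == AA_BY_CODON[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return ok, syn, non

    results = [walk(order) for order in permutations(positions)]
    valid = [(s, n) for ok, s, n in results if ok]
    if not valid:
        valid = [(s, n) for _ok, s, n in results]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log(1 - 4.0 * p / 3.0)


def ng86_dnds(aln: CodonAlignment) -> RateEstimate:
    """Nei-Gojobori counting estimate of dN and dS from a prepared alignment.

    Codon pairs containing N, gaps, or a stop codon in either row are
    skipped.  Site counts are averaged over the two sequences.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for (_, ca), (_, cb) in zip(iter_codons(aln.seq1), iter_codons(aln.seq2)):
        if set(ca) - _ACGT or set(cb) - _ACGT:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1

    flags: list[str] = []
    if n_codons == 0:
        return RateEstimate(np.nan, np.nan, 0.0, 0.0, 0.0, 0.0, 0, ["no_codons"])
    ps = Sd / S if S > 0 else np.nan
    pn = Nd / N if N > 0 else np.nan
    ds = _jc_correct(ps) if np.isfinite(ps) else np.nan
    dn = _jc_correct(pn) if np.isfinite(pn) else np.nan
    if ds is None:
        flags.append("ps_saturated")
        ds = np.nan
    if dn is None:
        flags.append("pn_saturated")
        dn = np.nan
    if ds == 0:
        flags.append("ds_zero")
    return RateEstimate(float(dn), float(ds), S, N, Sd, Nd, n_codons, flags)


def sample_matched_intergenic(
    cds_lengths: list[int],
    regions: list[tuple[str, str]],
    seed: int | np.random.Generator,
) -> list[tuple[str, int, str]]:
    """Draw one intergenic subregion per CDS length.

    For each length L a region strictly longer than L is chosen uniformly,
    then a uniform start yields a subregion of exactly L bp.  Returns
    (region_id, start, subsequence) triples; the multiset of output lengths
    equals the input multiset by construction.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lens = np.array([len(s) for _, s in regions])
    out = []
    for L in cds_lengths:
        eligible = np.flatnonzero(lens > L)
        if eligible.size == 0:
            raise ValueError(f"no intergenic region longer than {L} bp")
        ridx = int(rng.choice(eligible))
        rid, rseq = regions[ridx]
        start = int(rng.integers(0, len(rseq) - L + 1))
        out.append((rid, start, rseq[start : start + L]))
    return out


def pnps(
    gene_id: str,
    cds: str,
    snps: list[tuple[int, str, str]],
) -> PolymorphismSummary:
    """Classify SNPs as synonymous/nonsynonymous against the reference CDS.

    ``snps`` are (1-based CDS position, ref, alt).  Each SNP is evaluated one
    at a time against the reference codon.  SNPs falling in a (reference)
    stop codon are excluded with a warning.  Site counts S and N come from
    NG86 over the reference CDS.
    """
    cds = cds.upper()
    S = N = 0.0
    for _, codon in iter_codons(cds):
        if set(codon) - _ACGT or codon in STOP_CODONS:
            continue
        s, n = ng86_sites(codon)
        S += s
        N += n
    flags: list[str] = []
    n_syn = n_non = 0
    for pos, ref, alt in snps:
        if not 1 <= pos <= len(cds):
            raise ValueError(f"SNP position {pos} outside CDS")
        if cds[pos - 1] != ref.upper():
            raise ValueError(
                f"SNP ref {ref} does not match CDS base {cds[pos - 1]} at {pos}"
            )
        ci = (pos - 1) // 3
        codon = cds[3 * ci : 3 * ci + 3]
        if len(codon) < 3 or set(codon) - _ACGT:
            flags.append(f"ambiguous_codon_pos{pos}")
            continue
        if codon in STOP_CODONS:
            warnings.warn(f"SNP at {pos} falls in a stop codon; excluded")
            flags.append(f"stop_codon_snp_pos{pos}")
            continue
        off = (pos - 1) % 3
        mutated = codon[:off] + alt.upper() + codon[off + 1 :]
        if AA_BY_CODON[codon] == AA_BY_CODON[mutated]:
            n_syn += 1
        else:
            n_non += 1
    if n_syn == 0:
        flags.append("ps_zero")
    return PolymorphismSummary(gene_id, n_syn, n_non, S, N, flags)


def load_external_rates(path) -> pd.DataFrame:
    """Adapter for externally computed (e.g. ML) dN/dS estimates.

    Expects a TSV with columns gene_id, dn, ds (extra columns pass through);
    adds a ``dnds`` column (NaN where dS == 0).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "dn", "ds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external rates file lacks columns: {sorted(missing)}")
    df = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["dnds"] = np.where(df["ds"] > 0, df["dn"] / df["ds"], np.nan)
    return df
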