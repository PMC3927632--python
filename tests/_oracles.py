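"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
per-base counting, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# Dollo reconstruction by exhaustive enumeration
# ---------------------------------------------------------------------------

# explicit tree: node -> children (leaves are strings)
_TREE = {
    "root": ("affinis", "n3"),
    "n3": ("lowei", "n2"),
    "n2": ("miranda", "n1"),
    "n1": ("persimilis", "pseudoobscura"),
}
_LEAVES = ("pseudoobscura", "persimilis", "miranda", "lowei", "affinis")
_GAIN_LABEL = {"pseudoobscura": 0, "n1": 1, "n2": 2, "n3": 3, "root": 4}
# every vertex with a parent edge a loss could occur on
_EDGES = ("affinis", "n3", "lowei", "n2", "miranda", "n1", "persimilis",
          "pseudoobscura")


def _leaves_below(vertex: str) -> frozenset[str]:
    if vertex in _LEAVES:
        return frozenset([vertex])
    out: frozenset[str] = frozenset()
    for child in _TREE[vertex]:
        out |= _leaves_below(child)
    return out


def _path_edges(gain: str, leaf: str) -> list[str]:
    """Edges (child vertices) on the path from the gain vertex down to a
    leaf; empty if the leaf is not below the gain vertex."""
    if gain == leaf:
        return []
    if gain in _LEAVES:
        return []
    for child in _TREE[gain]:
        if leaf in _leaves_below(child):
            return [child] + _path_edges(child, leaf)
    return []


def dollo_oracle(states: dict[str, str]) -> tuple[int, frozenset[str]]:
    """Minimal single-gain Dollo reconstruction by exhaustive search.

    ``states`` maps each leaf to intact/disrupted/absent (the focal species
    must be intact).  The intact-ORF character is present at a leaf iff the
    leaf is intact.  Returns the gain label of the minimal reconstruction
    and the set of forced terminal losses that are observable: branches in
    {lowei, miranda, persimilis} whose leaf is disrupted and which carry a
    loss in *every* minimal reconstruction.
    """
    has_char = {leaf: states[leaf] == "intact" for leaf in _LEAVES}
    assert has_char["pseudoobscura"]

    best = None
    minimal = []
    for gain in ("pseudoobscura", "n1", "n2", "n3", "root"):
        below = _leaves_below(gain)
        if not all(leaf in below for leaf in _LEAVES if has_char[leaf]):
            continue
        for r in range(len(_EDGES) + 1):
            from itertools import combinations

            for losses in combinations(_EDGES, r):
                ok = True
                for leaf in _LEAVES:
                    # character survives iff no loss edge lies on the
                    # gain->leaf path (which includes the terminal edge)
                    present = leaf in below and not any(
                        e in losses for e in _path_edges(gain, leaf)
                    )
                    if present != has_char[leaf]:
                        ok = False
                        break
                if not ok:
                    continue
                cost = 1 + len(losses)
                if best is None or cost < best:
                    best = cost
                    minimal = [(gain, frozenset(losses))]
                elif cost == best:
                    minimal.append((gain, frozenset(losses)))
    gains = {g for g, _ in minimal}
    assert len(gains) == 1, f"ambiguous minimal gain for {states}"
    gain = gains.pop()
    forced = frozenset.intersection(*[l for _, l in minimal])
    called = frozenset(
        b
        for b in ("lowei", "miranda", "persimilis")
        if b in forced and states[b] == "disrupted"
    )
    return _GAIN_LABEL[gain], called


# ---------------------------------------------------------------------------
# NG86 counting oracle
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    for i in range(3):
        n_syn = n_ok = 0
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt in _STOPS:
                continue
            n_ok += 1
            n_syn += _aa(alt) == _aa(codon)
        if n_ok:
            syn += n_syn / n_ok
    return syn, 3 - syn


def oracle_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged substitution counts, by explicit
    recursive enumeration of all orders of the differing positions."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []

    def recurse(cur: str, remaining: list[int], syn: float, non: float):
        if not remaining:
            paths.append((syn, non, True))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            rest = [p for p in remaining if p != pos]
            step_syn = _aa(cur) == _aa(nxt)
            blocked = nxt in _STOPS and rest  # intermediate stop
            if blocked:
                paths.append((syn + step_syn, non + (not step_syn), False))
            else:
                recurse(nxt, rest, syn + step_syn, non + (not step_syn))

    # enumerate orders explicitly so blocked paths can be dropped
    full = []
    for order in permutations(diff):
        cur = c1
        syn = non = 0.0
        ok = True
        for j, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and j < len(order) - 1:
                ok = False
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        full.append((syn, non, ok))
    valid = [(s, n) for s, n, ok in full if ok] or [(s, n) for s, n, _ in full]
    return (
        sum(s for s, _ in valid) / len(valid),
        sum(n for _, n in valid) / len(valid),
    )


def oracle_dnds(seq1: str, seq2: str) -> tuple[float, float]:
    """Full NG86+JC estimate (dn, ds) by the oracle's own accounting."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        a, b = seq1[i : i + 3], seq2[i : i + 3]
        if set(a + b) - set("ACGT") or a in _STOPS or b in _STOPS:
            continue
        sa, na = oracle_sites(a)
        sb, nb = oracle_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_pair_diffs(a, b)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    dn = -0.75 * np.log(1 - 4 * pn / 3)
    ds = -0.75 * np.log(1 - 4 * ps / 3)
    return float(dn), float(ds)


# ---------------------------------------------------------------------------
# SSR enumeration oracle
# ---------------------------------------------------------------------------


def _primitive(motif: str) -> bool:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return False
    return True


def oracle_ssrs(
    seq: str, min_total: int = 15, min_reps: int = 3, max_motif: int = 6
) -> list[tuple[str, int, int, int]]:
    """All maximal perfect repeats by direct enumeration, then the
    longest-first/leftmost non-overlap selection.  Returns
    (motif, start, end, repeat_count) sorted by start."""
    cands = set()
    n = len(seq)
    for start in range(n):
        for m in range(1, max_motif + 1):
            motif = seq[start : start + m]
            if len(motif) < m or set(motif) - set("ACGT") or not _primitive(motif):
                continue
            reps = 1
            while seq[start + reps * m : start + (reps + 1) * m] == motif:
                reps += 1
            if reps >= min_reps and reps * m >= min_total:
                cands.add((motif, start, start + reps * m, reps))
    chosen = []
    for cand in sorted(cands, key=lambda c: (-(c[2] - c[1]), c[1], c[0])):
        if all(cand[2] <= s or cand[1] >= e for _, s, e, _ in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda c: c[1])


# ---------------------------------------------------------------------------
# interval complement oracle
# ---------------------------------------------------------------------------


def oracle_complement_lengths(
    intervals: list[tuple[int, int]], chrom_length: int
) -> list[int]:
    base = np.zeros(chrom_length, dtype=bool)
    for s, e in intervals:
        base[max(0, s) : max(0, min(chrom_length, e))] = True
    lengths = []
    run = 0
    for covered in base:
        if covered:
            if run:
                lengths.append(run)
            run = 0
        else:
            run += 1
    if run:
        lengths.append(run)
    return lengths
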