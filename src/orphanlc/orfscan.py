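"""Detection of ORF-disrupting mutations in ortholog coding sequences.

Two kinds of disruption are recognised:

* premature termination codons (PTCs) — in-frame stop codons strictly before
  the terminal codon;
* frameshifts — indels whose length is not a multiple of three, read off a
  pairwise alignment against the intact reference CDS.

Positions are recorded both as 1-based codon indices and as relative ORF
positions ``rel_pos = codon_index / total_codons`` (the denominator includes
the terminal stop codon).  Pseudogene calls come in two modes: ``any`` (one
disruption anywhere suffices) and ``first_half`` (only disruptions with
``rel_pos <= 0.5`` count, a conservative set excluding late mutations with
presumably little functional impact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import STOP_CODONS

_VALID = set("ACGTN")


@dataclass(frozen=True)
class DisruptionEvent:
    """A single ORF-disrupting mutation in one gene x species."""

    gene_id: str
    species: str
    kind: str  # "PTC" or "frameshift"
    codon_index: int  # 1-based
    total_codons: int

    @property
    def rel_pos(self) -> float:
        return self.codon_index / self.total_codons


@dataclass
class PseudogeneCall:
    gene_id: str
    species: str
    is_pseudogene: bool
    mode: str
    supporting_events: list[DisruptionEvent] = field(default_factory=list)


def _frame_seq(cds: str) -> str:
    """Truncate at the 5' end so the length is a multiple of three."""
    return cds[len(cds) % 3 :]


def scan_ptc(cds: str, gene_id: str = "", species: str = "") -> list[DisruptionEvent]:
    """Find premature stop codons in ``cds``.

    The sequence is first 5'-truncated to a multiple of three.  The terminal
    codon is never reported; codons containing N are skipped (an ambiguous
    position cannot be confidently called a stop).
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than two codons")
    cds = cds.upper()
    bad = set(cds) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    framed = _frame_seq(cds)
    total = len(framed) // 3
    events = []
    for i in range(total - 1):  # exclude terminal codon
        codon = framed[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            events.append(
                DisruptionEvent(gene_id, species, "PTC", i + 1, total)
            )
    return events


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in ``row`` as (start, end) half-open column spans."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def detect_frameshifts(
    ref_aln: str,
    sp_aln: str,
    gene_id: str = "",
    species: str = "",
    net_frame: bool = False,
) -> list[DisruptionEvent]:
    """Frameshift events from a pairwise alignment of a species CDS against
    the reference CDS.

    Each maximal gap run (in either row) whose length is not a multiple of
    three yields one event, positioned at the reference codon containing the
    first gapped column.  With ``net_frame=True`` the per-run reading is
    replaced by a single event when the *net* indel length across the whole
    alignment is out of frame (positioned at the first out-of-frame run, or
    the first run if all runs are individually in frame).
    """
    if len(ref_aln) != len(sp_aln):
        raise ValueError("alignment rows have different lengths")
    ref_aln = ref_aln.upper()
    sp_aln = sp_aln.upper()
    ref_len = sum(1 for c in ref_aln if c != "-")
    total = max(1, ref_len // 3)

    # reference coordinate of each alignment column (bases consumed before it)
    ref_pos = np.cumsum([c != "-" for c in ref_aln])  # 1-based after column

    def codon_of_column(col: int) -> int:
        pos = int(ref_pos[col])  # reference bases consumed through col
        if ref_aln[col] == "-":
            # insertion: the codon interrupted is the one holding the next
            # reference base
            codon = pos // 3 + 1
        else:
            codon = (max(pos, 1) - 1) // 3 + 1
        return min(max(codon, 1), total)

    runs = [(s, e, "del") for s, e in _gap_runs(sp_aln)]
    runs += [(s, e, "ins") for s, e in _gap_runs(ref_aln)]
    runs.sort()

    events = []
    for s, e, _kind in runs:
        if (e - s) % 3 != 0:
            events.append(
                DisruptionEvent(
                    gene_id, species, "frameshift", codon_of_column(s), total
                )
            )
    if net_frame:
        net = sum((e - s) for s, e, k in runs if k == "ins") - sum(
            (e - s) for s, e, k in runs if k == "del"
        )
        if net % 3 == 0:
            return []
        first = events[0] if events else None
        if first is None and runs:
            s, e, _ = runs[0]
            first = DisruptionEvent(
                gene_id, species, "frameshift", codon_of_column(s), total
            )
        return [first] if first else []
    return events


def classify_pseudogene(
    events: list[DisruptionEvent],
    gene_id: str = "",
    species: str = "",
    mode: str = "any",
) -> PseudogeneCall:
    """Call a gene x species a pseudogene from its disruption events.

    ``mode='any'``: one event anywhere suffices.  ``mode='first_half'``:
    only events with ``rel_pos <= 0.5`` support the call.
    """
    if mode not in ("any", "first_half"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "first_half":
        support = [ev for ev in events if ev.rel_pos <= 0.5]
    else:
        support = list(events)
    return PseudogeneCall(gene_id, species, bool(support), mode, support)


def ptc_position_histogram(
    events: list[DisruptionEvent], n_bins: int
) -> np.ndarray:
    """Histogram of relative PTC positions over ``n_bins`` equal-width,
    right-closed bins on (0, 1]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        idx = int(np.ceil(ev.rel_pos * n_bins)) - 1
        counts[min(max(idx, 0), n_bins - 1)] += 1
    return counts
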