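"""Orphan classification and ortholog filtering.

A gene is an orphan when it has no homology hit below the E-value cutoff in
any of the outgroup species *and* no curated ortholog annotation; otherwise
it is an old gene (age class 5).  Ortholog calls in the focal species are
filtered by an empirically calibrated aligned-fraction cutoff (a lower
percentile of the old-gene distribution, computed per species) and,
optionally, by a synteny-conservative rule requiring at least one reference
flanking gene on the same contig.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_E_CUTOFF = 1e-4

#: species exempt from the synteny filter by default (fragmented assembly:
#: most contigs hold a single gene, so flank information is uninformative)
SYNTENY_EXEMPT = frozenset({"lowei"})

CHROM_ARMS = ("2", "3", "4", "XL", "XR", "unplaced")


@dataclass(frozen=True)
class HomologyHit:
    query_gene_id: str
    subject_species: str
    program: str  # protein-vs-protein | protein-vs-genome | nucleotide-vs-genome
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("negative E-value")


@dataclass
class OrthologRow:
    gene_id: str
    species: str
    chrom_arm: str
    aligned_fraction: float
    cds: str
    flanks_in_contig: tuple[bool, bool] | None = None

    def __post_init__(self):
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction outside [0, 1]")


def classify_orphan(
    gene_id: str,
    hits: list[HomologyHit],
    curated_ortholog: bool,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> str:
    """'orphan' iff no outgroup hit with E < cutoff and no curated ortholog."""
    for h in hits:
        if h.e_value < 0:
            raise ValueError("negative E-value")
    if curated_ortholog:
        return "old"
    if any(h.e_value < e_cutoff for h in hits):
        return "old"
    return "orphan"


def empirical_cutoff(
    old_gene_fractions: list[float], percentile: float = 5.0
) -> float:
    """Lower percentile of the old-gene aligned-fraction distribution.

    Uses the linear-interpolation ("type 7") quantile.  At least 20 values
    are required for a stable calibration.
    """
    if len(old_gene_fractions) == 0:
        raise ValueError("empty aligned-fraction list")
    if len(old_gene_fractions) < 20:
        raise ValueError("need >= 20 old-gene fractions to calibrate a cutoff")
    return float(np.percentile(old_gene_fractions, percentile))


def filter_orthologs(
    rows: list[OrthologRow], cutoffs: dict[str, float]
) -> tuple[list[OrthologRow], list[tuple[OrthologRow, str]]]:
    """Keep rows with aligned fraction strictly above their species cutoff.

    Returns (retained, dropped) where each dropped entry carries its reason.
    The comparison is strict: a row exactly at the cutoff is dropped.
    """
    retained, dropped = [], []
    for row in rows:
        if row.species not in cutoffs:
            raise ValueError(f"no cutoff for species {row.species!r}")
        cut = cutoffs[row.species]
        if row.aligned_fraction > cut:
            retained.append(row)
        else:
            dropped.append(
                (row, f"aligned_fraction {row.aligned_fraction} <= cutoff {cut}")
            )
    return retained, dropped


def synteny_conservative_set(
    rows: list[OrthologRow],
    neighbor_map: dict[str, tuple[str | None, str | None]],
    exempt_species: frozenset[str] = SYNTENY_EXEMPT,
) -> list[OrthologRow]:
    """Restrict to rows with >= 1 reference flanking gene in the same contig.

    ``neighbor_map`` gives the reference gene order (left, right neighbor or
    None at scaffold edges); ``row.flanks_in_contig`` flags, per flank,
    whether that neighbor's ortholog lies on the row's contig.  Rows without
    flank information are excluded.  Species in ``exempt_species`` pass
    through unfiltered.
    """
    out = []
    for row in rows:
        if row.species in exempt_species:
            out.append(row)
            continue
        if row.flanks_in_contig is None:
            continue
        neighbors = neighbor_map.get(row.gene_id, (None, None))
        ok = any(
            flank is not None and present
            for flank, present in zip(neighbors, row.flanks_in_contig)
        )
        if ok:
            out.append(row)
    return out
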