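"""Dollo-parsimony dating of gene origins and lineage-specific loss calls.

The species tree of the obscura group is fixed:

    (affinis,(lowei,(miranda,(persimilis,pseudoobscura)1)2)3)4

All internal nodes lie on the path from *D. pseudoobscura* to the root and
are labelled 1-4 from the shallowest; age class 0 means
pseudoobscura-specific and age class 5 means old (conserved outside the
group).  Under Dollo parsimony a gene is gained exactly once — at the
deepest node whose off-path subtree holds at least one species with an
*intact* ortholog — and lost any number of times.  Because every internal
node is an ancestor of *D. pseudoobscura* (whose copy is intact by study
design), presence at every internal node of the gene's age subtree is
guaranteed, so a disrupted terminal ortholog inside the subtree implies a
loss on that terminal branch.  Losses are only ever called on the lowei,
miranda, and persimilis branches: affinis losses cannot be polarised
without an extra outgroup, and internal-branch losses are impossible by
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .orfscan import DisruptionEvent
from .orthology import DEFAULT_E_CUTOFF, HomologyHit

FOCAL_SPECIES = "pseudoobscura"

#: off-path leaf attached at each labelled node, shallowest first
OFFPATH_LEAF = {1: "persimilis", 2: "miranda", 3: "lowei", 4: "affinis"}

#: position of each non-focal leaf along the caterpillar (1 = shallowest)
LEAF_POSITION = {sp: k for k, sp in OFFPATH_LEAF.items()}

SPECIES = (FOCAL_SPECIES, "persimilis", "miranda", "lowei", "affinis")

#: terminal branches on which losses may be called
CALLABLE_BRANCHES = ("persimilis", "miranda", "lowei")

OLD_AGE_CLASS = 5

NEWICK = "(affinis,(lowei,(miranda,(persimilis,pseudoobscura)1)2)3)4;"

_STATES = ("intact", "disrupted", "absent")


def species_tree():
    """The fixed obscura species tree as a dendropy Tree."""
    import dendropy

    tree = dendropy.Tree.get(data=NEWICK, schema="newick")
    tree.is_rooted = True
    return tree


def subtree_leaves(age_class: int) -> frozenset[str]:
    """Leaves of the subtree rooted at the given age-class node (focal
    species included); age class 5 covers all five species."""
    k = min(age_class, 4)
    return frozenset(
        [FOCAL_SPECIES] + [OFFPATH_LEAF[j] for j in range(1, k + 1)]
    )


@dataclass(frozen=True)
class AgeClassAssignment:
    gene_id: str
    age_class: int


@dataclass
class LossCall:
    gene_id: str
    branch: str
    mode: str
    events: list[DisruptionEvent] = field(default_factory=list)
    kind: str = "disabling"  # disabling | deletion


def _check_intactness(intactness: dict[str, str]) -> None:
    for sp, state in intactness.items():
        if sp not in SPECIES:
            raise ValueError(f"unknown species {sp!r}")
        if state not in _STATES:
            raise ValueError(f"unknown intactness state {state!r}")
    if intactness.get(FOCAL_SPECIES, "absent") != "intact":
        raise ValueError(
            "focal-species ortholog must be intact (all genes are annotated "
            "and intact in D. pseudoobscura by study design)"
        )


def assign_age_class(intactness: dict[str, str], old: bool = False) -> int:
    """Origin node of a gene from its per-species intactness pattern.

    The age class is the deepest node on the focal-to-root path whose
    off-path leaf carries an intact ortholog; 0 if none does.  Disrupted or
    absent orthologs do not extend a gene's age.  Old genes bypass the rule
    with age class 5.
    """
    _check_intactness(intactness)
    if old:
        return OLD_AGE_CLASS
    k = 0
    for j in (4, 3, 2, 1):
        if intactness.get(OFFPATH_LEAF[j], "absent") == "intact":
            k = j
            break
    return k


def call_losses(
    gene_id: str,
    intactness: dict[str, str],
    age_class: int,
    events_by_species: dict[str, list[DisruptionEvent]] | None = None,
    mode: str = "any",
    strict: bool = False,
) -> list[LossCall]:
    """Losses on terminal branches inside the gene's age-class subtree.

    A branch is called lost when its ortholog is disrupted and Dollo
    ancestral presence holds: at least one intact species on each *occupied*
    side of the branch within the age subtree (the focal species counts; a
    side with no species is vacuous).  With ``strict=True`` the two
    immediate phylogenetic neighbours must themselves exist and be intact.
    """
    _check_intactness(intactness)
    if age_class < 1:
        return []
    events_by_species = events_by_species or {}
    leaves = subtree_leaves(age_class)
    k = min(age_class, 4)
    calls = []
    for branch in CALLABLE_BRANCHES:
        if branch not in leaves:
            continue
        if intactness.get(branch, "absent") != "disrupted":
            continue
        p = LEAF_POSITION[branch]
        inner = [FOCAL_SPECIES] + [
            OFFPATH_LEAF[j] for j in range(1, p)
        ]
        outer = [OFFPATH_LEAF[j] for j in range(p + 1, k + 1)]
        if strict:
            inner_ok = intactness.get(inner[-1], "absent") == "intact"
            outer_ok = bool(outer) and (
                intactness.get(outer[0], "absent") == "intact"
            )
        else:
            inner_ok = any(
                intactness.get(sp, "absent") == "intact" for sp in inner
            )
            outer_ok = (not outer) or any(
                intactness.get(sp, "absent") == "intact" for sp in outer
            )
        if inner_ok and outer_ok:
            evs = events_by_species.get(branch, [])
            if mode == "first_half":
                evs = [e for e in evs if e.rel_pos <= 0.5]
                if events_by_species and branch in events_by_species and not evs:
                    continue
            calls.append(LossCall(gene_id, branch, mode, evs))
    return calls


def classify_deletion(
    ortholog_found: bool,
    hits: list[HomologyHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> bool:
    """Complete deletion: no ortholog call and no genome hit below cutoff.

    Deleted genes are excluded from turnover statistics — a missing
    annotation cannot be distinguished from a true deletion otherwise.
    """
    if ortholog_found:
        return False
    return not any(h.e_value < e_cutoff for h in hits)


def loss_fraction_table(
    gene_table: pd.DataFrame,
    normalize: bool = False,
    stratify_by: str = "none",
) -> pd.DataFrame:
    """Per (branch, age class[, chromosome arm]) loss fractions.

    ``gene_table`` needs columns gene_id, age_class, cds_len, chrom_arm and,
    per callable branch, ``status_<branch>`` in {lost, intact, absent}.
    The fraction is lost/(lost+intact); absent orthologs are excluded.  With
    ``normalize=True`` the fraction is divided by the median CDS length (bp)
    of the cell's genes, yielding a per-bp loss fraction that corrects for
    longer CDSs offering a larger mutational target.  Unplaced contigs are
    excluded from arm-stratified output.
    """
    if stratify_by not in ("none", "chrom_arm"):
        raise ValueError("stratify_by must be 'none' or 'chrom_arm'")
    df = gene_table
    if stratify_by == "chrom_arm":
        df = df[df["chrom_arm"] != "unplaced"]
    group_cols = ["age_class"] + (
        ["chrom_arm"] if stratify_by == "chrom_arm" else []
    )
    records = []
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for branch in CALLABLE_BRANCHES:
            col = f"status_{branch}"
            if col not in sub.columns:
                continue
            considered = sub[sub[col].isin(["lost", "intact"])]
            n_lost = int((considered[col] == "lost").sum())
            n_intact = int((considered[col] == "intact").sum())
            total = n_lost + n_intact
            frac = n_lost / total if total else np.nan
            rec = dict(zip(group_cols, key))
            rec.update(
                branch=branch, n_lost=n_lost, n_intact=n_intact, fraction=frac
            )
            if normalize:
                med = considered["cds_len"].median() if total else np.nan
                rec["median_cds_len"] = med
                rec["fraction_per_bp"] = (
                    frac / med if total and med and med > 0 else np.nan
                )
            records.append(rec)
    cols = group_cols + ["branch", "n_lost", "n_intact", "fraction"]
    if normalize:
        cols += ["median_cds_len", "fraction_per_bp"]
    return pd.DataFrame.from_records(records, columns=cols)


def disabling_vs_deletion_share(
    n_disabling: int, n_deletions: int
) -> float | None:
    """Share of losses due to disabling mutations rather than deletions."""
    total = n_disabling + n_deletions
    if total == 0:
        return None
    return n_disabling / total


def observable_age_classes(branch: str) -> tuple[int, ...]:
    """Orphan age classes at which losses on ``branch`` are observable.

    A gene lost on the branch that defines its age class can no longer be
    dated to that node (the intact-ortholog requirement fails), so losses on
    a branch at position p are only measurable for age classes > p:
    persimilis 2-4, miranda 3-4, lowei 4 only.
    """
    p = LEAF_POSITION[branch]
    return tuple(range(p + 1, 5))


def loss_ordering_by_branch(table: pd.DataFrame) -> dict[str, bool]:
    """Whether loss fractions strictly decrease with age class per branch.

    Only observable classes with a defined fraction enter; branches with
    fewer than two such cells are omitted from the result.
    """
    out: dict[str, bool] = {}
    for branch in CALLABLE_BRANCHES:
        classes = observable_age_classes(branch)
        sub = table[
            (table["branch"] == branch) & table["age_class"].isin(classes)
        ].sort_values("age_class")
        fr = sub["fraction"].dropna().to_numpy()
        if len(fr) < 2:
            continue
        out[branch] = bool(np.all(np.diff(fr) < 0))
    return out


def loss_trend_tests(table: pd.DataFrame) -> list[tuple[str, float, float]]:
    """Cochran-Armitage trend test per branch over its observable classes."""
    results = []
    for branch in CALLABLE_BRANCHES:
        classes = observable_age_classes(branch)
        sub = table[
            (table["branch"] == branch) & table["age_class"].isin(classes)
        ].sort_values("age_class")
        totals = (sub["n_lost"] + sub["n_intact"]).to_numpy()
        keep = totals > 0
        if keep.sum() < 2:
            continue
        z, p = cochran_armitage_trend(
            sub["n_lost"].to_numpy()[keep], totals[keep]
        )
        results.append((branch, z, p))
    return results


def cochran_armitage_trend(
    lost: np.ndarray, totals: np.ndarray, scores: np.ndarray | None = None
) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    Returns (z, two-sided p).  ``scores`` default to 0,1,2,... over the
    ordered categories (age classes).
    """
    lost = np.asarray(lost, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if scores is None:
        scores = np.arange(len(lost), dtype=float)
    scores = np.asarray(scores, dtype=float)
    N = totals.sum()
    if N == 0 or len(lost) < 2:
        return np.nan, np.nan
    pbar = lost.sum() / N
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    T = np.sum(scores * (lost - totals * pbar))
    var = pbar * (1 - pbar) * (
        np.sum(totals * scores**2) - np.sum(totals * scores) ** 2 / N
    )
    if var <= 0:
        return np.nan, np.nan
    z = T / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
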