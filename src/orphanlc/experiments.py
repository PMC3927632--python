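"""Parameter-recovery experiments on synthetic truth.

Reusable routines that quantify how well the analysis machinery recovers
known simulation parameters: loss-rate ordering across age classes, trend
test calibration under a uniform-loss null, dN/dS recovery, disruption
scanner round trips, and expression-bias recovery.  The intactness patterns
for the turnover experiments are drawn by a sequence-free fast path
(per-branch Bernoulli losses on the fixed tree); age assignment, loss
calling, and all downstream statistics go through the regular analysis
functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evorates import ng86_dnds, prepare_codon_alignment
from .expression import bias_retention_correlation
from .gainloss import (
    CALLABLE_BRANCHES,
    assign_age_class,
    call_losses,
    loss_fraction_table,
    loss_ordering_by_branch,
    loss_trend_tests,
    subtree_leaves,
)
from .orfscan import classify_pseudogene, detect_frameshifts, scan_ptc
from .simulate import inject_disruption, random_cds, simulate_codon_pair


# ---------------------------------------------------------------------------
# loss-rate recovery
# ---------------------------------------------------------------------------


def simulate_intactness_cohort(
    rng: np.random.Generator,
    n_per_class: dict[int, int],
    p_by_class: dict[int, float],
) -> pd.DataFrame:
    """Sequence-free cohort: per-gene age class and branch outcomes.

    Each callable branch inside a gene's age subtree is lost (disrupted)
    independently with the class's probability; no deletions, no couplings —
    the clean conditions for ordering and calibration experiments.
    """
    rows = []
    gid = 0
    for k in sorted(n_per_class):
        n = n_per_class[k]
        p = p_by_class.get(k, 0.0)
        leaves = subtree_leaves(k)
        in_tree = [b for b in CALLABLE_BRANCHES if b in leaves]
        lost = rng.random((n, len(in_tree))) < p
        for i in range(n):
            gid += 1
            rec = {"gene_id": f"g{gid:05d}", "true_age_class": k,
                   "cds_len": 300, "chrom_arm": "2"}
            for j, b in enumerate(in_tree):
                rec[b] = "disrupted" if lost[i, j] else "intact"
            for b in CALLABLE_BRANCHES:
                rec.setdefault(b, "absent")
            rec["affinis"] = "intact" if "affinis" in leaves else "absent"
            rows.append(rec)
    return pd.DataFrame(rows)


def recover_loss_fractions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Run Dollo age assignment and loss calling on a cohort, then tabulate
    loss fractions per (branch, observed age class)."""
    records = []
    for rec in cohort.to_dict("records"):
        intactness = {"pseudoobscura": "intact"}
        for sp in ("persimilis", "miranda", "lowei", "affinis"):
            intactness[sp] = rec[sp]
        old = rec["true_age_class"] == 5
        k = assign_age_class(intactness, old=old)
        calls = call_losses(rec["gene_id"], intactness, k)
        called = {c.branch for c in calls}
        row = {
            "gene_id": rec["gene_id"],
            "age_class": k,
            "chrom_arm": rec["chrom_arm"],
            "cds_len": rec["cds_len"],
        }
        for b in CALLABLE_BRANCHES:
            if b not in subtree_leaves(k):
                row[f"status_{b}"] = "absent"
            elif b in called:
                row[f"status_{b}"] = "lost"
            elif intactness[b] == "intact":
                row[f"status_{b}"] = "intact"
            else:
                row[f"status_{b}"] = "absent"
        records.append(row)
    return loss_fraction_table(pd.DataFrame(records))


def loss_ordering_experiment(
    seed: int,
    n_replicates: int = 100,
    n_per_class: dict[int, int] | None = None,
    p_by_class: dict[int, float] | None = None,
) -> float:
    """Fraction of replicates in which every branch's observable loss
    fractions strictly decrease with age class."""
    n_per_class = n_per_class or {k: 300 for k in (1, 2, 3, 4)}
    p_by_class = p_by_class or {1: 0.4, 2: 0.2, 3: 0.1, 4: 0.04}
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_replicates):
        cohort = simulate_intactness_cohort(rng, n_per_class, p_by_class)
        table = recover_loss_fractions(cohort)
        ordering = loss_ordering_by_branch(table)
        if ordering and all(ordering.values()):
            ok += 1
    return ok / n_replicates


def loss_trend_type1_experiment(
    seed: int,
    n_replicates: int = 1000,
    n_per_class: dict[int, int] | None = None,
    p_uniform: float = 0.1,
    alpha: float = 0.05,
) -> float:
    """Trend-test rejection rate under a uniform loss probability."""
    n_per_class = n_per_class or {k: 300 for k in (1, 2, 3, 4)}
    p_by_class = {k: p_uniform for k in n_per_class}
    rng = np.random.default_rng(seed)
    n_tests = n_reject = 0
    for _ in range(n_replicates):
        cohort = simulate_intactness_cohort(rng, n_per_class, p_by_class)
        table = recover_loss_fractions(cohort)
        for _branch, _z, p in loss_trend_tests(table):
            n_tests += 1
            n_reject += p < alpha
    return n_reject / n_tests if n_tests else float("nan")


# ---------------------------------------------------------------------------
# dN/dS recovery
# ---------------------------------------------------------------------------


def dnds_recovery_experiment(
    seed: int,
    ratios: tuple[float, ...] = (0.1, 0.5, 1.0),
    n_replicates: int = 200,
    n_codons: int = 500,
    ds: float = 0.2,
) -> dict[float, float]:
    """Mean estimated dN/dS per simulated true ratio."""
    rng = np.random.default_rng(seed)
    out = {}
    for true in ratios:
        estimates = []
        for _ in range(n_replicates):
            anc, der = simulate_codon_pair(n_codons, true, ds, rng)
            est = ng86_dnds(prepare_codon_alignment(anc, der))
            if est.dnds is not None:
                estimates.append(est.dnds)
        out[true] = float(np.mean(estimates))
    return out


# ---------------------------------------------------------------------------
# disruption-scanner round trip
# ---------------------------------------------------------------------------


def _truth_alignment(cds: str, mutated: str, off_codon: int) -> tuple[str, str]:
    """Reconstruct the trivially known alignment of an injected indel."""
    off = 3 * (off_codon - 1)
    diff = len(mutated) - len(cds)
    if diff < 0:  # deletion in the species copy
        return cds, mutated[:off] + "-" * (-diff) + mutated[off:]
    return cds[:off] + "-" * diff + cds[off:], mutated


def scanner_round_trip_experiment(
    seed: int, n_genes: int = 10_000
) -> dict[str, float]:
    """Inject one PTC or frameshift per gene and scan it back.

    Returns recall (event kind and codon recovered), the false-positive
    count on the matching clean ORFs, and the agreement rate between
    first-half pseudogene calls and the presence of an event at
    rel_pos <= 0.5.
    """
    rng = np.random.default_rng(seed)
    n_recalled = n_fp = n_firsthalf_ok = 0
    for i in range(n_genes):
        total = int(rng.integers(30, 300))
        cds = random_cds(rng, total)
        if scan_ptc(cds):
            n_fp += 1
        kind = "PTC" if i % 2 == 0 else "frameshift"
        idx = int(rng.integers(2, total - 1))
        mutated, truth = inject_disruption(
            cds, kind, (idx - 0.5) / total, rng
        )
        if kind == "PTC":
            events = scan_ptc(mutated)
        else:
            ref_aln, sp_aln = _truth_alignment(cds, mutated, truth.codon_index)
            events = detect_frameshifts(ref_aln, sp_aln)
        hit = any(
            e.kind == truth.kind and e.codon_index == truth.codon_index
            for e in events
        )
        n_recalled += hit
        call = classify_pseudogene(events, mode="first_half")
        expected = any(e.rel_pos <= 0.5 for e in events)
        n_firsthalf_ok += call.is_pseudogene == expected
    return {
        "recall": n_recalled / n_genes,
        "false_positives": float(n_fp),
        "first_half_agreement": n_firsthalf_ok / n_genes,
    }


# ---------------------------------------------------------------------------
# expression-bias recovery
# ---------------------------------------------------------------------------


def _nb(rng, mean, dispersion):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-9)))


def planted_shift_recovery(
    seed: int,
    shifts: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    n_genes_per_shift: int = 300,
    n_background: int = 1500,
    dispersion: float = 0.05,
    n_replicates_per_sex: int = 2,
    mean_count: float = 500.0,
) -> dict[float, float]:
    """Mean recovered log2 fold change per planted male-bias shift.

    Shifted genes sit on an unshifted background and male/female shifts are
    planted symmetrically, so median-of-ratios normalisation stays anchored
    by unbiased genes — as in real data, where most genes are not sex-biased
    and bias occurs in both directions.
    """
    from .expression import sex_bias

    rng = np.random.default_rng(seed)
    truth = np.concatenate(
        [np.zeros(n_background), np.repeat(shifts, n_genes_per_shift)]
    )
    base = mean_count * np.exp(rng.normal(0, 0.5, size=len(truth)))
    fc = 2.0 ** (truth / 2.0)
    cols = {}
    for j in range(n_replicates_per_sex):
        cols[f"male_{j+1}"] = _nb(rng, base * fc, dispersion)
    for j in range(n_replicates_per_sex):
        cols[f"female_{j+1}"] = _nb(rng, base / fc, dispersion)
    counts = pd.DataFrame(
        cols, index=[f"g{i:05d}" for i in range(len(truth))]
    )
    samples = pd.DataFrame(
        {
            "sample": list(cols),
            "sex": ["male"] * n_replicates_per_sex
            + ["female"] * n_replicates_per_sex,
            "strain": ["s1", "s2"] * 2,
        }
    )
    calls = sex_bias(counts, samples)
    planted = truth.copy()
    planted[:n_background] = np.nan  # background not scored
    out = {}
    for s in shifts:
        out[s] = float(calls.loc[planted == s, "log2fc"].mean())
    return out


def _bias_cohort(
    rng: np.random.Generator, n_genes: int, effect: float
) -> tuple[pd.DataFrame, pd.Series]:
    """Male-biased gene cohort with retention probability increasing in
    bias strength by ``effect`` logit units per log2 unit (0 = null)."""
    log2fc = np.abs(rng.normal(1.5, 0.8, size=n_genes)) + 0.2
    logit = -0.5 + effect * (log2fc - log2fc.mean())
    conserved = rng.random(n_genes) < 1.0 / (1.0 + np.exp(-logit))
    ids = [f"g{i:05d}" for i in range(n_genes)]
    calls = pd.DataFrame(
        {"gene_id": ids, "log2fc": log2fc, "bias": "male"}
    )
    return calls, pd.Series(conserved, index=ids)


def bias_retention_power_experiment(
    seed: int,
    n_replicates: int = 200,
    n_genes: int = 1000,
    effect: float = 1.5,
    n_bins: int = 7,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the bias-retention Spearman procedure.

    With ``effect=0`` this is the type-I error; with a strong positive
    effect the power.
    """
    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_replicates):
        calls, conserved = _bias_cohort(rng, n_genes, effect)
        res = bias_retention_correlation(calls, conserved, n_bins=n_bins)
        n_reject += res.p_value < alpha
    return n_reject / n_replicates
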