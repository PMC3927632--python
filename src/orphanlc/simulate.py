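"""Synthetic five-species ortholog datasets with known gain/loss truth.

The generator emulates the downstream products of the obscura-group study
design: ortholog tables on the fixed species tree with age-stratified gains,
branch-specific ORF-disrupting mutations and deletions, codon alignments
with controlled dN/dS, length-matched intergenic regions, SNP tables, and
negative-binomial count matrices in which male-biased, highly expressed
orphans are preferentially retained.

Codon divergence is simulated by uniform single-nucleotide proposals thinned
by a dN/dS acceptance ratio (synonymous weight 1, nonsynonymous weight
omega, stop-creating changes rejected) — not a full codon-model rate matrix;
only counting estimators consume the output.  Disruptions enter exclusively
through :func:`inject_disruption`, keeping the loss truth unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, STOP_CODONS, gc_fraction_codon, AA_BY_CODON
from .evorates import ng86_sites
from .gainloss import CALLABLE_BRANCHES, FOCAL_SPECIES, OLD_AGE_CLASS, subtree_leaves
from .orfscan import DisruptionEvent
from .seqfeatures import CodonUsageTable, default_codon_usage

#: branch-length multipliers applied to ds_target per species
BRANCH_DS_MULT = {
    "persimilis": 1.0,
    "miranda": 1.5,
    "lowei": 2.5,
    "affinis": 3.5,
}

OUTGROUP_SPECIES = (
    "melanogaster", "simulans", "sechellia", "erecta", "yakuba",
    "ananassae", "willistoni", "mojavensis", "virilis", "grimshawi",
)

_STOP_LIST = sorted(STOP_CODONS)


def uniform_loss_prob(p_by_class: dict[int, float]) -> dict[tuple[str, int], float]:
    """Expand a per-age-class loss probability to all callable branches."""
    return {
        (branch, k): p
        for k, p in p_by_class.items()
        for branch in CALLABLE_BRANCHES
    }


#: default per-class loss probabilities, decreasing with age.  The spacing
#: was fixed by an a-priori power analysis: with ~300 genes per class the
#: joint probability of strictly ordered per-branch loss fractions exceeds
#: 99%, so ordering-recovery experiments are adequately powered.
DEFAULT_LOSS_BY_CLASS = {1: 0.4, 2: 0.2, 3: 0.1, 4: 0.04, 5: 0.01}


@dataclass
class ExpressionConfig:
    mean_log_fpkm: float = math.log(100.0)
    nb_dispersion: float = 0.05
    male_bias_enrichment_conserved: float = 1.0
    n_replicates_per_sex: int = 2

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_replicates_per_sex < 2:
            raise ValueError("need >= 2 replicates per sex")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes_per_class: dict[int, int] = field(
        default_factory=lambda: {0: 150, 1: 120, 2: 90, 3: 70, 4: 60, 5: 300}
    )
    loss_prob: dict[tuple[str, int], float] = field(
        default_factory=lambda: uniform_loss_prob(DEFAULT_LOSS_BY_CLASS)
    )
    dnds_by_class: dict[int, float] = field(
        default_factory=lambda: {0: 0.5, 1: 0.45, 2: 0.45, 3: 0.4, 4: 0.4, 5: 0.15}
    )
    ds_target: float = 0.06
    ssr_insert_prob: float = 0.08
    #: fraction of losses realised as complete deletions rather than
    #: disabling mutations
    deletion_frac: float = 0.24
    #: retention couplings: loss probability is multiplied by
    #: 2**-(c_bias*max(log2fc,0) + c_expr*(log_mean - mean_log))
    retention_bias_coupling: float = 0.5
    retention_expression_coupling: float = 0.3
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        if not self.n_genes_per_class or all(
            v == 0 for v in self.n_genes_per_class.values()
        ):
            raise ValueError("no genes to simulate")
        for k, v in self.n_genes_per_class.items():
            if k not in range(6) or v < 0:
                raise ValueError(f"bad n_genes_per_class entry {k}: {v}")
        for key, p in self.loss_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"loss probability {key} outside [0, 1]")
        if not 0.0 <= self.deletion_frac <= 1.0:
            raise ValueError("deletion_frac outside [0, 1]")
        if not 0.0 <= self.ssr_insert_prob <= 1.0:
            raise ValueError("ssr_insert_prob outside [0, 1]")
        if any(w <= 0 for w in self.dnds_by_class.values()):
            raise ValueError("dN/dS must be positive")
        if self.ds_target < 0:
            raise ValueError("ds_target must be >= 0")
        self.expression.validate()


# ---------------------------------------------------------------------------
# sequence-level simulation
# ---------------------------------------------------------------------------

#: per sense codon: (synonymous alternatives, nonsynonymous alternatives,
#: fractional synonymous sites, fractional nonsynonymous sites).  Event
#: rates use the fractional site counts (stop-excluded denominators), the
#: same convention the counting estimator applies, so nominal per-site
#: divergence targets are matched exactly in expectation.
_CODON_MOVES: dict[str, tuple[list[str], list[str], float, float]] = {}
for _c in SENSE_CODONS:
    _syn, _non = [], []
    for _i in range(3):
        for _nt in "ACGT":
            if _nt == _c[_i]:
                continue
            _alt = _c[:_i] + _nt + _c[_i + 1 :]
            if _alt in STOP_CODONS:
                continue
            (_syn if AA_BY_CODON[_alt] == AA_BY_CODON[_c] else _non).append(_alt)
    _s, _n = ng86_sites(_c)
    _CODON_MOVES[_c] = (_syn, _non, _s, _n)


def random_cds(
    rng: np.random.Generator,
    n_codons: int,
    gc_weight: float = 0.0,
    cai_weight: float = 0.0,
    usage: CodonUsageTable | None = None,
) -> str:
    """An intact random ORF: ATG, sense codons, one terminal stop.

    ``gc_weight`` and ``cai_weight`` exponentially tilt codon sampling
    toward GC-rich and high-adaptiveness codons, steering base composition
    and codon usage bias of the simulated gene classes.
    """
    if n_codons < 4:
        raise ValueError("need at least 4 codons")
    usage = usage or default_codon_usage()
    codons = np.array(SENSE_CODONS)
    logw = np.array(
        [
            gc_weight * 3 * gc_fraction_codon(c)
            + cai_weight * math.log(usage.w[c])
            for c in SENSE_CODONS
        ]
    )
    p = np.exp(logw - logw.max())
    p /= p.sum()
    body = rng.choice(codons, size=n_codons - 2, p=p)
    stop = _STOP_LIST[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _mutable_span(seq: str) -> tuple[int, int]:
    """Codon index range [start, end) eligible for substitution: the start
    codon and a terminal stop codon (if present) are frozen."""
    n = len(seq) // 3
    last = seq[3 * (n - 1) : 3 * n]
    return 1, n - 1 if last in STOP_CODONS else n


def evolve_cds(
    seq: str, dnds: float, ds: float, rng: np.random.Generator
) -> str:
    """Evolve a descendant at synonymous divergence ``ds`` and ratio dN/dS.

    Substitutions are drawn sequentially with weight 1 for synonymous and
    ``dnds`` for nonsynonymous single-nucleotide changes; changes creating
    stop codons never occur.  The number of events is Poisson with mean
    ds * (S + dnds * N) over the mutable codons.
    """
    if dnds <= 0:
        raise ValueError("dnds must be > 0")
    if ds < 0:
        raise ValueError("ds must be >= 0")
    if ds == 0:
        return seq
    lo, hi = _mutable_span(seq)
    codons = [seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3)]
    idx = list(range(lo, hi))
    if not idx:
        return seq
    wsyn = np.array([_CODON_MOVES[codons[i]][2] for i in idx])
    wnon = np.array([_CODON_MOVES[codons[i]][3] for i in idx])
    n_events = rng.poisson(ds * (wsyn.sum() + dnds * wnon.sum()))
    for _ in range(n_events):
        rates = wsyn + dnds * wnon
        total = rates.sum()
        if total <= 0:
            break
        j = rng.choice(len(idx), p=rates / total)
        ci = idx[j]
        syn_alts, non_alts, s_c, n_c = _CODON_MOVES[codons[ci]]
        p_syn = s_c / (s_c + dnds * n_c)
        if (rng.random() < p_syn and syn_alts) or not non_alts:
            alt = syn_alts[rng.integers(0, len(syn_alts))]
        else:
            alt = non_alts[rng.integers(0, len(non_alts))]
        codons[ci] = alt
        _, _, wsyn[j], wnon[j] = _CODON_MOVES[alt]
    return "".join(codons)


def simulate_codon_pair(
    n_codons: int,
    dnds: float,
    ds: float,
    seed: int | np.random.Generator,
) -> tuple[str, str]:
    """An aligned ancestor/descendant CDS pair at controlled divergence.

    The ancestor is an intact random ORF (ATG start, no internal stops);
    synonymous changes accrue to an expected dS of ``ds`` per synonymous
    site and nonsynonymous changes at ``dnds`` times that rate.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if dnds <= 0:
        raise ValueError("dnds must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    anc = random_cds(rng, n_codons)
    der = evolve_cds(anc, dnds, ds, rng)
    return anc, der


def inject_disruption(
    cds: str,
    kind: str,
    rel_pos: float,
    rng: np.random.Generator,
    gene_id: str = "",
    species: str = "",
) -> tuple[str, DisruptionEvent]:
    """Plant one ORF-disrupting mutation at a relative ORF position.

    PTC: the codon at the requested position is overwritten with a stop.
    Frameshift: an indel of 1-2 nt (length not divisible by 3) at that
    position.  The affected codon index is ceil(rel_pos * total_codons),
    floored at codon 2 so the start codon survives; the terminal stop codon
    is never the target.
    """
    if kind not in ("PTC", "frameshift"):
        raise ValueError(f"unknown disruption kind {kind!r}")
    if not 0.0 <= rel_pos < 1.0:
        raise ValueError("rel_pos must be in [0, 1)")
    if len(cds) % 3 != 0 or not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG and be a codon multiple")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError("CDS must end with a stop codon")
    total = len(cds) // 3
    idx = max(2, math.ceil(rel_pos * total))
    if idx > total - 1 or total < 4:
        raise ValueError(
            f"CDS of {total} codons too short to place event at rel_pos {rel_pos}"
        )
    off = 3 * (idx - 1)
    if kind == "PTC":
        stop = _STOP_LIST[rng.integers(0, 3)]
        mutated = cds[:off] + stop + cds[off + 3 :]
    else:
        length = int(rng.integers(1, 3))  # 1 or 2 nt, never in frame
        if rng.random() < 0.5:
            mutated = cds[:off] + cds[off + length :]
        else:
            ins = "".join(rng.choice(list("ACGT"), size=length))
            mutated = cds[:off] + ins + cds[off:]
    event = DisruptionEvent(gene_id, species, kind, idx, total)
    return mutated, event


def inject_snps(
    cds: str, n_syn: int, n_nonsyn: int, rng: np.random.Generator
) -> list[tuple[int, str, str]]:
    """Plant synonymous/nonsynonymous SNPs at distinct CDS positions.

    Changes creating stop codons (and positions inside stop codons) are
    never drawn, so the planted counts are exactly what pN/pS counting
    should recover.
    """
    syn_pool: list[tuple[int, str, str]] = []
    non_pool: list[tuple[int, str, str]] = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS or set(codon) - set("ACGT"):
            continue
        for i in range(3):
            for nt in "ACGT":
                if nt == codon[i]:
                    continue
                alt = codon[:i] + nt + codon[i + 1 :]
                if alt in STOP_CODONS:
                    continue
                rec = (3 * ci + i + 1, codon[i], nt)
                if AA_BY_CODON[alt] == AA_BY_CODON[codon]:
                    syn_pool.append(rec)
                else:
                    non_pool.append(rec)
    if n_syn > len(syn_pool) or n_nonsyn > len(non_pool):
        raise ValueError("CDS too short for requested SNP counts")

    chosen: list[tuple[int, str, str]] = []
    used: set[int] = set()
    for pool, want in ((syn_pool, n_syn), (non_pool, n_nonsyn)):
        if want == 0:
            continue
        order = rng.permutation(len(pool))
        got = 0
        for j in order:
            pos, ref, alt = pool[j]
            if pos in used:
                continue
            used.add(pos)
            chosen.append(pool[j])
            got += 1
            if got == want:
                break
        if got < want:
            raise ValueError("could not place requested SNPs at distinct sites")
    chosen.sort()
    return chosen


# ---------------------------------------------------------------------------
# cohort-level simulation (presence/intactness truth, no sequences)
# ---------------------------------------------------------------------------


def simulate_gainloss_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-gene age classes, expression truth, and branch outcomes.

    Returns one row per gene with columns: gene_id, age_class, chrom_arm,
    n_codons, cds_len, log_mean, log2fc, status_<branch> in
    {intact, lost, deleted, absent}, loss_kind_<branch>, conserved.
    The sequence-free core used both by :func:`simulate_dataset` and by
    turnover-recovery experiments.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    exp = config.expression
    arms = np.array(["2", "3", "4", "XL", "XR", "unplaced"])
    arm_p = np.array([0.22, 0.22, 0.1, 0.22, 0.22, 0.02])

    rows = []
    gid = 0
    for k in sorted(config.n_genes_per_class):
        n = config.n_genes_per_class[k]
        orphan = k < OLD_AGE_CLASS
        for _ in range(n):
            gid += 1
            gene_id = f"g{gid:05d}"
            # orphans are short (median ~115 codons), old genes long (~490)
            log_med = math.log(115 if orphan else 490)
            n_codons = int(
                np.clip(round(math.exp(rng.normal(log_med, 0.5))), 25, 3000)
            )
            log_mean = rng.normal(
                exp.mean_log_fpkm - (0.4 if orphan else 0.0), 1.0
            )
            u = rng.random()
            if u < (0.35 if orphan else 0.20):
                log2fc = rng.normal(1.5, 0.6)
            elif u < (0.47 if orphan else 0.35):
                log2fc = -abs(rng.normal(1.2, 0.5))
            else:
                log2fc = rng.normal(0.0, 0.3)

            leaves = subtree_leaves(k)
            rec: dict = {
                "gene_id": gene_id,
                "age_class": k,
                "chrom_arm": str(rng.choice(arms, p=arm_p)),
                "n_codons": n_codons,
                "cds_len": 3 * n_codons,
                "log_mean": log_mean,
                "log2fc": log2fc,
            }
            modifier = 2.0 ** -(
                config.retention_bias_coupling * max(log2fc, 0.0)
                + config.retention_expression_coupling
                * (log_mean - exp.mean_log_fpkm)
            )
            any_loss = False
            for branch in CALLABLE_BRANCHES:
                if branch not in leaves:
                    rec[f"status_{branch}"] = "absent"
                    rec[f"loss_kind_{branch}"] = ""
                    continue
                base = config.loss_prob.get((branch, k), 0.0)
                p = float(np.clip(base * modifier, 0.0, 0.95))
                if rng.random() < p:
                    any_loss = True
                    if rng.random() < config.deletion_frac:
                        rec[f"status_{branch}"] = "deleted"
                        rec[f"loss_kind_{branch}"] = "deletion"
                    else:
                        rec[f"status_{branch}"] = "lost"
                        rec[f"loss_kind_{branch}"] = (
                            "PTC" if rng.random() < 0.5 else "frameshift"
                        )
                else:
                    rec[f"status_{branch}"] = "intact"
                    rec[f"loss_kind_{branch}"] = ""
            rec["status_affinis"] = (
                "intact" if "affinis" in leaves else "absent"
            )
            rec["conserved"] = not any_loss
            if orphan and rec["conserved"] and rng.random() < 0.3:
                rec["log2fc"] = (
                    rec["log2fc"] + exp.male_bias_enrichment_conserved
                )
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full dataset bundle
# ---------------------------------------------------------------------------


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-9))
    return rng.negative_binomial(r, p)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(list("ACGT"))


def _mutate_neutral(seq: str, d: float, rng: np.random.Generator) -> str:
    """Per-base Jukes-Cantor substitution at divergence ``d`` subs/site."""
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    idx = np.array([_BASE_INDEX[b] for b in seq])
    hit = rng.random(len(idx)) < p
    shift = rng.integers(1, 4, size=len(idx))
    idx[hit] = (idx[hit] + shift[hit]) % 4
    return "".join(_BASES[idx])


_SSR_MOTIFS = ("AC", "AG", "CT", "GT")


def _insert_ssr(cds: str, rng: np.random.Generator) -> str:
    """In-frame insertion of a perfect dinucleotide repeat (18 or 24 bp)."""
    total = len(cds) // 3
    if total < 6:
        return cds
    motif = _SSR_MOTIFS[rng.integers(0, len(_SSR_MOTIFS))]
    n_bp = int(rng.choice([18, 24]))
    insert = (motif * (n_bp // 2 + 1))[:n_bp]
    codon = int(rng.integers(2, total - 2))
    off = 3 * codon
    return cds[:off] + insert + cds[off:]


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[dict, pd.DataFrame]:
    """Generate a complete synthetic bundle and its truth table.

    Returns ``(bundle, truth)``; with ``out_dir`` the bundle is also written
    to disk (see :func:`write_bundle`).  The same config and seed always
    produce byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    usage = default_codon_usage()
    cohort = simulate_gainloss_cohort(config, rng)
    exp = config.expression

    ortho_rows = []
    hits_rows = []
    species_hits_rows = []
    genes_rows = []
    snps_rows = []
    truth_rows = []

    updated_lens = []
    for rec in cohort.to_dict("records"):
        k = rec["age_class"]
        orphan = k < OLD_AGE_CLASS
        gene_id = rec["gene_id"]
        conserved = rec["conserved"]
        # base-composition and codon-usage tilts per gene class; conserved
        # orphans get a mild GC boost over lost ones
        gc_w = (1.0 if not orphan else 0.4) + (
            0.35 if orphan and conserved else 0.0
        )
        cai_w = 1.0 if not orphan else 0.25
        cds = random_cds(rng, rec["n_codons"], gc_w, cai_w, usage)
        ssr_p = config.ssr_insert_prob * (
            1.0 if not orphan else (1.6 if conserved else 3.0)
        )
        if rng.random() < ssr_p:
            cds = _insert_ssr(cds, rng)
        rec["cds_len"] = len(cds)
        updated_lens.append(len(cds))
        total_codons = len(cds) // 3

        omega = config.dnds_by_class[k]
        leaves = subtree_leaves(k)
        losses = []
        for sp in ("persimilis", "miranda", "lowei", "affinis"):
            if sp not in leaves:
                continue
            status = rec.get(f"status_{sp}", "intact")
            if status == "deleted":
                losses.append(f"{sp}:deletion")
                continue
            sp_cds = evolve_cds(
                cds, omega, config.ds_target * BRANCH_DS_MULT[sp], rng
            )
            if status == "lost":
                kind = rec[f"loss_kind_{sp}"]
                idx = int(rng.integers(2, total_codons - 1))
                sp_cds, _ev = inject_disruption(
                    sp_cds, kind, (idx - 0.5) / total_codons, rng,
                    gene_id=gene_id, species=sp,
                )
                losses.append(f"{sp}:{kind}")
            frac = (
                round(0.9 + 0.1 * rng.random(), 4)
                if orphan
                else round(1.0 - 0.3 * rng.beta(1.5, 6.0), 4)
            )
            ortho_rows.append(
                {
                    "gene_id": gene_id,
                    "species": sp,
                    "chrom_arm": rec["chrom_arm"],
                    "aligned_fraction": frac,
                    "cds_seq": sp_cds,
                    "flank_left_in_contig": bool(rng.random() < 0.92),
                    "flank_right_in_contig": bool(rng.random() < 0.92),
                }
            )
            species_hits_rows.append(
                {
                    "gene_id": gene_id,
                    "species": sp,
                    "evalue": float(10.0 ** -rng.uniform(6, 40)),
                }
            )
        ortho_rows.append(
            {
                "gene_id": gene_id,
                "species": FOCAL_SPECIES,
                "chrom_arm": rec["chrom_arm"],
                "aligned_fraction": 1.0,
                "cds_seq": cds,
                "flank_left_in_contig": True,
                "flank_right_in_contig": True,
            }
        )

        curated = bool((not orphan) and rng.random() < 0.9)
        genes_rows.append({"gene_id": gene_id, "curated_ortholog": curated})
        if not orphan:
            n_hits = int(rng.integers(1, 4))
            for sp in rng.choice(OUTGROUP_SPECIES, size=n_hits, replace=False):
                hits_rows.append(
                    {
                        "qseqid": gene_id,
                        "sspecies": str(sp),
                        "program": "protein-vs-protein",
                        "evalue": float(10.0 ** -rng.uniform(5, 40)),
                    }
                )
        elif rng.random() < 0.15:
            hits_rows.append(
                {
                    "qseqid": gene_id,
                    "sspecies": str(rng.choice(OUTGROUP_SPECIES)),
                    "program": "protein-vs-genome",
                    "evalue": float(10.0 ** -rng.uniform(0.0, 3.5)),
                }
            )

        lam_s, lam_n = (2.0, 0.6) if not orphan else (1.5, 1.2)
        n_syn = int(rng.poisson(lam_s))
        n_non = int(rng.poisson(lam_n))
        try:
            for pos, ref, alt in inject_snps(cds, n_syn, n_non, rng):
                snps_rows.append(
                    {
                        "gene_id": gene_id,
                        "cds_pos_1based": pos,
                        "ref": ref,
                        "alt": alt,
                    }
                )
        except ValueError:
            pass  # tiny CDS: skip polymorphism for this gene

        truth_rows.append(
            {
                "gene_id": gene_id,
                "true_age_class": k,
                "true_losses": ";".join(losses),
                "true_dnds": omega,
                "true_log2fc": rec["log2fc"],
            }
        )

    cohort["cds_len"] = updated_lens
    orthologs = pd.DataFrame(ortho_rows)
    truth = pd.DataFrame(truth_rows)

    # --- expression matrix -------------------------------------------------
    nrep = exp.n_replicates_per_sex
    sample_names = [f"male_{i+1}" for i in range(nrep)] + [
        f"female_{i+1}" for i in range(nrep)
    ]
    samples = pd.DataFrame(
        {
            "sample": sample_names,
            "sex": ["male"] * nrep + ["female"] * nrep,
            "strain": [f"s{i+1}" for i in range(nrep)] * 2,
        }
    )
    lib_factor = np.exp(rng.normal(0.0, 0.15, size=2 * nrep))
    # expected fragment counts scale with transcript length, so log_mean is
    # an FPKM-like intensity and short orphans stay lowly expressed
    base = np.exp(cohort["log_mean"].to_numpy()) * (
        cohort["cds_len"].to_numpy() / 1000.0
    )
    fc = 2.0 ** (cohort["log2fc"].to_numpy() / 2.0)
    mean_m = base * fc
    mean_f = base / fc
    count_cols = {}
    for j, name in enumerate(sample_names):
        mu = (mean_m if samples.loc[j, "sex"] == "male" else mean_f) * lib_factor[j]
        count_cols[name] = _nb_counts(rng, mu, exp.nb_dispersion)
    counts = pd.DataFrame(count_cols, index=cohort["gene_id"])
    counts.index.name = "gene_id"

    # --- intergenic regions -------------------------------------------------
    orphan_lens = cohort.loc[cohort["age_class"] < 5, "cds_len"].to_numpy()
    max_len = int(orphan_lens.max()) if len(orphan_lens) else 3000
    region_lens = [
        int(L * rng.uniform(2.0, 4.0))
        for L in rng.choice(orphan_lens, size=max(30, len(orphan_lens) // 2))
    ] + [2 * max_len + 100] * 10
    intergenic = []
    intergenic_affinis = []
    gc_p = np.array([0.29, 0.21, 0.21, 0.29])
    d_aff = config.ds_target * BRANCH_DS_MULT["affinis"]
    for i, L in enumerate(region_lens):
        seq = "".join(rng.choice(list("ATCG"), size=L, p=gc_p))
        rid = f"ig{i+1:04d}"
        intergenic.append((rid, seq))
        intergenic_affinis.append((rid, _mutate_neutral(seq, d_aff, rng)))

    bundle = {
        "orthologs": orthologs,
        "genes": pd.DataFrame(genes_rows),
        "hits": pd.DataFrame(
            hits_rows, columns=["qseqid", "sspecies", "program", "evalue"]
        ),
        "species_hits": pd.DataFrame(
            species_hits_rows, columns=["gene_id", "species", "evalue"]
        ),
        "snps": pd.DataFrame(
            snps_rows, columns=["gene_id", "cds_pos_1based", "ref", "alt"]
        ),
        "counts": counts,
        "samples": samples,
        "intergenic": intergenic,
        "intergenic_affinis": intergenic_affinis,
        "codon_usage": usage,
        "config": config,
    }
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_bundle(bundle: dict, truth: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a simulated bundle as the standard plain-text file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    orthologs: pd.DataFrame = bundle["orthologs"]
    for sp, sub in orthologs.groupby("species"):
        _write_fasta(
            list(zip(sub["gene_id"], sub["cds_seq"])), out / f"cds_{sp}.fasta"
        )
    orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    bundle["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)
    bundle["hits"].to_csv(out / "hits.tsv", sep="\t", index=False)
    bundle["species_hits"].to_csv(out / "species_hits.tsv", sep="\t", index=False)
    bundle["snps"].to_csv(out / "snps.tsv", sep="\t", index=False)
    bundle["counts"].to_csv(out / "counts.tsv", sep="\t")
    bundle["samples"].to_csv(out / "samples.tsv", sep="\t", index=False)
    _write_fasta(bundle["intergenic"], out / "intergenic.fasta")
    _write_fasta(bundle["intergenic_affinis"], out / "intergenic_affinis.fasta")
    bundle["codon_usage"].to_tsv(out / "codon_usage.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["loss_prob"] = {f"{b}:{k}": p for (b, k), p in config.loss_prob.items()}
    return d
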