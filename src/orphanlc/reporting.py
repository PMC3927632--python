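"""End-to-end pipeline orchestration and group contrasts.

``run_pipeline`` executes orthology -> orfscan -> gainloss -> seqfeatures ->
evorates -> expression on a file bundle (synthetic or user-supplied), writes
one TSV per result table plus a machine-readable run manifest, and is
byte-identical across reruns with a fixed seed.  ``contrast_features`` runs
the two-group comparisons (orphan vs old, conserved vs lost orphans) with
Mann-Whitney / chi-square / Fisher tests and Benjamini-Hochberg adjustment
within each contrast family.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .evorates import ng86_dnds, pnps, prepare_codon_alignment, sample_matched_intergenic
from .expression import (
    bias_retention_correlation,
    expression_trend_by_age,
    fpkm,
    normalize_counts,
    sex_bias,
    size_factors,
)
from .gainloss import (
    CALLABLE_BRANCHES,
    FOCAL_SPECIES,
    OLD_AGE_CLASS,
    assign_age_class,
    call_losses,
    classify_deletion,
    disabling_vs_deletion_share,
    loss_fraction_table,
    subtree_leaves,
)
from .orfscan import classify_pseudogene, detect_frameshifts, scan_ptc
from .orthology import (
    HomologyHit,
    classify_orphan,
    empirical_cutoff,
    filter_orthologs,
    OrthologRow,
)
from .seqfeatures import CodonUsageTable, cai, find_ssrs, gc_content, ssr_fraction_of_cds

REQUIRED_FILES = (
    "orthologs.tsv",
    "genes.tsv",
    "hits.tsv",
    "snps.tsv",
    "counts.tsv",
    "samples.tsv",
    "intergenic.fasta",
    "codon_usage.tsv",
)

EXPECTED_OUTPUTS = (
    "cutoffs.tsv",
    "orphans.tsv",
    "disruptions.tsv",
    "pseudogenes.tsv",
    "ages.tsv",
    "losses.tsv",
    "deletions.tsv",
    "loss_fractions.tsv",
    "features.tsv",
    "rates.tsv",
    "intergenic_rates.tsv",
    "pnps.tsv",
    "sexbias.tsv",
    "bias_retention.tsv",
    "expression_by_age.tsv",
    "contrasts.tsv",
)

_FLOAT_FMT = "%.6g"


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def load_bundle(bundle_dir: str | Path) -> dict:
    """Read a bundle directory into memory, erroring on missing files."""
    d = Path(bundle_dir)
    for name in REQUIRED_FILES:
        if not (d / name).exists():
            raise FileNotFoundError(f"required input file missing: {d / name}")
    bundle = {
        "orthologs": pd.read_csv(d / "orthologs.tsv", sep="\t"),
        "genes": pd.read_csv(d / "genes.tsv", sep="\t"),
        "hits": pd.read_csv(d / "hits.tsv", sep="\t"),
        "snps": pd.read_csv(d / "snps.tsv", sep="\t"),
        "counts": pd.read_csv(d / "counts.tsv", sep="\t", index_col="gene_id"),
        "samples": pd.read_csv(d / "samples.tsv", sep="\t"),
        "intergenic": _read_fasta(d / "intergenic.fasta"),
        "codon_usage": CodonUsageTable.from_tsv(d / "codon_usage.tsv"),
    }
    sp_hits = d / "species_hits.tsv"
    bundle["species_hits"] = (
        pd.read_csv(sp_hits, sep="\t")
        if sp_hits.exists()
        else pd.DataFrame(columns=["gene_id", "species", "evalue"])
    )
    aff = d / "intergenic_affinis.fasta"
    bundle["intergenic_affinis"] = _read_fasta(aff) if aff.exists() else None
    return bundle


def _global_align(ref: str, query: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    aln = aligner.align(ref, query)[0]
    return str(aln[0]), str(aln[1])


def _project_to_ref_frame(ref_aln: str, sp_aln: str) -> str:
    """Species sequence in reference coordinates: insertion columns dropped,
    deleted positions filled with N (ambiguous for stop-codon calling)."""
    return "".join(
        (s if s != "-" else "N")
        for r, s in zip(ref_aln, sp_aln)
        if r != "-"
    )


def scan_ortholog_pair(
    gene_id: str, species: str, ref_cds: str, sp_cds: str
) -> list:
    """Disruption events for one species CDS against the reference CDS."""
    if len(sp_cds) == len(ref_cds):
        return scan_ptc(sp_cds, gene_id, species)
    ref_aln, sp_aln = _global_align(ref_cds, sp_cds)
    events = detect_frameshifts(ref_aln, sp_aln, gene_id, species)
    projected = _project_to_ref_frame(ref_aln, sp_aln)
    events += scan_ptc(projected, gene_id, species)
    return sorted(events, key=lambda e: e.codon_index)


def contrast_features(
    df: pd.DataFrame,
    group_col: str,
    features: list[str],
    categorical: tuple[str, ...] = ("bias",),
) -> pd.DataFrame:
    """Two-sided two-group tests per feature with BH adjustment.

    Numeric features use Mann-Whitney; categorical ones chi-square (Fisher
    for sparse 2x2).  Degenerate features (constant, or a group below two
    observations) are skipped with a warning.
    """
    groups = [g for g in df[group_col].dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"{group_col} must define exactly two groups")
    g1, g2 = sorted(map(str, groups))
    records = []
    for feat in features:
        a = df.loc[df[group_col].astype(str) == g1, feat].dropna()
        b = df.loc[df[group_col].astype(str) == g2, feat].dropna()
        if feat in categorical:
            tab = pd.crosstab(df[group_col].astype(str), df[feat])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                warnings.warn(f"contrast for {feat} skipped: degenerate table")
                continue
            if tab.shape == (2, 2) and (tab.to_numpy() < 5).any():
                stat, p = stats.fisher_exact(tab.to_numpy())
                test = "fisher"
            else:
                stat, p, _, _ = stats.chi2_contingency(tab.to_numpy())
                test = "chi-square"
            records.append(
                {
                    "feature": feat,
                    "test": test,
                    "group1": g1,
                    "group2": g2,
                    "median1": np.nan,
                    "median2": np.nan,
                    "direction": "",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
            continue
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"contrast for {feat} skipped: group below 2 values")
            continue
        pooled = pd.concat([a, b])
        if pooled.nunique() <= 1:
            warnings.warn(f"contrast for {feat} skipped: constant feature")
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        m1, m2 = float(a.median()), float(b.median())
        records.append(
            {
                "feature": feat,
                "test": "mann-whitney",
                "group1": g1,
                "group2": g2,
                "median1": m1,
                "median2": m2,
                "direction": f"{g1}>{g2}" if m1 > m2 else f"{g1}<{g2}",
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def run_pipeline(
    bundle_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    mode: str = "any",
    strict: bool = False,
    synteny: bool = False,
    n_bias_bins: int = 7,
    outputs: tuple[str, ...] | None = None,
) -> dict:
    """Execute the full analysis on a bundle directory.

    Writes all result TSVs plus ``manifest.json`` to ``out_dir`` and returns
    the result tables.  ``seed`` drives the intergenic-null sampling (the
    only stochastic step).  ``mode`` selects plain ('any') or conservative
    ('first_half') pseudogene calling.
    """
    bundle = load_bundle(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}}

    # ---------------- orthology ----------------
    orthologs = bundle["orthologs"]
    genes = bundle["genes"].set_index("gene_id")
    hits_by_gene: dict[str, list[HomologyHit]] = {}
    for r in bundle["hits"].itertuples():
        hits_by_gene.setdefault(r.qseqid, []).append(
            HomologyHit(r.qseqid, r.sspecies, r.program, r.evalue)
        )
    classification = pd.DataFrame(
        {
            "gene_id": genes.index,
            "classification": [
                classify_orphan(
                    g, hits_by_gene.get(g, []), bool(genes.loc[g, "curated_ortholog"])
                )
                for g in genes.index
            ],
        }
    )
    old_ids = set(
        classification.loc[
            classification["classification"] == "old", "gene_id"
        ]
    )

    non_focal = orthologs[orthologs["species"] != FOCAL_SPECIES]
    cutoffs = {}
    for sp, sub in non_focal.groupby("species"):
        old_fracs = sub.loc[
            sub["gene_id"].isin(old_ids), "aligned_fraction"
        ].tolist()
        cutoffs[sp] = empirical_cutoff(old_fracs)
    cutoffs_df = pd.DataFrame(
        sorted(cutoffs.items()), columns=["species", "cutoff"]
    )

    rows = [
        OrthologRow(
            r.gene_id,
            r.species,
            str(r.chrom_arm),
            r.aligned_fraction,
            r.cds_seq,
            (bool(r.flank_left_in_contig), bool(r.flank_right_in_contig))
            if hasattr(r, "flank_left_in_contig")
            else None,
        )
        for r in non_focal.itertuples()
    ]
    retained, dropped = filter_orthologs(rows, cutoffs)
    if synteny:
        from .orthology import synteny_conservative_set

        # reference gene order: consecutive gene ids on the same arm
        focal = orthologs[orthologs["species"] == FOCAL_SPECIES].sort_values(
            "gene_id"
        )
        neighbor_map = {}
        ids = focal["gene_id"].tolist()
        for i, g in enumerate(ids):
            neighbor_map[g] = (
                ids[i - 1] if i > 0 else None,
                ids[i + 1] if i < len(ids) - 1 else None,
            )
        retained = synteny_conservative_set(retained, neighbor_map)
    log["stages"]["orthology"] = {
        "n_genes": int(len(genes)),
        "n_orphans": int((classification["classification"] == "orphan").sum()),
        "rows_in": int(len(rows)),
        "rows_retained": int(len(retained)),
        "rows_dropped": int(len(dropped)),
    }

    # ---------------- orfscan ----------------
    ref_cds = dict(
        zip(
            orthologs.loc[orthologs["species"] == FOCAL_SPECIES, "gene_id"],
            orthologs.loc[orthologs["species"] == FOCAL_SPECIES, "cds_seq"],
        )
    )
    events_by_pair: dict[tuple[str, str], list] = {}
    for row in retained:
        evs = scan_ortholog_pair(
            row.gene_id, row.species, ref_cds[row.gene_id], row.cds
        )
        events_by_pair[(row.gene_id, row.species)] = evs
    disruptions = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "species": e.species,
                "kind": e.kind,
                "codon_index": e.codon_index,
                "rel_pos": e.rel_pos,
            }
            for evs in events_by_pair.values()
            for e in evs
        ],
        columns=["gene_id", "species", "kind", "codon_index", "rel_pos"],
    ).sort_values(["gene_id", "species", "codon_index"], ignore_index=True)
    pseudogenes = pd.DataFrame(
        [
            {
                "gene_id": g,
                "species": sp,
                "pseudogene_any": classify_pseudogene(evs, g, sp, "any").is_pseudogene,
                "pseudogene_first_half": classify_pseudogene(
                    evs, g, sp, "first_half"
                ).is_pseudogene,
            }
            for (g, sp), evs in sorted(events_by_pair.items())
        ],
        columns=["gene_id", "species", "pseudogene_any", "pseudogene_first_half"],
    )
    log["stages"]["orfscan"] = {
        "pairs_scanned": int(len(events_by_pair)),
        "n_events": int(len(disruptions)),
    }

    # ---------------- gainloss ----------------
    sp_hits_by_pair: dict[tuple[str, str], list[HomologyHit]] = {}
    for r in bundle["species_hits"].itertuples():
        sp_hits_by_pair.setdefault((r.gene_id, r.species), []).append(
            HomologyHit(r.gene_id, r.species, "nucleotide-vs-genome", r.evalue)
        )
    retained_pairs = {(r.gene_id, r.species) for r in retained}
    gene_records = []
    loss_rows = []
    deletion_rows = []
    for g in genes.index:
        is_old = g in old_ids
        intactness = {FOCAL_SPECIES: "intact"}
        events_by_species = {}
        for sp in ("persimilis", "miranda", "lowei", "affinis"):
            if (g, sp) not in retained_pairs:
                intactness[sp] = "absent"
                continue
            evs = events_by_pair.get((g, sp), [])
            if mode == "first_half":
                evs_eff = [e for e in evs if e.rel_pos <= 0.5]
            else:
                evs_eff = evs
            intactness[sp] = "disrupted" if evs_eff else "intact"
            events_by_species[sp] = evs
        k = assign_age_class(intactness, old=is_old)
        calls = call_losses(g, intactness, k, events_by_species, mode, strict)
        called = {c.branch for c in calls}
        loss_rows += [
            {"gene_id": g, "branch": c.branch, "mode": c.mode, "kind": c.kind}
            for c in calls
        ]
        rec = {
            "gene_id": g,
            "age_class": k,
            "chrom_arm": str(
                orthologs.loc[
                    (orthologs["gene_id"] == g)
                    & (orthologs["species"] == FOCAL_SPECIES),
                    "chrom_arm",
                ].iloc[0]
            ),
            "cds_len": len(ref_cds[g]),
        }
        for branch in CALLABLE_BRANCHES:
            if branch not in subtree_leaves(k):
                rec[f"status_{branch}"] = "absent"
            elif branch in called:
                rec[f"status_{branch}"] = "lost"
            elif intactness[branch] == "intact":
                rec[f"status_{branch}"] = "intact"
            else:
                # absent inside the age subtree: deletion candidate
                if intactness[branch] == "absent":
                    deleted = classify_deletion(
                        False, sp_hits_by_pair.get((g, branch), [])
                    )
                    rec[f"status_{branch}"] = "deleted" if deleted else "absent"
                    if deleted:
                        deletion_rows.append({"gene_id": g, "branch": branch})
                else:
                    rec[f"status_{branch}"] = "absent"
        gene_records.append(rec)
    gene_table = pd.DataFrame(gene_records)
    ages = gene_table[["gene_id", "age_class"]]
    losses = pd.DataFrame(
        loss_rows, columns=["gene_id", "branch", "mode", "kind"]
    )
    deletions = pd.DataFrame(deletion_rows, columns=["gene_id", "branch"])
    loss_fractions = loss_fraction_table(gene_table, normalize=True)
    share = disabling_vs_deletion_share(len(losses), len(deletions))
    log["stages"]["gainloss"] = {
        "n_losses": int(len(losses)),
        "n_deletions": int(len(deletions)),
        "disabling_share": share,
    }

    # ---------------- seqfeatures ----------------
    usage = bundle["codon_usage"]
    feat_rows = []
    for g in genes.index:
        cds = ref_cds[g]
        hits = find_ssrs(cds)
        feat_rows.append(
            {
                "gene_id": g,
                "cds_len": len(cds),
                "gc": gc_content(cds),
                "cai": cai(cds, usage),
                "ssr_fraction": ssr_fraction_of_cds(cds, hits),
            }
        )
    features = pd.DataFrame(feat_rows)
    log["stages"]["seqfeatures"] = {"n_genes": int(len(features))}

    # ---------------- evorates ----------------
    sp_cds = {
        (r.gene_id, r.species): r.cds_seq for r in non_focal.itertuples()
    }
    rate_rows = []
    for g in genes.index:
        pair = (g, "affinis")
        if pair not in retained_pairs or events_by_pair.get(pair):
            continue
        aln = prepare_codon_alignment(ref_cds[g], sp_cds[pair])
        est = ng86_dnds(aln)
        rate_rows.append(
            {
                "gene_id": g,
                "dn": est.dn,
                "ds": est.ds,
                "dnds": est.dnds if est.dnds is not None else np.nan,
                "syn_sites": est.syn_sites,
                "nonsyn_sites": est.nonsyn_sites,
                "flags": ";".join(est.flags),
            }
        )
    rates = pd.DataFrame(
        rate_rows,
        columns=["gene_id", "dn", "ds", "dnds", "syn_sites", "nonsyn_sites", "flags"],
    )

    orphan_ids = set(classification["gene_id"]) - old_ids
    ig_rows = []
    if bundle["intergenic_affinis"] is not None:
        aff_by_id = dict(bundle["intergenic_affinis"])
        orphan_lens = sorted(
            len(ref_cds[g]) for g in genes.index if g in orphan_ids
        )
        sampled = sample_matched_intergenic(
            orphan_lens, bundle["intergenic"], np.random.default_rng(seed)
        )
        for i, (rid, start, sub) in enumerate(sampled):
            counterpart = aff_by_id[rid][start : start + len(sub)]
            aln = prepare_codon_alignment(sub, counterpart)
            est = ng86_dnds(aln)
            ig_rows.append(
                {
                    "region": f"{rid}:{start}",
                    "length": len(sub),
                    "dn": est.dn,
                    "ds": est.ds,
                    "dnds": est.dnds if est.dnds is not None else np.nan,
                }
            )
    intergenic_rates = pd.DataFrame(
        ig_rows, columns=["region", "length", "dn", "ds", "dnds"]
    )

    snps = bundle["snps"]
    pnps_rows = []
    for g, sub in snps.groupby("gene_id"):
        summ = pnps(
            g,
            ref_cds[g],
            list(zip(sub["cds_pos_1based"], sub["ref"], sub["alt"])),
        )
        ratio = summ.pnps()
        pnps_rows.append(
            {
                "gene_id": g,
                "syn_count": summ.syn_count,
                "nonsyn_count": summ.nonsyn_count,
                "syn_sites": summ.syn_sites,
                "nonsyn_sites": summ.nonsyn_sites,
                "pnps": ratio if ratio is not None else np.nan,
            }
        )
    pnps_df = pd.DataFrame(
        pnps_rows,
        columns=["gene_id", "syn_count", "nonsyn_count", "syn_sites", "nonsyn_sites", "pnps"],
    )
    log["stages"]["evorates"] = {
        "n_pairs": int(len(rates)),
        "n_intergenic": int(len(intergenic_rates)),
    }

    # ---------------- expression ----------------
    counts, samples = bundle["counts"], bundle["samples"]
    factors = size_factors(counts)
    calls = sex_bias(counts, samples, factors)
    lengths = features.set_index("gene_id")["cds_len"]
    fpkm_mat = fpkm(counts, lengths)
    male_samples = samples.loc[samples["sex"] == "male", "sample"]
    male_fpkm = fpkm_mat[male_samples].mean(axis=1)
    female_fpkm = fpkm_mat[
        samples.loc[samples["sex"] == "female", "sample"]
    ].mean(axis=1)

    status_cols = [f"status_{b}" for b in CALLABLE_BRANCHES]
    gt = gene_table.set_index("gene_id")
    any_loss = (gt[status_cols] == "lost").any(axis=1) | (
        gt[status_cols] == "deleted"
    ).any(axis=1)
    conserved_flags = ~any_loss
    lost_lp = (
        (gt["status_lowei"] == "lost") | (gt["status_persimilis"] == "lost")
    )

    orphan_mask = gt["age_class"] < OLD_AGE_CLASS
    try:
        br = bias_retention_correlation(
            calls[calls["gene_id"].isin(gt.index[orphan_mask])],
            conserved_flags[orphan_mask],
            n_bins=n_bias_bins,
        )
        bias_retention = br.bin_table.assign(rho=br.rho, p_value=br.p_value)
    except ValueError as exc:
        warnings.warn(f"bias-retention correlation unavailable: {exc}")
        bias_retention = pd.DataFrame(
            columns=["bin", "n", "mean_abs_log2fc", "conserved_fraction", "rho", "p_value"]
        )
    norm_male = normalize_counts(counts, factors)[male_samples].mean(axis=1)
    trend = expression_trend_by_age(
        norm_male[orphan_mask.index[orphan_mask]],
        gt.loc[orphan_mask, "age_class"],
        conserved_flags[orphan_mask],
    )
    log["stages"]["expression"] = {
        "n_male_biased": int((calls["bias"] == "male").sum()),
        "n_female_biased": int((calls["bias"] == "female").sum()),
    }

    # ---------------- contrasts ----------------
    master = (
        features.merge(classification, on="gene_id")
        .merge(rates[["gene_id", "dnds"]], on="gene_id", how="left")
        .merge(calls, on="gene_id")
    )
    master["fpkm_male"] = master["gene_id"].map(male_fpkm)
    master["fpkm_female"] = master["gene_id"].map(female_fpkm)
    feature_list = [
        "cds_len", "gc", "cai", "ssr_fraction", "dnds",
        "fpkm_male", "fpkm_female", "log2fc", "bias",
    ]
    def _safe_contrast(df, group_col, label):
        counts_by_group = df[group_col].value_counts()
        if len(counts_by_group) != 2 or counts_by_group.min() < 2:
            warnings.warn(f"contrast {label} skipped: degenerate grouping")
            return pd.DataFrame()
        return contrast_features(df, group_col, feature_list).assign(
            contrast=label
        )

    c1 = _safe_contrast(master, "classification", "orphan-vs-old")
    orph = master[master["classification"] == "orphan"].copy()
    orph["fate"] = np.where(
        orph["gene_id"].map(conserved_flags),
        "conserved",
        np.where(orph["gene_id"].map(lost_lp), "lost", "other"),
    )
    orph = orph[orph["fate"] != "other"]
    c2 = _safe_contrast(orph, "fate", "conserved-vs-lost")
    contrasts = pd.concat([c1, c2], ignore_index=True)

    # ---------------- write ----------------
    tables = {
        "cutoffs.tsv": cutoffs_df,
        "orphans.tsv": classification,
        "disruptions.tsv": disruptions,
        "pseudogenes.tsv": pseudogenes,
        "ages.tsv": ages,
        "losses.tsv": losses,
        "deletions.tsv": deletions,
        "loss_fractions.tsv": loss_fractions,
        "features.tsv": features,
        "rates.tsv": rates,
        "intergenic_rates.tsv": intergenic_rates,
        "pnps.tsv": pnps_df,
        "sexbias.tsv": calls,
        "bias_retention.tsv": bias_retention,
        "expression_by_age.tsv": trend,
        "contrasts.tsv": contrasts,
    }
    for name, df in tables.items():
        if outputs is not None and name not in outputs:
            continue
        df.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest = {
        "package": "orphanlc",
        "version": __version__,
        "seed": seed,
        "mode": mode,
        "strict": strict,
        "synteny": synteny,
        "stages": log["stages"],
        "outputs": sorted(tables),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tables["manifest"] = manifest
    return tables
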