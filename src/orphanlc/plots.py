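"""Quick-look figures from a pipeline results directory.

Four summary panels at synthetic scale: loss fraction by age class and
branch, the PTC position histogram along the ORF, dN/dS of orphans vs old
genes vs the intergenic null, and conserved fraction vs sex-bias strength.
Plots are a convenience view of the TSV tables; every number shown is read
back from the written results, never recomputed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_summary(results_dir: str | Path, out_dir: str | Path | None = None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    out = Path(out_dir) if out_dir else res
    out.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))

    lf = pd.read_csv(res / "loss_fractions.tsv", sep="\t")
    ax = axes[0, 0]
    for branch, sub in lf.groupby("branch"):
        sub = sub.dropna(subset=["fraction"])
        ax.plot(sub["age_class"], sub["fraction"], "o-", label=branch)
    ax.set_xlabel("age class")
    ax.set_ylabel("loss fraction")
    ax.set_title("Orphan loss by age class")
    ax.legend(fontsize=8)

    dis = pd.read_csv(res / "disruptions.tsv", sep="\t")
    ax = axes[0, 1]
    ptc = dis[dis["kind"] == "PTC"]
    if len(ptc):
        ax.hist(ptc["rel_pos"], bins=10, range=(0, 1), color="tab:red")
    ax.set_xlabel("relative ORF position")
    ax.set_ylabel("PTC count")
    ax.set_title("Premature stop codons along the ORF")

    rates = pd.read_csv(res / "rates.tsv", sep="\t")
    orphans = pd.read_csv(res / "orphans.tsv", sep="\t")
    ig = pd.read_csv(res / "intergenic_rates.tsv", sep="\t")
    merged = rates.merge(orphans, on="gene_id")
    groups = {
        "old": merged.loc[merged["classification"] == "old", "dnds"].dropna(),
        "orphan": merged.loc[
            merged["classification"] == "orphan", "dnds"
        ].dropna(),
        "intergenic": ig["dnds"].dropna(),
    }
    ax = axes[1, 0]
    ax.boxplot(
        [v for v in groups.values() if len(v)],
        tick_labels=[k for k, v in groups.items() if len(v)],
        showfliers=False,
    )
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_ylabel("dN/dS")
    ax.set_title("Purifying selection on orphans")

    br = pd.read_csv(res / "bias_retention.tsv", sep="\t")
    ax = axes[1, 1]
    if len(br):
        ax.plot(br["bin"], br["conserved_fraction"], "s-")
        rho = br["rho"].iloc[0]
        ax.set_title(f"Retention vs male-bias strength (rho={rho:.2f})")
    else:
        ax.set_title("Retention vs male-bias strength (no data)")
    ax.set_xlabel("bias-strength bin")
    ax.set_ylabel("conserved fraction")

    fig.tight_layout()
    path = out / "summary.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
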