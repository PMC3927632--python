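import numpy as np
import pandas as pd
import pytest

from orphanlc.codons import STOP_CODONS, iter_codons
from orphanlc.gainloss import subtree_leaves
from orphanlc.orfscan import scan_ptc
from orphanlc.simulate import (
    SimulationConfig,
    evolve_cds,
    inject_disruption,
    random_cds,
    simulate_codon_pair,
    simulate_dataset,
    uniform_loss_prob,
)

from conftest import small_config


class TestConfigValidation:
    def test_bad_probability(self):
        cfg = SimulationConfig(loss_prob={("miranda", 2): 1.5})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_zero_genes(self):
        cfg = SimulationConfig(n_genes_per_class={})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_dispersion(self):
        cfg = SimulationConfig()
        cfg.expression.nb_dispersion = 0.0
        with pytest.raises(ValueError):
            cfg.validate()


class TestSimulateCodonPair:
    def test_zero_divergence_identical(self):
        anc, der = simulate_codon_pair(50, 0.5, 0.0, 1)
        assert anc == der

    def test_invalid_dnds(self):
        with pytest.raises(ValueError):
            simulate_codon_pair(50, 0.0, 0.1, 1)
        with pytest.raises(ValueError):
            simulate_codon_pair(5, 0.5, 0.1, 1)

    def test_ancestor_is_intact_orf(self, rng):
        for _ in range(50):
            anc, der = simulate_codon_pair(60, 0.5, 0.3, rng)
            assert anc.startswith("ATG")
            internal = [c for i, c in iter_codons(anc) if i < 59]
            assert not any(c in STOP_CODONS for c in internal)
            # evolution never creates stops either
            assert not any(
                c in STOP_CODONS for i, c in iter_codons(der) if i < 59
            )

    def test_divergence_scales_with_ds(self, rng):
        low = [simulate_codon_pair(200, 1.0, 0.02, rng) for _ in range(10)]
        high = [simulate_codon_pair(200, 1.0, 0.4, rng) for _ in range(10)]

        def mean_diff(pairs):
            return np.mean(
                [sum(x != y for x, y in zip(a, d)) for a, d in pairs]
            )

        assert mean_diff(high) > mean_diff(low) * 5


class TestInjectDisruption:
    def cds(self, rng, n=10):
        return random_cds(rng, n)

    def test_ptc_position_arithmetic(self, rng):
        mutated, event = inject_disruption(self.cds(rng), "PTC", 0.4, rng)
        assert event.codon_index == 4
        assert mutated[9:12] in STOP_CODONS
        assert len(mutated) == 30

    def test_frameshift_length_out_of_frame(self, rng):
        cds = self.cds(rng)
        mutated, event = inject_disruption(cds, "frameshift", 0.5, rng)
        assert abs(len(mutated) - len(cds)) % 3 != 0
        assert event.kind == "frameshift"

    def test_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            inject_disruption(self.cds(rng, 4), "PTC", 0.99, rng)

    def test_scan_recovers_injection(self, rng):
        for _ in range(100):
            total = int(rng.integers(10, 80))
            cds = self.cds(rng, total)
            idx = int(rng.integers(2, total - 1))
            mutated, event = inject_disruption(
                cds, "PTC", (idx - 0.5) / total, rng
            )
            assert [e.codon_index for e in scan_ptc(mutated)] == [idx]


class TestSimulateDataset:
    def test_zero_loss_prob_no_disruptions(self, tmp_path):
        cfg = SimulationConfig(
            seed=3,
            n_genes_per_class={2: 20, 4: 15},
            loss_prob=uniform_loss_prob({k: 0.0 for k in range(1, 6)}),
        )
        bundle, truth = simulate_dataset(cfg)
        assert (truth["true_losses"] == "").all()
        for r in bundle["orthologs"].itertuples():
            assert scan_ptc(r.cds_seq) == []
            assert len(r.cds_seq) % 3 == 0

    def test_loss_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(
            seed=5,
            n_genes_per_class={4: 100},
            loss_prob={("miranda", 4): 0.3},
            deletion_frac=0.0,
            retention_bias_coupling=0.0,
            retention_expression_coupling=0.0,
        )
        _, truth = simulate_dataset(cfg)
        lost = truth["true_losses"].str.contains("miranda").sum()
        half_width = 1.96 * np.sqrt(0.3 * 0.7 / 100)
        assert abs(lost / 100 - 0.3) <= half_width

    def test_same_seed_identical_files(self, tmp_path):
        cfg = small_config(seed=21)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(small_config(seed=21), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_dollo_consistency_of_truth(self, small_bundle_dir):
        """Every simulated gene's presence pattern is one gain at its true
        age class plus its listed losses — nothing else."""
        truth = pd.read_csv(small_bundle_dir / "truth.tsv", sep="\t").fillna(
            {"true_losses": ""}
        )
        orthologs = pd.read_csv(small_bundle_dir / "orthologs.tsv", sep="\t")
        present = set(zip(orthologs["gene_id"], orthologs["species"]))
        for rec in truth.itertuples():
            leaves = subtree_leaves(rec.true_age_class)
            lost = {
                e.split(":")[0]: e.split(":")[1]
                for e in str(rec.true_losses).split(";")
                if e
            }
            for sp in ("persimilis", "miranda", "lowei", "affinis"):
                has_row = (rec.gene_id, sp) in present
                if sp not in leaves:
                    assert not has_row  # outside the gain subtree
                elif lost.get(sp) == "deletion":
                    assert not has_row
                else:
                    assert has_row

    def test_truth_losses_confined_to_subtree(self, small_bundle_dir):
        truth = pd.read_csv(small_bundle_dir / "truth.tsv", sep="\t").fillna(
            {"true_losses": ""}
        )
        for rec in truth.itertuples():
            leaves = subtree_leaves(rec.true_age_class)
            for entry in str(rec.true_losses).split(";"):
                if entry:
                    assert entry.split(":")[0] in leaves


class TestEvolveCds:
    def test_start_and_stop_frozen(self, rng):
        cds = random_cds(rng, 40)
        der = evolve_cds(cds, 1.0, 0.5, rng)
        assert der.startswith("ATG")
        assert der[-3:] == cds[-3:]
        assert len(der) == len(cds)
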