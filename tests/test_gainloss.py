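import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import dollo_oracle
from orphanlc.gainloss import (
    assign_age_class,
    call_losses,
    classify_deletion,
    cochran_armitage_trend,
    disabling_vs_deletion_share,
    loss_fraction_table,
    observable_age_classes,
    species_tree,
)
from orphanlc.orthology import HomologyHit


def pattern(**kw):
    states = {
        "pseudoobscura": "intact",
        "persimilis": "absent",
        "miranda": "absent",
        "lowei": "absent",
        "affinis": "absent",
    }
    states.update(kw)
    return states


class TestAssignAgeClass:
    def test_intact_in_lowei_dates_to_node3(self):
        assert assign_age_class(pattern(lowei="intact")) == 3

    def test_focal_only_is_class_zero(self):
        assert assign_age_class(pattern()) == 0

    def test_disrupted_ortholog_does_not_extend_age(self):
        states = pattern(affinis="intact", miranda="disrupted")
        assert assign_age_class(states) == 4

    def test_old_bypasses(self):
        assert assign_age_class(pattern(), old=True) == 5

    def test_focal_must_be_intact(self):
        states = pattern()
        states["pseudoobscura"] = "disrupted"
        with pytest.raises(ValueError):
            assign_age_class(states)


class TestCallLosses:
    def test_miranda_loss_with_full_support(self):
        states = pattern(
            affinis="intact", lowei="intact", persimilis="intact",
            miranda="disrupted",
        )
        calls = call_losses("g", states, 4)
        assert [c.branch for c in calls] == ["miranda"]

    def test_affinis_never_called(self):
        states = pattern(affinis="disrupted", lowei="intact")
        calls = call_losses("g", states, assign_age_class(states))
        assert calls == []

    def test_branch_outside_subtree_not_called(self):
        # age-1 gene: lowei carries no ortholog; absence is not loss
        states = pattern(persimilis="intact")
        assert call_losses("g", states, 1) == []

    def test_strict_mode_requires_both_neighbors(self):
        states = pattern(
            affinis="intact", lowei="absent", persimilis="intact",
            miranda="disrupted",
        )
        weak = call_losses("g", states, 4, strict=False)
        strict = call_losses("g", states, 4, strict=True)
        assert [c.branch for c in weak] == ["miranda"]
        assert strict == []  # outer neighbour lowei is not intact


class TestDolloOracleEquivalence:
    def test_all_81_patterns(self):
        """Age assignment plus loss calling equals exhaustive minimal-event
        Dollo reconstruction for every intactness pattern."""
        for pat in itertools.product(
            ("intact", "disrupted", "absent"), repeat=4
        ):
            states = pattern(
                persimilis=pat[0], miranda=pat[1], lowei=pat[2], affinis=pat[3]
            )
            k_oracle, calls_oracle = dollo_oracle(states)
            k = assign_age_class(states)
            calls = frozenset(c.branch for c in call_losses("g", states, k))
            assert k == k_oracle, states
            assert calls == calls_oracle, states

    def test_never_affinis_or_internal(self):
        for pat in itertools.product(
            ("intact", "disrupted", "absent"), repeat=4
        ):
            states = pattern(
                persimilis=pat[0], miranda=pat[1], lowei=pat[2], affinis=pat[3]
            )
            calls = call_losses("g", states, assign_age_class(states))
            assert all(
                c.branch in ("lowei", "miranda", "persimilis") for c in calls
            )


class TestClassifyDeletion:
    def hit(self, e):
        return HomologyHit("g", "miranda", "nucleotide-vs-genome", e)

    def test_no_ortholog_no_hits(self):
        assert classify_deletion(False, []) is True

    def test_genome_hit_means_unannotated_ortholog(self):
        assert classify_deletion(False, [self.hit(1e-6)]) is False

    def test_ortholog_present(self):
        assert classify_deletion(True, []) is False


class TestLossFractionTable:
    def make_table(self, n_lost, n_intact, k=3, cds=500):
        rows = []
        for i in range(n_lost + n_intact):
            rows.append(
                {
                    "gene_id": f"g{i}",
                    "age_class": k,
                    "chrom_arm": "2",
                    "cds_len": cds,
                    "status_persimilis": "lost" if i < n_lost else "intact",
                    "status_miranda": "absent",
                    "status_lowei": "absent",
                }
            )
        return pd.DataFrame(rows)

    def test_fraction_arithmetic(self):
        table = loss_fraction_table(self.make_table(3, 27))
        cell = table[(table["branch"] == "persimilis")]
        assert cell["fraction"].iloc[0] == pytest.approx(0.10)

    def test_length_normalization(self):
        table = loss_fraction_table(self.make_table(3, 27), normalize=True)
        cell = table[(table["branch"] == "persimilis")]
        assert cell["fraction_per_bp"].iloc[0] == pytest.approx(0.10 / 500)

    def test_empty_cell_is_missing(self):
        df = self.make_table(0, 5)
        df["status_persimilis"] = "absent"
        table = loss_fraction_table(df)
        assert table["fraction"].isna().all()

    def test_arm_stratification_drops_unplaced(self):
        df = self.make_table(1, 9)
        df.loc[0, "chrom_arm"] = "unplaced"
        table = loss_fraction_table(df, stratify_by="chrom_arm")
        assert "unplaced" not in set(table["chrom_arm"])


class TestShareAndTrend:
    def test_share_values(self):
        assert disabling_vs_deletion_share(19, 6) == pytest.approx(0.76)
        assert disabling_vs_deletion_share(5, 0) == 1.0
        assert disabling_vs_deletion_share(0, 0) is None

    def test_observable_classes(self):
        assert observable_age_classes("persimilis") == (2, 3, 4)
        assert observable_age_classes("miranda") == (3, 4)
        assert observable_age_classes("lowei") == (4,)

    def test_trend_detects_strong_gradient(self):
        z, p = cochran_armitage_trend([80, 40, 10], [200, 200, 200])
        assert p < 1e-6 and z < 0

    def test_trend_flat_is_null(self):
        z, p = cochran_armitage_trend([20, 21, 19], [200, 200, 200])
        assert p > 0.5


def test_species_tree_topology():
    tree = species_tree()
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert labels == {
        "affinis", "lowei", "miranda", "persimilis", "pseudoobscura"
    }
    # persimilis and pseudoobscura are sisters at the shallowest node
    mrca = tree.mrca(taxon_labels=["persimilis", "pseudoobscura"])
    assert {l.taxon.label for l in mrca.leaf_iter()} == {
        "persimilis", "pseudoobscura"
    }
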