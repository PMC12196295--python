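"""Weak-edge filtering, reinstatement and compensatory-miR calls."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_compensatory
from compmir import SimConfig, generate_dataset
from compmir.compensatory import (
    call_compensatory,
    call_reinstatement,
    control_target_counts,
)
from compmir.diffexpr import Contrast, DEThresholds, classify_deg, nb_wald, tpm_normalize
from compmir.interactions import InteractionTable, filter_weak


def make_table(rows):
    return InteractionTable(
        pd.DataFrame(rows, columns=["mir_id", "gene_id", "source_db", "strength"])
    )


class TestFilterWeak:
    def test_no_weak_edges_is_identity(self):
        t = make_table([("miR-1", "G1", "TarBase", "strong"),
                        ("miR-1", "G2", "TarBase", "unspecified")])
        assert filter_weak(t).table.equals(t.table)

    def test_weak_edges_removed(self):
        t = make_table([("miR-1", "G1", "TarBase", "strong"),
                        ("miR-1", "G2", "TarBase", "weak")])
        out = filter_weak(t)
        assert out.edges() == {("mir-1", "G1")}

    def test_random_table_count_matches_direct_count(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"miR-{rng.integers(50)}", f"G{rng.integers(300)}",
             "RegNetwork", rng.choice(["strong", "weak", "unspecified"], p=[0.4, 0.3, 0.3]))
            for _ in range(1000)
        ]
        t = make_table(rows)
        expected = int((t.table["strength"] != "weak").sum())
        assert len(filter_weak(t)) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rows = [(f"m{i%20}", f"G{rng.integers(100)}", "Rise",
                 rng.choice(["strong", "weak"])) for i in range(300)]
        once = filter_weak(make_table(rows))
        twice = filter_weak(once)
        assert once.table.equals(twice.table)

    def test_unknown_strength_becomes_unspecified(self, caplog):
        with caplog.at_level("WARNING"):
            t = make_table([("m1", "G1", "STRING", "odd-label")])
        assert t.table["strength"].iloc[0] == "unspecified"
        assert len(filter_weak(t)) == 1

    def test_species_prefix_and_case_normalized(self):
        t = make_table([("mmu-miR-181a-5p", "grin2a", "TarBase", "strong"),
                        ("MiR-181a-5p", "Grin2a", "RegNetwork", "strong")])
        assert t.edges() == {("mir-181a-5p", "GRIN2A")}


def toy_expression(mean_tg3, mean_tg6):
    """Expression frame with two TG samples per age pinned at the given means."""
    cols = ["a3", "b3", "a6", "b6"]
    design = pd.DataFrame(
        {"genotype": ["TG"] * 4, "age": [3, 3, 6, 6]}, index=cols
    )
    values = [[mean_tg3, mean_tg3, mean_tg6, mean_tg6]]
    return pd.DataFrame(values, index=["G1"], columns=cols), design


class TestReinstatement:
    @pytest.mark.parametrize(
        "m3,m6,expected",
        [
            (10.0, 16.0, True),    # ratio 1.6 > 1.5
            (10.0, 15.0, False),   # ratio exactly 1.5: strict, excluded
            (10.0, 14.0, False),
            (0.0, 10.0, True),     # pseudocount keeps the ratio finite
        ],
    )
    def test_ratio_threshold_is_strict(self, m3, m6, expected):
        tpm, design = toy_expression(m3, m6)
        call = call_reinstatement(tpm, design, {"G1"}, pseudocount=0.0 if m3 else 0.5)
        assert bool(call.table.loc["G1", "reinstated"]) is expected

    def test_missing_gene_raises_with_ids(self):
        tpm, design = toy_expression(5, 5)
        with pytest.raises(KeyError, match="G-missing"):
            call_reinstatement(tpm, design, {"G1", "G-missing"})

    def test_planted_reinstated_genes_recovered(self):
        """>=90% sensitivity, <=10% false calls against planted truth, 10 seeds."""
        sens, false_rate = [], []
        for seed in range(1, 11):
            mrna, _, _, _, truth = generate_dataset(SimConfig(seed=seed))
            call = call_reinstatement(
                tpm_normalize(mrna), mrna.design, truth.dereg_genes
            )
            called = call.reinstated
            truly = truth.reinstated_genes
            persist = truth.dereg_genes - truly
            sens.append(len(called & truly) / len(truly))
            false_rate.append(len(called & persist) / len(persist))
        assert np.mean(sens) >= 0.9
        assert np.mean(false_rate) <= 0.1


class TestCompensatoryCall:
    def test_no_down_mirs_gives_empty_rescued(self):
        t = make_table([("m1", "G1", "TarBase", "strong")])
        call = call_compensatory({"G1"}, {"G1"}, set(), t)
        assert call.rescued_genes == set()
        assert call.frac_rescued == 0.0
        assert call.comp_mirs == {}

    def test_five_targets_inclusive_four_excluded(self):
        genes = {f"G{i}" for i in range(5)}
        t5 = make_table([("m1", g, "TarBase", "strong") for g in sorted(genes)])
        call = call_compensatory(genes, genes, {"m1"}, t5, k_min=5)
        assert set(call.comp_mirs) == {"m1"}
        t4 = make_table([("m1", g, "TarBase", "strong") for g in sorted(genes)][:4])
        call = call_compensatory(genes, genes, {"m1"}, t4, k_min=5)
        assert call.comp_mirs == {}
        assert call.rescued_genes == {"G0", "G1", "G2", "G3"}

    def test_matches_brute_force_on_random_bipartite_instance(self):
        rng = np.random.default_rng(7)
        mirs = [f"m{i}" for i in range(50)]
        genes = [f"G{i}" for i in range(200)]
        rows = [(m, g, "synthetic", "strong")
                for m in mirs for g in genes if rng.random() < 0.05]
        table = make_table(rows)
        reinstated = set(rng.choice(genes, 80, replace=False))
        down = set(rng.choice(mirs, 25, replace=False))
        call = call_compensatory(reinstated, reinstated, down, table, k_min=3)
        rescued, comp = brute_compensatory(reinstated, down, table.edges(), 3)
        assert call.rescued_genes == rescued
        assert call.comp_mirs == comp

    def test_set_chain_and_monotonicity(self):
        rng = np.random.default_rng(9)
        mirs = [f"m{i}" for i in range(30)]
        genes = [f"G{i}" for i in range(100)]
        rows = [(m, g, "synthetic", "strong")
                for m in mirs for g in genes if rng.random() < 0.08]
        table = make_table(rows)
        dereg = set(genes)
        reinstated = set(rng.choice(genes, 60, replace=False))
        down = set(rng.choice(mirs, 15, replace=False))
        base = call_compensatory(dereg, reinstated, down, table, k_min=4)
        assert base.rescued_genes <= base.reinstated_genes <= base.dereg_down_genes
        # raising k_min never grows the compensatory set
        stricter = call_compensatory(dereg, reinstated, down, table, k_min=6)
        assert set(stricter.comp_mirs) <= set(base.comp_mirs)
        # adding edges never shrinks the rescued set
        extra = make_table(rows + [("m0", "G0", "synthetic", "strong")])
        bigger = call_compensatory(dereg, reinstated, down, extra, k_min=4)
        assert base.rescued_genes <= bigger.rescued_genes

    def test_reinstated_outside_dereg_rejected(self):
        t = make_table([("m1", "G1", "TarBase", "strong")])
        with pytest.raises(ValueError, match="subset"):
            call_compensatory({"G1"}, {"G1", "G2"}, {"m1"}, t)


class TestControlCounts:
    def test_disjoint_up_set_counts_zero(self):
        genes = [f"G{i}" for i in range(6)]
        t = make_table([("m1", g, "TarBase", "strong") for g in genes])
        call = call_compensatory(set(genes), set(genes), {"m1"}, t, k_min=5)
        counts = control_target_counts(call, {"X1", "X2"}, t)
        assert counts["n_control_targets"].tolist() == [0]

    def test_up_set_equal_to_rescued_reproduces_target_counts(self):
        genes = [f"G{i}" for i in range(6)]
        t = make_table([("m1", g, "TarBase", "strong") for g in genes])
        call = call_compensatory(set(genes), set(genes), {"m1"}, t, k_min=5)
        counts = control_target_counts(call, call.rescued_genes, t)
        assert (counts["n_control_targets"] == counts["n_rescued_targets"]).all()

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(13)
        mirs = [f"m{i}" for i in range(20)]
        genes = [f"G{i}" for i in range(80)]
        rows = [(m, g, "synthetic", "strong")
                for m in mirs for g in genes if rng.random() < 0.1]
        t = make_table(rows)
        reinstated = set(rng.choice(genes, 50, replace=False))
        up = set(rng.choice(genes, 30, replace=False))
        call = call_compensatory(reinstated, reinstated, set(mirs), t, k_min=3)
        counts = control_target_counts(call, up, t).set_index("mir_id")
        edges = t.edges()
        for m in call.comp_mirs:
            expected = sum(1 for g in up if (m, g) in edges)
            assert counts.loc[m, "n_control_targets"] == expected


def test_end_to_end_planted_compensatory_recovery():
    """Full DE -> reinstatement -> compensatory chain finds the planted miRs."""
    jaccards = []
    for seed in range(1, 6):
        mrna, mir, inter, _, truth = generate_dataset(SimConfig(seed=seed))
        th = DEThresholds()
        _, dereg = classify_deg(
            nb_wald(mrna, Contrast("t3", ("age", 3), ("genotype", "WT", "TG"))),
            th, "strict")
        _, down_mirs = classify_deg(
            nb_wald(mir, Contrast("tc", ("genotype", "TG"), ("age", 3, 6))),
            th, "strict")
        reinst = call_reinstatement(tpm_normalize(mrna), mrna.design, dereg)
        call = call_compensatory(dereg, reinst.reinstated, down_mirs,
                                 filter_weak(inter))
        tn = truth.normalized()
        comp = set(call.comp_mirs)
        jaccards.append(len(comp & tn.comp_mirs) / len(comp | tn.comp_mirs))
    assert np.mean(jaccards) >= 0.9
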