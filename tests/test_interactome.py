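"""Class merging, network assembly, overlap arithmetic, iBAQ and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tapcall.interactome import (
    assign_interactor_classes,
    bait_enrichment_qc,
    build_network,
    ibaq,
    overlap_summary,
    theoretical_peptide_count,
    to_networkx,
    write_sif,
)
from tapcall.pipeline import PipelineParams, call_interactors, prepare_matrix
from tapcall.simulate import SimConfig, simulate_dataset

from conftest import make_design, make_matrix


def _enr_corr(fdr_class, class_c, class_d, preys=None):
    preys = preys or [f"p{i}" for i in range(len(fdr_class))]
    idx = pd.Index(preys, name="protein")
    enr = pd.DataFrame(
        {
            "fdr_class": fdr_class,
            "log2fc": np.linspace(1, 2, len(preys)),
            "d_stat": np.linspace(1, 3, len(preys)),
            "perm_p": np.full(len(preys), 0.01),
        },
        index=idx,
    )
    corr = pd.DataFrame(
        {
            "r_local": np.full(len(preys), 0.7),
            "r_global": np.full(len(preys), 0.5),
            "q_global": np.full(len(preys), 0.2),
            "class_c": class_c,
            "class_d": class_d,
            "self_flag": [False] * len(preys),
        },
        index=idx,
    )
    return enr, corr


class TestAssignInteractorClasses:
    def test_union_and_primary_order(self):
        enr, corr = _enr_corr(["A", "B", "none", "none"],
                              [True, False, True, False],
                              [False, False, False, False])
        calls = assign_interactor_classes(enr, corr, bait="BAIT")
        got = calls.set_index("prey")
        assert got.loc["p0", "classes"] == "ABC"  # Class A implies B-or-better
        assert got.loc["p0", "primary_class"] == "A"
        assert got.loc["p1", "classes"] == "B"
        assert got.loc["p2", "classes"] == "C"
        assert "p3" not in got.index  # no class, no call

    def test_correlation_only_call(self):
        enr, corr = _enr_corr(["none"], [True], [False])
        calls = assign_interactor_classes(enr, corr, bait="B")
        assert calls["classes"].tolist() == ["C"]

    def test_mismatched_universe_is_fatal(self):
        enr, _ = _enr_corr(["A"], [True], [False])
        _, corr = _enr_corr(["A", "B"], [True, False], [False, False])
        with pytest.raises(ValueError, match="universes"):
            assign_interactor_classes(enr, corr, bait="B")


class TestBuildNetwork:
    def _calls(self, bait, preys, primary="A"):
        return pd.DataFrame(
            {
                "bait": bait,
                "prey": preys,
                "classes": [primary] * len(preys),
                "primary_class": [primary] * len(preys),
                "log2fc": 1.0,
                "d_stat": 2.0,
                "perm_p": 0.01,
                "r_local": 0.7,
                "r_global": 0.6,
                "self_flag": [p == bait for p in preys],
            }
        )

    def test_shared_prey_keeps_per_bait_edges(self):
        edges, nodes = build_network(
            {"B1": self._calls("B1", ["shared"]), "B2": self._calls("B2", ["shared"])}
        )
        assert len(edges) == 2
        assert len(nodes) == 3
        g = to_networkx(edges, nodes)
        assert g.number_of_edges() == 2 and g.number_of_nodes() == 3

    def test_empty_calls_give_empty_tables(self):
        edges, nodes = build_network({})
        assert edges.empty and nodes.empty

    def test_edge_style_follows_primary_class(self):
        calls = pd.concat(
            [self._calls("B1", ["x"], "A"), self._calls("B1", ["y"], "C")], ignore_index=True
        )
        edges, _ = build_network({"B1": calls})
        styles = edges.set_index("prey")["style"]
        assert styles["x"] == "co-enrichment" and styles["y"] == "correlation"

    def test_edge_count_is_sum_of_per_bait_counts(self):
        per_bait = {f"B{i}": self._calls(f"B{i}", [f"p{j}" for j in range(i + 1)]) for i in range(3)}
        edges, _ = build_network(per_bait)
        assert len(edges) == sum(len(c) for c in per_bait.values())

    def test_sif_export(self, tmp_path):
        edges, _ = build_network({"B1": self._calls("B1", ["x", "y"])})
        out = tmp_path / "net.sif"
        write_sif(edges, out)
        lines = out.read_text().strip().splitlines()
        assert lines == ["B1\tA\tx", "B1\tA\ty"]


class TestOverlapSummary:
    def test_enumerated_example(self):
        got = overlap_summary({"A": {"p1", "p2", "p3"}, "B": {"p2", "p3"}, "C": {"p3"}})
        assert got["shared_ge2"] == 2
        assert got["shared_all"] == 1
        assert got["specific"] == 1
        assert got["union_size"] == 3
        assert got["specific_fraction"] == pytest.approx(1 / 3)

    def test_identical_sets(self):
        s = {"a", "b", "c"}
        got = overlap_summary({"A": set(s), "B": set(s)})
        assert got["specific"] == 0 and got["shared_all"] == 3

    @given(
        st.lists(
            st.sets(st.integers(0, 15), max_size=10), min_size=2, max_size=4
        )
    )
    def test_counting_invariants(self, sets):
        prey_sets = {f"B{i}": s for i, s in enumerate(sets)}
        union = set().union(*sets)
        if not union:
            return
        got = overlap_summary(prey_sets)
        assert got["shared_all"] <= got["shared_ge2"] <= got["union_size"]
        assert got["specific"] + got["shared_ge2"] == got["union_size"]

    def test_parsed_per_bait_tables_reproduce_counts(self, tmp_path):
        # per-bait interactor tables on disk -> overlap statement
        tables = {
            "MCU": ["MICU1", "MICU2", "EFHD1", "ONLY1"],
            "EMRE": ["MICU1", "MICU2", "EFHD1"],
            "MCUB": ["MICU1", "EFHD1", "ONLY2"],
        }
        sets = {}
        for bait, preys in tables.items():
            p = tmp_path / f"{bait}.tsv"
            pd.DataFrame({"prey": preys}).to_csv(p, sep="\t", index=False)
            sets[bait] = set(pd.read_csv(p, sep="\t")["prey"])
        got = overlap_summary(sets)
        assert got["shared_ge2"] == 3  # MICU1, MICU2, EFHD1
        assert got["shared_all"] == 2  # MICU1, EFHD1
        assert got["specific"] == 2  # ONLY1, ONLY2


class TestIbaq:
    def test_quotient_values(self):
        assert ibaq(1000, 10) == 100
        assert ibaq(0, 5) == 0
        assert ibaq(7, 2) == 3.5

    def test_zero_peptides_fatal(self):
        with pytest.raises(ValueError):
            ibaq(10, 0)

    @given(st.floats(0, 1e9), st.integers(1, 500), st.floats(0.1, 10))
    def test_linear_in_intensity_inverse_in_peptides(self, a, n, k):
        assert ibaq(k * a, n) == pytest.approx(k * ibaq(a, n))
        assert ibaq(a, n) == pytest.approx(ibaq(a, 1) / n)


class TestTheoreticalPeptideCount:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKAAAAAAAR", 1),  # MK too short, AAAAAAAR counts
            ("KRKR", 0),  # all fragments length 1
            ("AAAAAAA", 1),  # single terminal peptide, length 7
            ("AAAKPAAAR", 1),  # K before P does not cleave
            ("AAAAAAK" + "CCCCCCCCR", 2),  # two observable tryptic peptides
        ],
    )
    def test_digestion_rules(self, seq, expected):
        assert theoretical_peptide_count(seq) == expected

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            theoretical_peptide_count("")
        with pytest.raises(ValueError):
            theoretical_peptide_count("AXZ1")


class TestBaitEnrichmentQc:
    def test_ratio_values(self):
        design = make_design(2, 2, bait_name="BAIT")
        ibaq_m = np.array(
            [[500.0, 500, 50, 50], [50, 50, 50, 50], [5, 5, 50, 50]]
        )
        m = make_matrix(
            np.log2(ibaq_m), design.sample_ids, group_ids=["BAIT", "P1", "P2"], ibaq=ibaq_m
        )
        rec = bait_enrichment_qc(m, design, "bait-TAP")
        assert rec["per_sample_ratio"]["b1"] == pytest.approx(10.0)
        assert rec["per_sample_ratio"]["c1"] == pytest.approx(1.0)
        assert not rec["low_enrichment_flag"]

    def test_planted_twenty_fold_recovered(self):
        # QC fixture: 8 TAP replicates with moderate noise, so the arithmetic
        # mean of the per-sample linear-scale ratio estimates the planted
        # 20-fold enrichment without heavy lognormal-tail scatter
        from tapcall.simulate import BaitSpec

        ratios = []
        for seed in range(5):
            cfg = SimConfig(
                n_proteins=400,
                baits=(BaitSpec("MCU", 8),),
                seed=seed,
                missing_midpoint=None,
                bait_latent_sd=0.25,
                replicate_noise_sd=0.3,
            )
            m, design, _, _ = simulate_dataset(cfg)
            rec = bait_enrichment_qc(m, design, "MCU")
            ratios.append(rec["per_condition"]["MCU"]["mean_ratio"])
        assert all(15 <= r <= 25 for r in ratios)

    def test_missing_bait_is_fatal(self):
        design = make_design(2, 2, bait_name="NOPE")
        m = make_matrix(np.ones((2, 4)), design.sample_ids, ibaq=np.ones((2, 4)))
        with pytest.raises(KeyError):
            bait_enrichment_qc(m, design, "bait-TAP")


class TestMergedCallsOnSimulatedData:
    def test_classes_and_self_flag_flow_through(self):
        cfg = SimConfig(n_proteins=250, planted={"MCU": [(5, 4.5), (6, 4.5)]}, seed=12)
        m, design, ann, truth = simulate_dataset(cfg)
        params = PipelineParams()
        mi = prepare_matrix(m, design, ann, params, seed=0)
        res = call_interactors(mi, design, "MCU", "Ctrl-TAP", params, seed=1)
        calls = res["calls"].set_index("prey")
        assert calls.loc["MCU", "self_flag"]
        for prey in truth.planted_set("MCU"):
            assert "A" in calls.loc[prey, "classes"]
            assert calls.loc[prey, "primary_class"] == "A"
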