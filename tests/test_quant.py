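"""Parsing, filtering, transforming and imputing the quantification matrix."""

import numpy as np
import pandas as pd
import pytest

from tapcall.quant import (
    AnnotationSet,
    ProteinRecord,
    SampleDesign,
    annotate_mitochondrial,
    filter_flagged,
    impute_missing_downshifted,
    log2_transform,
    parse_protein_groups,
    replicate_presence_filter,
    write_protein_groups,
)
from tapcall.simulate import SimConfig, simulate_dataset

from conftest import make_design, make_matrix


def _toy_table(tmp_path, n_samples=4, reverse_row=None, zero_cell=None, bad_cell=None, with_ibaq=False):
    samples = [f"s{i+1}" for i in range(n_samples)]
    rows = []
    for i in range(3):
        row = {"Majority protein IDs": f"P{i};ALT{i}", "Gene names": f"G{i}"}
        for j, s in enumerate(samples):
            row[f"LFQ intensity {s}"] = str(100.0 * (i + 1) + j)
            if with_ibaq:
                row[f"iBAQ {s}"] = str(10.0 * (i + 1))
        row["Reverse"] = "+" if i == reverse_row else ""
        row["Potential contaminant"] = ""
        row["Only identified by site"] = ""
        rows.append(row)
    if zero_cell is not None:
        rows[zero_cell[0]][f"LFQ intensity {samples[zero_cell[1]]}"] = "0"
    if bad_cell is not None:
        rows[bad_cell[0]][f"LFQ intensity {samples[bad_cell[1]]}"] = "oops"
    path = tmp_path / "proteinGroups.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path, samples


def _design_for(samples):
    rows = [
        dict(sample_id=s, condition="bait-TAP" if i < 2 else "Ctrl-TAP",
             replicate=i % 2 + 1, role="bait" if i < 2 else "control",
             bait_name="P0" if i < 2 else None)
        for i, s in enumerate(samples)
    ]
    return SampleDesign(pd.DataFrame(rows))


class TestParseProteinGroups:
    def test_flag_passthrough(self, tmp_path):
        path, samples = _toy_table(tmp_path, reverse_row=1)
        m = parse_protein_groups(path, _design_for(samples))
        assert m.n_proteins == 3
        assert [p.is_reverse for p in m.proteins] == [False, True, False]
        assert m.proteins[0].all_ids == ("P0", "ALT0")
        assert m.proteins[0].group_id == "P0"

    def test_zero_is_missing(self, tmp_path):
        path, samples = _toy_table(tmp_path, zero_cell=(1, 2))
        m = parse_protein_groups(path, _design_for(samples))
        assert not m.observed[1, 2]
        assert np.isnan(m.values[1, 2])
        assert m.observed.sum() == 11

    def test_missing_sample_column_is_fatal(self, tmp_path):
        path, samples = _toy_table(tmp_path, n_samples=2)
        design = _design_for(samples + ["s3"])
        with pytest.raises(ValueError, match="LFQ intensity s3"):
            parse_protein_groups(path, design)

    def test_unreadable_cell_is_fatal_with_location(self, tmp_path):
        path, samples = _toy_table(tmp_path, bad_cell=(2, 1))
        with pytest.raises(ValueError, match="row 2.*LFQ intensity s2"):
            parse_protein_groups(path, _design_for(samples))

    def test_ibaq_attached_when_present(self, tmp_path):
        path, samples = _toy_table(tmp_path, with_ibaq=True)
        m = parse_protein_groups(path, _design_for(samples))
        assert m.ibaq is not None
        assert m.ibaq[2, 0] == 30.0

    def test_roundtrip_values_and_flags(self, tmp_path):
        cfg = SimConfig(n_proteins=40, seed=11)
        m, design, _, _ = simulate_dataset(cfg)
        out = tmp_path / "pg.tsv"
        write_protein_groups(m, out)
        m2 = parse_protein_groups(out, design)
        assert m2.group_ids == m.group_ids
        assert np.array_equal(m2.observed, m.observed)
        np.testing.assert_allclose(
            m2.values[m2.observed], m.values[m.observed], rtol=1e-5
        )


class TestFilters:
    def test_flag_filter_counts(self):
        m = make_matrix(np.zeros((5, 2)), ["a", "b"], scale_tag="log2")
        m.proteins[0] = ProteinRecord("P0", ("P0",), is_reverse=True)
        m.proteins[3] = ProteinRecord("P3", ("P3",), is_contaminant=True)
        out = filter_flagged(m)
        assert out.group_ids == ["P1", "P2", "P4"]

    def test_flag_filter_identity_and_idempotent(self):
        m = make_matrix(np.zeros((4, 2)), ["a", "b"], scale_tag="log2")
        once = filter_flagged(m)
        assert once.group_ids == m.group_ids
        assert filter_flagged(once).group_ids == once.group_ids

    def test_all_flagged_gives_empty(self):
        m = make_matrix(np.zeros((2, 2)), ["a", "b"], scale_tag="log2")
        m.proteins = [ProteinRecord(p.group_id, p.all_ids, only_by_site=True) for p in m.proteins]
        assert filter_flagged(m).n_proteins == 0

    def test_mito_annotation_matches_any_identifier(self):
        m = make_matrix(np.zeros((2, 2)), ["a", "b"], scale_tag="log2")
        m.proteins[0] = ProteinRecord("P1", ("P1", "P2"))
        ann = AnnotationSet(ids=frozenset({"P2"}), name="mito")
        out = annotate_mitochondrial(m, ann)
        assert out.proteins[0].is_mito is True
        assert out.proteins[1].is_mito is False

    def test_mito_disjoint_and_drop_idempotent(self):
        m = make_matrix(np.zeros((3, 2)), ["a", "b"], scale_tag="log2")
        ann = AnnotationSet(ids=frozenset({"ZZZ"}), name="mito")
        out = annotate_mitochondrial(m, ann, drop=True)
        assert out.n_proteins == 0
        ann2 = AnnotationSet(ids=frozenset({"P0", "P1"}), name="mito")
        once = annotate_mitochondrial(m, ann2, drop=True)
        twice = annotate_mitochondrial(once, ann2, drop=True)
        assert twice.group_ids == once.group_ids == ["P0", "P1"]

    def test_annotation_set_cardinality_and_duplicates(self, tmp_path):
        # synthetic stand-in for a curated organelle list of 1276 proteins
        path = tmp_path / "mito.txt"
        path.write_text("\n".join(f"MT{i:04d}" for i in range(1276)) + "\n")
        ann = AnnotationSet.from_file(path)
        assert len(ann) == 1276
        path.write_text("A\nB\nA\n")
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationSet.from_file(path)


class TestLog2Transform:
    def test_values_and_mask(self):
        vals = np.array([[8.0, 1.0], [np.nan, 4.0]])
        m = make_matrix(vals, ["a", "b"], scale_tag="raw-linear")
        out = log2_transform(m)
        assert out.values[0, 0] == 3.0
        assert out.values[0, 1] == 0.0
        assert out.values[1, 1] == 2.0
        assert np.isnan(out.values[1, 0]) and not out.observed[1, 0]
        assert out.scale_tag == "log2"

    def test_negative_is_fatal(self):
        m = make_matrix(np.array([[1.0, 2.0]]), ["a", "b"], scale_tag="raw-linear")
        m.values[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            log2_transform(m)


class TestReplicatePresenceFilter:
    def _matrix(self, obs_bait, obs_ctrl):
        n_b, n_c = len(obs_bait), len(obs_ctrl)
        vals = np.full((1, n_b + n_c), 20.0)
        observed = np.array([obs_bait + obs_ctrl])
        vals[~observed] = np.nan
        return make_matrix(vals, [f"b{i+1}" for i in range(n_b)] + [f"c{i+1}" for i in range(n_c)],
                           scale_tag="log2", observed=observed)

    def test_kept_when_quota_met_in_both(self):
        design = make_design(4, 4)
        m = self._matrix([True, True, True, False], [True, True, False, False])
        assert replicate_presence_filter(m, design, min_reps=2).n_proteins == 1

    def test_dropped_when_one_condition_fails(self):
        design = make_design(4, 4)
        m = self._matrix([True, True, True, True], [True, False, False, False])
        assert replicate_presence_filter(m, design, min_reps=2).n_proteins == 0
        kept = replicate_presence_filter(m, design, min_reps=2, scope="any-condition")
        assert kept.n_proteins == 1

    def test_min_reps_zero_is_identity(self):
        design = make_design(2, 2)
        m = self._matrix([False, False], [False, False])
        assert replicate_presence_filter(m, design, min_reps=0).n_proteins == 1

    def test_unsatisfiable_quota_is_fatal(self):
        design = make_design(1, 4)
        m = self._matrix([True], [True, True, True, True])
        with pytest.raises(ValueError, match="unsatisfiable"):
            replicate_presence_filter(m, design, min_reps=2)


class TestImputation:
    def test_no_missing_is_identity(self):
        vals = np.array([[20.0, 21.0], [22.0, 23.0], [24.0, 20.0]])
        m = make_matrix(vals, ["a", "b"], scale_tag="log2")
        out = impute_missing_downshifted(m, seed=1)
        np.testing.assert_array_equal(out.values, vals)
        assert out.scale_tag == "log2-imputed"

    def test_downshifted_distribution_monte_carlo(self):
        # column observed {20,22,24}: draws must match Normal(mu-1.8s, (0.3s)^2)
        n_miss = 100_000
        vals = np.full((n_miss + 3, 1), np.nan)
        vals[:3, 0] = [20.0, 22.0, 24.0]
        m = make_matrix(vals, ["a"], scale_tag="log2")
        out = impute_missing_downshifted(m, seed=5)
        draws = out.values[3:, 0]
        assert abs(draws.mean() - 18.4) < 0.02
        assert abs(draws.std(ddof=1) - 0.6) < 0.01
        # imputed values sit left of the observed minimum essentially always
        assert (draws < 20.0).mean() > 0.99

    def test_touches_exactly_the_missing_cells(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(25, 2, (50, 4))
        observed = rng.random((50, 4)) > 0.3
        vals_nan = np.where(observed, vals, np.nan)
        m = make_matrix(vals_nan, list("abcd"), scale_tag="log2", observed=observed)
        out = impute_missing_downshifted(m, seed=2)
        changed = out.values != np.nan_to_num(vals_nan, nan=np.inf)
        assert np.array_equal(out.values[observed], vals[observed])
        assert np.isfinite(out.values).all()
        assert np.array_equal(out.observed, observed)  # mask untouched
        assert int((~observed).sum()) == int((out.values != np.where(observed, vals, np.inf))[~observed].sum())

    def test_seed_reproducibility(self):
        vals = np.array([[20.0, np.nan], [22.0, 21.0], [24.0, 23.0], [np.nan, 22.5]])
        m = make_matrix(vals, ["a", "b"], scale_tag="log2")
        a = impute_missing_downshifted(m, seed=9)
        b = impute_missing_downshifted(m, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_column_with_single_observation_is_fatal(self):
        vals = np.array([[20.0, np.nan], [22.0, np.nan], [24.0, 21.0]])
        m = make_matrix(vals, ["a", "bad_col"], scale_tag="log2")
        with pytest.raises(ValueError, match="bad_col"):
            impute_missing_downshifted(m, seed=1)
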