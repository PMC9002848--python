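import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floraltime import (ExpressionProfiles, classify_expression, cpm_rpkm,
                        filter_low_counts, mds_qc, tmm_factors)
from floraltime.normalize import classical_mds

from .conftest import make_count_matrix, unit_factors
from .oracles import tmm_oracle


class TestFilterLowCounts:
    def test_single_time_point_above_threshold_kept(self):
        # per-time-point mean CPM (0.2, 0.3, 1.4, 0.1): kept because one
        # time point exceeds 1
        lib = 10_000_000
        rows = []
        for cpms in [(0.2, 0.3, 1.4, 0.1), (0.0, 0.0, 0.0, 0.0), (5, 5, 5, 5)]:
            rows.append(np.repeat([int(c * lib / 1e6) for c in cpms], 3))
        counts = np.array(rows)
        # pad with a constant filler gene so library sizes are ~1e6
        filler = np.full((1, 12), (lib - counts.sum(axis=0).max()) // 1)
        cm = make_count_matrix(np.vstack([counts, filler]))
        kept = filter_low_counts(cm)
        # recompute the rule by hand, gene by gene
        cpm = cm.counts / cm.library_sizes * 1e6
        expect = []
        for g in range(cm.n_genes):
            expect.append(any(cpm[g, cols].mean() > 1.0
                              for cols in cm.groups().values()))
        assert kept.gene_ids == [g for g, e in zip(cm.gene_ids, expect) if e]
        assert "g0" in kept.gene_ids and "g1" not in kept.gene_ids

    def test_all_zero_gene_removed(self):
        counts = np.vstack([np.zeros(12, int), np.full(12, 100)])
        kept = filter_low_counts(make_count_matrix(counts))
        assert kept.gene_ids == ["g1"]

    def test_brute_force_equivalence_on_synthetic(self, small_study):
        cm = small_study.counts
        kept = filter_low_counts(cm)
        cpm = cm.counts / cm.library_sizes * 1e6
        expect = set()
        for g in range(cm.n_genes):
            for cols in cm.groups().values():
                if cpm[g, cols].mean() > 1.0:
                    expect.add(cm.gene_ids[g])
                    break
        assert set(kept.gene_ids) == expect

    def test_empty_result_is_error(self):
        cm = make_count_matrix(np.ones((3, 12), int))
        with pytest.raises(ValueError, match="no genes pass"):
            filter_low_counts(cm, min_cpm=1e9)


class TestTMM:
    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=200)
        counts = np.column_stack([base, 2 * base])
        cm = make_count_matrix(counts, n_reps=1, timepoints=(10, 15))
        nf = tmm_factors(cm)
        np.testing.assert_allclose(nf.tmm_factors, [1.0, 1.0], atol=1e-9)

    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 500, size=100)
        cm = make_count_matrix(np.column_stack([base, base]),
                               n_reps=1, timepoints=(10, 15))
        np.testing.assert_allclose(tmm_factors(cm).tmm_factors, [1.0, 1.0], atol=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(4, 0.005, size=(200, 6))
        cm = make_count_matrix(counts, n_reps=3, timepoints=(10, 29))
        nf = tmm_factors(cm)
        np.testing.assert_allclose(nf.tmm_factors, tmm_oracle(counts), atol=1e-8)

    def test_geometric_mean_is_one(self, small_study):
        nf = tmm_factors(filter_low_counts(small_study.counts))
        assert abs(np.exp(np.mean(np.log(nf.tmm_factors))) - 1.0) < 1e-9

    def test_invariant_to_gene_order_and_global_scaling(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(4, 0.01, size=(150, 4))
        cm = make_count_matrix(counts, n_reps=2, timepoints=(10, 15))
        f0 = tmm_factors(cm).tmm_factors
        perm = rng.permutation(150)
        f1 = tmm_factors(make_count_matrix(counts[perm], n_reps=2,
                                           timepoints=(10, 15))).tmm_factors
        f2 = tmm_factors(make_count_matrix(counts * 3, n_reps=2,
                                           timepoints=(10, 15))).tmm_factors
        np.testing.assert_allclose(f0, f1, atol=1e-12)
        np.testing.assert_allclose(f0, f2, atol=1e-12)


class TestCpmRpkm:
    def test_closed_form_rpkm(self):
        # count 10, effective library 1e6, length 1000 -> RPKM 10
        counts = np.array([[10, 0], [999_990, 1_000_000]])
        cm = make_count_matrix(counts, n_reps=1, timepoints=(10, 15))
        prof = cpm_rpkm(cm, unit_factors(cm), {"g0": 1000, "g1": 1000})
        assert prof.rpkm.loc["g0"].iloc[0] == pytest.approx(10.0)
        assert prof.rpkm.loc["g0"].iloc[1] == 0.0
        assert prof.cpm.loc["g0"].iloc[0] == pytest.approx(10.0)

    def test_cpm_sums_to_million_with_unit_factors(self):
        rng = np.random.default_rng(4)
        cm = make_count_matrix(rng.integers(0, 100, (50, 12)))
        prof = cpm_rpkm(cm, unit_factors(cm), {g: 1000 for g in cm.gene_ids})
        np.testing.assert_allclose(prof.cpm.sum(axis=0), 1e6)

    def test_expressed_call_at_threshold(self):
        counts = np.full((2, 12), 0)
        counts[0] = 300          # exactly RPKM 0.3 at length 1000, lib 1e9? craft below
        cm = make_count_matrix(counts + np.array([[0], [10_000]]))
        nf = unit_factors(cm)
        prof = cpm_rpkm(cm, nf, {g: 1000 for g in cm.gene_ids})
        # mean RPKM >= 0.3 is an expressed call, strict boundary included
        mr = prof.mean_rpkm.loc["g0"]
        assert (prof.expressed.loc["g0"] == (mr >= 0.3)).all()

    def test_missing_length_lists_genes(self):
        cm = make_count_matrix(np.ones((2, 12), int))
        with pytest.raises(ValueError, match="g1"):
            cpm_rpkm(cm, unit_factors(cm), {"g0": 1000})


class TestClassifyExpression:
    def _profiles(self, values):
        tps = [10, 15, 19, 29]
        mr = pd.DataFrame({t: values for t in tps},
                          index=[f"g{i}" for i in range(len(values))], dtype=float)
        return ExpressionProfiles(cpm=mr.copy(), rpkm=mr.copy(), mean_rpkm=mr,
                                  expressed=mr >= 0.3)

    def test_level_boundaries(self):
        values = [0.29999, 0.3, 0.99999, 1.0, 9.99999, 10.0, 99.99999, 100.0, 150.0]
        out = classify_expression(self._profiles(values))
        assert list(out["level"]) == ["not_expressed", "low", "low", "medium",
                                      "medium", "high", "high", "very_high",
                                      "very_high"]

    def test_pattern_labels(self):
        tps = [10, 15, 19, 29]
        mr = pd.DataFrame([[0.5, 0.5, 0.1, 0.1], [0.5] * 4, [0.1] * 4],
                          columns=tps, index=["a", "b", "c"])
        prof = ExpressionProfiles(cpm=mr, rpkm=mr, mean_rpkm=mr, expressed=mr >= 0.3)
        out = classify_expression(prof)
        assert out.loc["a", "pattern"] == "10+15"
        assert out.loc["b", "pattern"] == "10+15+19+29"
        assert out.loc["c", "pattern"] == "none"

    def test_partition_property(self, small_study):
        from floraltime import cpm_rpkm as _cr, filter_low_counts as _f, tmm_factors as _t
        cm = _f(small_study.counts)
        prof = _cr(cm, _t(cm), small_study.annotation)
        out = classify_expression(prof)
        # every gene in exactly one level and one pattern
        assert out["level"].notna().all() and out["pattern"].notna().all()
        assert out.groupby(["level", "pattern"]).size().sum() == cm.n_genes
        # expressed nowhere <=> not_expressed level
        nowhere = ~prof.expressed.any(axis=1)
        assert ((out["level"] == "not_expressed") == nowhere).all()


class TestMDS:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 1000, 600)
        counts = np.column_stack([col, col, rng.integers(0, 1000, 600)])
        cm = make_count_matrix(counts, n_reps=1, timepoints=(10, 15, 19))
        coords = mds_qc(cm, unit_factors(cm), top_n=500)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-6)

    def test_classical_mds_preserves_metric_distances(self):
        # three points with a valid metric: reconstructed pairwise distances
        # match the input
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        coords = classical_mds(d, n_dims=2)
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-6)

    def test_extreme_time_points_separate_most(self, small_study):
        from floraltime import filter_low_counts as _f, tmm_factors as _t
        cm = _f(small_study.counts)
        coords = mds_qc(cm, _t(cm)).to_numpy()
        tps = np.array([s.timepoint_dap for s in cm.samples])
        cent = {t: coords[tps == t].mean(axis=0) for t in (10, 15, 19, 29)}
        d_10_29 = np.linalg.norm(cent[10] - cent[29])
        d_15_19 = np.linalg.norm(cent[15] - cent[19])
        assert d_10_29 > d_15_19


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_tmm_depth_invariance_property(seed):
    """Multiplying one library by an integer depth factor leaves TMM
    factors at 1 (no composition change)."""
    rng = np.random.default_rng(seed)
    base = rng.integers(1, 300, size=120)
    k = int(rng.integers(2, 6))
    cm = make_count_matrix(np.column_stack([base, k * base]),
                           n_reps=1, timepoints=(10, 15))
    np.testing.assert_allclose(tmm_factors(cm).tmm_factors, [1, 1], atol=1e-9)
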