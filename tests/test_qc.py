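"""PCA quality control, outlier flagging, overlap matrices and reference sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dimerscope.errors import DataError
from dimerscope.io_filter import collapse_technical_replicates
from dimerscope.qc import (compare_reference, flag_outliers, overlap_matrix,
                           read_identifier_list, run_pca)

import oracles
from conftest import make_matrix, make_toy_design


class TestRunPCA:
    def _matrix(self, seed=0, n=40, runs=8):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.normal(24, 2, (n, runs)),
                           {"A": runs // 2, "B": runs - runs // 2})

    def test_identical_samples_get_identical_scores(self):
        vals = np.tile(np.linspace(20, 25, 10)[:, None], (1, 4))
        m = make_matrix(vals, {"A": 2, "B": 2})
        res = run_pca(m)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[1],
                                   atol=1e-10)

    def test_explained_variance_fractions(self):
        res = run_pca(self._matrix())
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_scores_match_eigendecomposition_up_to_sign(self):
        m = self._matrix(seed=3)
        res = run_pca(m)
        expected = oracles.pca_scores_eigh(m.values.to_numpy().T)
        got = res.scores.to_numpy()
        for j in range(got.shape[1]):
            col, ref = got[:, j], expected[:, j]
            assert (np.allclose(col, ref, atol=1e-8)
                    or np.allclose(col, -ref, atol=1e-8))

    def test_reordering_samples_permutes_scores(self):
        m = self._matrix(seed=5)
        res = run_pca(m)
        perm = np.random.default_rng(0).permutation(len(m.run_ids))
        cols = [m.run_ids[i] for i in perm]
        design2 = m.design.set_index("run_id").loc[cols].reset_index()
        from dimerscope.matrix import IntensityMatrix
        m2 = IntensityMatrix(m.values[cols], design2)
        res2 = run_pca(m2)
        for j in range(res.scores.shape[1]):
            a = res.scores.to_numpy()[perm, j]
            b = res2.scores.to_numpy()[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_single_sample_rejected(self):
        m = make_matrix(np.ones((5, 1)) * 20, {"A": 1})
        with pytest.raises(DataError):
            run_pca(m)

    def test_missing_values_rejected(self):
        vals = np.full((4, 4), 20.0)
        vals[0, 0] = np.nan
        with pytest.raises(DataError):
            run_pca(make_matrix(vals, {"A": 2, "B": 2}))


class TestFlagOutliers:
    def _scores(self, displace=None, spread=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, design_rows = [], []
        for g, centre in zip("ABCD", ([0, 0], [30, 0], [0, 30], [30, 30])):
            for i in range(1, 7):
                rows.append(np.asarray(centre) + rng.normal(0, spread, 2))
        design = make_toy_design({g: 6 for g in "ABCD"})
        scores = pd.DataFrame(rows, index=design["run_id"],
                              columns=["PC1", "PC2"])
        if displace is not None:
            run, shift = displace
            scores.loc[run] += shift
        return scores, design

    def test_no_flags_when_all_identical(self):
        scores, design = self._scores(spread=0.0)
        assert flag_outliers(scores, design, k_sd=4) == []

    def test_single_displaced_sample_flagged(self):
        scores, design = self._scores(seed=0)
        dist = np.sqrt(((scores[["PC1", "PC2"]]
                         - scores.groupby(design.set_index("run_id")
                                          ["condition_label"].loc[scores.index]
                                          .values).transform("mean")) ** 2)
                       .sum(axis=1))
        robust = np.median(dist) / np.sqrt(2 * np.log(2))
        scores2 = scores.copy()
        scores2.loc["A_r1"] += np.array([10 * robust, 0.0])
        flagged = flag_outliers(scores2, design, k_sd=4)
        assert flagged == ["A_r1"]

    def test_conservative_at_large_k(self):
        scores, design = self._scores(seed=2)
        scores.loc["B_r3"] += 50
        assert flag_outliers(scores, design, k_sd=1e9) == []

    def test_corrupted_biological_replicate_both_runs_flagged(self, design96):
        """A failed pulldown shifts both technical replicates of one
        biological replicate; PCA-based flagging catches both runs."""
        from dimerscope.io_filter import from_dataframe, log2_transform
        from dimerscope.synthetic import GroundTruth, simulate_lfq
        from dimerscope.design import FACTORS
        rng = np.random.default_rng(21)
        n = 120
        truth = GroundTruth([f"P{i}" for i in range(n)], rng.normal(26, 2, n),
                            np.zeros((n, len(FACTORS))),
                            censor_midpoint=-1000.0,
                            n_contaminant=0, n_reverse=0, n_onlysite=0)
        ds = simulate_lfq(design96, truth, seed=21)
        bad = ["v600e_s_ac_b2_t1", "v600e_s_ac_b2_t2"]
        for run in bad:
            ds.table[f"LFQ intensity {run}"] *= 2.0 ** 6  # +6 log2 units
        m = log2_transform(from_dataframe(ds.table), design96)
        res = run_pca(m)
        flagged = flag_outliers(res.scores, m.design, k_sd=4)
        assert set(bad) <= set(flagged)


class TestOverlapMatrix:
    def test_textbook_entries(self):
        mat = overlap_matrix({"A": {"p1", "p2", "p3"}, "B": {"p2", "p3"}})
        assert mat.entry("A", "B") == (2, 3)
        assert mat.entry("B", "A") == (2, 2)
        assert mat.to_strings().loc["A", "B"] == "2/3"

    def test_diagonal_is_full_set(self):
        mat = overlap_matrix({"A": {"x", "y"}, "B": set()})
        assert mat.entry("A", "A") == (2, 2)
        assert mat.entry("B", "B") == (0, 0)

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            mat = overlap_matrix({"A": ["p1", "p1", "p2"], "B": ["p2"]})
        assert mat.entry("A", "A") == (2, 2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariants_and_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        sets = {f"C{k}": set(rng.choice(universe,
                                        size=rng.integers(0, 20),
                                        replace=False))
                for k in range(rng.integers(2, 6))}
        mat = overlap_matrix(sets)
        expected = oracles.overlap_bruteforce(sets)
        for r in mat.labels:
            for c in mat.labels:
                n, d = mat.entry(r, c)
                assert (n, d) == expected[(r, c)]
                assert n <= min(len(sets[r]), len(sets[c]))
                assert mat.numerator.loc[r, c] == mat.numerator.loc[c, r]
            assert mat.entry(r, r) == (len(sets[r]), len(sets[r]))


class TestCompareReference:
    def test_identity_reference(self):
        rep = compare_reference({"a", "b"}, ["a", "b"])
        assert rep["n_overlap"] == 2 and rep["shared"] == ["a", "b"]

    def test_disjoint_reference(self):
        rep = compare_reference({"a"}, ["x", "y"])
        assert rep["n_overlap"] == 0

    def test_partial_overlap_counts(self):
        ours = {f"p{i}" for i in range(20)}
        ref = {f"p{i}" for i in range(15, 23)}
        rep = compare_reference(ours, ref)
        assert rep["n_overlap"] == 5
        assert rep["n_set"] == 20 and rep["n_reference"] == 8

    def test_empty_reference_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            rep = compare_reference({"a"}, [])
        assert rep["n_overlap"] == 0

    def test_identifier_list_io(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# header\np1\n\np2\n")
        assert read_identifier_list(p) == ["p1", "p2"]
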