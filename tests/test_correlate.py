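import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import teconet as tc
from oracles import bh_step_up, naive_correlations


class TestPearsonR:
    def test_perfect_linear(self):
        assert tc.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert tc.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # deviations (-1.5,-.5,.5,1.5) x (-1.5,.5,-.5,1.5): sum 4 / (sqrt5*sqrt5)
        assert tc.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tc.pearson_r([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=12),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    def test_affine_invariance_and_symmetry(self, xs, slope, offset):
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        x = np.asarray(xs)
        if np.ptp(x) < 1e-3 or ys.std() == 0:  # avoid ill-conditioned shifts
            return
        r = tc.pearson_r(x, ys)
        assert tc.pearson_r(ys, x) == pytest.approx(r, abs=1e-12)
        assert tc.pearson_r(slope * x + offset, ys) == pytest.approx(r, abs=1e-7)
        assert tc.pearson_r(-slope * x + offset, ys) == pytest.approx(-r, abs=1e-7)


class TestCorrelationP:
    def test_null_and_boundary(self):
        assert tc.correlation_p(0.0, 10) == pytest.approx(1.0)
        assert tc.correlation_p(1.0, 5) == 0.0
        assert tc.correlation_p(-1.0, 5) == 0.0

    def test_strong_correlation_tiny_p(self):
        # independent t-CDF evaluation
        t = 0.8 * np.sqrt(28 / (1 - 0.64))
        expected = 2 * stats.t.sf(t, df=28)
        assert tc.correlation_p(0.8, 30) == pytest.approx(expected)
        assert tc.correlation_p(0.8, 30) < 1e-6

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            tc.correlation_p(0.5, 2)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        assert np.allclose(tc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_constant_vectors(self):
        assert tc.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(tc.bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_matches_hand_rule_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(tc.bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_reordering_permutes_output(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(tc.bh_adjust(p)[perm], tc.bh_adjust(p[perm]))

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            tc.bh_adjust([0.5, 1.5])


class TestCorrelateAll:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(size=(40, 10)),
            index=[f"g{i}" for i in range(20)] + [f"t{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(10)],
        )
        genes = [f"g{i}" for i in range(20)]
        tes = [f"t{i}" for i in range(20)]
        recs = tc.correlate_all(expr, genes, tes, apply_presence_filter=False)
        oracle = naive_correlations(expr, genes, tes, expr.columns)
        for row in recs.itertuples(index=False):
            assert abs(row.r - oracle[(row.gene_id, row.te_id)]) < 1e-10

    def test_planted_pair_significant(self, planted_data, planted_human_expr):
        ann = planted_data.annotation
        genes = sorted(ann.index[ann["kind"] == "gene"])
        tes = sorted(ann.index[ann["kind"] == "TE"])
        recs = tc.correlate_all(planted_human_expr, genes, tes)
        keyed = recs.set_index(["gene_id", "te_id"])
        for row in planted_data.truth["planted"].itertuples(index=False):
            rec = keyed.loc[(row.gene_id, row.te_id)]
            assert bool(rec["significant"])
            assert np.sign(rec["r"]) == np.sign(row.target_r)

    def test_constant_row_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(10, 1, size=(4, 8)),
            index=["g1", "g2", "t1", "t2"],
            columns=[f"s{j}" for j in range(8)],
        )
        expr.loc["t2"] = 7.0
        with caplog.at_level("WARNING"):
            recs = tc.correlate_all(
                expr, ["g1", "g2"], ["t1", "t2"], apply_presence_filter=False
            )
        assert "t2" not in set(recs["te_id"])
        assert "zero variance" in caplog.text

    def test_null_false_positive_rate_bounded(self, null_expr, null_data):
        ann = null_data.annotation
        genes = sorted(ann.index[ann["kind"] == "gene"])
        tes = sorted(ann.index[ann["kind"] == "TE"])
        recs = tc.correlate_all(null_expr, genes, tes)
        bound = 0.01 + 3 * np.sqrt(0.01 * 0.99 / len(recs))
        assert recs["significant"].mean() <= bound

    def test_deterministic(self, null_expr, null_data):
        ann = null_data.annotation
        genes = sorted(ann.index[ann["kind"] == "gene"])[:10]
        tes = sorted(ann.index[ann["kind"] == "TE"])[:10]
        a = tc.correlate_all(null_expr, genes, tes)
        b = tc.correlate_all(null_expr, genes, tes)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_samples(self, null_expr):
        with pytest.raises(ValueError, match="3 samples"):
            tc.correlate_all(null_expr, ["ZNF0001"], ["TE0001"],
                             samples=list(null_expr.columns[:2]))


def _loo_fixture(outlier=False, seed=0):
    """4 individuals x 6 samples; optionally one individual whose
    shared shift manufactures the whole correlation."""
    rng = np.random.default_rng(seed)
    n_ind, per = 4, 6
    cols = [f"i{i}_s{j}" for i in range(n_ind) for j in range(per)]
    ind = {c: c.split("_")[0] for c in cols}
    g = rng.normal(0, 1, len(cols))
    t = rng.normal(0, 1, len(cols))
    if outlier:
        g[-per:] += 8
        t[-per:] += 8
    else:
        t = 0.95 * g + np.sqrt(1 - 0.95**2) * t
    expr = pd.DataFrame([g, t], index=["gene1", "te1"], columns=cols)
    # pad with null features so BH has a family; shift positive so the
    # presence filter keeps everything (affine shift leaves r unchanged)
    pad = pd.DataFrame(
        rng.normal(size=(20, len(cols))),
        index=[f"g{i}" for i in range(10)] + [f"t{i}" for i in range(10)],
        columns=cols,
    )
    return pd.concat([expr, pad]) + 20.0, ind


class TestLeaveOneOut:
    def _run(self, expr, ind):
        genes = ["gene1"] + [f"g{i}" for i in range(10)]
        tes = ["te1"] + [f"t{i}" for i in range(10)]
        return tc.leave_one_out_consensus(expr, genes, tes, ind)

    def test_robust_pair_retained(self):
        expr, ind = _loo_fixture(outlier=False, seed=1)
        recs = self._run(expr, ind)
        hit = recs[(recs["gene_id"] == "gene1") & (recs["te_id"] == "te1")]
        assert bool(hit["significant"].item())

    def test_outlier_driven_pair_dropped(self):
        expr, ind = _loo_fixture(outlier=True, seed=2)
        full = tc.correlate_all(expr, ["gene1"], ["te1"],
                                apply_presence_filter=False)
        assert abs(full["r"].item()) > 0.4  # looks strong on all samples
        recs = self._run(expr, ind)
        hit = recs[(recs["gene_id"] == "gene1") & (recs["te_id"] == "te1")]
        assert not bool(hit["significant"].item())

    def test_requires_three_individuals(self):
        expr, ind = _loo_fixture()
        two = {c: ("i0" if v in ("i0", "i1") else "i2") for c, v in ind.items()}
        with pytest.raises(ValueError, match="3 individuals"):
            tc.leave_one_out_consensus(expr, ["gene1"], ["te1"], two)
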