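"""Optimal 1-D k-means, predictor assembly, OLS + backward selection, CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bprm.core import (
    DegenerateScaleError,
    FitError,
    ParameterError,
    UndefinedCorrelationError,
)
from bprm.lac import LACRecord
from bprm.scaling_model import (
    PREDICTOR_NAMES,
    assemble_predictors,
    backward_select,
    ckmeans_1d,
    cross_validate,
    fit_full_model,
    fit_scale_model,
    parse_predictor_name,
    pearson,
    predictor_name,
)


def brute_force_wss(xs: np.ndarray, k: int) -> float:
    """Exhaustive minimum WSS over all contiguous k-partitions of sorted data."""
    xs = np.sort(xs)
    n = len(xs)

    def seg(a, b):  # WSS of xs[a:b]
        s = xs[a:b]
        return float(((s - s.mean()) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        wss = sum(seg(bounds[i], bounds[i + 1]) for i in range(k))
        best = min(best, wss)
    return best


class TestCkmeans:
    def test_two_obvious_clusters(self):
        res = ckmeans_1d([1, 2, 10, 11], 2)
        assert res.wss == pytest.approx(1.0)
        assert list(res.labels) == [0, 0, 1, 1]
        assert res.centers == pytest.approx([1.5, 10.5])

    def test_k_equals_n_gives_zero_wss(self):
        res = ckmeans_1d([3.0, 1.0, 2.0], 3)
        assert res.wss == 0.0
        assert sorted(res.labels) == [0, 1, 2]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            ckmeans_1d([1.0, 2.0], 3)

    @pytest.mark.parametrize("n,k", [(8, 2), (10, 3), (12, 3), (12, 4)])
    def test_matches_exhaustive_enumeration(self, n, k):
        rng = np.random.default_rng(n * 100 + k)
        for _ in range(20):
            x = rng.uniform(0, 1, n)
            res = ckmeans_1d(x, k)
            assert res.wss == pytest.approx(brute_force_wss(x, k), abs=1e-10)

    def test_labels_contiguous_in_sorted_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        res = ckmeans_1d(x, 4)
        lab_sorted = res.labels[np.argsort(x)]
        assert np.all(np.diff(lab_sorted) >= 0)


class TestScaleModel:
    def test_well_separated_masses_get_own_scale(self):
        pool = np.concatenate([np.full(20, m) + np.linspace(0, 1e-4, 20)
                               for m in range(1, 11)])
        sm = fit_scale_model(pool, k=10)
        assert np.all(np.diff(sm.boundaries) > 0)
        for m in range(1, 11):
            assert sm.assign([float(m) + 5e-5])[0] == m

    def test_out_of_range_values_clamp(self):
        sm = fit_scale_model(np.arange(1.0, 101.0), k=10)
        assert sm.assign([-5.0])[0] == 1
        assert sm.assign([1e6])[0] == 10

    def test_boundary_assignment_reproduces_dp_partition(self):
        rng = np.random.default_rng(11)
        pool = np.sort(rng.lognormal(-7, 1.2, 300))
        sm = fit_scale_model(pool, k=10)
        res = ckmeans_1d(pool, 10)
        assert np.array_equal(sm.assign(pool) - 1, res.labels)

    def test_subsampled_fit_is_dp_optimal_on_subsample(self):
        rng = np.random.default_rng(5)
        pool = rng.lognormal(-7, 1.3, 10_000)
        sm = fit_scale_model(pool, k=10, max_fit_n=200)
        sub = np.sort(pool)[np.linspace(0, 9999, 200).round().astype(int)]
        res = ckmeans_1d(sub, 10)
        assert sm.assign(sub).tolist() == (res.labels + 1).tolist()

    def test_too_few_distinct_values(self):
        with pytest.raises(DegenerateScaleError):
            fit_scale_model([1.0] * 50, k=10)


def _rec(phase, lad, group, lac_class="plain", fsad_frac=1.0, voxels=1000):
    return LACRecord(id=1, phase=phase, threshold=-950, voxel_count=voxels,
                     lad=lad, max_erosion_depth=0, centroid_mm=(0, 0, 0),
                     side="left", group=group, lac_class=lac_class,
                     fsad_voxels=int(round(fsad_frac * voxels)))


@pytest.fixture()
def unit_scales():
    from bprm.pipeline import scale_model_from_boundaries

    b = np.linspace(0.01, 0.09, 9)
    return {"emph950": scale_model_from_boundaries(b),
            "fsad": scale_model_from_boundaries(b)}


class TestAssemblePredictors:
    def test_no_lacs_gives_zero_vector(self, unit_scales):
        x = assemble_predictors([], unit_scales)
        assert (x == 0).all()

    def test_single_inspiratory_lac(self, unit_scales):
        x = assemble_predictors([_rec("inspiratory", 0.025, "upper")], unit_scales)
        assert x[predictor_name(3, "upper", "emph950")] == pytest.approx(2.5)
        assert x.drop(predictor_name(3, "upper", "emph950")).abs().sum() == 0

    def test_emph_predominant_expiratory_excluded(self, unit_scales):
        x = assemble_predictors(
            [_rec("expiratory", 0.05, "lower", "emph_predominant")], unit_scales)
        assert (x == 0).all()

    def test_fsad_uses_fsad_voxel_density(self, unit_scales):
        x = assemble_predictors(
            [_rec("expiratory", 0.05, "lower", "fsad", fsad_frac=0.6)], unit_scales)
        assert x.sum() == pytest.approx(100 * 0.05 * 0.6)

    def test_scale_sums_reproduce_regional_lav(self, unit_scales):
        rng = np.random.default_rng(2)
        recs = [_rec("inspiratory", lad, "upper")
                for lad in rng.uniform(0.001, 0.1, 25)]
        x = assemble_predictors(recs, unit_scales)
        total = sum(x[predictor_name(s, "upper", "emph950")] for s in range(1, 11))
        assert total == pytest.approx(100 * sum(r.lad for r in recs), abs=1e-12)


class TestLinearModel:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.uniform(0, 10, 50),
                          "x2": rng.uniform(0, 10, 50)})
        y = 70 - 2.0 * X["x1"]
        full = fit_full_model(X, y)
        assert full.params["x1"] == pytest.approx(-2.0, abs=1e-10)
        assert full.pvalues["x1"] < 1e-20

    def test_constant_design_gives_mean_intercept(self):
        X = pd.DataFrame({"x1": np.zeros(20)})
        y = np.arange(20.0)
        with pytest.warns(UserWarning):
            full = fit_full_model(X, y)
        assert full.params["const"] == pytest.approx(y.mean())

    def test_too_few_subjects_rejected(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 12)))
        with pytest.raises(FitError):
            fit_full_model(X, np.arange(10.0))

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        X["c"] = X["a"] + X["b"]
        y = X["a"] + rng.normal(size=40)
        with pytest.warns(UserWarning, match="rank-deficient"):
            full = fit_full_model(X, y)
        assert len(full.dropped) == 1


class TestBackwardSelect:
    def test_already_valid_model_unchanged(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.normal(size=100)})
        y = 3 * X["x1"].to_numpy() + rng.normal(size=100)
        full = fit_full_model(X, y)
        model = backward_select(full)
        assert model.term_names == ["x1"]
        assert model.terms[0].coefficient == pytest.approx(full.params["x1"])

    def test_true_predictor_kept_noise_pruned(self):
        kept_true = 0
        noise_kept = 0
        n_noise = 5
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(200, n_noise + 1)),
                             columns=[f"x{i}" for i in range(n_noise + 1)])
            y = 5.0 * X["x0"].to_numpy() + rng.normal(size=200)
            model = backward_select(fit_full_model(X, y))
            kept_true += "x0" in model.term_names
            noise_kept += len(set(model.term_names) - {"x0"})
        assert kept_true == 60
        # each noise predictor survives with probability ~ alpha
        assert noise_kept / (60 * n_noise) < 0.12

    def test_all_noise_collapses_to_intercept_mostly(self):
        intercept_only = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(80, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = rng.normal(size=80)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                model = backward_select(fit_full_model(X, y))
            intercept_only += not model.terms
        # expect roughly (1-alpha)^p ~ 0.74 of runs; allow wide slack
        assert intercept_only >= 0.5 * 40

    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 6)),
                         columns=list("abcdef"))
        y = 2 * X["b"].to_numpy() + X["e"].to_numpy() + rng.normal(size=60)
        m1 = backward_select(fit_full_model(X, y))
        m2 = backward_select(fit_full_model(X[list("fedcba")], y))
        assert sorted(m1.term_names) == sorted(m2.term_names)
        for t1 in m1.terms:
            t2 = next(t for t in m2.terms if t.name == t1.name)
            assert t1.coefficient == pytest.approx(t2.coefficient)


class TestCrossValidate:
    def test_noiseless_linear_cohort_perfect(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.uniform(0, 10, 60),
                          "x2": rng.uniform(0, 10, 60)})
        y = 50 - 2 * X["x1"].to_numpy() + 0.5 * X["x2"].to_numpy()
        cv = cross_validate(X, y, repeats=3, seed=0)
        assert np.all(cv.per_repeat_r > 1 - 1e-9)

    def test_permutation_null_near_zero(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=[f"x{i}" for i in range(5)])
        y = rng.normal(size=100)  # independent of X
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            cv = cross_validate(X, y, repeats=30, seed=5)
        assert abs(cv.mean_r) < 0.15

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X["a"].to_numpy() * 2 + rng.normal(size=50)
        cv1 = cross_validate(X, y, repeats=4, seed=33)
        cv2 = cross_validate(X, y, repeats=4, seed=33)
        assert np.array_equal(cv1.per_repeat_r, cv2.per_repeat_r)

    def test_record_table_shape(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X["a"].to_numpy() * 2 + rng.normal(size=50)
        cv = cross_validate(X, y, folds=5, repeats=4, seed=1)
        assert len(cv.records) == 20

    def test_tiny_folds_rejected(self):
        with pytest.raises(ParameterError):
            cross_validate(pd.DataFrame({"a": range(8)}), np.arange(8.0),
                           folds=5, repeats=1, seed=0)


class TestPearson:
    def test_perfect_correlation(self):
        a = np.arange(10.0)
        assert pearson(a, a)[0] == pytest.approx(1.0)
        assert pearson(a, -a)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 4, 6, 9])
        # direct formula
        expect = (np.sum((a - a.mean()) * (b - b.mean()))
                  / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
        assert pearson(a, b)[0] == pytest.approx(expect)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 2.0], [1.0, 2.0])


def test_predictor_name_round_trip():
    for name in PREDICTOR_NAMES:
        s, g, t = parse_predictor_name(name)
        assert predictor_name(s, g, t) == name
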