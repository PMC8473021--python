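"""RBF engine: scaling, splitting, fitting, metrics, persistence."""

import json

import numpy as np
import pandas as pd
import pytest

import dentage as d
from dentage.errors import (
    CapacityError,
    DegenerateColumnError,
    FormatError,
    NumericalError,
    SchemaVersionError,
    SizeError,
    UndefinedQualityError,
)
from dentage.rbf import ScaleParams


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(400, (200, 100, 100)), (4, (2, 1, 1)), (619, (309, 154, 156))],
    )
    def test_two_one_one_allocation(self, n, expected):
        split = d.split_cohort([f"c{i}" for i in range(n)], seed=1)
        assert (len(split.train_ids), len(split.valid_ids), len(split.test_ids)) == expected

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"c{i}" for i in range(101)]
        split = d.split_cohort(ids, seed=7)
        parts = [set(split.train_ids), set(split.valid_ids), set(split.test_ids)]
        assert sum(len(p) for p in parts) == 101
        assert set().union(*parts) == set(ids)

    def test_seed_determinism_and_variation(self):
        ids = [f"c{i}" for i in range(40)]
        assert d.split_cohort(ids, 3) == d.split_cohort(ids, 3)
        assert d.split_cohort(ids, 3) != d.split_cohort(ids, 4)

    def test_too_small_cohort(self):
        with pytest.raises(SizeError):
            d.split_cohort(["a", "b", "c"], seed=0)


class TestScaling:
    def test_extremes_map_to_unit_interval(self):
        assert d.minimax_scale(np.array([5.0]), 5.0, 9.0)[0] == 0.0
        assert d.minimax_scale(np.array([9.0]), 5.0, 9.0)[0] == 1.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-30, 70, 100)
        back = d.minimax_unscale(d.minimax_scale(vals, -30, 70), -30, 70)
        assert back == pytest.approx(vals, abs=1e-12)

    def test_degenerate_column_raises(self):
        with pytest.raises(DegenerateColumnError):
            d.minimax_scale(np.array([1.0]), 2.0, 2.0)
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(DegenerateColumnError, match="b"):
            ScaleParams.fit(X, np.array([1.0, 2.0]), ["a", "b"])


class TestFit:
    def test_interpolation_with_h_equal_n(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=len(X), ridge=0.0, seed=0)
        assert d.rmse_scaled(m, X, y) < 1e-6

    def test_constant_target_gives_constant_predictions(self, tiny_regression):
        X, _ = tiny_regression
        y = pd.Series(96.0, index=X.index)
        m = d.fit_rbf(X, y, H=3, seed=0)
        assert m.predict(X) == pytest.approx(np.full(len(X), 96.0), abs=1e-6)
        assert m.weights[:-1] == pytest.approx(np.zeros(3), abs=1e-6)

    def test_capacity_error(self, tiny_regression):
        X, y = tiny_regression
        with pytest.raises(CapacityError):
            d.fit_rbf(X, y, H=len(X) + 1)

    def test_output_weights_match_normal_equations(self):
        """5-case, H=2 fixture solved by explicitly assembled normal equations."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(0, 1, (5, 2)), columns=["u", "v"])
        y = pd.Series(rng.uniform(50, 140, 5))
        ridge = 1e-4
        m = d.fit_rbf(X, y, H=2, seed=3, ridge=ridge)
        # independent path: rebuild the design matrix and solve (A'A + rD)w = A'y
        Xs = m.scale.scale_x(X.to_numpy())
        d2 = ((Xs[:, None, :] - m.centers[None, :, :]) ** 2).sum(axis=2)
        A = np.hstack([np.exp(-d2 / (2 * m.widths**2)), np.ones((5, 1))])
        D = np.diag([1.0, 1.0, 0.0])
        w_oracle = np.linalg.solve(A.T @ A + ridge * D, A.T @ m.scale.scale_y(y))
        assert m.weights == pytest.approx(w_oracle, abs=1e-8)

    def test_monotone_capacity_with_nested_centers(self, tiny_regression):
        """With nested fixed center sets and ridge 0, training RMSE never grows."""
        X, y = tiny_regression
        base = d.fit_rbf(X, y, H=len(X), ridge=0.0, seed=0)
        all_centers = base.scale.scale_x(X.to_numpy())
        errs = []
        for k in range(1, 7):
            m = d.fit_rbf(X, y, H=k, ridge=0.0, seed=0, centers=all_centers[:k])
            errs.append(d.rmse_scaled(m, X, y))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_singular_design_with_zero_ridge_advises_ridge(self, tiny_regression):
        X, y = tiny_regression
        c = d.fit_rbf(X, y, H=2, seed=0).centers
        dup = np.vstack([c[0], c[0]])  # coincident centers -> identical columns
        with pytest.raises(NumericalError, match="ridge"):
            d.fit_rbf(X, y, H=2, ridge=0.0, seed=0, centers=dup)

    def test_seed_determinism(self, small_xy, small_split):
        X, y = small_xy
        tr = list(small_split.train_ids)
        m1 = d.fit_rbf(X.loc[tr], y.loc[tr], H=8, seed=5)
        m2 = d.fit_rbf(X.loc[tr], y.loc[tr], H=8, seed=5)
        assert np.array_equal(m1.centers, m2.centers)
        assert np.array_equal(m1.weights, m2.weights)


class TestPredict:
    def test_zero_weights_predict_inverse_scaled_bias(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=2, seed=0)
        m.weights = np.array([0.0, 0.0, 0.25])
        expected = m.scale.unscale_y(np.array([0.25]))[0]
        assert m.predict(X) == pytest.approx(np.full(len(X), expected))

    def test_single_unit_hand_model(self):
        """One center, width 1, weight 1, bias 0: pocket-calculator Gaussian."""
        scale = ScaleParams(("a",), np.array([0.0]), np.array([1.0]), 48.0, 144.0)
        m = d.RBFModel(
            input_names=("a",),
            centers=np.array([[0.2]]),
            widths=np.array([1.0]),
            weights=np.array([1.0, 0.0]),
            scale=scale,
            input_means=np.array([0.5]),
        )
        x = 0.7
        expected = 48.0 + 96.0 * np.exp(-((x - 0.2) ** 2) / 2.0)
        assert d.predict_age(m, np.array([x])) == pytest.approx(expected, abs=1e-12)

    def test_interpolating_model_reproduces_center_targets(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=len(X), ridge=0.0, seed=0)
        assert m.predict(X) == pytest.approx(y.to_numpy(), abs=1e-4)

    def test_clamp_flag_limits_to_validity_window(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=4, seed=0)
        m.weights = np.array([0.0] * 4 + [2.0])  # scaled output 2 -> far above range
        assert np.all(m.predict(X, clamp=True) <= 144.0)


class TestMetrics:
    def test_quality_perfect_and_antiperfect(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert d.quality(t, t) == pytest.approx(1.0)
        assert d.quality(-t, t) == pytest.approx(-1.0)

    def test_quality_four_point_fixture(self):
        # direct formula: cov / (sd_p * sd_t) = 4.0 / 5.0
        assert d.quality([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_quality_undefined_cases(self):
        with pytest.raises(UndefinedQualityError):
            d.quality([1.0], [1.0])
        with pytest.raises(UndefinedQualityError):
            d.quality([1.0, 1.0], [1.0, 2.0])

    def test_rmse_scaled_hand_fixture(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=3, seed=1)
        # direct formula on the three first cases
        sub = X.iloc[:3]
        resid = m.predict_scaled(sub) - m.scale.scale_y(y.iloc[:3].to_numpy())
        expected = float(np.sqrt((resid**2).mean()))
        assert d.rmse_scaled(m, sub, y.iloc[:3]) == pytest.approx(expected, abs=1e-12)

    def test_rmse_constant_offset(self, tiny_regression):
        X, y = tiny_regression
        m = d.fit_rbf(X, y, H=len(X), ridge=0.0, seed=0)
        m.weights = m.weights.copy()
        m.weights[-1] += 0.05  # constant shift of the scaled output
        assert d.rmse_scaled(m, X, y) == pytest.approx(0.05, abs=1e-5)

    def test_rmse_empty_case_set(self, small_model, small_xy):
        X, y = small_xy
        with pytest.raises(SizeError):
            d.rmse_scaled(small_model, X.iloc[:0], y.iloc[:0])

    def test_report_invariant_to_case_order(self, small_model, small_xy, small_split):
        X, y = small_xy
        r1 = d.report(small_model, X, y, small_split)
        perm = list(X.index)[::-1]
        r2 = d.report(small_model, X.loc[perm], y.loc[perm], small_split)
        assert r1 == r2

    def test_interpolating_model_report(self, tiny_regression):
        X, y = tiny_regression
        split = d.DataSplit(tuple(X.index[:6]), tuple(X.index[6:9]), tuple(X.index[9:]))
        tr = list(split.train_ids)
        m = d.fit_rbf(X.loc[tr], y.loc[tr], H=6, ridge=0.0, seed=0)
        rep = d.report(m, X, y, split)
        assert rep.training_quality == pytest.approx(1.0, abs=1e-6)
        assert rep.training_error < 1e-6


class TestTopology:
    @pytest.mark.parametrize(
        "s,expected",
        [("RBF 22:22-15-1:1", (22, 15, 1)), ("RBF 13:13-1-1:1", (13, 1, 1)),
         ("RBF 18:18-1-1:1", (18, 1, 1))],
    )
    def test_parse_well_formed(self, s, expected):
        assert d.parse_topology(s) == expected
        assert d.format_topology(*expected) == s

    @pytest.mark.parametrize("s", ["RBF 22-15-1", "MLP 22:22-15-1:1", "RBF 22:21-15-1:1"])
    def test_parse_malformed(self, s):
        with pytest.raises(FormatError):
            d.parse_topology(s)


class TestDesignerSearch:
    def test_retains_at_most_n_sorted_by_validation_error(self, small_xy, small_split):
        X, y = small_xy
        got = d.designer_search(X, y, small_split, [4, 8, 12], n_test=20, n_retain=10, seed=2)
        assert 1 <= len(got) <= 10
        errs = [c.validation_rmse for c in got]
        assert errs == sorted(errs)

    def test_single_candidate_returned(self, small_xy, small_split):
        X, y = small_xy
        got = d.designer_search(X, y, small_split, [6], n_test=1, n_retain=1, seed=2)
        assert len(got) == 1 and got[0].H == 6

    def test_diversity_cap_on_shared_topology(self, small_xy, small_split):
        X, y = small_xy
        got = d.designer_search(X, y, small_split, [4, 9], n_test=16, n_retain=6, seed=2)
        counts = {}
        for c in got:
            counts[c.H] = counts.get(c.H, 0) + 1
        assert all(v <= 3 for v in counts.values())  # ceil(6/2)

    def test_best_matches_exhaustive_grid(self, small_xy, small_split):
        """Retained leader equals the minimum over all candidates re-trained."""
        X, y = small_xy
        kept = d.designer_search(X, y, small_split, [2, 5, 9], n_test=8, n_retain=4, seed=6)
        everything = d.designer_search(X, y, small_split, [2, 5, 9], n_test=8, n_retain=8, seed=6)
        assert kept[0].validation_rmse == min(c.validation_rmse for c in everything)

    def test_empty_candidates_rejected(self, small_xy, small_split):
        X, y = small_xy
        with pytest.raises(d.DentageError):
            d.designer_search(X, y, small_split, [], n_test=2, n_retain=1)


class TestPersistence:
    def test_round_trip_predicts_identically(self, small_model, tmp_path):
        p = tmp_path / "m.json"
        d.save_model(small_model, p)
        back = d.load_model(p)
        rng = np.random.default_rng(1)
        probe = rng.uniform(0.5, 2.0, (50, len(small_model.input_names)))
        assert back.predict(probe) == pytest.approx(small_model.predict(probe), abs=1e-12)
        assert back.topology == small_model.topology

    def test_save_is_deterministic(self, small_model, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        d.save_model(small_model, p1)
        d.save_model(small_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_field_raises_format_error(self, small_model, tmp_path):
        p = tmp_path / "m.json"
        d.save_model(small_model, p)
        doc = json.loads(p.read_text())
        del doc["widths"]
        p.write_text(json.dumps(doc))
        with pytest.raises(FormatError, match="widths"):
            d.load_model(p)

    def test_schema_mismatch_raises(self, small_model, tmp_path):
        p = tmp_path / "m.json"
        d.save_model(small_model, p)
        doc = json.loads(p.read_text())
        doc["schema"] = "dentage-rbf/99"
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaVersionError):
            d.load_model(p)
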