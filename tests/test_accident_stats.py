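"""Weibull speed fitting, IPF and probability-table construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aebrisk.accident_stats import (
    AccidentRecord,
    ContingencyTable,
    InsufficientDataError,
    ProbabilityTables,
    WeibullParams,
    conflict_probabilities,
    fit_tables,
    fit_weibull,
    ipf,
    normalize_cluster_shares,
    read_accident_records,
    severity_probabilities,
    write_accident_records,
)


class TestFitWeibull:
    def test_parameter_recovery(self):
        """MLE recovers generator parameters at large n."""
        rng = np.random.default_rng(7)
        x = 40.0 * rng.weibull(2.0, 5000)
        p = fit_weibull(x)
        assert abs(p.shape - 2.0) / 2.0 < 0.05
        assert abs(p.scale - 40.0) / 40.0 < 0.05
        assert p.n == np.count_nonzero(x > 0)

    def test_recovery_median_relative_error(self):
        """Median relative error over seeded replicates stays below 5%."""
        errs_shape, errs_scale = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = 35.0 * rng.weibull(1.8, 2000)
            p = fit_weibull(x)
            errs_shape.append(abs(p.shape - 1.8) / 1.8)
            errs_scale.append(abs(p.scale - 35.0) / 35.0)
        assert np.median(errs_shape) <= 0.05
        assert np.median(errs_scale) <= 0.05

    def test_exponential_special_case_matches_sample_mean(self):
        """With shape ~1 data, the fitted scale approaches the closed-form
        exponential MLE (the sample mean)."""
        rng = np.random.default_rng(3)
        x = 10.0 * rng.weibull(1.0, 200_000)
        p = fit_weibull(x)
        assert abs(p.shape - 1.0) < 0.02
        assert abs(p.scale - x[x > 0].mean()) / x[x > 0].mean() < 0.02

    def test_insufficient_samples_rejected(self):
        with pytest.raises(InsufficientDataError, match="insufficient"):
            fit_weibull([30.0, 35.0], min_n=3)

    def test_zero_speeds_excluded_before_fit(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([40.0 * rng.weibull(2.0, 1000), np.zeros(50)])
        p = fit_weibull(x)
        assert p.n == 1000
        # zeros and min_n interact: all-zero sample is insufficient
        with pytest.raises(InsufficientDataError):
            fit_weibull([0.0, 0.0, 0.0, 0.0])

    def test_cdf_evaluable(self):
        p = WeibullParams(2.0, 40.0, 10)
        assert p.cdf(0.0) == 0.0
        assert 0.0 < p.cdf(40.0) < 1.0
        assert p.cdf(1e6) == pytest.approx(1.0)


class TestIPF:
    def test_hand_iteration_oracle_2x2(self):
        """Independence seed converges to the product of margins / total."""
        t = ipf(ContingencyTable(np.ones((2, 2)), [3.0, 1.0], [2.0, 2.0]))
        np.testing.assert_allclose(t.cells, [[1.5, 1.5], [0.5, 0.5]], atol=1e-9)

    def test_fixed_point_unchanged(self):
        cells = np.array([[2.0, 1.0], [1.0, 2.0]])
        t = ipf(ContingencyTable(cells.copy(), [3.0, 3.0], [3.0, 3.0]))
        np.testing.assert_allclose(t.cells, cells, atol=1e-12)

    def test_zero_cells_preserved(self):
        seed = ContingencyTable(np.array([[0.0, 2.0], [3.0, 1.0]]), [2.0, 4.0], [3.0, 3.0])
        t = ipf(seed)
        assert t.cells[0, 0] == 0.0

    def test_margins_satisfied_within_tolerance(self, rng):
        cells = rng.uniform(0.1, 5.0, size=(4, 6))
        row_t = rng.uniform(1.0, 10.0, size=4)
        col_t = rng.uniform(1.0, 10.0, size=6)
        col_t *= row_t.sum() / col_t.sum()
        t = ipf(ContingencyTable(cells, row_t, col_t), tol=1e-8)
        assert np.abs(t.cells.sum(axis=1) - row_t).max() <= 1e-8
        assert np.abs(t.cells.sum(axis=0) - col_t).max() <= 1e-8

    def test_odds_ratios_preserved(self, rng):
        """IPF scales rows/columns, so 2x2 cross-product ratios survive."""
        cells = rng.uniform(0.5, 4.0, size=(5, 5))
        row_t = rng.uniform(1.0, 10.0, size=5)
        col_t = rng.uniform(1.0, 10.0, size=5)
        col_t *= row_t.sum() / col_t.sum()
        t = ipf(ContingencyTable(cells.copy(), row_t, col_t), tol=1e-12)
        for _ in range(20):
            i, j = rng.choice(5, 2, replace=False)
            k, l = rng.choice(5, 2, replace=False)
            before = (cells[i, k] * cells[j, l]) / (cells[i, l] * cells[j, k])
            after = (t.cells[i, k] * t.cells[j, l]) / (t.cells[i, l] * t.cells[j, k])
            assert after == pytest.approx(before, rel=1e-6)

    def test_infeasible_margins_error(self):
        seed = ContingencyTable(np.array([[0.0, 0.0], [1.0, 1.0]]), [2.0, 2.0], [2.0, 2.0])
        with pytest.raises(ValueError, match="infeasible"):
            ipf(seed)

    def test_unequal_margin_totals_rejected(self):
        with pytest.raises(ValueError, match="total"):
            ContingencyTable(np.ones((2, 2)), [3.0, 1.0], [1.0, 1.0])


class TestCategoricalProbabilities:
    def test_severity_normalization(self):
        p = severity_probabilities({"slight": 70, "severe": 25, "fatal": 5})
        assert p == {"slight": 0.70, "severe": 0.25, "fatal": 0.05}
        assert severity_probabilities({"slight": 1, "severe": 0, "fatal": 0})["slight"] == 1.0

    def test_all_zero_severities_rejected(self):
        with pytest.raises(ValueError):
            severity_probabilities({"slight": 0, "severe": 0})

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_severity_probabilities_sum_to_one(self, weights):
        p = severity_probabilities({f"s{i}": w for i, w in enumerate(weights)})
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_cluster_share_one_is_identity(self):
        within = {("slight", "A"): {"x": 0.4, "y": 0.6}}
        out = conflict_probabilities(within, {"slight": {"A": 1.0}})
        assert out == {("slight", "x"): 0.4, ("slight", "y"): 0.6}

    def test_two_cluster_product(self):
        within = {("slight", "A"): {"a": 0.5, "b": 0.5}, ("slight", "B"): {"c": 1.0}}
        out = conflict_probabilities(within, {"slight": {"A": 0.8, "B": 0.2}})
        assert out[("slight", "a")] == pytest.approx(0.4)
        assert out[("slight", "b")] == pytest.approx(0.4)
        assert out[("slight", "c")] == pytest.approx(0.2)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_cluster_distribution_error(self):
        with pytest.raises(ValueError, match="no within-cluster"):
            conflict_probabilities({}, {"slight": {"A": 1.0}})

    def test_excluded_clusters_dropped(self):
        shares = normalize_cluster_shares({"A": 0.5, "Unspecified": 0.3, "Others": 0.2})
        assert shares == {"A": 1.0}


class TestProbabilityTables:
    def test_blocks_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            ProbabilityTables(
                p_is={"slight": 0.5, "severe": 0.4},
                p_cs_given_is={"slight": {"A": 1.0}},
                p_rc_given_is_cs={},
            )

    def test_yaml_round_trip_bit_identical(self, small_tables, tmp_path):
        p1 = tmp_path / "a.yaml"
        p2 = tmp_path / "b.yaml"
        small_tables.to_yaml(p1)
        ProbabilityTables.from_yaml(p1).to_yaml(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestFitTables:
    def _records(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            sev = ["slight", "severe"][rng.integers(2)]
            cs = ["SCPPL", "SCPPR"][rng.integers(2)]
            records.append(
                AccidentRecord(
                    case_id=f"c{i}", conflict_situation=cs, cluster="Crossing",
                    injury_severity=sev, v_veh0=float(35 * rng.weibull(2.0)),
                    v_vru0=float(5 * rng.weibull(1.8)),
                    road_condition=["dry", "non_dry"][rng.integers(2)],
                    source=["A", "B"][i % 2],
                )
            )
        return records

    def test_fitted_blocks_normalized(self):
        tables = fit_tables(self._records())
        tables.validate()
        for sev, block in tables.p_cs_given_is.items():
            assert sum(block.values()) == pytest.approx(1.0, abs=1e-9)

    def test_speed_distributions_fitted_per_stratum(self):
        tables = fit_tables(self._records())
        assert ("slight", "SCPPL", "vehicle") in tables.speed_dists
        assert ("slight", "SCPPL", "vru") in tables.speed_dists

    def test_record_io_round_trip(self, tmp_path):
        records = self._records(n=20)
        path = tmp_path / "records.csv"
        write_accident_records(records, path)
        back = read_accident_records(path)
        assert back == records
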