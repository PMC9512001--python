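"""Agreement statistics: paired summaries, LoA confidence intervals, reports."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from okfluor import stats as st


def t_tail_by_quadrature(t_abs: float, df: int) -> float:
    """Independent oracle: two-sided t p-value by integrating the density."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    density = lambda x: const * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = quad(density, t_abs, np.inf)
    return 2.0 * tail


def _table_from_arrays(values: dict) -> st.MeasurementTable:
    """values maps (observer, method) -> {zone: array over eyes}."""
    rows = []
    for (obs, method), zones in values.items():
        for zone, arr in zones.items():
            for eye, v in enumerate(arr):
                rows.append(
                    {"eye_id": f"eye{eye:02d}", "observer": obs, "method": method,
                     "zone": zone, "width_mm": v}
                )
    return st.MeasurementTable(pd.DataFrame(rows))


class TestPairedSummary:
    def test_printed_between_software_central_bearing_loa(self):
        # a difference series with mean -0.07 and SD 0.28 must give the
        # published limits [-0.62, 0.48] to 2 dp, whatever the raw values
        lo, hi = st.limits_of_agreement(-0.07, 0.28)
        assert round(lo, 2) == -0.62
        assert round(hi, 2) == 0.48

    def test_identical_series(self):
        s = st.paired_summary([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.mean_diff == 0 and s.sd_diff == 0
        assert (s.loa_low, s.loa_high) == (0, 0)
        assert s.pearson_r is not None  # both series vary; r is defined (=1)
        assert math.isnan(s.t_stat)

    def test_constant_series_r_undefined(self):
        s = st.paired_summary([1.0, 1.0, 1.0, 1.0], [1.0, 1.2, 0.9, 1.1])
        assert s.pearson_r is None and s.r_p_value is None
        assert "zero variance" in s.r_note
        assert np.isfinite(s.t_stat)  # differences still vary

    def test_small_case_t_and_p(self):
        s = st.paired_summary([1, 2, 3, 4], [1, 2, 3, 5])
        assert s.mean_diff == pytest.approx(-0.25)
        assert s.sd_diff == pytest.approx(0.5)
        assert s.t_stat == pytest.approx(-1.0)
        assert s.df == 3
        assert s.p_value == pytest.approx(0.391, abs=5e-4)

    def test_p_matches_quadrature_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a = rng.normal(1.0, 0.3, n)
            b = a + rng.normal(0.05, 0.2, n)
            s = st.paired_summary(a, b)
            assert s.p_value == pytest.approx(
                t_tail_by_quadrature(abs(s.t_stat), s.df), abs=1e-6
            )

    def test_antisymmetry_under_order_swap(self, rng):
        a = rng.normal(4.2, 0.7, 26)
        b = a + rng.normal(-0.07, 0.28, 26)
        s_ab = st.paired_summary(a, b)
        s_ba = st.paired_summary(b, a)
        assert s_ba.mean_diff == pytest.approx(-s_ab.mean_diff)
        assert s_ba.loa_low == pytest.approx(-s_ab.loa_high)
        assert s_ba.loa_high == pytest.approx(-s_ab.loa_low)
        assert s_ba.t_stat == pytest.approx(-s_ab.t_stat)
        assert s_ba.p_value == pytest.approx(s_ab.p_value)
        assert s_ba.pearson_r == pytest.approx(s_ab.pearson_r)

    def test_unit_scaling(self, rng):
        a = rng.normal(4.2, 0.7, 26)
        b = a + rng.normal(-0.07, 0.28, 26)
        s1 = st.paired_summary(a, b)
        s10 = st.paired_summary(10 * a, 10 * b)
        assert s10.mean_diff == pytest.approx(10 * s1.mean_diff)
        assert s10.sd_diff == pytest.approx(10 * s1.sd_diff)
        assert s10.loa_low == pytest.approx(10 * s1.loa_low)
        assert s10.t_stat == pytest.approx(s1.t_stat)
        assert s10.p_value == pytest.approx(s1.p_value)
        assert s10.pearson_r == pytest.approx(s1.pearson_r)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="3"):
            st.paired_summary([1, 2], [1, 2])


class TestLoaConfidenceInterval:
    def _summary(self, n, mean, sd):
        lo, hi = st.limits_of_agreement(mean, sd)
        return st.AgreementSummary(
            n=n, mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
            loa_low_ci=(lo, lo), loa_high_ci=(hi, hi), t_stat=0.0, df=n - 1,
            p_value=1.0, pearson_r=None, r_p_value=None,
            mean_a=0, sd_a=1, ci_a=(0, 0), mean_b=0, sd_b=1, ci_b=(0, 0),
        )

    def test_printed_interobserver_upper_limit(self):
        # published inter-observer central-bearing summary: -0.16 +/- 0.37,
        # n = 26, upper limit 0.57 with interval about [0.31, 0.83]
        s = self._summary(26, -0.16, 0.37)
        assert round(s.loa_high, 2) == 0.57
        lo_ci, hi_ci = st.loa_confidence_interval(s)
        assert hi_ci[0] == pytest.approx(0.31, abs=0.01)
        assert hi_ci[1] == pytest.approx(0.83, abs=0.01)

    def test_degenerate_zero_sd(self):
        s = self._summary(10, 0.2, 0.0)
        assert st.loa_confidence_interval(s) == ((0.2, 0.2), (0.2, 0.2))

    def test_higher_level_widens(self):
        s = self._summary(26, -0.16, 0.37)
        (l95, h95) = st.loa_confidence_interval(s, level=0.95)[1]
        (l99, h99) = st.loa_confidence_interval(s, level=0.99)[1]
        assert l99 < l95 and h99 > h95

    def test_exact_mode_brackets_the_limit(self):
        s = self._summary(26, -0.16, 0.37)
        for ci, limit in zip(
            st.loa_confidence_interval(s, mode="exact"), (s.loa_low, s.loa_high)
        ):
            assert ci[0] < limit < ci[1]

    def test_exact_mode_converges_to_approximate(self):
        # both constructions should agree ever more closely as n grows
        s = self._summary(2000, -0.16, 0.37)
        approx = st.loa_confidence_interval(s, mode="approximate")[1]
        exact = st.loa_confidence_interval(s, mode="exact")[1]
        assert approx[0] == pytest.approx(exact[0], abs=5e-3)
        assert approx[1] == pytest.approx(exact[1], abs=5e-3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            st.loa_confidence_interval(self._summary(10, 0, 1), mode="bootstrap")


class TestMeasurementTable:
    def test_duplicate_keys_rejected(self):
        rows = pd.DataFrame(
            [{"eye_id": "e1", "observer": 1, "method": "algorithm",
              "zone": "edge_lift", "width_mm": 0.5}] * 2
        )
        with pytest.raises(ValueError, match="duplicate"):
            st.MeasurementTable(rows)

    def test_nonpositive_width_rejected(self):
        rows = pd.DataFrame(
            [{"eye_id": "e1", "observer": 1, "method": "algorithm",
              "zone": "edge_lift", "width_mm": 0.0}]
        )
        with pytest.raises(ValueError, match="non-positive"):
            st.MeasurementTable(rows)

    def test_wide_reader_matches_long(self, tmp_path, rng):
        eyes = [f"eye{i}" for i in range(5)]
        wide = pd.DataFrame({
            "eye_id": eyes,
            "cb_o1_alg": rng.normal(4.2, 0.3, 5),
            "cb_o2_alg": rng.normal(4.2, 0.3, 5),
        })
        path = tmp_path / "wide.csv"
        wide.to_csv(path, index=False)
        table = st.MeasurementTable.from_wide_csv(path, {
            "cb_o1_alg": ("central_bearing", 1, "algorithm"),
            "cb_o2_alg": ("central_bearing", 2, "algorithm"),
        })
        assert len(table.frame) == 10
        sub = table.frame.query("observer == 1")
        np.testing.assert_allclose(
            sub.sort_values("eye_id")["width_mm"].to_numpy(),
            wide.sort_values("eye_id")["cb_o1_alg"].to_numpy(),
        )


class TestAgreementReport:
    def test_constant_offset_between_methods(self, rng):
        base = {z: rng.normal(2.0, 0.4, 12) + 1 for z in st.ZONES}
        values = {
            (1, "algorithm"): base,
            (2, "algorithm"): base,
            (1, "imagej"): {z: v + 0.1 for z, v in base.items()},
            (2, "imagej"): {z: v + 0.1 for z, v in base.items()},
        }
        report = st.agreement_report(_table_from_arrays(values), "inter_method")
        for zone, s in report.items():
            assert s.mean_diff == pytest.approx(-0.1)
            assert s.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_seeded_gaussian_difference_recovery(self):
        rng = np.random.default_rng(1234)
        n = 26
        base = {z: np.abs(rng.normal(2.0, 0.4, n)) + 1 for z in st.ZONES}
        shifted = {z: v + rng.normal(0.05, 0.2, n) for z, v in base.items()}
        values = {
            (1, "algorithm"): base, (2, "algorithm"): base,
            (1, "imagej"): shifted, (2, "imagej"): shifted,
        }
        report = st.agreement_report(_table_from_arrays(values), "inter_method")
        for s in report.values():
            se = 0.2 / np.sqrt(n)
            assert abs(-s.mean_diff - 0.05) < 3 * se

    def test_inter_method_uses_observer_mean(self, rng):
        n = 8
        values = {
            (1, "algorithm"): {z: np.full(n, 2.0) for z in st.ZONES},
            (2, "algorithm"): {z: np.full(n, 3.0) for z in st.ZONES},
            (1, "imagej"): {z: np.full(n, 2.5) for z in st.ZONES},
            (2, "imagej"): {z: np.full(n, 2.5) for z in st.ZONES},
        }
        report = st.agreement_report(_table_from_arrays(values), "inter_method")
        for s in report.values():  # mean(2,3) = 2.5 on both sides
            assert s.mean_diff == pytest.approx(0.0)

    def test_inter_observer_requires_method(self, rng):
        base = {z: rng.normal(2, 0.2, 5) + 1 for z in st.ZONES}
        table = _table_from_arrays({(1, "algorithm"): base, (2, "algorithm"): base})
        with pytest.raises(ValueError, match="method"):
            st.agreement_report(table, "inter_observer")
        report = st.agreement_report(table, "inter_observer", method="algorithm")
        assert set(report) == set(st.ZONES)

    def test_incomplete_pairing_lists_missing_eyes(self, rng):
        base = {z: rng.normal(2, 0.2, 5) + 1 for z in st.ZONES}
        table = _table_from_arrays({(1, "algorithm"): base, (2, "algorithm"): base})
        trimmed = st.MeasurementTable(
            table.frame[~((table.frame.eye_id == "eye00") & (table.frame.observer == 2))]
        )
        with pytest.raises(ValueError, match="eye00"):
            st.agreement_report(trimmed, "inter_observer", method="algorithm")

    def test_summary_frame_layout(self, rng):
        base = {z: rng.normal(2, 0.2, 6) + 1 for z in st.ZONES}
        table = _table_from_arrays({(1, "algorithm"): base, (2, "algorithm"): base})
        frame = st.summary_frame(st.agreement_report(table, "inter_observer", method="algorithm"))
        assert list(frame.index) == list(st.ZONES)
        for col in ("mean_diff", "sd_diff", "loa_low", "loa_high", "p", "r"):
            assert col in frame.columns


class TestBlandAltmanPlot:
    def test_plot_renders_without_error(self, tmp_path, rng):
        import matplotlib

        matplotlib.use("Agg")
        a = rng.normal(4.2, 0.7, 26)
        b = a + rng.normal(-0.07, 0.28, 26)
        s = st.paired_summary(a, b)
        ax = st.bland_altman_plot(a, b, s, title="central bearing")
        ax.figure.savefig(tmp_path / "ba.png")
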