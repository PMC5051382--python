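"""Decision metrics: ICER, NMB, CEAC, CE-plane quadrants, summaries."""

import numpy as np
import pandas as pd
import pytest

from cvdcea import ceac, icer, nmb, plane_quadrants, summarize
from cvdcea.econ_outputs import DOMINANT, DOMINATED, INDIFFERENT, summary_table
from cvdcea.psa import ARM_COLUMNS, PSAResult


def make_result(dc, dq, base_cost=6600.0, base_qaly=8.57, scenario="2y"):
    dc = np.asarray(dc, dtype=float)
    dq = np.asarray(dq, dtype=float)
    data = pd.DataFrame(
        {
            "iteration": np.arange(len(dc)),
            "control_cost": base_cost,
            "control_qaly": base_qaly,
            "intervention_cost": base_cost + dc,
            "intervention_qaly": base_qaly + dq,
        }
    )
    return PSAResult(scenario=scenario, seed=0, n_iter=len(dc), data=data)


class TestIcer:
    @pytest.mark.parametrize(
        "dc, dq, expected",
        [
            (131.0, 0.011, pytest.approx(11909.09, abs=0.01)),
            (-5.0, 0.02, DOMINANT),
            (5.0, -0.02, DOMINATED),
            (0.0, 0.0, INDIFFERENT),
            (10.0, 0.0, "+inf"),
            (-10.0, 0.0, "-inf"),
            (0.0, 0.01, 0.0),
        ],
    )
    def test_cases(self, dc, dq, expected):
        assert icer(dc, dq) == expected


class TestNmb:
    @pytest.mark.parametrize(
        "threshold, dc, dq, expected",
        [
            (20000.0, 131.0, 0.011, pytest.approx(89.0)),
            (0.0, 131.0, 0.011, pytest.approx(-131.0)),
            (20000.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_cases(self, threshold, dc, dq, expected):
        assert nmb(threshold, dc, dq) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            nmb(-1.0, 0.0, 0.0)

    def test_sign_flips_at_icer_of_means(self):
        dc, dq = 131.0, 0.011
        ratio = icer(dc, dq)
        assert nmb(ratio * 0.99, dc, dq) < 0 < nmb(ratio * 1.01, dc, dq)


class TestCeac:
    def test_all_dominant_is_one_everywhere(self):
        res = make_result(dc=[-10, -20, -5], dq=[0.01, 0.02, 0.03])
        curve = ceac(res, [0, 10000, 30000])
        assert (curve["prob_ce"] == 1.0).all()

    def test_counting(self):
        # NMBs at 20k: +69, +169, -31, -131
        res = make_result(dc=[131, 31, 231, 331], dq=[0.01] * 4)
        curve = ceac(res, [20000.0])
        assert curve["prob_ce"].iloc[0] == 0.5

    def test_matches_normal_tail_probability(self):
        """CEAC at a threshold approximates the analytic Gaussian tail of
        the NMB distribution within 3 binomial SEs."""
        from scipy.stats import norm  # oracle only

        rng = np.random.default_rng(3)
        n = 1000
        mu_c, sd_c = 130.0, 60.0
        mu_q, sd_q = 0.012, 0.004
        dc = rng.normal(mu_c, sd_c, n)
        dq = rng.normal(mu_q, sd_q, n)
        res = make_result(dc=dc, dq=dq)
        lam = 20000.0
        p_hat = ceac(res, [lam])["prob_ce"].iloc[0]
        mu = lam * mu_q - mu_c
        sd = np.sqrt((lam * sd_q) ** 2 + sd_c**2)
        p_true = 1.0 - norm.cdf(0.0, loc=mu, scale=sd)
        assert abs(p_hat - p_true) <= 3 * np.sqrt(p_true * (1 - p_true) / n)

    def test_limits(self):
        rng = np.random.default_rng(0)
        res = make_result(dc=rng.normal(0, 50, 400), dq=rng.normal(0, 0.01, 400))
        low = ceac(res, [0.0])["prob_ce"].iloc[0]
        assert low == (res.delta_cost < 0).mean()
        high = ceac(res, [1e12])["prob_ce"].iloc[0]
        assert high == (res.delta_qaly > 0).mean()

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(1)
        res = make_result(dc=rng.normal(100, 50, 500),
                          dq=rng.uniform(0.001, 0.02, 500))
        curve = ceac(res, np.arange(0, 50001, 500))
        assert (np.diff(curve["prob_ce"]) >= 0).all()

    def test_empty_grid_rejected(self):
        res = make_result(dc=[1.0], dq=[0.01])
        with pytest.raises(ValueError):
            ceac(res, [])


class TestPlaneQuadrants:
    def test_all_northeast(self):
        res = make_result(dc=[10, 20], dq=[0.01, 0.02])
        q = plane_quadrants(res)
        assert q["NE"] == 1.0 and sum(q.values()) == 1.0

    def test_symmetric_cloud(self):
        rng = np.random.default_rng(9)
        res = make_result(dc=rng.normal(0, 1, 4000), dq=rng.normal(0, 1, 4000))
        q = plane_quadrants(res)
        assert sum(q.values()) == pytest.approx(1.0)
        for share in q.values():
            assert share == pytest.approx(0.25, abs=3 * 0.25 / np.sqrt(4000))

    def test_axis_convention(self):
        res = make_result(dc=[0.0, 5.0], dq=[0.0, 0.01])
        q = plane_quadrants(res)
        # (0, 0) goes to the costlier / less-effective side: NW
        assert q["NW"] == 0.5 and q["NE"] == 0.5


class TestSummarize:
    def test_degenerate_psa_collapses_intervals(self):
        res = make_result(dc=[131.0] * 3, dq=[0.011] * 3)
        s = summarize(res, thresholds=[0, 20000, 30000])
        assert s.ci_delta_cost["percentile"] == (pytest.approx(131.0),) * 2
        assert s.ci_delta_qaly["se"][0] == pytest.approx(0.011)
        assert s.icer == pytest.approx(11909.09, abs=0.01)
        assert s.nmb[20000.0] == pytest.approx(89.0)

    def test_null_intervention(self):
        res = make_result(dc=[0.0] * 4, dq=[0.0] * 4)
        s = summarize(res, thresholds=[20000, 30000])
        assert s.delta_cost == 0.0 and s.delta_qaly == 0.0
        assert s.icer == INDIFFERENT
        assert s.nmb[20000.0] == 0.0

    def test_percentile_interval_coverage(self):
        """Over repeated synthetic PSAs with normal increments, the 95%
        percentile interval covers the true mean in roughly 95% of
        replicates (the interval is a distributional band, so coverage of
        the mean exceeds 90% comfortably at these settings)."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for _ in range(reps):
            dc = rng.normal(100.0, 30.0, 250)
            s = summarize(make_result(dc=dc, dq=np.full(250, 0.01)),
                          thresholds=[20000])
            lo, hi = s.ci_delta_cost["percentile"]
            hits += lo <= 100.0 <= hi
        assert hits / reps > 0.9

    def test_summary_table_layout(self):
        rng = np.random.default_rng(5)
        summaries = [
            summarize(make_result(dc=rng.normal(120, 10, 50),
                                  dq=rng.normal(0.012, 0.002, 50),
                                  scenario=lab),
                      thresholds=[20000, 30000])
            for lab in ("1y", "2y", "5y", "lifetime")
        ]
        table = summary_table(summaries)
        assert list(table.columns) == ["1y", "2y", "5y", "lifetime"]
        assert "ICER" in table.index
        assert "Control arm NHS costs" in table.index
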