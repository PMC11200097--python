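"""expMotif cascade: groups, primary filter, regression suite, calls, KDE."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ssrexp.detector import (
    MotifRegionGroup,
    build_groups,
    call_expmotifs,
    fit_regressions,
    position_density,
    primary_filter,
)
from ssrexp.simulate import (
    simulate_association_groups,
    simulate_regression_group,
)


def _tiny_assignment():
    return pd.DataFrame(
        {
            "transcript_id": ["t1", "t1", "t2", "t3"],
            "motif": ["AG", "AG", "GA", "A"],
            "canonical_motif": ["AG", "AG", "AG", "A"],
            "motif_size": [2, 2, 2, 1],
            "repeat_count": [8, 9, 8, 15],
            "start": [1, 100, 10, 5],
            "end": [16, 117, 25, 19],
            "tract_length": [16, 18, 16, 15],
            "region": ["5UTR", "5UTR", "5UTR", "3UTR"],
        }
    )


def _tiny_profiles():
    return pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3", "t4"],
            "tpm_max": [100.0, 10.0, 1.0, 50.0],
            "tpm_cv": [1.0, 2.0, 0.5, 1.5],
        }
    )


class TestBuildGroups:
    def test_characteristics_per_carrier(self):
        lengths = {"t1": 2000, "t2": 1000, "t3": 500, "t4": 800}
        groups = build_groups(
            _tiny_assignment(), _tiny_profiles(), lengths, mode="standardized"
        )
        by = {(g.motif, g.region): g for g in groups}
        ag = by[("AG", "5UTR")].members.set_index("transcript_id")
        assert ag.loc["t1", "abundance"] == 2
        assert ag.loc["t1", "length"] == 34
        assert ag.loc["t1", "density"] == pytest.approx(2 / (2000 / 1e6))
        assert ag.loc["t1", "ln_tpm_max"] == pytest.approx(np.log(100.0))
        assert ag.loc["t2", "abundance"] == 1

    def test_actual_mode_separates_strand_variants(self):
        lengths = {"t1": 2000, "t2": 1000, "t3": 500, "t4": 800}
        groups = build_groups(
            _tiny_assignment(), _tiny_profiles(), lengths, mode="actual"
        )
        motifs = {g.motif for g in groups}
        assert {"AG", "GA", "A"} <= motifs

    def test_nonpositive_responses_dropped(self):
        profiles = _tiny_profiles()
        profiles.loc[profiles["transcript_id"] == "t2", "tpm_max"] = 0.0
        lengths = {"t1": 2000, "t2": 1000, "t3": 500, "t4": 800}
        groups = build_groups(_tiny_assignment(), profiles, lengths)
        by = {(g.motif, g.region): g for g in groups}
        assert "t2" not in set(by[("AG", "5UTR")].members["transcript_id"])


class TestPrimaryFilter:
    def test_planted_shift_detected(self, rng):
        groups, profiles, planted = simulate_association_groups(
            seed=11, n_null_groups=3, n_carriers=200, n_background=500,
            planted_beta=0.004,
        )
        cand = primary_filter(groups, profiles, responses=("ln_tpm_max",))
        planted_row = cand[cand["motif"] == planted].iloc[0]
        assert planted_row["candidate"]
        assert planted_row["mw_p"] < 1e-6

    def test_small_carrier_group_skipped_with_warning(self):
        members = pd.DataFrame(
            {
                "transcript_id": ["x1", "x2"],
                "abundance": [1.0, 1.0],
                "density": [500.0, 700.0],
                "length": [16.0, 16.0],
                "ln_tpm_max": [1.0, 2.0],
                "ln_tpm_cv": [0.1, 0.2],
            }
        )
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        with pytest.warns(UserWarning, match="skipped"):
            cand = primary_filter([group], _tiny_profiles())
        assert cand.empty

    def test_kw_added_for_motifs_in_three_regions(self):
        rng = np.random.default_rng(5)
        groups = []
        ids = []
        for region in ("5UTR", "CDS", "3UTR"):
            members = pd.DataFrame(
                {
                    "transcript_id": [f"{region}_{i}" for i in range(20)],
                    "abundance": np.ones(20),
                    "density": rng.uniform(300, 3000, 20),
                    "length": np.full(20, 16.0),
                    "ln_tpm_max": rng.normal(0, 1, 20),
                    "ln_tpm_cv": rng.normal(0, 0.3, 20),
                }
            )
            ids.extend(members["transcript_id"])
            groups.append(MotifRegionGroup("AG", "standardized", region, members))
        profiles = pd.DataFrame(
            {
                "transcript_id": ids + [f"bg{i}" for i in range(50)],
                "tpm_max": np.exp(rng.normal(0, 1, len(ids) + 50)),
                "tpm_cv": np.exp(rng.normal(0, 0.3, len(ids) + 50)),
            }
        )
        cand = primary_filter(groups, profiles, responses=("ln_tpm_max",))
        assert cand["kw_p"].notna().all()


class TestFitRegressions:
    def test_noiseless_line_recovers_coefficients(self):
        rng = np.random.default_rng(3)
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(50)],
                "abundance": rng.uniform(1, 4, 50),
                "density": rng.uniform(300, 3000, 50),
                "length": rng.uniform(15, 60, 50),
            }
        )
        members["ln_tpm_max"] = 2.0 + 3.0 * members["density"]
        members["ln_tpm_cv"] = 0.0
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        suite = fit_regressions(group, "ln_tpm_max")
        assert suite.optimal is not None
        assert suite.optimal.form == "linear"
        assert suite.optimal.predictors == ("density",)
        assert suite.optimal.coefficients == pytest.approx([2.0, 3.0])
        assert suite.optimal.r_squared == pytest.approx(1.0)

    def test_quadratic_truth_beats_linear_by_bic(self):
        wins = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 4, 500)
            y = 1.0 + 0.5 * x - 0.4 * x**2 + rng.normal(0, 0.1, 500)
            members = pd.DataFrame(
                {
                    "transcript_id": [f"c{i}" for i in range(500)],
                    "abundance": rng.uniform(1, 4, 500),
                    "density": x,
                    "length": rng.uniform(15, 60, 500),
                    "ln_tpm_max": y,
                    "ln_tpm_cv": np.zeros(500),
                }
            )
            group = MotifRegionGroup("AG", "standardized", "CDS", members)
            suite = fit_regressions(group, "ln_tpm_max")
            density_fits = {
                f.form: f for f in suite.fits if f.predictors == ("density",)
            }
            if density_fits["quadratic"].bic < density_fits["linear"].bic:
                wins += 1
        assert wins >= int(0.95 * reps)

    def test_perfect_collinearity_discards_bivariate_fit(self):
        rng = np.random.default_rng(7)
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(30)],
                "abundance": rng.uniform(1, 4, 30),
                "density": rng.uniform(300, 3000, 30),
            }
        )
        members["length"] = 2.0 * members["density"]
        members["ln_tpm_max"] = rng.normal(0, 1, 30)
        members["ln_tpm_cv"] = np.zeros(30)
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        suite = fit_regressions(group, "ln_tpm_max")
        biv = [
            f for f in suite.fits
            if f.form == "bivariate" and set(f.predictors) == {"density", "length"}
        ]
        assert len(biv) == 1
        assert not biv[0].eligible
        assert biv[0].excluded_reason == "VIF above threshold"

    def test_constant_characteristic_skipped(self):
        rng = np.random.default_rng(9)
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(20)],
                "abundance": np.ones(20),
                "density": rng.uniform(300, 3000, 20),
                "length": rng.uniform(15, 60, 20),
                "ln_tpm_max": rng.normal(0, 1, 20),
                "ln_tpm_cv": np.zeros(20),
            }
        )
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        suite = fit_regressions(group, "ln_tpm_max")
        const = [f for f in suite.fits if f.predictors == ("abundance",)]
        assert all(f.excluded_reason == "constant predictor" for f in const)

    def test_too_few_carriers_rejected(self):
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(5)],
                "abundance": np.arange(5.0),
                "density": np.arange(5.0),
                "length": np.arange(5.0),
                "ln_tpm_max": np.arange(5.0),
                "ln_tpm_cv": np.zeros(5),
            }
        )
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        with pytest.raises(ValueError, match="> 10"):
            fit_regressions(group, "ln_tpm_max")


class TestCalls:
    def test_primary_significant_but_no_fit_is_not_called(self):
        """Conjunction rule: a pure mean shift with constant characteristics
        passes the primary filter but yields no significant regression."""
        rng = np.random.default_rng(21)
        n = 40
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(n)],
                "abundance": np.ones(n),
                "density": np.full(n, 800.0),
                "length": np.full(n, 16.0),
                "ln_tpm_max": rng.normal(5.0, 1.0, n),  # strong shift vs background
                "ln_tpm_cv": rng.normal(0, 0.3, n),
            }
        )
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        profiles = pd.DataFrame(
            {
                "transcript_id": list(members["transcript_id"])
                + [f"bg{i}" for i in range(300)],
                "tpm_max": np.concatenate(
                    [np.exp(members["ln_tpm_max"]), np.exp(rng.normal(0, 1, 300))]
                ),
                "tpm_cv": np.exp(rng.normal(0, 0.3, n + 300)),
            }
        )
        cand = primary_filter([group], profiles, responses=("ln_tpm_max",))
        assert cand["candidate"].iloc[0]
        calls, _ = call_expmotifs(cand, [group])
        assert not calls["called"].iloc[0]

    def test_conjunction_soundness_on_simulated_run(self):
        groups, profiles, _ = simulate_association_groups(
            seed=42, n_null_groups=20, n_carriers=30, n_background=300
        )
        cand = primary_filter(groups, profiles, responses=("ln_tpm_max",))
        calls, suites = call_expmotifs(cand, groups)
        for row in calls.itertuples(index=False):
            if row.called:
                assert row.primary_p < 0.05
                assert row.best_form != ""
        # and every called row's optimal fit is significant
        for key, suite in suites.items():
            if suite.optimal is not None:
                assert suite.optimal.significant

    def test_response_specific_call(self):
        """An effect planted on lnTPM_CV only is called for that response."""
        rng = np.random.default_rng(33)
        n = 60
        density = rng.uniform(300, 3000, n)
        members = pd.DataFrame(
            {
                "transcript_id": [f"c{i}" for i in range(n)],
                "abundance": 1 + rng.poisson(0.7, n).astype(float),
                "density": density,
                "length": rng.uniform(15, 60, n),
                "ln_tpm_max": rng.normal(0, 1, n),
                "ln_tpm_cv": 0.002 * density + rng.normal(0, 0.2, n),
            }
        )
        group = MotifRegionGroup("AG", "standardized", "5UTR", members)
        profiles = pd.DataFrame(
            {
                "transcript_id": list(members["transcript_id"])
                + [f"bg{i}" for i in range(400)],
                "tpm_max": np.exp(rng.normal(0, 1, n + 400)),
                "tpm_cv": np.concatenate(
                    [np.exp(members["ln_tpm_cv"]), np.exp(rng.normal(0, 0.2, 400))]
                ),
            }
        )
        # carriers keep their own responses
        profiles.loc[: n - 1, "tpm_max"] = np.exp(members["ln_tpm_max"]).to_numpy()
        cand = primary_filter([group], profiles)
        calls, _ = call_expmotifs(cand, [group])
        by_resp = calls.set_index("response")["called"]
        assert bool(by_resp["ln_tpm_cv"])
        assert not bool(by_resp["ln_tpm_max"])


class TestPositionDensity:
    def test_identical_positions_single_peak(self):
        curves, peaks = position_density([0.5] * 10, [1] * 10)
        assert peaks[1] == [pytest.approx(0.5, abs=0.01)]

    def test_uniform_positions_flat_density(self, rng):
        pts = rng.uniform(0.0001, 1.0, 10_000)
        curves, _ = position_density(pts, np.ones(10_000, dtype=int))
        mid = curves[(curves["x"] >= 0.1) & (curves["x"] <= 0.9)]
        assert np.all(np.abs(mid["density"] - 1.0) <= 0.1)

    def test_two_planted_clusters_recovered(self, rng):
        pts = np.concatenate(
            [
                np.clip(rng.normal(0.2, 0.03, 500), 0.001, 1.0),
                np.clip(rng.normal(0.8, 0.03, 500), 0.001, 1.0),
            ]
        )
        _, peaks = position_density(pts, np.ones(1000, dtype=int))
        locs = sorted(peaks[1])
        assert len(locs) == 2
        assert abs(locs[0] - 0.2) <= 0.05 and abs(locs[1] - 0.8) <= 0.05

    def test_curves_integrate_to_one(self, rng):
        pts = rng.beta(2, 5, 800)
        pts = np.clip(pts, 1e-4, 1.0)
        levels = rng.integers(1, 4, 800)
        curves, _ = position_density(pts, levels)
        for _, grp in curves.groupby("level"):
            mass = np.trapezoid(grp["density"], grp["x"])
            assert mass == pytest.approx(1.0, abs=0.02)

    def test_small_level_skipped_with_warning(self):
        pts = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.9])
        levels = np.array([1, 1, 1, 1, 1, 2, 2])
        with pytest.warns(UserWarning, match="skipped"):
            curves, peaks = position_density(pts, levels)
        assert set(curves["level"]) == {1}
        assert 2 not in peaks

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_density([], [])


def test_regression_beta_recovery_smoke():
    """The optimal model's density coefficient tracks the planted slope."""
    group = simulate_regression_group(seed=7, n=500, beta=1.0)
    suite = fit_regressions(group, "ln_tpm_max")
    assert suite.optimal is not None
    assert "density" in suite.optimal.predictors
    k = 1 + suite.optimal.predictors.index("density")
    assert suite.optimal.coefficients[k] == pytest.approx(1.0, rel=0.05)
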