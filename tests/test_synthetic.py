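"""Tests for the synthetic-cohort generator."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cogspan as cs
from cogspan.cohort import filter_outliers_two_pass
from cogspan.synthetic import _AGE_TRUNCNORM_LOC, _AGE_TRUNCNORM_SCALE


class TestTrajectory:
    def test_value_at_breakpoint_and_endpoints(self):
        spec = cs.TrajectorySpec(-0.30, (20.42,), (0.036, -0.023))
        assert spec.value(20.42) == pytest.approx(-0.30 + 0.036 * 8.42)
        assert spec.value(12.0) == pytest.approx(-0.30)

    def test_line_identity_without_breakpoints(self):
        spec = cs.TrajectorySpec(1.5, (), (0.07,))
        a1, a2 = 19.3, 55.8
        assert spec.value(a2) - spec.value(a1) == pytest.approx(
            0.07 * (a2 - a1)
        )

    def test_continuity_across_breakpoints(self):
        spec = cs.TrajectorySpec(0.0, (20.0, 40.0), (0.1, -0.05, 0.02))
        for bp in spec.breakpoints:
            lo, hi = spec.value(bp - 1e-9), spec.value(bp + 1e-9)
            assert abs(hi - lo) < 1e-8

    def test_age_outside_range_rejected(self):
        spec = cs.TrajectorySpec(0.0, (), (0.1,))
        with pytest.raises(ValueError, match="outside"):
            spec.value(70.0)

    @pytest.mark.parametrize("bad", [
        dict(intercept=0, breakpoints=(30, 20), slopes=(1, 2, 3)),
        dict(intercept=0, breakpoints=(11.0,), slopes=(1, 2)),
        dict(intercept=0, breakpoints=(20.0,), slopes=(1,)),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            cs.TrajectorySpec(**bad)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = cs.generate_cohort(cs.default_config(300, seed=5))
        b = cs.generate_cohort(cs.default_config(300, seed=5))
        assert a.data.to_csv() == b.data.to_csv()
        c = cs.generate_cohort(cs.default_config(300, seed=6))
        assert not a.data.equals(c.data)

    def test_marginal_test_means_match_mixed_trajectories(self):
        cfg = cs.default_config(20000, seed=17)
        table = cs.generate_cohort(cfg)
        ages = np.linspace(12, 69, 4000)
        a, b = [(v - _AGE_TRUNCNORM_LOC) / _AGE_TRUNCNORM_SCALE
                for v in (12, 69)]
        w = stats.truncnorm.pdf(ages, a, b, loc=_AGE_TRUNCNORM_LOC,
                                scale=_AGE_TRUNCNORM_SCALE)
        w /= w.sum()
        Ar = cfg.weights.values
        for sex in cs.SEX_LEVELS:
            sub = table.data[table.data.sex == sex]
            dom = np.column_stack([
                np.sum(w * cfg.trajectories[d][sex].value(ages))
                for d in cs.DOMAINS
            ]).ravel()
            expected = Ar @ dom
            observed = sub[list(cs.TEST_COLUMNS)].mean().to_numpy()
            sem = sub[list(cs.TEST_COLUMNS)].std().to_numpy() / np.sqrt(len(sub))
            assert np.all(np.abs(observed - expected) < 3 * sem + 1e-3)

    def test_flat_trajectories_show_no_age_association(self):
        flat = {d: {s: cs.TrajectorySpec(0.0, (), (0.0,))
                    for s in cs.SEX_LEVELS} for d in cs.DOMAINS}
        covered = 0
        for rep in range(20):
            cfg = cs.default_config(5000, seed=200 + rep)
            cfg.trajectories = flat
            t = cs.generate_cohort(cfg)
            x = t.data.age.to_numpy()
            y = t.data[cs.TEST_COLUMNS[0]].to_numpy()
            res = stats.linregress(x, y)
            half = 1.96 * res.stderr
            covered += abs(res.slope) <= half
        assert covered >= 18

    def test_null_covariates_are_exchangeable(self):
        """All sex effects zero: rejections at alpha=.05 occur ~5% of the time."""
        covs = tuple(
            cs.CovariateSpec(c.name, c.var_type, 0.0, c.levels,
                             c.probabilities, c.mean, c.sd)
            for c in cs.default_covariates()
        )
        rejections = total = 0
        for rep in range(60):
            cfg = cs.default_config(1000, seed=3000 + rep)
            cfg.covariates = covs
            t = cs.generate_cohort(cfg)
            for row in cs.compare_demographics(t):
                rejections += row.p_raw < 0.05
                total += 1
        assert 0.02 <= rejections / total <= 0.08

    def test_downstream_fit_recovers_breakpoint(self):
        """WM breakpoint at 20 survives mixing, scoring and refitting."""
        hits = 0
        for rep in range(20):
            cfg = cs.default_config(13444, seed=400 + rep)
            cfg.trajectories["wm"] = {
                s: cs.TrajectorySpec(-0.2, (20.0,), (0.04, -0.02))
                for s in cs.SEX_LEVELS
            }
            t = cs.generate_cohort(cfg)
            Y = cs.compute_domain_scores(cs.zscore_tests(t), cfg.weights)
            mask = (t.data.sex == "female").to_numpy()
            fit = cs.fit_segmented(t.data.age.to_numpy()[mask],
                                   Y["wm"].to_numpy()[mask], 1)
            hits += abs(fit.psi[0] - 20.0) <= 1.5
        assert hits >= 18


@pytest.fixture(scope="module")
def big():
    return cs.generate_cohort(cs.default_config(20000, seed=77))


class TestCovariateEffects:
    def test_continuous_effect_near_target(self, big):
        w = big.data[big.data.sex == "female"]
        m = big.data[big.data.sex == "male"]
        _, _, _, d = cs.welch_t(w.sleep_hours, m.sleep_hours)
        assert d == pytest.approx(0.10, abs=0.03)
        _, _, _, d = cs.welch_t(w.caffeine_units, m.caffeine_units)
        assert d == pytest.approx(-0.19, abs=0.03)

    def test_ordinal_effect_near_target(self, big):
        w = big.data[big.data.sex == "female"]
        m = big.data[big.data.sex == "male"]
        _, _, _, r = cs.wilcoxon_rank_sum(w.anxiety, m.anxiety)
        assert r == pytest.approx(0.15, abs=0.03)

    def test_categorical_effect_near_target(self, big):
        ct = pd.crosstab(big.data.sex, big.data.tech_savvy).to_numpy()
        _, _, _, v = cs.chi_square_test(ct)
        assert v == pytest.approx(0.24, abs=0.03)


class TestOutliersAndMissing:
    def test_rate_zero_is_identity(self, small_cohort):
        out, altered = cs.inject_outliers(small_cohort, 0.0, 7.0, seed=1)
        assert altered == [] and out.data.equals(small_cohort.data)

    def test_magnitude_must_exceed_screen(self, small_cohort):
        with pytest.raises(ValueError, match="exceed 4"):
            cs.inject_outliers(small_cohort, 0.01, 3.0, seed=1)

    def test_altered_count_and_determinism(self, small_cohort):
        out1, alt1 = cs.inject_outliers(small_cohort, 0.01, 7.0, seed=9)
        out2, alt2 = cs.inject_outliers(small_cohort, 0.01, 7.0, seed=9)
        assert alt1 == alt2 and out1.data.equals(out2.data)
        assert len(alt1) == round(0.01 * small_cohort.n * 12)

    def test_injected_outliers_removed_by_two_pass_screen(self, small_cohort):
        out, altered = cs.inject_outliers(small_cohort, 0.01, 7.0, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered, _ = filter_outliers_two_pass(out)
        dirty = {pid for pid, _ in altered}
        survivors = set(filtered.data.participant_id)
        assert dirty.isdisjoint(survivors)

    def test_missing_rate_reflected_in_completeness_filter(self):
        cfg = cs.default_config(5000, seed=55, missing_rate=0.137)
        t = cs.generate_cohort(cfg)
        _, report = cs.filter_complete(t)
        assert report.n_removed / report.n_before == pytest.approx(
            0.137, abs=0.01
        )


def test_yaml_config_roundtrip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_per_sex: 40\nseed: 3\nnoise_sd: 0.5\nmissing_rate: 0.1\n")
    cfg = cs.load_config(p)
    assert cfg.n_per_sex == {"female": 40, "male": 40}
    assert cfg.seed == 3 and cfg.noise_sd == 0.5 and cfg.missing_rate == 0.1
    t = cs.generate_cohort(cfg)
    assert t.n == 80
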