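"""Interaction screen, per-group/partial/repeated-measures correlation and
the age-(in)dependent routing scheme."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myonet.simulate import SimulationConfig, _make_design, generate_dataset
from myonet.trait import (
    baseline_mvc,
    classify_module_trait,
    group_correlation,
    interaction_screen,
    partial_correlation,
    repeated_measures_correlation,
)


def interaction_f_oracle(x, y, age) -> float:
    """Two-model F-test: with vs. without the interaction term (1 df)."""
    a = (age == np.unique(age)[1]).astype(float)
    X0 = np.column_stack([np.ones_like(x), x, a])
    X1 = np.column_stack([X0, x * a])
    rss = []
    for X in (X0, X1):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(r @ r)
    df2 = len(y) - X1.shape[1]
    f = (rss[0] - rss[1]) / (rss[1] / df2)
    return float(stats.f.sf(f, 1, df2))


class TestInteractionScreen:
    def test_equal_slopes_no_noise_gives_p_near_one(self):
        x = np.linspace(-1, 1, 16)
        age = np.array(["young"] * 8 + ["older"] * 8)
        y = 2.0 * x + 3.0 * (age == "older")
        assert interaction_screen(x, y, age) > 0.99

    def test_crossover_slopes_detected(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            x = g.normal(size=16)
            age = np.array(["young"] * 8 + ["older"] * 8)
            slope = np.where(age == "young", 1.0, -1.0)
            y = slope * x + g.normal(0, 0.1, 16)
            hits += interaction_screen(x, y, age) < 0.05
        assert hits >= 9

    def test_equals_f_test_oracle(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = g.normal(size=14)
            age = np.array(["young", "older"] * 7)
            y = g.normal(size=14)
            assert interaction_screen(x, y, age) == pytest.approx(
                interaction_f_oracle(x, y, age), abs=1e-8
            )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            interaction_screen(np.arange(8.0), np.arange(8.0), np.array(["young"] * 8))


class TestGroupCorrelation:
    def test_perfect_association(self):
        x = np.arange(12.0)
        age = np.array(["young"] * 6 + ["older"] * 6)
        out = group_correlation(x, x, age)
        for assoc in out.values():
            assert assoc.r == pytest.approx(1.0)
            assert assoc.p < 1e-6 and assoc.significant

    def test_hand_computed_pearson_on_printed_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0, 2.0, 1.0, 4.0, 3.0, 5.0])
        age = np.array(["young"] * 5 + ["older"] * 5)
        out = group_correlation(x, y, age)
        # long-hand: cov = 1.6, sd_x = sd_y = sqrt(2), r = 0.8
        assert out["young"].r == pytest.approx(0.8, abs=1e-12)

    def test_null_false_positive_rate_bounded(self):
        g = np.random.default_rng(123)
        age = np.array(["young"] * 8 + ["older"] * 8)
        flags = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = g.normal(size=16), g.normal(size=16)
            out = group_correlation(x, y, age)
            flags += any(a.significant for a in out.values())
        assert flags / n_rep <= 0.10


class TestPartialCorrelation:
    def test_orthogonal_covariate_reduces_to_pearson(self):
        g = np.random.default_rng(0)
        n = 40
        z = np.tile([1.0, -1.0], n // 2)
        x = g.normal(size=n)
        y = g.normal(size=n)
        x -= z * (x @ z) / (z @ z)  # orthogonalise against covariate and intercept
        y -= z * (y @ z) / (z @ z)
        x -= x.mean()
        y -= y.mean()
        plain = np.corrcoef(x, y)[0, 1]
        assert partial_correlation(x, y, z).r == pytest.approx(plain, abs=1e-10)

    def test_trait_identical_to_covariate_degenerate(self):
        z = np.arange(10.0)
        x = np.random.default_rng(1).normal(size=10)
        assoc = partial_correlation(x, z, z)
        assert assoc.r == 0.0 and assoc.p == 1.0

    def test_matches_recursive_formula(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            x, y, z = g.normal(size=(3, 15))
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_correlation(x, y, z).r == pytest.approx(oracle, abs=1e-10)


def rmcorr_dummy_oracle(x, y, subject):
    """Explicit dummy-coded ANCOVA oracle for the repeated-measures r."""
    subs = pd.unique(subject)
    D = np.column_stack([(subject == s).astype(float) for s in subs])
    X1 = np.column_stack([D, x])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    b0, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss0 = float(((y - D @ b0) ** 2).sum())
    ss_x = rss0 - rss1
    slope = b1[-1]
    r = np.sign(slope) * np.sqrt(ss_x / (ss_x + rss1))
    df = len(y) - len(subs) - 1
    t = r * np.sqrt(df / (1 - r**2))
    return float(r), float(2 * stats.t.sf(abs(t), df)), float(slope)


class TestRepeatedMeasuresCorrelation:
    def test_subject_shifted_perfect_lines(self):
        x = np.tile(np.arange(4.0), 3)
        subject = np.repeat(["a", "b", "c"], 4)
        offsets = np.repeat([0.0, 5.0, -2.0], 4)
        y = x + offsets
        assoc = repeated_measures_correlation(x, y, subject)
        assert assoc.r == pytest.approx(1.0)

    def test_equals_dummy_coded_regression_oracle(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            subject = np.repeat([f"p{i}" for i in range(6)], 4)
            x = g.normal(size=24)
            y = g.normal(size=24)
            assoc = repeated_measures_correlation(x, y, subject)
            r_o, p_o, _ = rmcorr_dummy_oracle(x, y, subject)
            assert assoc.r == pytest.approx(r_o, abs=1e-10)
            assert assoc.p == pytest.approx(p_o, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        g = np.random.default_rng(99)
        df = pd.DataFrame(
            {"x": g.normal(size=20), "y": g.normal(size=20),
             "subject": np.repeat(list("abcde"), 4)}
        )
        res = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assoc = repeated_measures_correlation(df["x"], df["y"], df["subject"])
        assert assoc.r == pytest.approx(float(res["r"].iloc[0]), abs=1e-8)
        assert assoc.p == pytest.approx(float(res["pval"].iloc[0]), abs=1e-8)

    def test_null_rate_near_alpha(self):
        g = np.random.default_rng(77)
        subject = np.repeat([f"p{i}" for i in range(8)], 3)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = g.normal(size=24), g.normal(size=24)
            rejections += repeated_measures_correlation(x, y, subject).p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_small_subjects_rejected_and_dropped(self):
        with pytest.raises(ValueError):
            repeated_measures_correlation([1, 2, 3], [1, 2, 3], ["a", "a", "b"])


@pytest.fixture(scope="module")
def planted():
    # module 5 has age-crossover trait coupling; module 4 a common slope
    return generate_dataset(SimulationConfig(trait_noise_sd=1.0), seed=5)


class TestClassifyModuleTrait:
    def test_two_leg_averaging(self):
        traits = pd.DataFrame(
            {"baseline_mvc_left": [100.0], "baseline_mvc_right": [120.0]}, index=["p1"]
        )
        assert baseline_mvc(traits).iloc[0] == pytest.approx(110.0)

    def test_age_dependent_and_independent_routing(self, planted):
        ds = planted
        design = ds.design
        bl = design.index[design["condition"] == "BL"]
        eig = pd.DataFrame(
            {4: ds.truth.factors.loc[4], 5: ds.truth.factors.loc[5]}
        ).T
        res = classify_module_trait(eig, ds.traits, design)
        by_mod = {}
        for a in res:
            by_mod.setdefault(a.module, []).append(a)
        schemes_m5 = {a.scheme for a in by_mod[5]}
        assert "per_group" in schemes_m5  # crossover -> age-dependent route
        groups = {a.group: a.r for a in by_mod[5] if a.scheme == "per_group"}
        assert np.sign(groups["young"]) != np.sign(groups["older"])
        schemes_m4 = {a.scheme for a in by_mod[4]}
        assert "partial" in schemes_m4  # common slope -> age-independent route
        partial = [a for a in by_mod[4] if a.scheme == "partial"][0]
        assert partial.significant

    def test_decisions_deterministic(self, planted):
        ds = planted
        eig = ds.truth.factors.loc[[4, 5]]
        r1 = classify_module_trait(eig, ds.traits, ds.design)
        r2 = classify_module_trait(eig, ds.traits, ds.design)
        assert [(a.module, a.scheme, a.r, a.p) for a in r1] == [
            (a.module, a.scheme, a.r, a.p) for a in r2
        ]

    def test_global_null_rarely_flags(self):
        cfg = SimulationConfig(module_sizes=(20,) * 50, n_background=0,
                               effects={}, trait_couplings={})
        flagged = []
        for seed in range(10):
            ds = generate_dataset(cfg, seed=200 + seed)
            res = classify_module_trait(ds.truth.factors, ds.traits, ds.design)
            mods = {a.module for a in res if a.scheme != "interaction" and a.significant}
            flagged.append(len(mods))
        # lenient bound: both |r| > 0.5 and p < 0.05 must hold jointly
        assert np.mean(flagged) <= 50 * 0.05 * 2

    def test_rmcorr_used_for_pooled_modes_and_pearson_for_single(self):
        ds = generate_dataset(SimulationConfig(), seed=3)
        eig = ds.truth.factors.loc[[2, 3]]
        res = classify_module_trait(
            eig, ds.traits, ds.design,
            responsive={2: {"ECC"}, 3: {"ECC", "CON"}},
        )
        schemes = {(a.module, a.scheme) for a in res if a.measure and a.measure.startswith("post")}
        assert (2, "pearson") in schemes
        assert (3, "rmcorr") in schemes
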