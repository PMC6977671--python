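"""Subject-blocked GLS, consensus correlation and moderated contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cholesky
from scipy.stats import t as t_dist

from myonet.diffexpr import (
    default_contrasts,
    differential_analysis,
    estimate_within_subject_correlation,
    estimate_variance_prior,
    fit_module_models,
    group_factor,
    moderated_contrasts,
)
from myonet.simulate import SimulationConfig, _make_design


def simulate_eigengenes(n_modules, design, rng, icc=0.3, shift=None, shift_cond="ECC"):
    """Null (or single-shift) eigengene matrix with subject random intercepts."""
    subs = pd.unique(design["subject"])
    sd_b, sd_e = np.sqrt(icc), np.sqrt(1 - icc)
    rows = {}
    for m in range(n_modules):
        b = dict(zip(subs, rng.normal(0, sd_b, len(subs))))
        y = np.array([b[s] for s in design["subject"]]) + rng.normal(0, sd_e, len(design))
        if shift is not None and m == 0:
            y = y + shift * sd_e * (design["condition"] == shift_cond).to_numpy()
        rows[m + 1] = y
    return pd.DataFrame(rows, index=design.index).T


@pytest.fixture(scope="module")
def design():
    return _make_design(SimulationConfig())


class TestConsensusCorrelation:
    def test_null_subject_variance_gives_near_zero(self, design):
        d12 = _make_design(SimulationConfig(n_subjects_per_group=6))
        for seed in range(3):
            eig = simulate_eigengenes(30, d12, np.random.default_rng(seed), icc=1e-12)
            block = estimate_within_subject_correlation(eig, d12)
            assert abs(block.consensus_rho) < 0.15

    def test_icc_half_recovered(self, design):
        eig = simulate_eigengenes(50, design, np.random.default_rng(10), icc=0.5)
        block = estimate_within_subject_correlation(eig, design)
        assert block.consensus_rho == pytest.approx(0.5, abs=0.1)

    def test_single_sample_per_subject_warns_zero(self):
        design = pd.DataFrame(
            {"subject": [f"p{i}" for i in range(8)],
             "age_group": ["young"] * 4 + ["older"] * 4,
             "condition": ["BL", "ECC"] * 4},
            index=[f"s{i}" for i in range(8)],
        )
        eig = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 8)),
                           columns=design.index)
        block = estimate_within_subject_correlation(eig, design)
        assert block.consensus_rho == 0.0


class TestModuleFits:
    def test_rho_zero_equals_ols(self, design):
        eig = simulate_eigengenes(6, design, np.random.default_rng(1))
        fits = fit_module_models(eig, design, rho=0.0)
        X = pd.get_dummies(group_factor(design)).to_numpy(float)
        levels = list(pd.get_dummies(group_factor(design)).columns)
        for mod in eig.index:
            beta, *_ = np.linalg.lstsq(X, eig.loc[mod].to_numpy(), rcond=None)
            fitted = fits.coefficients.loc[mod].reindex(levels).to_numpy()
            np.testing.assert_allclose(fitted, beta, atol=1e-10)

    def test_noiseless_group_means_exact(self):
        design = _make_design(SimulationConfig(n_subjects_per_group=3))
        means = {"BL": 0.0, "ECC": 1.0, "CON": 1.0}
        y = design["condition"].map(means).astype(float)
        eig = pd.DataFrame([y.to_numpy()], index=[1], columns=design.index)
        fits = fit_module_models(eig, design, rho=0.0)
        for level, value in fits.coefficients.loc[1].items():
            assert value == pytest.approx(means[level.split(":")[1]], abs=1e-12)

    def test_matches_explicit_whitening_oracle(self, design):
        rho = 0.5
        eig = simulate_eigengenes(4, design, np.random.default_rng(2), icc=0.4)
        fits = fit_module_models(eig, design, rho=rho)
        subj = design["subject"].to_numpy()
        B = (subj[:, None] == subj[None, :]).astype(float)
        sigma = (1 - rho) * np.eye(len(design)) + rho * B
        L = cholesky(sigma, lower=True)
        X = pd.get_dummies(group_factor(design)).to_numpy(float)
        levels = list(pd.get_dummies(group_factor(design)).columns)
        Xw = np.linalg.solve(L, X)
        for mod in eig.index:
            yw = np.linalg.solve(L, eig.loc[mod].to_numpy())
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            np.testing.assert_allclose(
                fits.coefficients.loc[mod].reindex(levels).to_numpy(), beta, atol=1e-8
            )

    def test_rank_deficient_design_names_alias(self):
        design = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"],
             "age_group": ["young"] * 4,
             "condition": ["BL", "BL", "BL", "BL"]},
            index=[f"s{i}" for i in range(4)],
        )
        eig = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=[1], columns=design.index)
        fits = fit_module_models(eig, design)  # single group: full rank, fine
        assert list(fits.coefficients.columns) == ["young:BL"]


class TestModeration:
    def test_full_shrinkage_limit_uses_prior_variance(self, design):
        # identical residual variances: d0 = inf, moderated t uses s0
        from scipy.special import digamma
        eig = simulate_eigengenes(6, design, np.random.default_rng(3))
        fits = fit_module_models(eig, design, rho=0.0)
        fits.sigma2[:] = 0.25
        res = moderated_contrasts(fits)
        contrasts = default_contrasts(fits.group_levels)
        C = contrasts.to_numpy()
        # closed-form prior variance in the d0 -> inf limit:
        # s0^2 = exp(mean log s^2 - digamma(d/2) + log(d/2))
        d = fits.df_residual
        s0 = np.sqrt(0.25 * np.exp(np.log(d / 2) - digamma(d / 2)))
        se = s0 * np.sqrt(np.einsum("ij,jk,ki->i", C.T, fits.cov_unscaled, C))
        for mi, mod in enumerate(fits.coefficients.index):
            est = fits.coefficients.loc[mod].to_numpy() @ C
            expected_t = est / se
            got = res[res["module"] == mod].set_index("contrast")
            for ci, cname in enumerate(contrasts.columns):
                assert got.loc[cname, "moderated_t"] == pytest.approx(expected_t[ci], abs=1e-10)
        assert np.isinf(res["df_total"]).all()

    def test_moment_prior_roundtrip(self):
        g = np.random.default_rng(4)
        d0_true, s0_true, d = 8.0, 0.5, 10.0
        s2 = s0_true * d0_true / g.chisquare(d0_true, 5000) * g.chisquare(d, 5000) / d
        d0, s0 = estimate_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_moderated_t_monotone_in_estimate_at_fixed_variance(self, design):
        eig = simulate_eigengenes(8, design, np.random.default_rng(5))
        fits = fit_module_models(eig, design, rho=0.0)
        fits.sigma2[:] = 0.3  # hold variances fixed across modules
        res = moderated_contrasts(fits)
        one = res[res["contrast"] == res["contrast"].iloc[0]].copy()
        order_est = one.sort_values("estimate")["module"].tolist()
        order_t = one.sort_values("moderated_t")["module"].tolist()
        assert order_est == order_t


class TestBHFamily:
    def test_adjusted_p_bounds_and_permutation_equivariance(self, design):
        eig = simulate_eigengenes(20, design, np.random.default_rng(6))
        res, _ = differential_analysis(eig, design)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert (res["p_adj"] <= 1.0).all()
        from statsmodels.stats.multitest import multipletests
        p = res["p"].to_numpy()
        perm = np.random.default_rng(7).permutation(len(p))
        adj_perm = multipletests(p[perm], method="fdr_bh")[1]
        np.testing.assert_allclose(adj_perm, res["p_adj"].to_numpy()[perm], atol=1e-12)

    def test_contrast_family_is_nine_for_full_design(self, design):
        contrasts = default_contrasts(
            [f"{a}:{c}" for a in ("young", "older") for c in ("BL", "ECC", "CON")]
        )
        assert contrasts.shape[1] == 9
        assert (contrasts.sum(axis=0) == 0).all()


class TestCalibration:
    def test_null_type_one_error_and_power(self, design):
        fracs, n_sig = [], []
        for seed in range(4):
            eig = simulate_eigengenes(200, design, np.random.default_rng(100 + seed))
            res, _ = differential_analysis(eig, design)
            fracs.append(float((res["p"] < 0.05).mean()))
            n_sig.append(int(res["significant"].sum()))
        assert all(0.02 <= f <= 0.08 for f in fracs)
        assert sum(s == 0 for s in n_sig) >= 3

    def test_classical_limit_on_homoscedastic_data(self, design):
        # rho = 0 and strong shrinkage: moderated p close to pooled-variance t
        eig = simulate_eigengenes(60, design, np.random.default_rng(8), icc=1e-12)
        fits = fit_module_models(eig, design, rho=0.0)
        res = moderated_contrasts(fits)
        contrasts = default_contrasts(fits.group_levels)
        C = contrasts.to_numpy()
        se_f = np.sqrt(np.einsum("ij,jk,ki->i", C.T, fits.cov_unscaled, C))
        pooled = float(fits.sigma2.mean())
        for mod in list(fits.coefficients.index)[:5]:
            est = fits.coefficients.loc[mod].to_numpy() @ C
            t_classic = est / (np.sqrt(pooled) * se_f)
            got = res[res["module"] == mod]["moderated_t"].to_numpy()
            np.testing.assert_allclose(got, t_classic, rtol=0.25, atol=0.05)
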