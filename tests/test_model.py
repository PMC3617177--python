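"""Stacked mixed-model estimation, FDR control and network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mlvarnet as m

from conftest import small_config


class TestUnivariateFit:
    def test_single_person_no_random_effects_equals_ols(self):
        """With random effects disabled the mixed machinery must reproduce
        closed-form least squares exactly (normal-equations oracle)."""
        cfg = small_config(n_persons=1, n_days=6, n_beeps=10, omega=[np.zeros((4, 4))] * 3,
                           missing_rate=0.0)
        design = m.build_lagged_design(m.simulate_esm(cfg))
        fit = m.fit_univariate(design, "worry", m.RandomSpec("none"))
        X = np.column_stack(
            [np.ones(len(design.data))]
            + [design.data[c].to_numpy() for c in design.predictor_columns]
        )
        y = design.data["y_worry"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.gamma, beta, atol=1e-8)

    def test_random_effects_demand_multiple_persons(self):
        cfg = small_config(n_persons=1, missing_rate=0.0)
        design = m.build_lagged_design(m.simulate_esm(cfg))
        with pytest.raises(ValueError, match="single-person"):
            m.fit_univariate(design, "worry")

    def test_blups_average_to_zero(self, model3):
        for f in model3.fits:
            assert np.abs(f.blups.mean(axis=0)).max() < 0.02

    def test_omega_symmetric_psd_and_sigma2_positive(self, model3):
        for f in model3.fits:
            np.testing.assert_allclose(f.Omega, f.Omega.T, atol=1e-12)
            assert np.linalg.eigvalsh(f.Omega).min() > -1e-10
            assert f.sigma2 > 0
            assert f.converged

    def test_unknown_response_rejected(self, sim3):
        _data, design = sim3
        with pytest.raises(KeyError, match="unknown response"):
            m.fit_univariate(design, "joy")


class TestStacking:
    def test_assembly_is_reindexing_not_reestimation(self, sim3, model3):
        """Refitting one equation in isolation reproduces the stacked
        model's row bit-identically (pseudo-likelihood contract)."""
        _data, design = sim3
        j = 1
        solo = m.fit_univariate(design, model3.variables[j])
        np.testing.assert_array_equal(model3.Phi[j], solo.gamma[1:])
        np.testing.assert_array_equal(model3.pvalues[j], solo.pvalues[1:])
        np.testing.assert_array_equal(model3.intercepts[j], solo.gamma[0])

    def test_recovers_generating_matrix_direction(self, model3):
        gamma = small_config().gamma
        r = np.corrcoef(model3.Phi.ravel(), gamma.ravel())[0, 1]
        assert r > 0.7

    def test_permutation_equivariance(self, sim3):
        """Relabeling the variables permutes Phi and the Wald statistics
        without changing them."""
        data, design = sim3
        perm = [2, 0, 1]
        pdata = m.ESMDataset(
            data.data.copy(), [data.variables[i] for i in perm], data.scale
        )
        pdesign = m.build_lagged_design(pdata)
        a = m.fit_mlvar(design, m.RandomSpec("intercept"))
        b = m.fit_mlvar(pdesign, m.RandomSpec("intercept"))
        P = np.eye(3)[perm]
        np.testing.assert_allclose(P @ a.Phi @ P.T, b.Phi, atol=1e-6)
        np.testing.assert_allclose(P @ a.pvalues @ P.T, b.pvalues, atol=1e-6)

    def test_partial_model_refuses_downstream_networks(self, model3):
        import copy

        broken = copy.copy(model3)
        broken.errors = {"worry": "synthetic failure"}
        with pytest.raises(RuntimeError, match="worry"):
            m.population_network(broken)


class TestResidualCorrelations:
    def test_diagonal_is_exactly_one(self, model3):
        assert model3.resid_corr is not None
        np.testing.assert_array_equal(np.diag(model3.resid_corr), 1.0)

    def test_recovers_innovation_correlation(self):
        sigma = 0.8 * np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
        cfg = small_config(sigma=sigma, n_persons=60, seed=5)
        model = m.fit_mlvar(m.build_lagged_design(m.simulate_esm(cfg)))
        assert abs(model.resid_corr[0, 1] - 0.6) < 0.1
        assert abs(model.resid_corr[0, 2]) < 0.1

    def test_mismatched_row_sets_are_an_error(self, model3):
        import copy

        broken = copy.copy(model3)
        broken.fits = list(model3.fits)
        broken.fits[0] = copy.copy(model3.fits[0])
        broken.fits[0].n_obs -= 1
        with pytest.raises(ValueError, match="row counts"):
            m.residual_correlations(broken)


class TestBhFdr:
    def test_hand_worked_step_up(self):
        # ordered p: .001 <= .0125, .02 <= .025, .03 <= .0375, .5 > .05
        mask = m.bh_fdr([0.001, 0.02, 0.03, 0.5], q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_ones_reject_nothing(self):
        assert not m.bh_fdr(np.ones(10)).any()

    def test_nan_pvalues_excluded_never_rejected(self):
        mask = m.bh_fdr([0.001, np.nan, 0.002], q=0.05)
        np.testing.assert_array_equal(mask, [True, False, True])

    def test_shape_preserved(self):
        assert m.bh_fdr(np.full((3, 3), 0.5)).shape == (3, 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        st.floats(0.001, 0.2),
        st.floats(0.001, 0.2),
    )
    def test_monotone_in_q(self, pvals, q1, q2):
        lo, hi = sorted([q1, q2])
        m_lo, m_hi = m.bh_fdr(pvals, lo), m.bh_fdr(pvals, hi)
        assert not (m_lo & ~m_hi).any()


class TestNetworks:
    def test_population_mask_empty_when_nothing_significant(self, model3):
        import copy

        flat = copy.copy(model3)
        flat.pvalues = np.ones_like(model3.pvalues)
        g = m.population_network(flat)
        assert not g.mask.any()
        np.testing.assert_array_equal(g.weights, model3.Phi)

    def test_fdr_mask_subset_of_raw_mask(self, model3):
        raw = m.population_network(model3, use_fdr=False)
        fdr = m.population_network(model3, use_fdr=True)
        assert not (fdr.mask & ~raw.mask).any()

    def test_sd_network_infinite_cutoff_masks_nothing(self, model3):
        g = m.random_sd_network(model3, cutoff=np.inf)
        assert not g.mask.any()
        np.testing.assert_array_equal(g.weights, model3.Sd)

    def test_individual_networks_average_to_population(self, model3):
        stack = np.array(
            [m.individual_network(model3, p).weights for p in model3.persons]
        )
        np.testing.assert_allclose(stack.mean(axis=0), model3.Phi, atol=0.02)

    def test_unknown_person_lists_known_ids(self, model3):
        with pytest.raises(KeyError, match="known ids"):
            m.individual_network(model3, "nobody")


def test_mixed_fit_matches_lme4_oracle(tmp_path):
    """Independent cross-check: the same random-intercept equation fitted
    by R's lme4 (REML) reproduces fixed effects, variance components and
    the summed-parameter BIC convention."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    data = m.simulate_esm(small_config(n_persons=30, seed=3))
    design = m.build_lagged_design(data)
    fit = m.fit_univariate(design, "worry", m.RandomSpec("intercept"))
    csv = tmp_path / "design.csv"
    design.data[["person", "y_worry", "lag_calm", "lag_worry", "lag_sad"]].to_csv(
        csv, index=False
    )
    script = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{csv}")
    fit <- lmer(y_worry ~ lag_calm + lag_worry + lag_sad + (1|person),
                data = d, REML = TRUE)
    cat(fixef(fit), "\\n")
    cat(as.data.frame(VarCorr(fit))$sdcor, "\\n")
    cat(BIC(fit), "\\n")
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    lines = out.stdout.strip().splitlines()
    fe = np.array(lines[0].split(), float)
    sd_int, sd_resid = np.array(lines[1].split(), float)
    bic = float(lines[2])
    np.testing.assert_allclose(fit.gamma, fe, atol=1e-5)
    assert np.sqrt(fit.Omega[0, 0]) == pytest.approx(sd_int, abs=1e-4)
    assert np.sqrt(fit.sigma2) == pytest.approx(sd_resid, abs=1e-4)
    assert fit.bic == pytest.approx(bic, abs=0.01)


def test_model_json_roundtrips_phi(tmp_path, model3):
    import json

    path = model3.to_json(tmp_path / "model.json", metadata={"seed": 1})
    payload = json.loads(path.read_text())
    np.testing.assert_allclose(np.asarray(payload["Phi"]), model3.Phi)
    assert payload["seed"] == 1
    assert "worry" in payload["equations"]
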