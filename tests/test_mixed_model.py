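"""Model assembly, Gibbs sampler behaviour, and the closed-form BLUP oracle."""

import numpy as np
import pandas as pd
import pytest

from hybridpred import (
    ModelSpec,
    SamplerSettings,
    blup_oracle,
    enumerate_model_specs,
    fit_gibbs,
)
from hybridpred.mixed_model import ModelError, ModelTerms, RandomTerm, SamplerError

from conftest import random_psd


def single_kernel_terms(rng, n=25, n_masked=0, kernel=None, trait="GY"):
    """Intercept + one record-level kernel; y drawn from the model."""
    K = kernel if kernel is not None else random_psd(rng, n)
    g = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
    y = 2.0 + g + rng.standard_normal(n)
    records = pd.DataFrame(
        {"hybrid": [f"h{i}" for i in range(n)], "environment": "E1", "value": y}
    )
    terms = ModelTerms(
        records=records,
        X=np.ones((n, 1)),
        x_labels=["intercept"],
        random=[RandomTerm("g", K)],
        spec=ModelSpec("B", "none", trait),
    )
    mask = np.zeros(n, dtype=bool)
    mask[:n_masked] = True
    return terms, mask


class TestAssembly:
    def test_twelve_model_enumeration(self):
        specs = enumerate_model_specs("GY")
        assert len(specs) == 12
        assert len({s.name for s in specs}) == 12

    @pytest.mark.parametrize(
        ("family", "mode", "expected_terms", "expected_x"),
        [
            ("D", "none", {"env", "h", "u_H"}, 1),
            ("B", "AC", {"env", "g_M", "g_F", "h", "u_M", "u_F", "u_H"}, 7),
            ("A", "C", {"env", "g_M", "g_F", "h", "u_M", "u_F", "u_H"}, 3),
            ("C", "none", {"env", "h", "u_H"}, 1),
        ],
    )
    def test_term_sets_per_family(self, small_dataset, family, mode,
                                  expected_terms, expected_x):
        terms = small_dataset.assemble(ModelSpec(family, mode, "GY"))
        assert {t.name for t in terms.random} == expected_terms
        assert terms.X.shape[1] == expected_x

    def test_non_genomic_h_kernel_is_identity_expansion(self, small_dataset):
        terms = small_dataset.assemble(ModelSpec("A", "none", "GY"))
        h = next(t for t in terms.random if t.name == "h")
        hybrids = terms.records["hybrid"].to_numpy()
        expected = (hybrids[:, None] == hybrids[None, :]).astype(float)
        np.testing.assert_allclose(h.kernel, expected)

    def test_genomic_required_for_family_b(self, small_dataset):
        from hybridpred import assemble_model

        records = small_dataset.records_for_trait("GY")
        with pytest.raises(ModelError, match="genomic"):
            assemble_model(ModelSpec("B"), records, small_dataset.pedigree)

    def test_covariates_required_when_mode_set(self, small_dataset):
        from hybridpred import assemble_model

        records = small_dataset.records_for_trait("GY")
        with pytest.raises(ModelError, match="covariates"):
            assemble_model(
                ModelSpec("A", "C"), records, small_dataset.pedigree
            )

    def test_literal_uh_uses_genomic_sca_kernel(self, small_dataset):
        plain = small_dataset.assemble(ModelSpec("C", "none", "GY"))
        literal = small_dataset.assemble(
            ModelSpec("C", "none", "GY"), literal_uh=True
        )
        uh_plain = next(t for t in plain.random if t.name == "u_H")
        uh_lit = next(t for t in literal.random if t.name == "u_H")
        assert not np.allclose(uh_plain.kernel, uh_lit.kernel)


class TestGibbs:
    def test_seeded_determinism(self, small_dataset, quick_sampler):
        terms = small_dataset.assemble(ModelSpec("B", "C", "GY"))
        mask = np.zeros(terms.n_records, dtype=bool)
        mask[::5] = True
        a = fit_gibbs(terms, mask=mask, settings=quick_sampler, seed=3)
        b = fit_gibbs(terms, mask=mask, settings=quick_sampler, seed=3)
        np.testing.assert_array_equal(a.eta_mean, b.eta_mean)
        assert a.variance_mean == b.variance_mean
        np.testing.assert_array_equal(a.predicted(), b.predicted())

    def test_constant_response_predicts_constant(self, rng):
        terms, mask = single_kernel_terms(rng, n=30, n_masked=6)
        terms.records["value"] = 5.0
        fit = fit_gibbs(
            terms, mask=mask,
            settings=SamplerSettings(n_iter=2000, burn_in=500, thin=2), seed=0,
        )
        np.testing.assert_allclose(fit.predicted(), 5.0, atol=0.15)

    def test_zero_covariate_column_leaves_predictions_unchanged(self, rng):
        terms, mask = single_kernel_terms(rng, n=40, n_masked=8)
        padded = ModelTerms(
            records=terms.records,
            X=np.hstack([terms.X, np.zeros((40, 1))]),
            x_labels=terms.x_labels + ["zero"],
            random=terms.random,
            spec=terms.spec,
        )
        st = SamplerSettings(n_iter=4000, burn_in=1000, thin=2)
        base = fit_gibbs(terms, mask=mask, settings=st, seed=11)
        pad = fit_gibbs(padded, mask=mask, settings=st, seed=12)
        assert np.max(np.abs(base.predicted() - pad.predicted())) < 0.1 * np.std(
            terms.y
        )

    def test_all_masked_rejected(self, rng):
        terms, _ = single_kernel_terms(rng, n=10)
        with pytest.raises(SamplerError, match="masked"):
            fit_gibbs(terms, mask=np.ones(10, dtype=bool))

    def test_environment_without_training_records_named(self, small_dataset,
                                                        quick_sampler):
        terms = small_dataset.assemble(ModelSpec("A", "none", "GY"))
        mask = (terms.records["environment"] == "E2").to_numpy()
        with pytest.raises(ModelError, match="E2"):
            fit_gibbs(terms, mask=mask, settings=quick_sampler)

    def test_posterior_variances_positive(self, small_dataset, quick_sampler):
        terms = small_dataset.assemble(ModelSpec("D", "none", "GY"))
        fit = fit_gibbs(terms, settings=quick_sampler, seed=1)
        assert all(v > 0 for v in fit.variance_mean.values())
        assert fit.n_samples == 100

    def test_entity_effects_constant_within_entity(self, small_dataset,
                                                   quick_sampler):
        terms = small_dataset.assemble(ModelSpec("B", "none", "GY"))
        fit = fit_gibbs(terms, settings=quick_sampler, seed=5)
        h_rec = fit.effect_record_mean["h"]
        hybrids = terms.records["hybrid"]
        for hid, grp in pd.Series(h_rec).groupby(hybrids.values):
            assert grp.nunique() == 1 or grp.std() < 1e-12
        assert set(fit.entity_effects["g_M"].index) == set(
            small_dataset.pedigree.male_ids
        )


class TestBlupOracle:
    def test_zero_variances_reduce_to_gls(self, rng):
        terms, _ = single_kernel_terms(rng, n=15)
        res = blup_oracle(terms, {"g": 0.0}, residual_variance=1.0)
        # V proportional to I -> GLS is OLS: intercept-only fit is the mean
        np.testing.assert_allclose(res.yhat, terms.y.mean(), atol=1e-6)

    def test_single_record_intercept_only(self):
        records = pd.DataFrame(
            {"hybrid": ["h1"], "environment": ["E1"], "value": [3.7]}
        )
        terms = ModelTerms(records, np.ones((1, 1)), ["intercept"], [], ModelSpec("A"))
        res = blup_oracle(terms, {}, residual_variance=1.0)
        assert res.yhat[0] == pytest.approx(3.7)

    def test_matches_dense_mixed_model_equations(self, rng):
        n, n_test = 20, 5
        K = random_psd(rng, n) + 0.5 * np.eye(n)  # full rank for the MME route
        terms, mask = single_kernel_terms(rng, n=n, n_masked=n_test, kernel=K)
        s2g, s2e = 0.8, 1.3
        res = blup_oracle(terms, {"g": s2g}, residual_variance=s2e, mask=mask)

        # independent route: Henderson's mixed-model equations on the
        # training block, kernel-regression extension to the test block
        tr = ~mask
        Xt = terms.X[tr]
        Ktt = K[np.ix_(tr, tr)]
        yt = terms.y[tr]
        nt = tr.sum()
        A = np.block(
            [
                [Xt.T @ Xt / s2e, Xt.T / s2e],
                [Xt / s2e, np.eye(nt) / s2e + np.linalg.inv(s2g * Ktt)],
            ]
        )
        rhs = np.concatenate([Xt.T @ yt / s2e, yt / s2e])
        sol = np.linalg.solve(A, rhs)
        beta_mme, u_train = sol[:1], sol[1:]
        u_test = K[np.ix_(mask, tr)] @ np.linalg.solve(Ktt, u_train)
        yhat_test = terms.X[mask] @ beta_mme + u_test

        np.testing.assert_allclose(res.beta, beta_mme, atol=1e-6)
        np.testing.assert_allclose(res.yhat[mask], yhat_test, atol=1e-6)

    def test_permuting_records_permutes_predictions(self, rng):
        terms, mask = single_kernel_terms(rng, n=18, n_masked=4)
        res = blup_oracle(terms, {"g": 1.0}, residual_variance=1.0, mask=mask)
        perm = rng.permutation(18)
        K = terms.random[0].kernel
        terms_p = ModelTerms(
            records=terms.records.iloc[perm].reset_index(drop=True),
            X=terms.X[perm],
            x_labels=terms.x_labels,
            random=[RandomTerm("g", K[np.ix_(perm, perm)])],
            spec=terms.spec,
        )
        res_p = blup_oracle(
            terms_p, {"g": 1.0}, residual_variance=1.0, mask=mask[perm]
        )
        np.testing.assert_allclose(res_p.yhat, res.yhat[perm], atol=1e-8)

    def test_missing_variance_rejected(self, rng):
        terms, _ = single_kernel_terms(rng, n=10)
        with pytest.raises(ModelError, match="variance"):
            blup_oracle(terms, {}, residual_variance=1.0)
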