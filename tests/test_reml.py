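import numpy as np
import pandas as pd
import pytest

from cherryblup import (
    KernelGBLUP,
    KernelSet,
    SimulationScenario,
    simulate_founders,
    simulate_phenotypes,
)
from cherryblup.model import (
    DesignSet,
    assemble_design,
    extended_hat_diagonal,
    incidence_matrix,
    influence_diagnostics,
    reml_loglik,
    residual_only_reml_loglik,
    solve_mme,
    spectral_additive_reml,
    wald_test_fixed,
)

from _oracles import dense_reml_loglik, grid_search_single_kernel

TIGHT = dict(loglik_rtol=1e-8, param_rtol=1e-4, max_iter=200)


def _single_year_pheno(ids, y, year=2011):
    return pd.DataFrame({"individual": ids, "year": year, "trait": "t", "value": y})


@pytest.fixture(scope="module")
def founder_setup():
    founders = simulate_founders(60, 200, (0.2, 0.5), seed=31)
    return founders, KernelSet.from_genotypes(founders)


class TestDesignAssembly:
    def test_complete_two_by_two(self):
        df = pd.DataFrame({
            "individual": ["a", "b", "a", "b"],
            "year": [2011, 2011, 2012, 2012],
            "trait": "t",
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        design = assemble_design(df, ["a", "b"])
        Z1 = incidence_matrix(design, "a").toarray()
        assert Z1.shape == (4, 2)
        assert Z1.sum(axis=0).tolist() == [2.0, 2.0]
        assert design.X.shape == (4, 2)  # intercept + one year contrast

    def test_missing_record_leaves_empty_interaction_column(self):
        df = pd.DataFrame({
            "individual": ["a", "b", "a"],
            "year": [2011, 2011, 2012],
            "trait": "t",
            "value": [1.0, 2.0, 3.0],
        })
        design = assemble_design(df, ["a", "b"])
        Z4 = incidence_matrix(design, "aY").toarray()
        assert Z4.shape == (3, 4)
        # the (b, 2012) cell received no observation
        assert Z4[:, 3].sum() == 0.0

    def test_every_row_has_one_incidence_entry(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            missing_pattern=(0.4, 0.2, 0.1), seed=1,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        design = assemble_design(pheno, ks.ids)
        for term in ("a", "aY"):
            Z = incidence_matrix(design, term)
            assert (np.asarray(Z.sum(axis=1)).ravel() == 1.0).all()

    def test_unknown_individual_named(self):
        df = _single_year_pheno(["a", "zzz"], [1.0, 2.0])
        with pytest.raises(KeyError, match="zzz"):
            assemble_design(df, ["a", "b"])


class TestRemlLoglik:
    def test_matches_textbook_dense_formula(self, founder_setup):
        founders, ks = founder_setup
        rng = np.random.default_rng(7)
        ids = founders.ids[:12]
        y = rng.standard_normal(12)
        design = assemble_design(_single_year_pheno(ids, y), ks.ids)
        theta = {"a": 0.7, "e": 0.4}
        ours = reml_loglik(theta, design, ks)
        K = ks.Ga[np.ix_(design.ind_idx, design.ind_idx)]
        oracle = dense_reml_loglik(0.7 * K + 0.4 * np.eye(12), design.X, y)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_scaling_shift_is_closed_form(self, founder_setup):
        founders, ks = founder_setup
        rng = np.random.default_rng(8)
        ids = founders.ids[:15]
        y = rng.standard_normal(15)
        design = assemble_design(_single_year_pheno(ids, y), ks.ids)
        c2 = 4.0
        l1 = reml_loglik({"a": 0.5, "e": 0.5}, design, ks)
        l2 = reml_loglik({"a": 0.5 * c2, "e": 0.5 * c2}, design, ks,
                         y=np.sqrt(c2) * y)
        N, f = 15, 1
        assert l2 - l1 == pytest.approx(-(N - f) / 2 * np.log(c2), abs=1e-8)

    def test_disjoint_stack_adds_logliks(self):
        import scipy.linalg as sla

        fA = simulate_founders(10, 80, (0.2, 0.5), seed=1)
        KA = KernelSet.from_genotypes(fA)
        fB = simulate_founders(12, 80, (0.2, 0.5), seed=2)
        fB.ids = np.array([f"B{i}" for i in range(12)], dtype=object)
        KB = KernelSet.from_genotypes(fB)
        scA = SimulationScenario(n_founders=10, n_families=0, offspring_per_family=0,
                                 n_markers=80, missing_pattern=(0, 0, 0), seed=3)
        scB = SimulationScenario(n_founders=12, n_families=0, offspring_per_family=0,
                                 n_markers=80, years=(2013, 2014, 2015),
                                 missing_pattern=(0, 0, 0), seed=4)
        phA, _ = simulate_phenotypes(fA, KA, scA)
        phB, _ = simulate_phenotypes(fB, KB, scB)
        ids = np.concatenate([KA.ids, KB.ids])
        stack = KernelSet(ids=ids, Ga=sla.block_diag(KA.Ga, KB.Ga),
                          D=np.eye(22), Gaa=np.eye(22))
        ph = pd.concat([phA, phB], ignore_index=True)
        dA = assemble_design(phA, KA.ids)
        dB = assemble_design(phB, KB.ids)
        dS = assemble_design(ph, ids)

        def theta(design):
            th = {"a": 0.3, "e": 0.5}
            ys = design.years
            for p in range(len(ys)):
                for q in range(p + 1, len(ys)):
                    th[f"c:{ys[p]}:{ys[q]}"] = 0.1 if abs(ys[p] - ys[q]) < 3 else 0.0
            return th

        lsum = reml_loglik(theta(dA), dA, KA) + reml_loglik(theta(dB), dB, KB)
        lstack = reml_loglik(theta(dS), dS, stack)
        assert lstack == pytest.approx(lsum, abs=1e-8)

    def test_invariant_to_observation_order(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            missing_pattern=(0.2, 0.1, 0.1), seed=5,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        shuffled = pheno.sample(frac=1.0, random_state=0).reset_index(drop=True)
        theta = {"a": 0.4, "e": 0.5, "c:2010:2011": 0.05,
                 "c:2010:2012": 0.05, "c:2011:2012": 0.05}
        l1 = reml_loglik(theta, assemble_design(pheno, ks.ids), ks)
        l2 = reml_loglik(theta, assemble_design(shuffled, ks.ids), ks)
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestRemlFit:
    def test_null_data_keeps_genetic_variance_near_boundary(self, founder_setup):
        # under a true null the additive estimate hugs the zero boundary
        # on average and the fit barely improves on the residual-only model
        founders, ks = founder_setup
        rng = np.random.default_rng(17)
        fracs, gaps = [], []
        for _ in range(10):
            y = rng.standard_normal(60)
            pheno = _single_year_pheno(founders.ids, y)
            fit = KernelGBLUP(terms=("a",), residual="independent", **TIGHT).fit(pheno, ks)
            fracs.append(fit.variance_components_["a"] / np.var(y))
            gaps.append(fit.loglik_ - residual_only_reml_loglik(fit.design_.X, fit.design_.y))
        assert np.mean(fracs) < 0.3
        assert 0.0 <= np.mean(gaps) < 0.5

    def test_matches_grid_search_oracle_at_n8(self):
        founders = simulate_founders(8, 60, (0.2, 0.5), seed=41)
        ks = KernelSet.from_genotypes(founders)
        sc = SimulationScenario(
            n_founders=8, n_families=0, offspring_per_family=0, n_markers=60,
            n_years=1, years=(2011,), year_means=(5.0,), missing_pattern=(0.0,),
            residual_year_correlations=(),
            sigma2={"a": 0.9, "d": 0, "aa": 0, "aY": 0, "dY": 0, "aaY": 0},
            residual_variance=0.6, seed=8,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        fit = KernelGBLUP(terms=("a",), residual="independent", **TIGHT).fit(pheno, ks)
        design = fit.design_
        K = ks.Ga[np.ix_(design.ind_idx, design.ind_idx)]
        grid = np.linspace(1e-6, 4.0, 55)
        _, sa, se = grid_search_single_kernel(K, design.X, design.y, grid, grid)
        spacing = grid[1] - grid[0]
        assert abs(fit.variance_components_["a"] - sa) <= spacing
        assert abs(fit.variance_components_["error"] - se) <= spacing

    def test_agrees_with_spectral_reparameterization(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            n_years=1, years=(2011,), year_means=(5.0,), missing_pattern=(0.0,),
            residual_year_correlations=(),
            sigma2={"a": 0.6, "d": 0, "aa": 0, "aY": 0, "dY": 0, "aaY": 0},
            residual_variance=0.4, seed=9,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        fit = KernelGBLUP(terms=("a",), residual="independent", **TIGHT).fit(pheno, ks)
        design = fit.design_
        K = ks.Ga[np.ix_(design.ind_idx, design.ind_idx)]
        sa, se, logl = spectral_additive_reml(K, design.X, design.y)
        assert fit.variance_components_["a"] == pytest.approx(sa, rel=1e-4, abs=1e-8)
        assert fit.variance_components_["error"] == pytest.approx(se, rel=1e-4)
        assert fit.loglik_ == pytest.approx(logl, abs=1e-6)

    def test_local_maximum_at_convergence(self, small_data):
        fit = KernelGBLUP(terms=("a", "d"), **TIGHT).fit(
            small_data.phenotypes, small_data.kernels
        )
        design, ks = fit.design_, small_data.kernels
        var_y = np.var(design.y)
        base = dict(fit.theta_)
        for name, val in base.items():
            if val <= 1e-6 * var_y:
                continue  # boundary-pinned parameters may only improve inward
            for mult in (0.99, 1.01):
                theta = dict(base)
                theta[name] = val * mult
                perturbed = reml_loglik(theta, design, ks,
                                        spec=fit.spec_)
                assert perturbed <= fit.loglik_ + 5e-3

    def test_extra_null_term_never_decreases_loglik(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            sigma2={"a": 0.5, "d": 0, "aa": 0, "aY": 0, "dY": 0, "aaY": 0},
            residual_variance=0.5, seed=10,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        la = KernelGBLUP(terms=("a",), **TIGHT).fit(pheno, ks).loglik_
        lad = KernelGBLUP(terms=("a", "d"), **TIGHT).fit(pheno, ks).loglik_
        assert lad >= la - 1e-3

    def test_convergence_trace_records_iterations(self, adi_fit):
        assert adi_fit.converged_
        assert len(adi_fit.trace_) == adi_fit.n_iter_ + 1
        assert adi_fit.trace_[-1]["loglik"] >= adi_fit.trace_[0]["loglik"]


class TestBlups:
    def test_zero_genetic_variance_gives_zero_blups(self, founder_setup):
        founders, ks = founder_setup
        rng = np.random.default_rng(19)
        pheno = _single_year_pheno(founders.ids, rng.standard_normal(60))
        fit = KernelGBLUP(terms=("a",), residual="independent").fit(pheno, ks)
        # at theta with zero genetic variance the BLUPs vanish exactly
        fit.theta_["a"] = 0.0
        fit._solve_blups()
        assert (fit.blups_["a"] == 0.0).all()

    def test_mme_route_equals_projection_route(self, adi_fit):
        _, u = solve_mme(adi_fit)
        for term, vals in u.items():
            assert np.max(np.abs(vals - adi_fit.blups_[term])) < 1e-7

    def test_unphenotyped_individual_predicted_through_kernel(self, small_data):
        pheno = small_data.phenotypes
        held = pheno["individual"].unique()[:3]
        train = pheno[~pheno["individual"].isin(set(held))]
        ks = small_data.kernels
        fit = KernelGBLUP(terms=("a",), **TIGHT).fit(train, ks)
        design = fit.design_
        resid = design.y - design.X @ fit.beta_
        s = np.bincount(design.ind_idx, weights=fit._Vinv_ @ resid,
                        minlength=design.n_individuals)
        pos = {ind: k for k, ind in enumerate(ks.ids)}
        for ind in held:
            expected = fit.theta_["a"] * ks.Ga[pos[ind]] @ s
            assert fit.blups_["a"][pos[ind]] == pytest.approx(expected, abs=1e-10)
            assert fit.blups_["a"][pos[ind]] != 0.0


class TestWald:
    def test_huge_year_effect_detected(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            year_means=(10.0, 0.0, -10.0), residual_variance=1.0,
            sigma2={"a": 0.3, "d": 0, "aa": 0, "aY": 0, "dY": 0, "aaY": 0},
            seed=11,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        fit = KernelGBLUP(terms=("a",)).fit(pheno, ks)
        stat, df, p = wald_test_fixed(fit, "year")
        assert df == 2 and p < 1e-3

    def test_invariant_to_reference_year_recoding(self, founder_setup):
        founders, ks = founder_setup
        sc = SimulationScenario(
            n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
            seed=12,
        )
        pheno, _ = simulate_phenotypes(founders, ks, sc)
        relabel = {2010: 2012, 2011: 2011, 2012: 2010}
        recoded = pheno.assign(year=pheno["year"].map(relabel))
        s1, _, p1 = wald_test_fixed(KernelGBLUP(terms=("a",), **TIGHT).fit(pheno, ks))
        s2, _, p2 = wald_test_fixed(KernelGBLUP(terms=("a",), **TIGHT).fit(recoded, ks))
        assert s1 == pytest.approx(s2, rel=1e-4)

    def test_type_one_error_near_nominal(self, founder_setup):
        founders, ks = founder_setup
        rej, B = 0, 150
        for b in range(B):
            sc = SimulationScenario(
                n_founders=60, n_families=0, offspring_per_family=0, n_markers=200,
                year_means=(0.0, 0.0, 0.0), residual_variance=0.7,
                sigma2={"a": 0.3, "d": 0, "aa": 0, "aY": 0, "dY": 0, "aaY": 0},
                missing_pattern=(0.1, 0.1, 0.1), seed=5000 + b,
            )
            pheno, _ = simulate_phenotypes(founders, ks, sc)
            _, _, p = wald_test_fixed(KernelGBLUP(terms=("a",)).fit(pheno, ks))
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / B)
        assert rej / B <= 0.05 + 3 * se + 0.02

    def test_single_level_rejected(self, founder_setup):
        founders, ks = founder_setup
        rng = np.random.default_rng(20)
        pheno = _single_year_pheno(founders.ids, rng.standard_normal(60))
        fit = KernelGBLUP(terms=("a",), residual="independent").fit(pheno, ks)
        with pytest.raises((ValueError, KeyError)):
            wald_test_fixed(fit, "year")


class TestExtendedHat:
    def test_fixed_only_reduces_to_ols_hat(self):
        rng = np.random.default_rng(23)
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        diag = extended_hat_diagonal(X, [], [], np.eye(12))
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        assert diag == pytest.approx(np.diag(H), abs=1e-10)
        assert diag.sum() == pytest.approx(2.0)

    def test_matches_dense_oracle_on_fit(self, adi_fit):
        from cherryblup.model import _mme_blocks, incidence_matrix

        diag, flags = influence_diagnostics(adi_fit)
        Zs, Gs, R = _mme_blocks(adi_fit)
        X = adi_fit.design_.X
        W = np.hstack([X] + Zs)
        Rinv = np.linalg.inv(R)
        import scipy.linalg as sla

        C = W.T @ Rinv @ W + sla.block_diag(
            np.zeros((X.shape[1], X.shape[1])), *[np.linalg.inv(G) for G in Gs]
        )
        H = W @ np.linalg.inv(C) @ W.T
        assert diag == pytest.approx(np.diag(H), abs=1e-6)

    def test_balanced_identity_design_has_no_flags(self):
        n = 10
        ids = [f"i{k}" for k in range(n)]
        ks = KernelSet(ids=ids, Ga=np.eye(n), D=np.eye(n), Gaa=np.eye(n))
        rng = np.random.default_rng(24)
        pheno = _single_year_pheno(ids, rng.standard_normal(n))
        fit = KernelGBLUP(terms=("a",), residual="independent").fit(pheno, ks)
        diag, flags = influence_diagnostics(fit)
        assert not flags.any()
        assert np.ptp(diag) < 1e-8  # exchangeable design: equal leverage
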