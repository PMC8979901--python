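"""Design construction, MME oracle checks and Gibbs/MME agreement."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from ssgeval import (
    Pedigree,
    PhenotypeTable,
    RelationshipMatrix,
    SimConfig,
    a22,
    a_inverse,
    blend_g,
    build_design,
    fit_gibbs,
    genomic_relationship,
    h_matrix,
    numerator_relationship,
    reliabilities,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    solve_mme,
    solve_mme_fit,
)
from ssgeval.io_formats import age_class
from ssgeval.ssgblup import ModelFit

from .conftest import random_pedigree


def _phenotypes(ped, heights, ages, ids=None):
    ids = ids or list(ped.ids)[: len(heights)]
    bd = date(2010, 1, 1)
    rows = pd.DataFrame(
        {
            "animal_id": ids,
            "height": heights,
            "measurement_date": [
                bd + timedelta(days=int(a * 365.25)) for a in ages
            ],
            "source": ["SBR"] * len(ids),
            "age": ages,
            "age_class": [age_class(a) for a in ages],
        }
    )
    return PhenotypeTable(rows)


def _chol_of_a(ped):
    A = numerator_relationship(ped)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(ped)))
    return A, RelationshipMatrix("H_cholesky", list(ped.ids), L)


class TestBuildDesign:
    def test_one_mare_per_age_class(self):
        rng = np.random.default_rng(0)
        ped = random_pedigree(rng, 5, n_founders=5)
        tab = _phenotypes(ped, [165.0] * 5, [2.5, 3.5, 4.5, 5.5, 8.0])
        _, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        assert d.X.shape == (5, 5)
        np.testing.assert_allclose(d.X[:, 0], 1.0)
        assert d.X[:, 1:].sum() == 4  # one indicator per non-reference class

    def test_z_single_one_per_row(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(rng, 8, n_founders=8)
        tab = _phenotypes(ped, [165.0] * 8, [4.0] * 8)
        _, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        np.testing.assert_allclose(d.Z.sum(axis=1), 1.0)
        assert ((d.Z == 0) | (d.Z == 1)).all()

    def test_fa_product_equals_zhz(self):
        rng = np.random.default_rng(2)
        ped = random_pedigree(rng, 20)
        ids = list(ped.ids)[:10]
        tab = _phenotypes(ped, [166.0] * 10, [4.0] * 10, ids=ids)
        A, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        H = L.values @ L.values.T
        np.testing.assert_allclose(
            d.Fa @ d.Fa.T, d.Z @ H @ d.Z.T, atol=1e-8
        )

    def test_empty_phenotypes_rejected(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(rng, 5, n_founders=5)
        _, L = _chol_of_a(ped)
        with pytest.raises(ValueError, match="empty"):
            build_design(
                PhenotypeTable(
                    pd.DataFrame(columns=PhenotypeTable.COLUMNS)
                ),
                ped,
                L,
            )

    def test_absent_age_class_column_dropped(self):
        rng = np.random.default_rng(4)
        ped = random_pedigree(rng, 6, n_founders=6)
        tab = _phenotypes(ped, [165.0] * 6, [2.0, 2.5, 4.5, 4.2, 8.0, 9.0])
        _, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        assert "age_class_2" not in d.x_labels
        assert d.X.shape[1] == 3  # intercept + classes 3 and 5


class TestSolveMme:
    def test_unrelated_animals_without_records_get_zero(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, 6, n_founders=6)  # founders: unrelated
        y = np.array([170.0])
        X = np.ones((1, 1))
        Z = np.zeros((1, 6))
        Z[0, 0] = 1
        Ainv = a_inverse(ped).values
        b, a, pev = solve_mme(y, X, Z, Ainv, 4.0, 8.0)
        np.testing.assert_allclose(a[1:], 0.0, atol=1e-12)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, 10)
        n = 6
        y = 160 + rng.standard_normal(n)
        X = np.ones((n, 1))
        Z = np.eye(10)[:n]
        Ainv = a_inverse(ped).values
        _, a, _ = solve_mme(y, X, Z, Ainv, 1e-10, 1.0)
        np.testing.assert_allclose(a, 0.0, atol=1e-6)

    def test_matches_dense_augmented_least_squares(self):
        """MME solution equals GLS via an independently built dense system."""
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, 50)
        n = 30
        ids = list(ped.ids)[:n]
        y = 165 + rng.standard_normal(n) * 3
        cls = rng.integers(1, 6, size=n)
        X = np.column_stack(
            [np.ones(n)] + [(cls == k).astype(float) for k in (2, 3, 4, 5)]
        )
        Z = np.zeros((n, 50))
        Z[np.arange(n), ped.indices_of(ids)] = 1.0
        A = numerator_relationship(ped).values
        Ainv = np.linalg.inv(A)
        s2a, s2e = 4.0, 8.0
        b, a, pev = solve_mme(y, X, Z, Ainv, s2a, s2e)
        # oracle: joint generalized least squares on the observed-data
        # covariance V = Z A Z' s2a + I s2e, then BLUP a = s2a A Z' V^-1 r
        V = Z @ A @ Z.T * s2a + np.eye(n) * s2e
        Vinv = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        r = y - X @ b_gls
        a_blup = s2a * A @ Z.T @ Vinv @ r
        np.testing.assert_allclose(b, b_gls, atol=1e-8)
        np.testing.assert_allclose(a, a_blup, atol=1e-8)

    def test_singular_system_raises(self):
        y = np.array([1.0, 2.0])
        X = np.ones((2, 2))  # two identical columns -> confounded
        Z = np.eye(2)
        with pytest.raises(np.linalg.LinAlgError, match="confounded|[Ss]ingular"):
            solve_mme(y, X, Z, np.eye(2), 1.0, 1.0)

    def test_no_signal_data_gives_zero_breeding_values(self):
        """Heights fully explained by age classes leave all GEBVs at zero."""
        cfg = SimConfig(
            seed=21, n_breeds=1, breed_sizes=(60,), breed_names=("X",),
            qtl_spec=(), h2_polygenic=0.0, sd_total=0.0,
            n_chromosomes=3, markers_per_chrom=10, missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        tab = simulate_phenotypes(ped, g, cfg)
        A, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        Ainv = a_inverse(ped)
        fit = solve_mme_fit(d, Ainv, 4.0, 8.0)
        span = tab.data["height"].max() - tab.data["height"].min()
        assert np.abs(fit.gebv).max() < 1e-6 * max(span, 1.0)


class TestGibbs:
    def _simulated_design(self, seed, n_final=120):
        cfg = SimConfig(
            seed=seed, n_breeds=1, breed_sizes=(n_final,), breed_names=("X",),
            n_generations=2, qtl_spec=((2, 50_000_000, 0.15),),
            h2_polygenic=0.25, n_chromosomes=5, markers_per_chrom=40,
            missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        cohort = ped.leaf_females()
        g = simulate_genotypes(ped, cfg, animals=cohort)
        tab = simulate_phenotypes(ped, g, cfg, animals=cohort)
        from ssgeval import qc_filter

        g, _ = qc_filter(g)  # drop cohort-monomorphic markers
        A = numerator_relationship(ped)
        A22m = a22(ped, [a for a in ped.ids if a in set(cohort)], A=A)
        Gb = blend_g(genomic_relationship(g.subset_animals(A22m.index)), A22m)
        H, L = h_matrix(A, Gb, A22m.index)
        Hinv = RelationshipMatrix(
            "H_inverse", list(ped.ids), np.linalg.inv(H.values)
        )
        return build_design(tab, ped, L), Hinv

    def test_fixed_variances_match_mme(self):
        """Posterior means at frozen variances agree with the MME solve."""
        design, Hinv = self._simulated_design(31)
        s2a, s2e = 5.0, 7.0
        fit_g = fit_gibbs(
            design, n_iter=6000, burn_in=1000, thin=2, seed=17,
            fixed_variances=(s2a, s2e), rao_blackwell=True,
        )
        fit_m = solve_mme_fit(design, Hinv, s2a, s2e)
        assert np.abs(fit_g.b - fit_m.b).max() < 0.02
        assert np.abs(fit_g.gebv - fit_m.gebv).max() < 0.02

    def test_gibbs_pev_matches_mme_pev(self):
        """Posterior variances of breeding values track the MME PEVs."""
        design, Hinv = self._simulated_design(32)
        s2a, s2e = 5.0, 7.0
        fit_g = fit_gibbs(
            design, n_iter=6000, burn_in=1000, thin=2, seed=18,
            fixed_variances=(s2a, s2e),
        )
        fit_m = solve_mme_fit(design, Hinv, s2a, s2e)
        # Monte-Carlo variance of a variance estimate: compare in relative terms
        rel = np.abs(fit_g.pev - fit_m.pev) / fit_m.pev
        assert np.median(rel) < 0.10

    def test_deterministic_given_seed(self):
        design, _ = self._simulated_design(33, n_final=50)
        f1 = fit_gibbs(design, n_iter=300, burn_in=100, seed=9)
        f2 = fit_gibbs(design, n_iter=300, burn_in=100, seed=9)
        np.testing.assert_array_equal(f1.gebv, f2.gebv)
        assert f1.sigma2_a == f2.sigma2_a

    def test_no_signal_posterior_mean_near_zero(self):
        cfg = SimConfig(
            seed=41, n_breeds=1, breed_sizes=(80,), breed_names=("X",),
            qtl_spec=(), h2_polygenic=0.0, sd_total=0.0,
            n_chromosomes=3, markers_per_chrom=10, missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        tab = simulate_phenotypes(ped, g, cfg)
        A, L = _chol_of_a(ped)
        d = build_design(tab, ped, L)
        fit = fit_gibbs(d, n_iter=3000, burn_in=500, seed=3)
        span = tab.data["height"].max() - tab.data["height"].min()
        assert np.abs(fit.gebv).mean() < 0.02 * span

    def test_divergent_inputs_raise(self):
        design, _ = self._simulated_design(34, n_final=40)
        with pytest.raises(ValueError, match="n_iter"):
            fit_gibbs(design, n_iter=100, burn_in=200, seed=1)


class TestReliabilities:
    def _fit(self, pev, s2a=4.0):
        n = len(pev)
        return ModelFit(
            animal_ids=[f"I{i}" for i in range(n)],
            b=np.zeros(1),
            b_labels=["intercept"],
            gebv=np.zeros(n),
            pev=np.asarray(pev, dtype=float),
            sigma2_a=s2a,
            sigma2_e=8.0,
        )

    def test_zero_pev_is_full_reliability(self):
        assert reliabilities(self._fit([0.0]))[0] == 1.0

    def test_pev_equal_to_variance_is_zero(self):
        assert reliabilities(self._fit([4.0]))[0] == 0.0

    def test_clipping(self):
        r = reliabilities(self._fit([5.0, -0.5]))
        assert r[0] == 0.0 and r[1] == 1.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            reliabilities(self._fit([1.0], s2a=0.0))
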