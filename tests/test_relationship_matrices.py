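"""A, A^-1, G, H identities against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from ssgeval import (
    GenotypeMatrix,
    RelationshipMatrix,
    a22,
    a_inverse,
    blend_g,
    genomic_relationship,
    grm_pca,
    h_inverse,
    h_matrix,
    ld_r2,
    numerator_relationship,
)

from .conftest import random_genotypes, random_pedigree


def gene_dropping_kinship(ped, n_reps, rng):
    """Monte-Carlo additive relationship: 2x kinship from allele dropping.

    Every founder carries two unique alleles; transmission is an
    independent coin flip per replicate.  The additive relationship of a
    pair is twice the probability that random alleles drawn one from each
    animal are identical by descent.
    """
    n = len(ped)
    alleles = np.empty((2, n, n_reps), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        for h, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                alleles[h, i, :] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_reps)
                alleles[h, i, :] = alleles[pick, parent, np.arange(n_reps)]
    est = np.empty((n, n))
    var = np.empty((n, n))
    for i in range(n):
        s = np.zeros((n, n_reps))
        for hi in range(2):
            for hj in range(2):
                s += alleles[hi, i][None, :] == alleles[hj, :, :]
        s *= 0.5  # 2 * kinship per replicate
        est[i] = s.mean(axis=1)
        var[i] = s.var(axis=1)
    se = np.sqrt(var / n_reps)
    return est, se


class TestNumeratorRelationship:
    def test_two_founders_identity(self):
        from ssgeval import Pedigree

        ped = Pedigree.from_records(
            [("A", "0", "0", None, "M", ""), ("B", "0", "0", None, "F", "")]
        )
        A = numerator_relationship(ped)
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_full_sib_inbreeding(self, fullsib_pedigree):
        A = numerator_relationship(fullsib_pedigree)
        i = {a: k for k, a in enumerate(A.index)}
        assert A.values[i["C"], i["D"]] == pytest.approx(0.5)
        assert A.values[i["E"], i["E"]] == pytest.approx(1.25)

    def test_matches_gene_dropping_oracle_small(self):
        """Tabular A vs Monte-Carlo 2x-kinship on a 60-animal pedigree."""
        rng = np.random.default_rng(12)
        ped = random_pedigree(rng, 60)
        A = numerator_relationship(ped).values
        est, se = gene_dropping_kinship(ped, 20_000, rng)
        dev = np.abs(A - est) / np.maximum(se, 1e-12)
        exact = se < 1e-12  # deterministic entries (founder diagonals etc.)
        assert np.abs(A - est)[exact].max() < 1e-12
        frac_in = (dev[~exact] <= 3).mean()
        assert frac_in > 0.985

    def test_permutation_invariance(self):
        """Reordering input records permutes A rows/cols consistently."""
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, 40)
        A1 = numerator_relationship(ped)
        from ssgeval import Pedigree

        records = [
            (
                ped.ids[i],
                ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0",
                ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0",
                ped.birth_date[i],
                ped.sex[i],
                ped.breed[i],
            )
            for i in rng.permutation(len(ped))
        ]
        A2 = numerator_relationship(Pedigree.from_records(records))
        pos = {a: k for k, a in enumerate(A2.index)}
        idx = [pos[a] for a in A1.index]
        np.testing.assert_allclose(
            A1.values, A2.values[np.ix_(idx, idx)], atol=1e-12
        )


class TestAInverse:
    def test_founders_only_identity(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(rng, 10, n_founders=10)
        np.testing.assert_allclose(a_inverse(ped).values, np.eye(10))

    def test_trio_offspring_diagonal_is_two(self, trio_pedigree):
        Ainv = a_inverse(trio_pedigree)
        c = Ainv.index.index("C")
        assert Ainv.values[c, c] == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [30, 120, 400])
    def test_inverse_identity(self, n):
        rng = np.random.default_rng(n)
        ped = random_pedigree(rng, n)
        A = numerator_relationship(ped).values
        Ainv = a_inverse(ped).values
        assert np.abs(Ainv @ A - np.eye(n)).max() < 1e-8


class TestGenomicRelationship:
    def test_hand_example_two_animals_one_snp(self):
        markers = pd.DataFrame(
            {
                "snp_id": ["S"],
                "chrom": [1],
                "bp": [100],
                "alleleA": ["A"],
                "alleleB": ["B"],
            }
        )
        g = GenotypeMatrix(
            ["x", "y"], markers, np.array([[0], [2]], dtype=np.int8)
        )
        G = genomic_relationship(g)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_duplicated_animal_rows_identical(self):
        rng = np.random.default_rng(2)
        g = random_genotypes(rng, 6, 80)
        calls = g.calls.copy()
        calls[5] = calls[0]
        g2 = GenotypeMatrix(g.animal_ids, g.markers, calls)
        G = genomic_relationship(g2).values
        np.testing.assert_allclose(G[0], G[5])
        assert G[0, 5] == pytest.approx(G[0, 0])

    def test_missing_calls_rejected(self):
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 5, 10, missing_rate=0.2)
        with pytest.raises(ValueError, match="missing"):
            genomic_relationship(g)

    def test_monomorphic_marker_rejected(self):
        calls = np.ones((4, 2), dtype=np.int8)
        calls[:, 0] = 2
        markers = pd.DataFrame(
            {
                "snp_id": ["S0", "S1"],
                "chrom": [1, 1],
                "bp": [1, 2],
                "alleleA": ["A", "A"],
                "alleleB": ["B", "B"],
            }
        )
        g = GenotypeMatrix(["a", "b", "c", "d"], markers, calls)
        with pytest.raises(ValueError, match="monomorphic"):
            genomic_relationship(g)

    def test_half_sib_families_mean_relationship(self):
        """G averages ~0.25 within half-sib families, ~0 across."""
        rng = np.random.default_rng(8)
        m = 2000
        p = rng.uniform(0.2, 0.8, size=m)
        n_sires, fam = 12, 12
        sire_h = rng.random((n_sires, 2, m)) < p
        rows, labels = [], []
        for s in range(n_sires):
            for _ in range(fam):
                gamete_s = sire_h[s, rng.integers(0, 2, size=m), np.arange(m)]
                gamete_d = rng.random(m) < p
                rows.append(gamete_s.astype(np.int8) + gamete_d.astype(np.int8))
                labels.append(s)
        markers = pd.DataFrame(
            {
                "snp_id": [f"S{j}" for j in range(m)],
                "chrom": [1] * m,
                "bp": np.arange(1, m + 1),
                "alleleA": ["A"] * m,
                "alleleB": ["B"] * m,
            }
        )
        g = GenotypeMatrix(
            [f"I{i}" for i in range(len(rows))], markers, np.array(rows)
        )
        G = genomic_relationship(g).values
        labels = np.array(labels)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(rows), dtype=bool)
        within = G[same & off].mean()
        across = G[~same].mean()
        assert abs(within - 0.25) < 0.05
        assert abs(across) < 0.05


class TestBlendAndH:
    def _setup(self, seed, n=30, n_geno=12, m=300):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n)
        A = numerator_relationship(ped)
        geno_ids = [ped.ids[i] for i in sorted(rng.choice(n, n_geno, replace=False))]
        g0 = random_genotypes(rng, n_geno, m)
        g = GenotypeMatrix(geno_ids, g0.markers, g0.calls)
        A22m = a22(ped, geno_ids)
        Graw = genomic_relationship(g)
        return ped, A, A22m, Graw, geno_ids

    def test_blend_weight_one_is_identity(self):
        _, _, A22m, Graw, _ = self._setup(1)
        out = blend_g(Graw, A22m, weight=1.0)
        np.testing.assert_allclose(out.values, Graw.values)

    def test_blend_definitional(self):
        _, _, A22m, Graw, _ = self._setup(2)
        out = blend_g(Graw, A22m, weight=0.95)
        np.testing.assert_allclose(
            out.values, 0.95 * Graw.values + 0.05 * A22m.values, atol=1e-12
        )

    def test_blend_fixes_singular_g(self):
        _, _, A22m, Graw, ids = self._setup(3)
        V = Graw.values.copy()
        V[1] = V[0]
        V[:, 1] = V[:, 0]  # duplicate animal -> singular
        Graw2 = RelationshipMatrix("G", ids, V)
        out = blend_g(Graw2, A22m, weight=0.95)
        assert np.linalg.eigvalsh(out.values)[0] > 0

    def test_blend_weight_out_of_range(self):
        _, _, A22m, Graw, _ = self._setup(4)
        with pytest.raises(ValueError):
            blend_g(Graw, A22m, weight=0.0)

    def test_h_reduces_to_a_when_g_equals_a22(self):
        ped, A, A22m, _, ids = self._setup(5)
        Gfake = RelationshipMatrix("G", ids, A22m.values.copy())
        H, L = h_matrix(A, Gfake, ids)
        np.testing.assert_allclose(H.values, A.values, atol=1e-8)
        Ainv = a_inverse(ped)
        Hinv = h_inverse(
            Ainv,
            RelationshipMatrix("H_inverse", ids, np.linalg.inv(Gfake.values)),
            RelationshipMatrix("H_inverse", ids, np.linalg.inv(A22m.values)),
            ids,
        )
        np.testing.assert_allclose(Hinv.values, Ainv.values, atol=1e-8)
        np.testing.assert_allclose(L.values @ L.values.T, H.values, atol=1e-8)

    def test_h_inverse_no_genotyped_is_a_inverse(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, 20)
        Ainv = a_inverse(ped)
        empty = RelationshipMatrix("H_inverse", [], np.empty((0, 0)))
        Hinv = h_inverse(Ainv, empty, empty, [])
        np.testing.assert_allclose(Hinv.values, Ainv.values)

    def test_h_inverse_matches_brute_force_inverse(self):
        ped, A, A22m, Graw, ids = self._setup(7)
        Gb = blend_g(Graw, A22m, weight=0.95)
        H, L = h_matrix(A, Gb, ids)
        Hinv = h_inverse(
            a_inverse(ped),
            RelationshipMatrix("H_inverse", ids, np.linalg.inv(Gb.values)),
            RelationshipMatrix("H_inverse", ids, np.linalg.inv(A22m.values)),
            ids,
        )
        assert np.abs(Hinv.values - np.linalg.inv(H.values)).max() < 1e-6
        np.testing.assert_allclose(L.values @ L.values.T, H.values, atol=1e-8)

    def test_index_mismatch_rejected(self):
        ped, A, A22m, Graw, ids = self._setup(8)
        Ginv = RelationshipMatrix(
            "H_inverse", ids[::-1], np.linalg.inv(Graw.values)
        )
        with pytest.raises(ValueError):
            h_inverse(a_inverse(ped), Ginv, Ginv, ids)


class TestPcaAndLd:
    def test_two_group_separation(self):
        # two groups related within and anti-related across (the structure
        # of a centred GRM over two diverged populations)
        n = 10
        v = np.concatenate([np.ones(n), -np.ones(n)])
        G = RelationshipMatrix(
            "G",
            [f"I{i}" for i in range(2 * n)],
            0.4 * np.outer(v, v) + 0.6 * np.eye(2 * n),
        )
        scores, frac = grm_pca(G, 2)
        signs = np.sign(scores[:, 0])
        assert (signs[:n] == signs[0]).all()
        assert (signs[n:] == -signs[0]).all()

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((15, 40))
        G = RelationshipMatrix(
            "G", [f"I{i}" for i in range(15)], M @ M.T / 40
        )
        _, frac = grm_pca(G, 10)
        assert frac.sum() <= 1 + 1e-12
        assert (np.diff(frac) <= 1e-12).all()

    def test_ld_self_is_one(self):
        rng = np.random.default_rng(4)
        g = random_genotypes(rng, 50, 10)
        sid = g.markers["snp_id"].iloc[0]
        assert ld_r2(g, sid, sid) == pytest.approx(1.0)

    def test_ld_duplicated_column_is_one(self):
        rng = np.random.default_rng(5)
        g = random_genotypes(rng, 50, 5)
        calls = g.calls.copy()
        calls[:, 1] = calls[:, 0]
        g2 = GenotypeMatrix(g.animal_ids, g.markers, calls)
        ids = g2.markers["snp_id"]
        assert ld_r2(g2, ids.iloc[0], ids.iloc[1]) == pytest.approx(1.0)

    def test_independent_snps_low_ld(self):
        rng = np.random.default_rng(6)
        n = 10_000
        calls = np.column_stack(
            [rng.binomial(2, 0.5, n), rng.binomial(2, 0.3, n)]
        ).astype(np.int8)
        markers = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chrom": [1, 2],
                "bp": [1, 1],
                "alleleA": ["A", "A"],
                "alleleB": ["B", "B"],
            }
        )
        g = GenotypeMatrix([f"I{i}" for i in range(n)], markers, calls)
        assert ld_r2(g, "a", "b") < 0.01

    def test_monomorphic_ld_is_nan(self):
        calls = np.column_stack(
            [np.full(20, 1, dtype=np.int8), np.full(20, 2, dtype=np.int8)]
        )
        markers = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chrom": [1, 1],
                "bp": [1, 2],
                "alleleA": ["A", "A"],
                "alleleB": ["B", "B"],
            }
        )
        g = GenotypeMatrix([f"I{i}" for i in range(20)], markers, calls)
        with pytest.warns(UserWarning):
            assert np.isnan(ld_r2(g, "a", "b"))


def test_sparse_text_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    ped = random_pedigree(rng, 25)
    A = numerator_relationship(ped)
    A.to_sparse_text(tmp_path / "a.txt")
    back = RelationshipMatrix.from_sparse_text(tmp_path / "a.txt", index=A.index)
    assert back.kind == "A"
    np.testing.assert_allclose(back.values, A.values, atol=1e-10)
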