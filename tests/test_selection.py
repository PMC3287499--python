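"""Gene ranking, PC1 variance contribution, prefix selection, projection."""

import numpy as np
import pytest
from scipy.stats import rankdata

import condegree as cd
from condegree.selection import _project


def _em(values, prefix="g"):
    g, s = values.shape
    return cd.ExpressionMatrix(
        [f"{prefix}{i:03d}" for i in range(g)], [f"s{j}" for j in range(s)], values
    )


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            # midrank oracle: ranks x=[1,2.5,2.5,4], y=[1.5,1.5,3.5,3.5],
            # Pearson of those = 1/sqrt(2)
            ([1, 2, 2, 4], [0, 0, 1, 1], 0.7071067811865476),
        ],
    )
    def test_values(self, x, y, expected):
        assert cd.spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(cd.UndefinedCorrelationError):
            cd.spearman_rho([1, 1, 1, 1], [0, 0, 1, 1])


class TestRankGenes:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        vals = rng.normal(size=(10, 6))
        vals[7] = y  # perfect monotone gene
        ranked = cd.rank_genes(_em(vals), y)
        assert ranked.gene_ids[0] == "g007"
        assert abs(ranked.rho[0]) == pytest.approx(1.0)

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(40, 12))
        y = rng.integers(0, 2, 12).astype(float)
        em = _em(vals)
        ranked = cd.rank_genes(em, y)
        # independent oracle: per-gene midrank Pearson, then sort
        ry = rankdata(y)
        oracle = {}
        for gid, row in zip(em.gene_ids, vals):
            rx = rankdata(row)
            oracle[gid] = np.corrcoef(rx, ry)[0, 1]
        expect = sorted(oracle, key=lambda g: (-abs(oracle[g]), g))
        assert ranked.gene_ids == expect
        for gid, rho in zip(ranked.gene_ids, ranked.rho):
            assert rho == pytest.approx(oracle[gid], abs=1e-12)

    def test_duplicate_genes_tiebreak_by_id(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=8)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        vals = np.vstack([row, row, rng.normal(size=8)])
        em = cd.ExpressionMatrix(["gB", "gA", "gC"], [f"s{j}" for j in range(8)], vals)
        ranked = cd.rank_genes(em, y)
        pos_a, pos_b = ranked.gene_ids.index("gA"), ranked.gene_ids.index("gB")
        assert pos_b == pos_a + 1  # adjacent, id order breaks the tie

    def test_all_constant_degenerate(self):
        with pytest.raises(cd.DegenerateInputError):
            cd.rank_genes(_em(np.ones((4, 6))), [0, 0, 0, 1, 1, 1])


class TestPC1Contribution:
    def test_rank_one_matrix_gives_one(self):
        rng = np.random.default_rng(0)
        signal = rng.normal(size=10)
        sub = np.outer(signal, rng.normal(size=4))  # samples x genes, rank 1
        assert cd.pc1_contribution(sub) == pytest.approx(1.0)

    def test_identity_covariance_gives_half(self):
        # construct two exactly orthonormal centred columns -> equal eigenvalues
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        a -= a.mean()
        b = rng.normal(size=12)
        b -= b.mean()
        b -= (a @ b) / (a @ a) * a
        sub = np.column_stack([a / np.linalg.norm(a), b / np.linalg.norm(b)])
        assert cd.pc1_contribution(sub) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_matches_eigendecomposition_oracle(self, kernel):
        rng = np.random.default_rng(2)
        for _ in range(10):
            sub = rng.normal(size=(20, 10))
            got = cd.pc1_contribution(sub, kernel=kernel)
            if kernel == "linear":
                xc = sub - sub.mean(axis=0)
                lam = np.linalg.eigvalsh(np.cov(xc, rowvar=False, bias=True))
                expect = lam[-1] / lam.sum()
            else:
                xc = sub - sub.mean(axis=0)
                d2 = ((xc[:, None, :] - xc[None, :, :]) ** 2).sum(-1)
                gamma = 1.0 / (2.0 * np.median(d2[np.triu_indices(20, 1)]))
                K = np.exp(-gamma * d2)
                H = np.eye(20) - 1.0 / 20
                lam = np.clip(np.linalg.eigvalsh(H @ K @ H), 0, None)
                expect = lam[-1] / lam.sum()
            assert got == pytest.approx(expect, abs=1e-10)
            assert 0.0 < got <= 1.0

    def test_zero_variance_degenerate(self):
        with pytest.raises(cd.DegenerateInputError):
            cd.pc1_contribution(np.ones((5, 3)))


class TestSelectGeneset:
    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        for trial in range(50):
            g = int(rng.integers(8, 20))
            s = int(rng.integers(6, 15))
            vals = rng.normal(size=(g, s))
            y = np.zeros(s)
            y[s // 2 :] = 1
            em = _em(vals, prefix=f"t{trial}_g")
            try:
                sel = cd.select_geneset(em, y, k_min=2, k_max=g)
            except cd.DegenerateInputError:
                continue
            ranked = cd.rank_genes(em, y)
            sub = em.subset_genes(ranked.gene_ids).values.T
            oracle = {
                k: cd.pc1_contribution(sub[:, :k]) for k in range(2, len(ranked.gene_ids) + 1)
            }
            best = max(oracle.values())
            assert sel.contribution == pytest.approx(best, abs=1e-12)
            # smallest prefix achieving the max
            assert sel.prefix_size == min(
                k for k, v in oracle.items() if v == pytest.approx(best, abs=1e-12)
            )

    def test_kmin_equals_kmax(self):
        rng = np.random.default_rng(6)
        em = _em(rng.normal(size=(12, 8)))
        y = np.array([0] * 4 + [1] * 4, dtype=float)
        sel = cd.select_geneset(em, y, k_min=7, k_max=7)
        assert sel.prefix_size == 7

    def test_tie_prefers_smaller_prefix(self):
        # duplicated top genes: contribution identical for prefixes 2 and 3
        rng = np.random.default_rng(7)
        base = rng.normal(size=8)
        y = np.array([0] * 4 + [1] * 4, dtype=float)
        vals = np.vstack([base + y, base + y, base + y, rng.normal(size=8) * 0.01])
        em = _em(vals)
        sel = cd.select_geneset(em, y, k_min=2, k_max=3)
        assert sel.prefix_size == 2


class TestProjectPC1:
    def test_separated_clusters_score_separation(self):
        expr, clin = cd.simulate_two_class(cd.SimConfig(seed=9))
        aligned, y = cd.align(expr, clin, "class")
        sel = cd.select_geneset(aligned, y)
        scores = cd.project_pc1(aligned, sel, y)
        s = scores.score
        within = np.var(s[y == 0]) + np.var(s[y == 1])
        between = (s[y == 1].mean() - s[y == 0].mean()) ** 2
        assert between > within
        assert s[y == 1].mean() >= s[y == 0].mean()  # orientation convention

    def test_global_sign_flip_invariance(self, tiny_expr):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        sel = cd.select_geneset(tiny_expr, y, k_min=3, k_max=5)
        s1 = cd.project_pc1(tiny_expr, sel, y).score
        flipped = cd.ExpressionMatrix(
            tiny_expr.gene_ids, tiny_expr.sample_ids, -tiny_expr.values
        )
        sel2 = cd.select_geneset(flipped, y, k_min=3, k_max=5)
        s2 = cd.project_pc1(flipped, sel2, y).score
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_sample_permutation_equivariance(self, tiny_expr):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        perm = np.array([3, 1, 6, 0, 7, 2, 5, 4])
        s1 = _project(tiny_expr.values.T, y)
        s2 = _project(tiny_expr.values.T[perm], y[perm])
        np.testing.assert_allclose(s2, s1[perm], atol=1e-9)


class TestSelectorEstimator:
    def test_sklearn_contract(self, small_two_class):
        aligned, y = small_two_class
        X = aligned.values.T
        sel = cd.CorrelatedGeneSelector(k_min=5, k_max=50).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], sel.prefix_size_)
        assert sel.get_params()["k_min"] == 5
        assert sel.contribution_ == max(sel.contribution_curve_)
        # informative genes dominate the selection
        assert np.mean(sel.selected_idx_ < 20) > 0.8
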