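"""Newick parsing, tip covariance, and the phylogenetic PCA model."""

import numpy as np
import pandas as pd
import pytest

from lamellometry import (
    PhyloPCA,
    parse_newick,
    ppca,
    simulate_brownian_traits,
    variance_explained,
)

# Independent cross-check values computed with phyl.pca (phytools, R) in
# correlation mode on the bundled trait matrix and tree, unit branch lengths.
PHYTOOLS_PCT = [57.441445, 23.708697, 9.648003, 7.228977, 1.972877]
PHYTOOLS_PC1 = {
    "rel_area_largest": 0.412036,
    "lamellar_number": -0.695413,
    "pct_increase": 0.946596,
    "branching_index": 0.730295,
    "brinkhoff": 0.888439,
}
PHYTOOLS_PC2 = {
    "rel_area_largest": 0.797511,
    "lamellar_number": -0.478488,
    "pct_increase": -0.186940,
    "branching_index": -0.521461,
    "brinkhoff": -0.116579,
}


class TestParseNewick:
    def test_star_tree_identity_covariance(self):
        tree = parse_newick("(A,B);", unit_branch_lengths=True)
        C = tree.covariance()
        assert np.allclose(C.to_numpy(), np.eye(2))

    def test_caterpillar_shared_paths(self):
        tree = parse_newick("((A,B),C);", unit_branch_lengths=True)
        C = tree.covariance(["A", "B", "C"])
        expected = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 1]], float)
        assert np.allclose(C.to_numpy(), expected)

    def test_missing_branch_lengths_default_to_one(self):
        t1 = parse_newick("((A:1,B:1):1,C:1);")
        t2 = parse_newick("((A,B),C);")
        assert np.allclose(
            t1.covariance(["A", "B", "C"]).to_numpy(),
            t2.covariance(["A", "B", "C"]).to_numpy(),
        )

    def test_study_tree_tips_and_polytomy(self, study_tree):
        assert len(study_tree.tip_labels) == 14
        C = study_tree.covariance()
        # the three Raja species form a polytomy: pairwise shared depth equal
        raja = ["Raja_brachyura", "Raja_polystigma", "Raja_miraletus"]
        sub = C.loc[raja, raja].to_numpy()
        off = sub[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_study_covariance_is_psd(self, study_tree):
        ev = np.linalg.eigvalsh(study_tree.covariance().to_numpy())
        assert ev.min() >= -1e-10

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            parse_newick("((A,B,C);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A,A);")

    def test_unknown_tip_rejected(self, study_tree):
        with pytest.raises(ValueError, match="not in tree"):
            study_tree.covariance(["Nonexistent_species"])


class TestPhyloPCAModel:
    def test_star_tree_reduces_to_ordinary_pca(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(size=(12, 4)),
            index=[f"t{i}" for i in range(12)],
            columns=list("abcd"),
        )
        C = pd.DataFrame(np.eye(12), index=X.index, columns=X.index)
        res = ppca(X, C, mode="correlation")
        plain = np.sort(np.linalg.eigvalsh(np.corrcoef(X.T)))[::-1]
        assert np.allclose(res.eigenvalues, plain, atol=1e-10)

    def test_scores_phylogenetically_uncorrelated(self, trait_matrix, study_tree):
        res = PhyloPCA(trait_matrix, study_tree).fit()
        S = res.scores.to_numpy()
        G = S.T @ np.linalg.inv(res.C.to_numpy()) @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_percent_variances_sum_to_100(self, trait_matrix, study_tree):
        res = PhyloPCA(trait_matrix, study_tree).fit()
        assert res.percent_variance.sum() == pytest.approx(100.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_matches_phytools_reference(self, trait_matrix, study_tree):
        """Correlation-mode fit agrees with the R phytools implementation."""
        res = PhyloPCA(trait_matrix, study_tree).fit()
        assert np.allclose(res.percent_variance, PHYTOOLS_PCT, atol=1e-4)
        for trait, val in PHYTOOLS_PC1.items():
            assert res.loadings.loc[trait, "PC1"] == pytest.approx(val, abs=1e-4)
        for trait, val in PHYTOOLS_PC2.items():
            assert res.loadings.loc[trait, "PC2"] == pytest.approx(val, abs=1e-4)

    def test_sign_convention_orients_dominant_trait_positive(
        self, trait_matrix, study_tree
    ):
        res = PhyloPCA(trait_matrix, study_tree).fit()
        for pc in res.loadings.columns:
            col = res.loadings[pc]
            assert col[col.abs().idxmax()] > 0

    def test_study_headline_variances(self, trait_matrix, study_tree):
        """PC1+PC2 carry ~81% of the correlation-mode variance (published:
        81.3 total, 57.8 and 23.5 individually; within 1 point here)."""
        res = PhyloPCA(trait_matrix, study_tree).fit()
        assert res.variance_explained(2) == pytest.approx(81.3, abs=1.0)
        assert res.percent_variance[0] == pytest.approx(57.8, abs=1.0)
        assert res.percent_variance[1] == pytest.approx(23.5, abs=1.0)

    def test_pc1_correlates_with_fold_traits(self, trait_matrix, study_tree):
        """PC1 rises with fold increase, branching and Brinkhoff index and
        falls with lamellar number; PC2 rises with relative lamella area and
        falls with branching — the published loading pattern."""
        L = PhyloPCA(trait_matrix, study_tree).fit().loadings
        assert L.loc["pct_increase", "PC1"] > 0
        assert L.loc["branching_index", "PC1"] > 0
        assert L.loc["brinkhoff", "PC1"] > 0
        assert L.loc["lamellar_number", "PC1"] < 0
        assert L.loc["rel_area_largest", "PC2"] > 0
        assert L.loc["branching_index", "PC2"] < 0

    def test_variance_explained_bounds(self, trait_matrix, study_tree):
        res = PhyloPCA(trait_matrix, study_tree).fit()
        assert res.variance_explained(5) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            variance_explained(res, 0)
        with pytest.raises(ValueError):
            variance_explained(res, 6)

    def test_missing_cells_rejected(self, study_tree):
        X = pd.DataFrame(
            {"a": [1.0, np.nan], "b": [2.0, 3.0]},
            index=["Chimaera_monstrosa", "Raja_brachyura"],
        )
        with pytest.raises(ValueError, match="missing"):
            PhyloPCA(X, study_tree)

    def test_summary_reports_headline(self, trait_matrix, study_tree):
        text = PhyloPCA(trait_matrix, study_tree).fit().summary()
        assert "PC1" in text and "% variance" in text
        assert "correlation" in text


class TestBrownianRecovery:
    def test_rank_one_sigma_single_component(self, study_tree):
        """A rank-1 trait covariance loads everything on PC1."""
        v = np.array([1.0, 0.5, -0.25, 2.0, 1.5])
        sigma = np.outer(v, v)
        X = simulate_brownian_traits(study_tree, sigma, seed=11)
        res = ppca(X, study_tree.covariance(), mode="covariance")
        assert res.percent_variance[0] > 99.9

    def test_star_tree_identity_sigma_is_iid_normal(self):
        from scipy import stats

        n = 40
        C = pd.DataFrame(np.eye(n), index=[f"t{i}" for i in range(n)],
                         columns=[f"t{i}" for i in range(n)])
        draws = np.concatenate(
            [
                simulate_brownian_traits(C, np.eye(2), seed=s).to_numpy().ravel()
                for s in range(20)
            ]
        )
        assert stats.kstest(draws, "norm").pvalue > 0.01

    def test_non_psd_sigma_rejected(self, study_tree):
        sigma = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_brownian_traits(study_tree, sigma, seed=0)

    def test_known_spectrum_recovered(self, study_tree):
        """Mean evolutionary covariance over 200 Brownian replicates recovers
        a known eigenvalue spectrum within 15% mean relative error."""
        lam = np.array([3.0, 1.0, 0.5, 0.3, 0.2])
        rng = np.random.default_rng(42)
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        sigma = Q @ np.diag(lam) @ Q.T
        C = study_tree.covariance()
        Vs = [
            ppca(simulate_brownian_traits(C, sigma, seed=1000 + rep), C,
                 mode="covariance").evolutionary_matrix.to_numpy()
            for rep in range(200)
        ]
        ev = np.sort(np.linalg.eigvalsh(np.mean(Vs, axis=0)))[::-1]
        rel_err = np.abs(ev - lam) / lam
        assert rel_err.mean() < 0.15
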