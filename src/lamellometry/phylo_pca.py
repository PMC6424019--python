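"""Phylogenetically informed PCA of morphometric traits.

Species trait values are not independent samples: under a Brownian-motion
model of trait evolution the expected covariance between two tips equals the
branch length they share from the root to their most recent common ancestor.
The phylogenetic PCA therefore (i) estimates the phylogenetic (GLS) mean
``a = (1' C^-1 1)^-1 1' C^-1 X`` from the tip covariance matrix ``C``,
(ii) forms the evolutionary covariance
``V = (X - 1a)' C^-1 (X - 1a) / (n - 1)`` (rescaled to a correlation matrix in
``"correlation"`` mode, the default here because the traits mix counts,
percentages and unit-interval indexes), and (iii) eigendecomposes ``V``.
Scores are the centred traits projected on the eigenvectors; loadings are
reported as trait-component correlations.  With a star tree and unit
branches (``C = I``) the procedure reduces exactly to ordinary PCA.

The model/results split follows the statsmodels convention:
``PhyloPCA(X, tree).fit()`` returns a :class:`PhyloPCAResults` carrying
eigenvalues, percent variance, loadings, scores and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "parse_newick",
    "phylo_covariance",
    "PhyloPCA",
    "PhyloPCAResults",
    "ppca",
    "variance_explained",
]


class PhyloTree:
    """Rooted tree wrapper exposing the Brownian tip-covariance matrix.

    Branch lengths absent from the source Newick default to 1 (the study sets
    every branch to 1); ``unit_branch_lengths=True`` forces all branches to 1
    regardless of what the file carries.  Polytomies are handled natively.
    """

    def __init__(self, tree: dendropy.Tree, unit_branch_lengths: bool = False):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                edge.length = 0.0
            elif unit_branch_lengths or edge.length is None:
                edge.length = 1.0
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        self.tip_labels: list[str] = labels

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def covariance(self, tips: list[str] | None = None) -> pd.DataFrame:
        """Shared root-to-MRCA path length for every tip pair (C matrix)."""
        if tips is None:
            tips = self.tip_labels
        missing = set(tips) - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        tree = self._tree
        # depth of every node from the root
        depth: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            depth[id(node)] = (0.0 if parent is None else depth[id(parent)]) + (
                node.edge.length or 0.0
            )
        leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        n = len(tips)
        C = np.zeros((n, n))
        pdm = {}
        for i, a in enumerate(tips):
            C[i, i] = depth[id(leaf[a])]
            for j in range(i + 1, n):
                b = tips[j]
                mrca = pdm.get((a, b))
                if mrca is None:
                    mrca = tree.mrca(taxa=[leaf[a].taxon, leaf[b].taxon])
                    pdm[(a, b)] = mrca
                C[i, j] = C[j, i] = depth[id(mrca)]
        return pd.DataFrame(C, index=tips, columns=tips)


def parse_newick(source: str, unit_branch_lengths: bool = False) -> PhyloTree:
    """Parse a Newick string (or text stream content) into a :class:`PhyloTree`."""
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(source),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate tip labels in Newick source: {e}") from e
    return PhyloTree(tree, unit_branch_lengths=unit_branch_lengths)


def phylo_covariance(tree: PhyloTree, tips: list[str] | None = None) -> pd.DataFrame:
    """Convenience alias for ``tree.covariance(tips)``."""
    return tree.covariance(tips)


@dataclass
class PhyloPCAResults:
    """Fitted phylogenetic PCA: eigenvalues, loadings, scores, diagnostics."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # traits x components, trait-component correlations
    scores: pd.DataFrame  # specimens x components
    phylo_mean: pd.Series
    evolutionary_matrix: pd.DataFrame  # V (covariance or correlation)
    mode: str
    C: pd.DataFrame

    def variance_explained(self, k: int) -> float:
        """Cumulative percent variance of the first ``k`` components."""
        return variance_explained(self, k)

    def summary(self) -> str:
        lines = ["Phylogenetic PCA (mode=%s)" % self.mode]
        lines.append(
            "n = %d specimens, m = %d traits" % (self.scores.shape[0], self.loadings.shape[0])
        )
        lines.append("")
        header = "%-12s %12s %12s %12s" % ("component", "eigenvalue", "% variance", "cum. %")
        lines.append(header)
        lines.append("-" * len(header))
        cum = 0.0
        for k, (ev, pct) in enumerate(zip(self.eigenvalues, self.percent_variance), 1):
            cum += pct
            lines.append("%-12s %12.4f %12.2f %12.2f" % (f"PC{k}", ev, pct, cum))
        lines.append("")
        lines.append("Loadings (trait-component correlations):")
        lines.append(self.loadings.round(4).to_string())
        return "\n".join(lines)

    def plot_scores(self, x: int = 1, y: int = 2, color_by: pd.Series | None = None, ax=None):
        """Scatter of component scores, optionally coloured by a metadata column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = self.scores.iloc[:, x - 1]
        ys = self.scores.iloc[:, y - 1]
        if color_by is not None:
            cats = color_by.reindex(self.scores.index)
            for cat, idx in self.scores.groupby(cats.astype(str)).groups.items():
                ax.scatter(xs.loc[idx], ys.loc[idx], label=cat)
            ax.legend(frameon=False, fontsize=8)
        else:
            ax.scatter(xs, ys)
        for label in self.scores.index:
            ax.annotate(label, (xs[label], ys[label]), fontsize=7)
        ax.set_xlabel(f"PC{x} ({self.percent_variance[x - 1]:.1f}%)")
        ax.set_ylabel(f"PC{y} ({self.percent_variance[y - 1]:.1f}%)")
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
        return ax


class PhyloPCA:
    """Phylogenetic PCA model for a trait matrix and a phylogeny.

    Parameters
    ----------
    X
        Specimens x traits DataFrame; the index must match tree tip labels
        1:1 (a subset of the tips is allowed — the covariance is restricted).
    tree
        A :class:`PhyloTree`, or a precomputed tip-covariance DataFrame.
    mode
        ``"correlation"`` (default; traits on incommensurate scales) or
        ``"covariance"``.
    ridge
        Diagonal regularization added to ``C`` only if it is numerically
        singular.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        tree: "PhyloTree | pd.DataFrame",
        mode: str = "correlation",
        ridge: float = 1e-10,
    ):
        if mode not in ("correlation", "covariance"):
            raise ValueError("mode must be 'correlation' or 'covariance'")
        if X.isna().any().any():
            raise ValueError("trait matrix has missing cells")
        self.X = X.astype(float)
        self.mode = mode
        self.ridge = ridge
        if isinstance(tree, PhyloTree):
            self.C = tree.covariance(list(X.index))
        else:
            missing = set(X.index) - set(tree.index)
            if missing:
                raise ValueError(f"specimens not in covariance: {sorted(missing)}")
            self.C = tree.loc[list(X.index), list(X.index)].astype(float)
        n, m = self.X.shape
        if m > n:
            import warnings

            warnings.warn(
                f"more traits ({m}) than specimens ({n}): evolutionary "
                "covariance is rank deficient",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, trait_columns: list[str], tree: PhyloTree, **kw
    ) -> "PhyloPCA":
        return cls(df[trait_columns], tree, **kw)

    def fit(self) -> PhyloPCAResults:
        X = self.X.to_numpy(float)
        n, m = X.shape
        C = self.C.to_numpy(float)
        try:
            invC = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "tip covariance is singular; pass a small ridge (e.g. 1e-10) "
                "or check for zero-length terminal branches"
            )
        cond = np.linalg.cond(C)
        if cond > 1e12:
            C = C + self.ridge * np.eye(n)
            invC = np.linalg.inv(C)
        one = np.ones((n, 1))

        def gls_mean(Y):
            return (one.T @ invC @ Y) / (one.T @ invC @ one)

        a = gls_mean(X)
        V = (X - a).T @ invC @ (X - a) / (n - 1)
        Y = X
        if self.mode == "correlation":
            sd = np.sqrt(np.diag(V))
            Y = X / sd
            V = V / np.outer(sd, sd)
            a = gls_mean(Y)
        evals, evecs = np.linalg.eigh(V)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        resid = Y - a
        scores = resid @ evecs
        # loadings: correlation of each trait with each component score
        Vdiag = np.diag(V)
        cov_ts = V @ evecs  # phylogenetic covariance of traits with scores
        with np.errstate(divide="ignore", invalid="ignore"):
            L = cov_ts / np.sqrt(np.outer(Vdiag, np.where(evals > 0, evals, np.nan)))
        L = np.nan_to_num(L)
        # sign convention: largest-|loading| trait of each component positive
        for j in range(m):
            i_star = np.argmax(np.abs(L[:, j]))
            if L[i_star, j] < 0:
                L[:, j] *= -1
                evecs[:, j] *= -1
                scores[:, j] *= -1
        pcs = [f"PC{k + 1}" for k in range(m)]
        pct = 100.0 * evals / evals.sum()
        return PhyloPCAResults(
            eigenvalues=evals,
            percent_variance=pct,
            loadings=pd.DataFrame(L, index=self.X.columns, columns=pcs),
            scores=pd.DataFrame(scores, index=self.X.index, columns=pcs),
            phylo_mean=pd.Series(a.ravel(), index=self.X.columns),
            evolutionary_matrix=pd.DataFrame(
                V, index=self.X.columns, columns=self.X.columns
            ),
            mode=self.mode,
            C=self.C,
        )


def ppca(
    X: pd.DataFrame, C: "pd.DataFrame | PhyloTree", mode: str = "correlation"
) -> PhyloPCAResults:
    """Functional wrapper: fit a :class:`PhyloPCA` in one call."""
    return PhyloPCA(X, C, mode=mode).fit()


def variance_explained(result: PhyloPCAResults, k: int) -> float:
    """Percent of total variance captured by the first ``k`` components."""
    m = len(result.percent_variance)
    if not (1 <= k <= m):
        raise ValueError(f"k must be in [1, {m}]")
    return float(result.percent_variance[:k].sum())
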