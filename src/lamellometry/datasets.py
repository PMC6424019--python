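"""Bundled study data: the 16-specimen measurement table, the species
phylogeny (Newick, unit branch lengths) and the ecology metadata table.

These are the published per-specimen numbers the pipeline consumes; no raw
images or per-lamella lengths were deposited, so image-level stages are
exercised through :mod:`lamellometry.synthetic` instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_measurements",
    "load_tree_text",
    "load_tree",
    "load_ecology",
    "load_trait_matrix",
    "TRAIT_COLUMNS",
]

#: the five morphometric traits fed to the phylogenetic PCA
TRAIT_COLUMNS = [
    "rel_area_largest",
    "lamellar_number",
    "pct_increase",
    "branching_index",
    "brinkhoff",
]


def _data(name: str):
    return resources.files("lamellometry.data").joinpath(name)


def load_measurements() -> pd.DataFrame:
    """Per-specimen measurement and index table (16 specimens, 14 species)."""
    with resources.as_file(_data("olfactory_measurements.csv")) as path:
        return pd.read_csv(path)


def load_tree_text() -> str:
    """The species phylogeny as a Newick string (branch lengths implicit)."""
    return _data("chondrichthyes_tree.nwk").read_text().strip()


def load_tree(unit_branch_lengths: bool = True):
    """The species phylogeny as a :class:`~lamellometry.phylo_pca.PhyloTree`."""
    from .phylo_pca import parse_newick

    return parse_newick(load_tree_text(), unit_branch_lengths=unit_branch_lengths)


def load_ecology() -> pd.DataFrame:
    """Habitat and feeding-preference metadata per species (cosmetic overlay)."""
    with resources.as_file(_data("ecology.csv")) as path:
        return pd.read_csv(path)


def load_trait_matrix(one_per_species: bool = True) -> pd.DataFrame:
    """Specimens x traits matrix for the phylogenetic PCA.

    With ``one_per_species=True`` (default) the smaller specimen of each
    doubly-sampled species is dropped (Gm3 and Sc7, keeping Gm1 and Sc8),
    leaving 14 rows indexed by species name to match the tree tips.
    """
    df = load_measurements()
    if one_per_species:
        df = (
            df.sort_values("size_cm", ascending=False)
            .drop_duplicates("species", keep="first")
            .sort_index()
        )
        return df.set_index("species")[TRAIT_COLUMNS].astype(float)
    return df.set_index("specimen")[TRAIT_COLUMNS].astype(float)
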