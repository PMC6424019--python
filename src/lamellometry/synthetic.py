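"""Synthetic fixtures: lamella silhouettes, measurement tables, Brownian traits.

Real lamella silhouettes come from traced histological sections, which no
public archive carries; the generator emulates the three fold morphologies
seen across chondrichthyans — short unbranched, long/dense unbranched, and
branched — with a handful of knobs.  A lamella is modelled as a stadium-shaped
body (long axis horizontal) carrying rectangular secondary folds normal to
the axis on both sides; branches are lateral arm pairs added to the folds
(depth 1: a pair at each fold tip; depth 2: a second pair at mid-stem).
Every object is emitted with an exact ground-truth record (polygon area and
perimeter, fold count, expected skeleton branch count) so pipeline outputs
can be checked against construction, not against themselves.

Seeding: one global integer seed drives a counter-based per-object substream
(`numpy` ``SeedSequence(seed, spawn_key=(i,))``), so adding an object never
perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from .silhouette import Silhouette

__all__ = [
    "SyntheticLamellaSpec",
    "LamellaTruth",
    "make_lamella",
    "SyntheticMeasurementSpec",
    "make_measurement_table",
    "make_study_like_table",
    "simulate_brownian_traits",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Lamella silhouettes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticLamellaSpec:
    """Parameters of one synthetic lamella silhouette.

    Lengths in mm; ``resolution`` in px/mm.  ``n_folds`` counts folds per
    side (both faces carry folds).  ``branch_depth`` 0 gives unbranched
    folds, 1 adds a pair of lateral arms at each fold tip, 2 adds a second
    pair at mid-stem height; each arm is drawn independently with
    ``branch_prob``.  The defaults leave enough lateral clearance for the
    depth-2 arm pairs at the given fold pitch.
    """

    body_length: float = 10.0
    body_width: float = 1.2
    n_folds: int = 8
    fold_length: float = 1.2
    fold_width: float = 0.25
    branch_depth: int = 0
    branch_prob: float = 1.0
    jitter_sd: float = 0.0
    resolution: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_depth not in (0, 1, 2):
            raise ValueError("branch_depth must be 0, 1 or 2")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.resolution <= 0 or self.body_length <= 0 or self.body_width <= 0:
            raise ValueError("lengths and resolution must be positive")


@dataclass(frozen=True)
class LamellaTruth:
    """Construction ground truth for one synthetic lamella."""

    area_mm2: float
    perimeter_mm: float
    n_folds: int  # total over both sides
    n_arms: int  # tip-level arms
    n_children: int  # mid-stem arms (depth 2)
    expected_branches: int
    expected_notches: int
    spec: SyntheticLamellaSpec = field(repr=False)


def _fold_positions(spec: SyntheticLamellaSpec, rng: np.random.Generator):
    """Jittered fold centres per side; top and bottom staggered by half a pitch."""
    margin = spec.body_width / 2 + spec.fold_width
    usable = spec.body_length - 2 * margin
    if spec.n_folds == 0:
        return np.array([]), np.array([])
    if spec.n_folds == 1:
        top = np.array([margin + 0.4 * usable])
        bot = np.array([margin + 0.6 * usable])
    else:
        # one shared pitch; the bottom row is shifted by half a pitch so every
        # fold base meets the central axis at its own junction
        pitch = usable / (spec.n_folds - 0.5)
        top = margin + pitch * np.arange(spec.n_folds)
        bot = top + pitch / 2
    if spec.jitter_sd > 0:
        top = top + rng.normal(0, spec.jitter_sd, size=top.size)
        bot = bot + rng.normal(0, spec.jitter_sd, size=bot.size)
    return top, bot


def make_lamella(spec: SyntheticLamellaSpec) -> tuple[Silhouette, LamellaTruth]:
    """Generate one lamella silhouette with its ground-truth record.

    Deterministic for a fixed ``spec.seed``.  If the jittered fold layout
    would make protrusions touch (a self-intersecting outline), a fresh
    substream is drawn, up to 100 times, before giving up with the violated
    constraint in the error message.
    """
    last_err = "no attempt made"
    for attempt in range(100):
        rng = _rng(spec.seed, attempt)
        result = _try_make(spec, rng)
        if isinstance(result, str):
            last_err = result
            if spec.jitter_sd == 0:
                break  # deterministic layout: retrying cannot help
            continue
        return result
    raise ValueError(f"infeasible lamella geometry after retries: {last_err}")


def _try_make(spec: SyntheticLamellaSpec, rng: np.random.Generator):
    W, L = spec.body_width, spec.body_length
    w, ell = spec.fold_width, spec.fold_length
    body = LineString([(0.0, 0.0), (L, 0.0)]).buffer(W / 2, quad_segs=16)
    parts = [body]
    top, bot = _fold_positions(spec, rng)
    n_arms = 0
    n_children = 0
    n_folds_total = 0

    if spec.n_folds > 1:
        pitch = (L - W - 2 * w) / (spec.n_folds - 0.5)  # same-side fold spacing
    else:
        pitch = L / 2
    # lateral arms from neighbouring folds must not meet: keep each tip-to-tip
    # pair short of the same-side pitch
    arm_len = max(0.0, min(0.38 * pitch - w / 2, 0.5 * ell)) if ell > 0 else 0.0

    for xs in (top, bot):
        if xs.size > 1 and np.diff(np.sort(xs)).min() < w + 2 * arm_len + 0.04:
            return "jittered folds closer than one fold width plus arm span"

    n_mid_junctions = 0
    if ell > 0:
        for side, xs in ((1, top), (-1, bot)):
            for xc in xs:
                y0 = W / 2 - w  # overlap into the body so the union is clean
                y1 = W / 2 + ell
                sgn = side
                parts.append(box(xc - w / 2, min(sgn * y0, sgn * y1), xc + w / 2, max(sgn * y0, sgn * y1)))
                n_folds_total += 1
                if spec.branch_depth >= 1 and arm_len > 0.05:
                    # arm pairs: tip pair always at depth >= 1, mid-stem pair at depth 2
                    levels = [(y1 - w, y1, "tip")]
                    if spec.branch_depth >= 2 and ell > 3 * w:
                        lo_m = W / 2 + 0.55 * ell - w / 2
                        levels.append((lo_m, lo_m + w, "mid"))
                    for lo_y, hi_y, level in levels:
                        drawn = 0
                        for direction in (-1, 1):
                            if rng.random() > spec.branch_prob:
                                continue
                            x_out = xc + direction * (w / 2 + arm_len)
                            parts.append(
                                box(
                                    min(xc, x_out),
                                    min(sgn * lo_y, sgn * hi_y),
                                    max(xc, x_out),
                                    max(sgn * lo_y, sgn * hi_y),
                                )
                            )
                            drawn += 1
                        if level == "tip":
                            n_arms += drawn
                        else:
                            n_children += drawn
                            if drawn:
                                n_mid_junctions += 1  # mid arms split the stem

    shape = unary_union(parts)
    if shape.geom_type != "Polygon":
        return "fold protrusions are disconnected from the body"
    if shape.interiors:
        return "fold protrusions enclose an interior hole"
    if not shape.is_valid:
        return "self-intersecting outline"
    coords = np.asarray(shape.exterior.coords)[:-1]
    # shift to positive quadrant with a 1-fold margin for rasterization
    shift = coords.min(axis=0) - (2 / spec.resolution)
    coords = coords - shift
    sil = Silhouette(polygon=coords, scale=1.0 / spec.resolution, id=f"synthetic-{spec.seed}")
    sil.mask = sil.to_mask()

    # staggered layout: every fold base is its own junction on the central
    # axis, so the axis splits into n_folds_total + 1 edges; each fold stem is
    # one edge (two when a mid-arm pair splits it), plus one edge per arm
    axis_edges = n_folds_total + 1
    stem_edges = n_folds_total + n_mid_junctions
    expected_branches = axis_edges + stem_edges + n_arms + n_children if n_folds_total else 1
    truth = LamellaTruth(
        area_mm2=sil.area,
        perimeter_mm=sil.perimeter,
        n_folds=max(1, n_folds_total),
        n_arms=n_arms,
        n_children=n_children,
        expected_branches=expected_branches,
        expected_notches=2 * n_folds_total,
        spec=spec,
    )
    return sil, truth


def random_star_polygon(
    rng: np.random.Generator, n_min: int = 5, n_max: int = 40
) -> np.ndarray:
    """Random simple polygon: vertices sorted by angle around an interior point.

    Angular gaps are kept below pi so the centre stays inside the polygon,
    which guarantees simplicity; radii are uniform on [0.2, 1].
    """
    n = int(rng.integers(n_min, n_max))
    while True:
        theta = np.sort(rng.uniform(0, 2 * np.pi, size=n))
        gaps = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
        if gaps.max() < 0.95 * np.pi and gaps.min() > 1e-6:
            break
    r = rng.uniform(0.2, 1.0, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMeasurementSpec:
    """Distributional parameters for a synthetic specimen table.

    Sizes are lognormal (median cm, sigma of log); lamellar numbers normal
    (clipped at 20); the true per-specimen fold increase ``p`` is drawn
    uniformly over ``pct_mean_range`` with a per-lamella sd uniform over
    ``pct_sd_range`` — the ranges printed for the study's 16 specimens.
    ``noise_sd`` adds multiplicative lognormal measurement noise to the
    semi-boundaries on top of the per-lamella biological variation.
    """

    size_cm: tuple[float, float] = (55.0, 0.5)
    lamellar_number: tuple[float, float] = (45.0, 15.0)
    area_largest_mm2: tuple[float, float] = (15.0, 0.7)
    a_small_ratio: tuple[float, float] = (0.2, 0.05)
    pct_mean_range: tuple[float, float] = (70.0, 495.0)
    pct_sd_range: tuple[float, float] = (8.5, 93.0)
    linear_length_mm: tuple[float, float] = (3.0, 0.15)
    noise_sd: float = 0.0
    round_frac: float = 0.125
    n_lamellae: int = 4
    seed: int = 0


def _lamella_pairs(
    rng: np.random.Generator,
    p_mean: float,
    p_sd: float,
    lin_mu: float,
    lin_sd: float,
    noise_sd: float,
    n: int,
) -> list[tuple[float, float]]:
    pairs = []
    for _ in range(n):
        lin = max(0.2, rng.normal(lin_mu, lin_sd))
        p = max(0.0, rng.normal(p_mean, p_sd))
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        semi = lin * (1.0 + p / 100.0) * noise
        pairs.append((lin, max(lin, semi)))
    return pairs


def _pairs_to_row(pairs: list[tuple[float, float]]) -> dict:
    row = {}
    for i, (lin, semi) in enumerate(pairs, 1):
        row[f"L_lin_{i}"] = lin
        row[f"L_semi_{i}"] = semi
    return row


def pairs_from_row(row: "pd.Series | dict") -> list[tuple[float, float]]:
    """Extract the ``(L_lin_i, L_semi_i)`` pairs from a measurement-table row."""
    pairs = []
    i = 1
    while f"L_lin_{i}" in row and not pd.isna(row[f"L_lin_{i}"]):
        pairs.append((float(row[f"L_lin_{i}"]), float(row[f"L_semi_{i}"])))
        i += 1
    return pairs


def make_measurement_table(
    spec: SyntheticMeasurementSpec, n_specimens: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a specimen measurement table plus its ground-truth side table.

    The measurement table is directly consumable by the surface-area and
    group-statistics layers; the truth table retains the generating values
    (true mean and sd of ``p``, true gross area) for recovery tests.
    """
    if n_specimens < 2:
        raise ValueError("need n_specimens >= 2")
    rows, truths = [], []
    for i in range(n_specimens):
        rng = _rng(spec.seed, 1, i)
        raphe = "round" if rng.random() < spec.round_frac else "elongated"
        size = float(spec.size_cm[0] * np.exp(rng.normal(0, spec.size_cm[1])))
        ln = int(max(20, round(rng.normal(*spec.lamellar_number))))
        a_l = float(spec.area_largest_mm2[0] * np.exp(rng.normal(0, spec.area_largest_mm2[1])))
        ratio = float(np.clip(rng.normal(*spec.a_small_ratio), 0.02, 0.9))
        a_s = a_l * ratio
        p_mean = float(rng.uniform(*spec.pct_mean_range))
        p_sd = float(rng.uniform(*spec.pct_sd_range))
        pairs = _lamella_pairs(
            rng, p_mean, p_sd, *spec.linear_length_mm, spec.noise_sd, spec.n_lamellae
        )
        if raphe == "round":
            gross = 2.0 * a_l * ln
        else:
            gross = 2.0 * a_l * 0.7 * ln + 2.0 * a_s * 0.3 * ln
        pcts = [100.0 * (s - l) / l for l, s in pairs]
        row = {
            "specimen": f"S{i:03d}",
            "size_cm": size,
            "size_kind": "TL",
            "raphe_type": raphe,
            "lamellar_number": ln,
            "area_largest_mm2": a_l,
            "area_smallest_mm2": None if raphe == "round" else a_s,
            "w_max": 0.7,
            "pct_increase": float(np.mean(pcts)),
            "pct_increase_sd": float(np.std(pcts, ddof=1)),
        }
        row.update(_pairs_to_row(pairs))
        rows.append(row)
        truths.append(
            {
                "specimen": f"S{i:03d}",
                "true_p_mean": p_mean,
                "true_p_sd": p_sd,
                "true_gross_area_mm2": gross,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truths)


def make_study_like_table(
    seed: int = 0, noise_sd: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-lamella measurements matched to the study's 16 specimens.

    Sizes, lamellar numbers, raphe types and gross areas are taken from the
    embedded study table; the four per-lamella (linear, semi-boundary) pairs
    are drawn with the specimen's printed mean and sd of the percentage
    increase, which the study itself does not publish at lamella level.
    """
    from .datasets import load_measurements

    study = load_measurements()
    rows, truths = [], []
    for i, (_, srow) in enumerate(study.iterrows()):
        rng = _rng(seed, 2, i)
        pairs = _lamella_pairs(
            rng,
            float(srow["pct_increase"]),
            float(srow["pct_increase_sd"]),
            3.0,
            0.15,
            noise_sd,
            4,
        )
        pcts = [100.0 * (s - l) / l for l, s in pairs]
        row = {
            "specimen": srow["specimen"],
            "size_cm": srow["size_cm"],
            "size_kind": srow["size_kind"],
            "raphe_type": srow["raphe_type"],
            "lamellar_number": srow["lamellar_number"],
            "area_largest_mm2": srow["area_largest_mm2"],
            "gross_area_mm2": srow["gross_area_mm2"],
            "pct_increase": float(np.mean(pcts)),
            "pct_increase_sd": float(np.std(pcts, ddof=1)),
        }
        row.update(_pairs_to_row(pairs))
        rows.append(row)
        truths.append(
            {
                "specimen": srow["specimen"],
                "true_p_mean": float(srow["pct_increase"]),
                "true_p_sd": float(srow["pct_increase_sd"]),
                "true_gross_area_mm2": float(srow["gross_area_mm2"]),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# Brownian trait simulation
# ---------------------------------------------------------------------------


def _psd_sqrt(M: np.ndarray, name: str) -> np.ndarray:
    evals, evecs = np.linalg.eigh(M)
    if evals.min() < -1e-8 * max(1.0, abs(evals).max()):
        raise ValueError(f"{name} is not positive semi-definite")
    return evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T


def simulate_brownian_traits(
    tree_or_C, sigma: np.ndarray, seed: int = 0, trait_names: list[str] | None = None
) -> pd.DataFrame:
    """Simulate correlated traits evolving by Brownian motion on a tree.

    ``X = L_C Z L_S'`` with ``C = L_C L_C'`` the tip covariance and
    ``sigma = L_S L_S'`` the trait covariance: a matrix-normal draw with row
    covariance from the phylogeny and column covariance ``sigma``.
    Deterministic per seed.
    """
    from .phylo_pca import PhyloTree

    if isinstance(tree_or_C, PhyloTree):
        C = tree_or_C.covariance()
    else:
        C = tree_or_C
    tips = list(C.index)
    Cm = C.to_numpy(float)
    S = np.asarray(sigma, float)
    m = S.shape[0]
    Lc = _psd_sqrt(Cm, "tip covariance")
    Ls = _psd_sqrt(S, "trait covariance")
    rng = _rng(seed, 3)
    Z = rng.standard_normal((len(tips), m))
    X = Lc @ Z @ Ls.T
    if trait_names is None:
        trait_names = [f"trait_{j + 1}" for j in range(m)]
    return pd.DataFrame(X, index=tips, columns=trait_names)
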