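"""Olfactory surface-area arithmetic.

The olfactory organ is an array of two-faced primary lamellae around a raphe.
Gross surface area ignores secondary folds: for a *round* raphe (lamellae of
homogeneous size) it is ``2 * a_L * LN``; for an *elongated* raphe the largest
and a smallest lamella bracket the size gradient and are combined with a
weight ``w_max`` on the lamellar number (default 0.7, presets 0.6 for bent
and 0.8 for linear raphes).  The percentage increase due to secondary folds is
measured in histological section as the excess of the epithelial semi-boundary
over the straight (linear) lamellar length, averaged over four lamellae, and
scales the gross area to a fold-inclusive estimate.  Areas are compared across
body sizes as ``100 * area_mm2 / size_cm**2`` (the study's mixed-unit
convention, preserved as such).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenMeasurements",
    "AreaWeights",
    "gross_area_round",
    "gross_area_elongated",
    "pct_increase",
    "specimen_pct_increase",
    "area_with_folds",
    "normalize_area",
    "round_half_up",
    "compute_area_table",
    "plot_normalized_areas",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as in the study's reported tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AreaWeights:
    """Fraction of the lamellar number attributed to the largest lamella."""

    w_max: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.w_max < 1.0):
            raise ValueError(f"w_max must be in (0, 1), got {self.w_max}")

    @property
    def w_min(self) -> float:
        return 1.0 - self.w_max


#: presets for elongated raphes: bent (e.g. Greenland shark) and linear (blue shark)
W_MAX_BENT = 0.6
W_MAX_LINEAR = 0.8


@dataclass
class SpecimenMeasurements:
    """Anatomical measurements for one specimen (one row of the study table)."""

    id: str
    size_cm: float
    size_kind: str  # TL | SL | DW
    raphe_type: str  # round | elongated
    lamellar_number: int
    area_largest_mm2: float
    area_smallest_mm2: float | None = None
    epithelium_pairs: list[tuple[float, float]] = field(default_factory=list)
    w_max: float = 0.7

    def __post_init__(self) -> None:
        if self.lamellar_number < 1:
            raise ValueError("lamellar number must be >= 1")
        if self.area_largest_mm2 <= 0:
            raise ValueError("largest-lamella area must be > 0")
        if (
            self.area_smallest_mm2 is not None
            and self.area_smallest_mm2 > self.area_largest_mm2
        ):
            raise ValueError("smallest-lamella area exceeds largest-lamella area")
        for lin, semi in self.epithelium_pairs:
            if semi < lin:
                raise ValueError("semi-boundary shorter than linear length")

    def gross_area(self) -> float:
        if self.raphe_type == "round":
            return gross_area_round(self.area_largest_mm2, self.lamellar_number)
        if self.area_smallest_mm2 is None:
            raise ValueError(
                f"{self.id}: elongated raphe needs a smallest-lamella area"
            )
        return gross_area_elongated(
            self.area_largest_mm2,
            self.area_smallest_mm2,
            self.lamellar_number,
            AreaWeights(self.w_max),
        )


def gross_area_round(a_largest: float, lamellar_number: int) -> float:
    """Gross area for a round raphe: ``2 * a_L * LN`` (both lamella faces)."""
    if a_largest <= 0:
        raise ValueError("lamella area must be > 0")
    if lamellar_number < 1:
        raise ValueError("lamellar number must be >= 1")
    return 2.0 * a_largest * lamellar_number


def gross_area_elongated(
    a_largest: float,
    a_smallest: float,
    lamellar_number: int,
    weights: AreaWeights | float = AreaWeights(),
) -> float:
    """Gross area for an elongated raphe, weighting large vs small lamellae.

    ``2*a_L*(w_max*LN) + 2*a_S*((1-w_max)*LN)``.  The default ``w_max = 0.7``
    averages the bent-raphe (0.6) and linear-raphe (0.8) presets; using the
    presets brackets the default from below and above when ``a_L > a_S``.
    """
    if isinstance(weights, (int, float)):
        weights = AreaWeights(float(weights))
    if a_smallest > a_largest:
        raise ValueError("smallest-lamella area exceeds largest-lamella area")
    if a_smallest <= 0:
        raise ValueError("lamella areas must be > 0")
    return 2.0 * a_largest * weights.w_max * lamellar_number + 2.0 * a_smallest * (
        weights.w_min * lamellar_number
    )


def pct_increase(linear_mm: float, semi_boundary_mm: float) -> float:
    """Percent excess of the fold-inclusive semi-boundary over the linear length."""
    if linear_mm <= 0:
        raise ValueError("linear length must be > 0")
    if semi_boundary_mm < linear_mm:
        raise ValueError("semi-boundary shorter than linear length")
    return 100.0 * (semi_boundary_mm - linear_mm) / linear_mm


def specimen_pct_increase(
    pairs: list[tuple[float, float]]
) -> tuple[float, float]:
    """Mean and sample sd of the per-lamella percentage increases.

    Four lamellae per specimen is the canonical design; at least two are
    required for the sample standard deviation to exist.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 (linear, semi-boundary) pairs for mean and sd")
    pcts = np.array([pct_increase(lin, semi) for lin, semi in pairs])
    return float(pcts.mean()), float(pcts.std(ddof=1))


def area_with_folds(gross_area_mm2: float, pct: float) -> float:
    """Scale the gross area by the measured fold-driven percentage increase."""
    if pct < 0:
        raise ValueError("percentage increase must be >= 0")
    return gross_area_mm2 * (1.0 + pct / 100.0)


def normalize_area(area_mm2: float, size_cm: float) -> float:
    """Size-normalized area: ``100 * area_mm2 / size_cm**2``.

    The mm^2 / cm^2 mixed units are the study's reporting convention and are
    preserved bit-for-bit; batoids are normalized by disk width, all other
    specimens by total (or standard) length, and the two kinds must not be
    compared directly.
    """
    if size_cm <= 0:
        raise ValueError("size must be > 0")
    return 100.0 * area_mm2 / size_cm**2


def compute_area_table(df: pd.DataFrame, check_size_kinds: bool = True) -> pd.DataFrame:
    """Recompute every derived area column of a measurement table.

    ``df`` needs columns ``specimen, size_cm, size_kind, raphe_type,
    lamellar_number, area_largest_mm2, pct_increase`` and, for elongated-raphe
    rows with no precomputed ``gross_area_mm2``, ``area_smallest_mm2``
    (optionally ``w_max``).  Derived columns are returned at full precision;
    apply :func:`round_half_up` at report time.
    """
    if check_size_kinds and df["size_kind"].nunique() > 1:
        kinds = sorted(df["size_kind"].unique())
        warnings.warn(
            f"mixed size kinds {kinds}: normalized areas are only comparable "
            "within one size kind",
            stacklevel=2,
        )
    out = df.copy()
    gross = []
    has_gross = "gross_area_mm2" in df.columns
    for _, row in df.iterrows():
        if has_gross and pd.notna(row["gross_area_mm2"]):
            gross.append(float(row["gross_area_mm2"]))
        elif row["raphe_type"] == "round":
            gross.append(gross_area_round(row["area_largest_mm2"], int(row["lamellar_number"])))
        else:
            gross.append(
                gross_area_elongated(
                    row["area_largest_mm2"],
                    row["area_smallest_mm2"],
                    int(row["lamellar_number"]),
                    AreaWeights(float(row.get("w_max", 0.7) or 0.7)),
                )
            )
    out["gross_area_mm2"] = gross
    out["folds_area_mm2"] = [
        area_with_folds(g, p) for g, p in zip(out["gross_area_mm2"], out["pct_increase"])
    ]
    out["rel_area_largest"] = [
        normalize_area(a, s) for a, s in zip(out["area_largest_mm2"], out["size_cm"])
    ]
    out["rel_gross_area"] = [
        normalize_area(a, s) for a, s in zip(out["gross_area_mm2"], out["size_cm"])
    ]
    out["rel_folds_area"] = [
        normalize_area(a, s) for a, s in zip(out["folds_area_mm2"], out["size_cm"])
    ]
    return out


def plot_normalized_areas(df: pd.DataFrame, ax=None):
    """Grouped bar chart of normalized gross vs fold-inclusive areas.

    Error bars on the fold-inclusive bars propagate the sd of the percentage
    increase (``pct_increase_sd`` column, if present).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(df), 4))
    x = np.arange(len(df))
    gross = df["rel_gross_area"].to_numpy(float)
    folds = df["rel_folds_area"].to_numpy(float)
    err = None
    if "pct_increase_sd" in df.columns:
        err = (
            df["rel_gross_area"].to_numpy(float)
            * df["pct_increase_sd"].to_numpy(float)
            / 100.0
        )
    ax.bar(x - 0.2, gross, width=0.4, color="0.8", edgecolor="k", label="gross")
    ax.bar(
        x + 0.2,
        folds,
        width=0.4,
        color="0.4",
        edgecolor="k",
        yerr=err,
        capsize=3,
        label="with secondary folds",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(df["specimen"], rotation=45, ha="right")
    ax.set_ylabel(r"$100 \cdot$ area (mm$^2$) / size$^2$ (cm$^2$)")
    ax.legend(frameon=False)
    return ax
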