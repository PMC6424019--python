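"""Significance tests on the fold-driven epithelial length increase.

Two layers: a per-specimen one-way ANOVA comparing the linear lamellar
lengths against the fold-inclusive semi-boundaries (with two groups this is
the unpaired t-test, ``F = t**2``; a paired alternative is offered), and an
all-pairs comparison of per-specimen mean percentage increases via one-way
ANOVA followed by Tukey's HSD (Tukey-Kramer for unbalanced groups), reported
as a symmetric star matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAR_THRESHOLDS",
    "star_code",
    "epithelium_increase_test",
    "tukey_matrix",
    "SignificanceMatrix",
]

#: decade scheme for the star codes (the study's 5-star scale is undefined;
#: this standard mapping is used and documented)
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (1e-5, "*****"),
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
    (1e-1, "."),
)


def star_code(p: float) -> str:
    """Map a p-value to its significance stars (empty string if p >= 0.1)."""
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            return code
    return ""


def epithelium_increase_test(
    pairs: list[tuple[float, float]], paired: bool = False
) -> tuple[float, float]:
    """Test whether semi-boundaries exceed linear lengths for one specimen.

    One-way ANOVA between the linear-length group and the semi-boundary group
    (canonically 2 groups x 4 lamellae); returns ``(F, p)``.  ``paired=True``
    switches to a paired t-test on the per-lamella differences (returned on
    the same ``(F, p)`` scale with ``F = t**2``).
    """
    if len(pairs) < 2:
        raise ValueError("need measurements from >= 2 lamellae")
    linear = np.array([p[0] for p in pairs], dtype=float)
    semi = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(linear.std(), 0) and np.allclose(semi.std(), 0):
        if np.allclose(linear.mean(), semi.mean()):
            return 0.0, 1.0
        # exact separation: zero within-group variance with distinct means
        return float("inf"), float(np.finfo(float).tiny)
    if paired:
        t, p = stats.ttest_rel(semi, linear)
        return float(t**2), float(p)
    f, p = stats.f_oneway(linear, semi)
    return float(f), float(p)


@dataclass
class SignificanceMatrix:
    """All-pairs Tukey HSD result: symmetric p-value and star-code matrices."""

    p_values: pd.DataFrame
    stars: pd.DataFrame
    anova_f: float
    anova_p: float

    def to_long(self) -> pd.DataFrame:
        """Long-format table with one row per unordered group pair."""
        rows = []
        names = list(self.p_values.index)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "p_value": self.p_values.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def tukey_matrix(groups: dict[str, "np.ndarray | list[float]"]) -> SignificanceMatrix:
    """One-way ANOVA across groups followed by Tukey's HSD on every pair.

    ``groups`` maps a label (e.g. specimen id) to its per-lamella percentage
    increases.  Unbalanced groups use the Tukey-Kramer correction; groups with
    a single value are rejected.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays.append(arr)
    f, p_anova = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    n = len(names)
    pmat = pd.DataFrame(np.ones((n, n)), index=names, columns=names)
    smat = pd.DataFrame([[""] * n for _ in range(n)], index=names, columns=names)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pij = float(res.pvalue[i, j])
            pmat.iloc[i, j] = pij
            smat.iloc[i, j] = star_code(pij)
    return SignificanceMatrix(
        p_values=pmat, stars=smat, anova_f=float(f), anova_p=float(p_anova)
    )
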