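"""Agreement between automatic and manual fly counts.

Three metrics: the fraction of images where the automatic count matches
the manual one or is off by one, the fraction where they agree within
three individuals, and the Pearson correlation between the two counts
(overall, and per group such as experiment date).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CountPair", "ValidationReport", "validate", "significance_of_r"]


@dataclass(frozen=True)
class CountPair:
    """Automatic and manual count of the same image."""

    image_id: str
    group: str
    auto: int
    manual: int

    def __post_init__(self) -> None:
        if self.auto < 0 or self.manual < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ValidationReport:
    n: int
    frac_within_1: float
    frac_within_3: float
    pearson_r: float | None          # None when a column has zero variance
    per_group_r: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        rows = [("overall", self.pearson_r)] + sorted(self.per_group_r.items())
        return pd.DataFrame(rows, columns=["group", "pearson_r"]).assign(
            n=self.n,
            frac_within_1=self.frac_within_1,
            frac_within_3=self.frac_within_3,
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Product-moment correlation; None when undefined (zero variance)."""
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def validate(pairs: list[CountPair] | pd.DataFrame) -> ValidationReport:
    """Compute the discrepancy fractions and correlations for count pairs.

    Accepts a list of :class:`CountPair` or a data frame with columns
    ``group``, ``auto``, ``manual``.  The overall correlation pools all
    pairs; per-group correlations are reported for groups with at least two
    pairs.  Degenerate groups (zero variance) get ``None`` rather than an
    exception.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        df = pd.DataFrame(
            [(p.group, p.auto, p.manual) for p in pairs],
            columns=["group", "auto", "manual"],
        )
    if len(df) == 0:
        raise ValueError("no count pairs supplied")
    if (df["auto"] < 0).any() or (df["manual"] < 0).any():
        raise ValueError("counts must be non-negative")

    diff = (df["auto"] - df["manual"]).abs()
    auto = df["auto"].to_numpy(dtype=float)
    manual = df["manual"].to_numpy(dtype=float)
    per_group = {
        str(g): _pearson(
            sub["auto"].to_numpy(float), sub["manual"].to_numpy(float)
        )
        for g, sub in df.groupby("group")
        if len(sub) >= 2
    }
    return ValidationReport(
        n=len(df),
        frac_within_1=float((diff <= 1).mean()),
        frac_within_3=float((diff <= 3).mean()),
        pearson_r=_pearson(auto, manual),
        per_group_r=per_group,
    )


def significance_of_r(r: float, n: int) -> tuple[float, bool]:
    """Two-sided p-value of a Pearson correlation via the t transform.

    Uses ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom.
    Returns ``(p, exact)`` where ``exact`` flags the degenerate |r| = 1
    case, for which p = 0 is returned directly.
    """
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        return 0.0, True
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(p), False
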