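"""Group summaries and Welch two-sample t-screening of the band features.

The t statistic uses unpooled variances, ``t = (m1 - m2) / sqrt(s1²/n1 +
s2²/n2)``, with Welch-Satterthwaite (fractional) degrees of freedom and a
two-sided p-value.  ``welch_t_from_summary`` works from printed summary
statistics; ``welch_t_from_samples`` reduces the raw samples to their
summaries and delegates, so the two routes agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .epoch import BANDS
from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "welch_t_from_summary",
    "welch_t_from_samples",
    "band_ttests",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    band: str = ""


@dataclass(frozen=True)
class GroupSummary:
    """Per-band (mean, sd, n) per group, percent scale."""

    table: pd.DataFrame  # columns: band, group, n, mean, sd


def summarize(features: pd.DataFrame) -> GroupSummary:
    """Per-group, per-band sample mean and SD (n-1 denominator)."""
    groups = sorted(features["group"].unique())
    if len(groups) < 2:
        raise InvalidInputError("summary requires both groups to be present")
    rows = []
    for band in BANDS:
        col = f"{band}_pct"
        for group in groups:
            values = features.loc[features["group"] == group, col].to_numpy()
            if values.size < 2:
                raise InvalidInputError(f"group {group!r} needs n >= 2 epochs")
            rows.append(
                {
                    "band": band,
                    "group": group,
                    "n": int(values.size),
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)),
                }
            )
    return GroupSummary(table=pd.DataFrame(rows))


def welch_t_from_summary(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    band: str = "",
) -> TTestResult:
    """Welch t-test from the two groups' (mean, sd, n) summaries."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("Welch t-test requires n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise InvalidInputError("standard deviations must be nonnegative")
    if s1 == 0 and s2 == 0:
        raise InvalidInputError(
            "both group variances are zero: t statistic undefined"
        )
    v1 = s1 * s1 / n1
    v2 = s2 * s2 / n2
    se2 = v1 + v2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 * se2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, band=band)


def welch_t_from_samples(x1, x2, band: str = "") -> TTestResult:
    """Welch t-test on raw samples (delegates to the summary route)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise InvalidInputError("Welch t-test requires n >= 2 per group")
    return welch_t_from_summary(
        float(x1.mean()), float(x1.std(ddof=1)), int(x1.size),
        float(x2.mean()), float(x2.std(ddof=1)), int(x2.size),
        band=band,
    )


def band_ttests(
    features: pd.DataFrame,
    group_order: tuple[str, str] = ("normal", "encephalopathy"),
) -> pd.DataFrame:
    """Per-band Welch t-tests across the two groups of a feature table."""
    g1, g2 = group_order
    rows = []
    for band in BANDS:
        col = f"{band}_pct"
        res = welch_t_from_samples(
            features.loc[features["group"] == g1, col],
            features.loc[features["group"] == g2, col],
            band=band,
        )
        rows.append({"band": band, "t": res.t, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)
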