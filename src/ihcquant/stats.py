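"""Marker co-localization statistics.

Per-sample stain fractions for a proliferation marker (Ki-67, epithelial
compartment) and a vascular marker (CD31, stromal compartment) are
combined into the proliferative vascular index, PVI = Ki-67 fraction /
CD31 fraction. Samples are grouped by Gleason score — low (<= 7) versus
high (>= 8) — and each endpoint (Ki-67, CD31, PVI) is compared between
groups with a two-tailed two-sample Student's t-test (pooled variance,
df = n1 + n2 - 2) at significance level 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MarkerPair",
    "GleasonGroup",
    "GroupComparison",
    "compute_pvi",
    "categorize_gleason",
    "compare_groups",
    "marker_summary",
    "analyze_marker_table",
    "join_marker_tables",
]

log = logging.getLogger(__name__)


class GleasonGroup(Enum):
    LOW = "low"  # Gleason 6 or 7
    HIGH = "high"  # Gleason 8+


@dataclass(frozen=True)
class MarkerPair:
    """Paired stain fractions for one sample."""

    sample_id: str
    ki67_fraction: float
    cd31_fraction: float
    gleason: int

    def __post_init__(self) -> None:
        for name in ("ki67_fraction", "cd31_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gleason < 6:
            log.warning(
                "sample %s has Gleason %d, below the usual cohort range 6-10",
                self.sample_id,
                self.gleason,
            )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Student's t-test result."""

    group_low: tuple[float, ...]
    group_high: tuple[float, ...]
    t_stat: float
    df: float
    p_value: float
    alpha_level: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_level


def compute_pvi(pair: MarkerPair) -> float:
    """Proliferative vascular index: Ki-67 fraction over CD31 fraction."""
    if pair.cd31_fraction == 0:
        raise ZeroDivisionError(
            f"sample {pair.sample_id}: CD31 fraction is 0, PVI undefined"
        )
    return pair.ki67_fraction / pair.cd31_fraction


def categorize_gleason(score: int) -> GleasonGroup:
    """LOW for Gleason <= 7, HIGH for >= 8."""
    if not isinstance(score, (int, np.integer)):
        raise TypeError(f"Gleason score must be an integer, got {score!r}")
    if not (2 <= score <= 10):
        raise ValueError(f"Gleason score {score} outside the valid range 2-10")
    return GleasonGroup.LOW if score <= 7 else GleasonGroup.HIGH


def compare_groups(
    group_low,
    group_high,
    alpha_level: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t-test between the low and high groups.

    Equal-variance (pooled) Student's t by default; ``welch=True``
    switches to the unequal-variance form for sensitivity analysis.
    """
    a = np.asarray(group_low, dtype=float)
    b = np.asarray(group_high, dtype=float)
    for name, g in (("low", a), ("high", b)):
        if g.size < 2:
            raise ValueError(f"group '{name}' needs at least 2 values, got {g.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = a.size + b.size - 2
    return GroupComparison(
        group_low=tuple(a),
        group_high=tuple(b),
        t_stat=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        alpha_level=alpha_level,
    )


def marker_summary(pairs: list[MarkerPair]) -> pd.DataFrame:
    """Per-category mean and SD for Ki-67, CD31 and PVI.

    Rows ordered LOW then HIGH. Samples with CD31 = 0 are excluded from
    the PVI column (logged), never silently zeroed. SD is NaN for
    single-sample categories.
    """
    if not pairs:
        raise ValueError("no marker pairs")
    rows = []
    for p in pairs:
        try:
            pvi = compute_pvi(p)
        except ZeroDivisionError as e:
            log.warning("excluding from PVI summary: %s", e)
            pvi = np.nan
        rows.append(
            {
                "sample_id": p.sample_id,
                "group": categorize_gleason(p.gleason).value,
                "ki67": p.ki67_fraction,
                "cd31": p.cd31_fraction,
                "pvi": pvi,
            }
        )
    df = pd.DataFrame(rows)
    present = df["group"].unique()
    for grp in (GleasonGroup.LOW, GleasonGroup.HIGH):
        if grp.value not in present:
            raise ValueError(f"no samples in Gleason category '{grp.value}'")
    summary = (
        df.groupby("group")[["ki67", "cd31", "pvi"]]
        .agg(["mean", "std", "count"])
        .reindex([GleasonGroup.LOW.value, GleasonGroup.HIGH.value])
    )
    return summary


def analyze_marker_table(
    pairs: list[MarkerPair], alpha_level: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Group comparison for each endpoint: ki67, cd31, pvi.

    Returns one row per endpoint with t, df, p and the significance flag.
    """
    low_k, high_k, low_c, high_c, low_p, high_p = [], [], [], [], [], []
    for p in pairs:
        grp = categorize_gleason(p.gleason)
        (low_k if grp is GleasonGroup.LOW else high_k).append(p.ki67_fraction)
        (low_c if grp is GleasonGroup.LOW else high_c).append(p.cd31_fraction)
        try:
            pvi = compute_pvi(p)
        except ZeroDivisionError as e:
            log.warning("excluding from PVI comparison: %s", e)
            continue
        (low_p if grp is GleasonGroup.LOW else high_p).append(pvi)
    rows = []
    for endpoint, lo, hi in (
        ("ki67", low_k, high_k),
        ("cd31", low_c, high_c),
        ("pvi", low_p, high_p),
    ):
        cmp = compare_groups(lo, hi, alpha_level=alpha_level, welch=welch)
        rows.append(
            {
                "endpoint": endpoint,
                "n_low": len(lo),
                "n_high": len(hi),
                "mean_low": float(np.mean(lo)),
                "mean_high": float(np.mean(hi)),
                "t": cmp.t_stat,
                "df": cmp.df,
                "p": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    return pd.DataFrame(rows)


def join_marker_tables(
    ki67: pd.DataFrame, cd31: pd.DataFrame, gleason: pd.DataFrame
) -> list[MarkerPair]:
    """Join two per-image quantification tables and a Gleason table.

    All three are keyed on ``sample_id`` (quantification tables use
    their ``image_id`` column as the key; ``stain_fraction`` carries the
    measurement).
    """

    def prep(df: pd.DataFrame, name: str) -> pd.DataFrame:
        key = "sample_id" if "sample_id" in df.columns else "image_id"
        return df[[key, "stain_fraction"]].rename(
            columns={key: "sample_id", "stain_fraction": name}
        )

    merged = prep(ki67, "ki67_fraction").merge(
        prep(cd31, "cd31_fraction"), on="sample_id"
    )
    merged = merged.merge(gleason[["sample_id", "gleason"]], on="sample_id")
    return [
        MarkerPair(
            sample_id=str(r.sample_id),
            ki67_fraction=float(r.ki67_fraction),
            cd31_fraction=float(r.cd31_fraction),
            gleason=int(r.gleason),
        )
        for r in merged.itertuples()
    ]
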