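"""Join differential transcription with feature-linked DMRs and test the
methylation-expression relationship.

The join is by gene identifier between a DET table and DMR-feature links
already deduplicated to one DMR per feature.  By default only CHH-context
DMRs are considered (the dominant and de-novo-maintained context) and only
transcripts with |log2 ratio| >= 1.5.  Reporting follows the scatterplot
convention: records are stratified by DMR position class and summarised as
quadrant shares over (sign of delta_mC x sign of ratio); the association is
tested by the correlation route — R^2 of the least-squares regression of
ratio on delta_mC, r = sign(slope) * sqrt(R^2), and a Student t-test of r
with n - 2 degrees of freedom.  For small samples (n < 50) an F-ratio
variance-homogeneity statistic between the two plotted variables is reported
alongside; it annotates, and never gates, the correlation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["IntegrationParams", "CorrelationResult", "join_dtg_dmr",
           "quadrant_summary", "correlation_test"]

QUADRANTS = ("hypo_up", "hypo_down", "hyper_up", "hyper_down")


@dataclass
class IntegrationParams:
    contexts: tuple = ("CHH",)
    min_abs_ratio: float = 1.5   # log2 units
    flank_small_n: int = 50      # below this, report the variance pre-check

    def __post_init__(self):
        if self.min_abs_ratio < 0:
            raise ValueError("min_abs_ratio must be >= 0")


@dataclass
class CorrelationResult:
    n: int
    r_squared: float
    r: float
    t: float
    p_value: float
    variance_test_p: float = float("nan")
    defined: bool = True


def join_dtg_dmr(dets, links, params=None):
    """Inner join of DETs with per-feature-deduplicated DMR links.

    Raises if ``links`` still carries a duplicated feature (the dedupe
    contract).  Records failing the context filter or the |ratio| threshold
    are dropped; output carries one row per gene with delta_mC, ratio,
    position class and kind.
    """
    params = params or IntegrationParams()
    if links["feature_id"].duplicated().any():
        dup = links.loc[links["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"links not deduplicated: feature {dup!r} appears twice")
    kept_links = links[links["context"].isin(params.contexts)]
    kept_dets = dets[dets["ratio"].abs() >= params.min_abs_ratio]
    joined = kept_dets.merge(kept_links, left_on="transcript_id",
                             right_on="feature_id", how="inner",
                             suffixes=("_det", ""))
    cols = ["transcript_id", "kind", "ratio", "p_value_det", "chrom", "dmr_start",
            "dmr_end", "context", "delta_mc", "direction", "position_class",
            "distance"]
    if "p_value_det" not in joined.columns:  # no column clash when links lack p
        joined = joined.rename(columns={"p_value": "p_value_det"})
    joined = joined.reindex(columns=cols)
    return joined.sort_values("transcript_id", kind="mergesort", ignore_index=True)


def quadrant_summary(records, by="position_class"):
    """Percentage of records per (sign delta_mC x sign ratio) quadrant.

    Returns ``{group: {quadrant: pct}}`` plus a ``"all"`` pooled entry; groups
    with no records map to None (undefined, not zeros).  Percentages within a
    group sum to 100.
    """
    def _one(df):
        if len(df) == 0:
            return None
        hypo = df["delta_mc"] < 0
        up = df["ratio"] > 0
        counts = {
            "hypo_up": int((hypo & up).sum()),
            "hypo_down": int((hypo & ~up).sum()),
            "hyper_up": int((~hypo & up).sum()),
            "hyper_down": int((~hypo & ~up).sum()),
        }
        total = sum(counts.values())
        return {q: 100.0 * c / total for q, c in counts.items()}

    out = {"all": _one(records)}
    if by is not None and len(records):
        for group in sorted(records[by].unique()):
            out[group] = _one(records[records[by] == group])
    return out


def correlation_test(records, params=None):
    """Correlation of expression ratio with methylation change.

    Least-squares regression of ratio on delta_mC; R^2 = 1 - SSres/SStot;
    r = sign(slope) * sqrt(R^2); t = r * sqrt((n-2)/(1-R^2)) tested two-sided
    against Student's law with n-2 df.  With n below ``flank_small_n`` the
    F ratio var(delta_mC)/var(ratio) and its two-sided p are reported as a
    variance-homogeneity annotation.
    """
    params = params or IntegrationParams()
    x = np.asarray(records["delta_mc"], float)
    y = np.asarray(records["ratio"], float)
    n = len(x)
    if n < 3:
        raise ValueError("correlation_test needs n >= 3 records")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(n, math.nan, math.nan, math.nan, math.nan,
                                 defined=False)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    r = math.copysign(math.sqrt(r2), slope) if slope != 0 else 0.0
    if r2 >= 1.0:
        t = math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    var_p = math.nan
    if n < params.flank_small_n:
        f = np.var(x, ddof=1) / np.var(y, ddof=1)
        tail = stats.f.sf(f, n - 1, n - 1)
        var_p = float(2.0 * min(tail, 1.0 - tail))
    return CorrelationResult(n=n, r_squared=r2, r=r, t=t, p_value=p,
                             variance_test_p=var_p)
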