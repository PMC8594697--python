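"""Sliding-window differential-methylation calling with replicate SDA filtering.

The unit of testing is a 200-bp window advanced in 100-bp steps, per cytosine
context (CG/CHG/CHH).  For every replicate the window methylation level is
the unweighted mean of per-site ``n_meth/n_total`` ratios over context sites
covered by at least ``min_site_coverage`` reads; a window is *defined* for a
replicate when it holds at least ``min_sites_per_window`` such sites.  Windows
defined in every replicate of both groups are tested with a two-sample t-test
on the replicate levels; the reported effect is

    delta_mC = mean(test levels) - mean(reference levels)   [percentage points]

so hypomethylation in the test condition has negative sign.  SDA ("standard
deviation of averages") is the sample standard deviation of each group's
replicate window levels and acts as a reproducibility filter: windows whose
SDA exceeds a per-context threshold in either group are discarded regardless
of p-value.  Each surviving significant window is reported as one DMR;
overlapping windows are deliberately not merged (an optional post-hoc merge
is provided).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS

logger = logging.getLogger(__name__)

__all__ = [
    "DmrCallParams", "MethylomeSet", "DmrSummary",
    "global_methylation_levels", "enumerate_windows", "window_replicate_level",
    "test_window", "window_stats", "call_dmrs", "summarize_dmrs", "merge_dmrs",
    "dmr_density", "round_half_away",
]


def _default_sda():
    # per-context reproducibility ceilings, percentage points; user-settable
    return {"CG": 10.0, "CHG": 10.0, "CHH": 5.0}


@dataclass
class DmrCallParams:
    """Tunables of the window caller (defaults follow the study's run)."""

    window_size: int = 200          # bp
    step: int = 100                 # bp
    min_site_coverage: int = 3      # reads per cytosine
    min_sites_per_window: int = 4   # eligible cytosines per window
    p_threshold: float = 0.01
    sda_threshold: dict = field(default_factory=_default_sda)  # pp, per context
    min_abs_delta: float = 0.0      # pp
    stat: str = "student"           # 'student' | 'welch' | 'fisher'

    def __post_init__(self):
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if self.step <= 0 or self.window_size <= 0:
            raise ValueError("window_size and step must be positive")
        if self.p_threshold < 0 or self.min_abs_delta < 0:
            raise ValueError("thresholds must be >= 0")
        if any(v < 0 for v in self.sda_threshold.values()):
            raise ValueError("SDA thresholds must be >= 0")
        if self.stat not in ("student", "welch", "fisher"):
            raise ValueError(f"unknown stat {self.stat!r}")

    def with_(self, **kw) -> "DmrCallParams":
        return replace(self, **kw)


@dataclass
class MethylomeSet:
    """One condition's replicated methylome: an ordered set of call tables."""

    condition: str
    samples: dict  # sample_id -> calls DataFrame (io.read_methylation_calls layout)

    def __post_init__(self):
        if not self.samples:
            raise ValueError(f"condition {self.condition!r} has no replicates")

    @property
    def sample_ids(self):
        return list(self.samples)

    @property
    def n_replicates(self):
        return len(self.samples)

    def chroms(self):
        out = set()
        for df in self.samples.values():
            out.update(df["chrom"].unique())
        return out

    def chrom_lengths(self):
        """Smallest per-chrom length covering every observed site."""
        lengths = {}
        for df in self.samples.values():
            for chrom, mx in df.groupby("chrom", observed=True)["pos"].max().items():
                lengths[chrom] = max(lengths.get(chrom, 0), int(mx))
        return lengths


# ---------------------------------------------------------------------------
# genome-wide averages

def global_methylation_levels(methylomes, min_site_coverage=3):
    """Genome-wide per-context methylation averages and pairwise t-tests.

    Per replicate the level is the unweighted mean of per-site ratios over
    sites with ``n_total >= min_site_coverage``, in percent.  Contexts with no
    qualifying site in a replicate are NaN (undefined, never coerced to 0).

    Returns ``(levels, tests)``: per-replicate/per-condition levels and a
    pairwise pooled-variance Student t-test per condition pair and context.
    """
    rows = []
    for mset in methylomes:
        for sample_id, df in mset.samples.items():
            kept = df[df["n_total"] >= min_site_coverage]
            ratio = kept["n_meth"] / kept["n_total"]
            per_ctx = ratio.groupby(kept["context"], observed=True).mean() * 100.0
            for ctx in CONTEXTS:
                rows.append((mset.condition, sample_id, ctx, per_ctx.get(ctx, np.nan)))
    levels = pd.DataFrame(rows, columns=["condition", "sample_id", "context", "level"])

    tests = []
    conds = [m.condition for m in methylomes]
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            for ctx in CONTEXTS:
                sel = (levels["context"] == ctx)
                a = levels[sel & (levels["condition"] == conds[i])]["level"].dropna()
                b = levels[sel & (levels["condition"] == conds[j])]["level"].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    p = stats.ttest_ind(a, b, equal_var=True).pvalue
                else:
                    p = np.nan
                tests.append((conds[i], conds[j], ctx, p))
    tests = pd.DataFrame(tests, columns=["condition_a", "condition_b", "context", "p_value"])
    return levels, tests


# ---------------------------------------------------------------------------
# windows

def enumerate_windows(chrom_lengths, params=None):
    """All sliding windows, in genomic order, as a DataFrame (chrom, start, end).

    Starts run 0, step, 2*step, ... while start < chromosome length; the last
    windows are truncated at the chromosome end.
    """
    params = params or DmrCallParams()
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, params.step, dtype=np.int64)
        ends = np.minimum(starts + params.window_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def _window_level_matrix(calls, chrom, starts, ends, context, params):
    """Vectorized per-window level/count for one replicate, chrom and context.

    Returns (levels %, n_sites); level is NaN where n_sites < min_sites_per_window.
    """
    sub = calls[(calls["chrom"] == chrom) & (calls["context"] == context)
                & (calls["n_total"] >= params.min_site_coverage)]
    pos0 = np.sort(sub["pos"].to_numpy(np.int64)) - 1  # to 0-based points
    order = np.argsort(sub["pos"].to_numpy(np.int64), kind="stable")
    ratio = (sub["n_meth"].to_numpy(float) / sub["n_total"].to_numpy(float))[order]
    csum = np.concatenate([[0.0], np.cumsum(ratio)])
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        level = 100.0 * (csum[hi] - csum[lo]) / n
    level[n < params.min_sites_per_window] = np.nan
    return level, n


def _window_count_matrix(calls, chrom, starts, ends, context, params):
    """Pooled (meth, total) read counts per window (for the Fisher variant)."""
    sub = calls[(calls["chrom"] == chrom) & (calls["context"] == context)
                & (calls["n_total"] >= params.min_site_coverage)]
    pos = sub["pos"].to_numpy(np.int64)
    order = np.argsort(pos, kind="stable")
    pos0 = pos[order] - 1
    meth = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy(np.int64)[order])])
    tot = np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy(np.int64)[order])])
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return meth[hi] - meth[lo], tot[hi] - tot[lo]


def window_replicate_level(calls, window, context, params=None):
    """One replicate's methylation level (%) and site count in one window.

    ``window`` is a (chrom, start, end) triple in 0-based half-open
    coordinates.  Returns ``(level, n_sites)``; level is NaN (undefined) when
    fewer than ``min_sites_per_window`` eligible sites fall in the window.
    """
    params = params or DmrCallParams()
    chrom, start, end = window
    level, n = _window_level_matrix(
        calls, chrom, np.array([start]), np.array([end]), context, params)
    return float(level[0]), int(n[0])


def test_window(levels_ref, levels_test, stat="student"):
    """Two-sample test on replicate window levels.

    Returns ``(p_value, delta_mc, sda_ref, sda_test)`` with
    ``delta_mc = mean(test) - mean(ref)`` in percentage points and SDA the
    sample (ddof=1) standard deviation of each group's replicate levels.
    """
    a = np.asarray(levels_ref, float)
    b = np.asarray(levels_test, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 defined replicate levels per group")
    delta = b.mean() - a.mean()
    sda_a = a.std(ddof=1)
    sda_b = b.std(ddof=1)
    p = _t_pvalues(a[None, :], b[None, :], stat)[0]
    return float(p), float(delta), float(sda_a), float(sda_b)


def _t_pvalues(A, B, stat):
    """Row-wise two-sample t-test p-values; degenerate rows -> 1 (equal) or 0."""
    if stat not in ("student", "welch"):
        raise ValueError(f"unknown stat {stat!r}")
    res = stats.ttest_ind(B, A, axis=1, equal_var=(stat == "student"))
    p = np.asarray(res.pvalue, float).copy()
    # both groups constant: identical means are a non-finding, distinct means
    # are an infinitely sharp one
    var0 = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    same = np.isclose(A.mean(axis=1), B.mean(axis=1))
    p[var0 & same] = 1.0
    p[var0 & ~same] = 0.0
    return p


def window_stats(ref, test, chrom_lengths=None, params=None, contexts=CONTEXTS):
    """Per-window statistics for every window defined in all replicates.

    This is the unfiltered stage of :func:`call_dmrs`: it computes, per
    context, replicate levels, group means, delta_mC, SDA per group and the
    p-value, for windows with defined levels in every replicate of both
    groups.  No significance or SDA filter is applied here.
    """
    params = params or DmrCallParams()
    if ref.n_replicates < 2 or test.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if chrom_lengths is None:
        merged = ref.chrom_lengths()
        for chrom, ln in test.chrom_lengths().items():
            merged[chrom] = max(merged.get(chrom, 0), ln)
        chrom_lengths = merged

    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, params.step, dtype=np.int64)
        ends = np.minimum(starts + params.window_size, length)
        for ctx in contexts:
            mats, counts = [], []
            for mset in (ref, test):
                for df in mset.samples.values():
                    lv, n = _window_level_matrix(df, chrom, starts, ends, ctx, params)
                    mats.append(lv)
                    counts.append(n)
            M = np.vstack(mats)                      # (n_reps_total, n_windows)
            defined = ~np.isnan(M).any(axis=0)
            if not defined.any():
                continue
            nA = ref.n_replicates
            A = M[:nA, defined].T                    # (n_def, n_reps_ref)
            B = M[nA:, defined].T
            n_sites = np.vstack(counts)[:, defined].min(axis=0)

            if params.stat == "fisher":
                p = _fisher_pooled(ref, test, chrom, starts[defined], ends[defined],
                                   ctx, params)
            else:
                p = _t_pvalues(A, B, params.stat)

            frames.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts[defined],
                "end": ends[defined],
                "context": ctx,
                "n_sites": n_sites,
                "mean_ref": A.mean(axis=1),
                "mean_test": B.mean(axis=1),
                "delta_mc": B.mean(axis=1) - A.mean(axis=1),
                "sda_ref": A.std(axis=1, ddof=1),
                "sda_test": B.std(axis=1, ddof=1),
                "p_value": p,
            }))
    if not frames:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "context", "n_sites", "mean_ref", "mean_test",
            "delta_mc", "sda_ref", "sda_test", "p_value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start", "context"], kind="mergesort",
                           ignore_index=True)


def _fisher_pooled(ref, test, chrom, starts, ends, context, params):
    """Fisher's exact test on read counts pooled over sites and replicates."""
    sums = []
    for mset in (ref, test):
        meth = np.zeros(len(starts), np.int64)
        tot = np.zeros(len(starts), np.int64)
        for df in mset.samples.values():
            m, t = _window_count_matrix(df, chrom, starts, ends, context, params)
            meth += m
            tot += t
        sums.append((meth, tot))
    (ma, ta), (mb, tb) = sums
    p = np.empty(len(starts))
    for i in range(len(starts)):
        table = [[ma[i], ta[i] - ma[i]], [mb[i], tb[i] - mb[i]]]
        p[i] = stats.fisher_exact(table)[1]
    return p


def call_dmrs(ref, test, chrom_lengths=None, params=None, contexts=CONTEXTS):
    """Call DMRs of the test condition against the reference condition.

    A window becomes a DMR when, within its context, it is defined in every
    replicate, ``p <= p_threshold``, both groups' SDA is at or below the
    per-context threshold and ``|delta_mC| >= min_abs_delta``.  ``direction``
    is ``hypo`` (test lower) or ``hyper`` from the sign of delta_mC.
    """
    params = params or DmrCallParams()
    if not ref.samples or not test.samples:
        logger.warning("call_dmrs: empty methylome, returning no DMRs")
    stats_df = window_stats(ref, test, chrom_lengths, params, contexts)
    if stats_df.empty:
        return stats_df.assign(direction=pd.Series(dtype=str))
    thr = stats_df["context"].map(params.sda_threshold).to_numpy(float)
    keep = (
        (stats_df["p_value"] <= params.p_threshold)
        & (stats_df["sda_ref"] <= thr)
        & (stats_df["sda_test"] <= thr)
        & (stats_df["delta_mc"].abs() >= params.min_abs_delta)
        & (stats_df["delta_mc"] != 0)
    )
    dmrs = stats_df[keep].copy()
    dmrs["direction"] = np.where(dmrs["delta_mc"] < 0, "hypo", "hyper")
    return dmrs.reset_index(drop=True)


def merge_dmrs(dmrs):
    """Merge overlapping/adjacent same-context same-direction DMR windows.

    Off by default in the pipeline; provided for region-level reporting.  The
    merged record keeps the extreme delta_mC and the smallest p-value.
    """
    if dmrs.empty:
        return dmrs.copy()
    out = []
    for (chrom, ctx, direction), grp in dmrs.groupby(
            ["chrom", "context", "direction"], observed=True):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["p_value"] = min(cur["p_value"], row.p_value)
                if abs(row.delta_mc) > abs(cur["delta_mc"]):
                    cur["delta_mc"] = row.delta_mc
            else:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "context": ctx, "delta_mc": row.delta_mc,
                       "p_value": row.p_value, "direction": direction}
        out.append(cur)
    return (pd.DataFrame(out)
            .sort_values(["chrom", "start", "context"], kind="mergesort",
                         ignore_index=True))


# ---------------------------------------------------------------------------
# summaries

def round_half_away(x, ndigits=0):
    """Round half away from zero (the convention of printed summary tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class DmrSummary:
    """Context x direction DMR counts with derived percentage views.

    Percentages are always computed from the stored counts; shares over an
    empty denominator are NaN (undefined), never 0.
    """

    def __init__(self, counts):
        # counts: {context: {'hypo': n, 'hyper': n}}
        self.counts = {ctx: {"hypo": int(c.get("hypo", 0)), "hyper": int(c.get("hyper", 0))}
                       for ctx, c in counts.items()}

    @classmethod
    def from_counts(cls, counts):
        return cls(counts)

    @property
    def total(self):
        return sum(c["hypo"] + c["hyper"] for c in self.counts.values())

    def context_total(self, context):
        c = self.counts.get(context, {"hypo": 0, "hyper": 0})
        return c["hypo"] + c["hyper"]

    def direction_count(self, direction, contexts=None):
        ctxs = contexts or list(self.counts)
        return sum(self.counts.get(c, {}).get(direction, 0) for c in ctxs)

    def direction_share(self, direction, contexts=None):
        """% of DMRs (within the given contexts) in the given direction."""
        ctxs = contexts or list(self.counts)
        denom = sum(self.context_total(c) for c in ctxs)
        if denom == 0:
            return float("nan")
        return 100.0 * self.direction_count(direction, ctxs) / denom

    def context_share(self, context):
        """% of all DMRs falling in the given context."""
        if self.total == 0:
            return float("nan")
        return 100.0 * self.context_total(context) / self.total

    def as_frame(self):
        rows = []
        for ctx in sorted(self.counts):
            c = self.counts[ctx]
            rows.append({
                "context": ctx, "hypo": c["hypo"], "hyper": c["hyper"],
                "total": c["hypo"] + c["hyper"],
                "pct_hypo": self.direction_share("hypo", [ctx]),
                "pct_hyper": self.direction_share("hyper", [ctx]),
                "pct_of_all": self.context_share(ctx),
            })
        rows.append({
            "context": "all",
            "hypo": self.direction_count("hypo"),
            "hyper": self.direction_count("hyper"),
            "total": self.total,
            "pct_hypo": self.direction_share("hypo"),
            "pct_hyper": self.direction_share("hyper"),
            "pct_of_all": 100.0 if self.total else float("nan"),
        })
        return pd.DataFrame(rows)


def summarize_dmrs(dmrs) -> DmrSummary:
    """Tabulate called DMRs per context and direction."""
    counts = {ctx: {"hypo": 0, "hyper": 0} for ctx in CONTEXTS}
    if len(dmrs):
        tab = dmrs.groupby(["context", "direction"], observed=True).size()
        for (ctx, direction), n in tab.items():
            counts.setdefault(ctx, {"hypo": 0, "hyper": 0})[direction] = int(n)
    return DmrSummary(counts)


def dmr_density(dmrs, chrom_lengths, bin_size=50_000, hotspot_quantile=0.99):
    """Per-context DMR start counts in fixed genomic bins, with hotspot flags.

    A bin is a hotspot for a context when its count reaches the
    ``hotspot_quantile`` of that context's *nonzero* bin counts.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    contexts = sorted(dmrs["context"].unique()) if len(dmrs) else []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size)) or 1
        bins = np.arange(n_bins, dtype=np.int64) * bin_size
        for ctx in contexts:
            sub = dmrs[(dmrs["chrom"] == chrom) & (dmrs["context"] == ctx)]
            idx = np.clip(sub["start"].to_numpy(np.int64) // bin_size, 0, n_bins - 1)
            counts = np.bincount(idx, minlength=n_bins)
            frames.append(pd.DataFrame({
                "chrom": chrom, "bin_start": bins, "context": ctx, "count": counts}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "bin_start", "context", "count", "hotspot"])
    track = pd.concat(frames, ignore_index=True)
    track["hotspot"] = False
    for ctx in contexts:
        mask = track["context"] == ctx
        nonzero = track.loc[mask & (track["count"] > 0), "count"]
        if len(nonzero):
            cutoff = np.quantile(nonzero, hotspot_quantile)
            track.loc[mask, "hotspot"] = track.loc[mask, "count"] >= cutoff
    return track
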