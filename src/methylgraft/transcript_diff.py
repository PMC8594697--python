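"""Differential-transcript selection, functional BIN classification,
hypergeometric enrichment and relative qPCR quantification.

The input contract is a normalized differential-transcription table
(transcript id, annotation kind, signed log2 ratio of test over reference,
p-value); upstream microarray processing is out of scope.  Transcripts with
``p <= alpha`` (1% by default) are differentially expressed transcripts
(DETs), split into differentially transcribed genes (DTGs) and transposable
elements (DTTEs).  Functional classes come from a Mercator-style BIN map;
over-representation per BIN is tested one-sided against the platform
background with the hypergeometric law and Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_dets", "assign_bins", "classify_bins", "enrichment",
    "compare_contrasts", "ddct_quantify", "QpcrMeasurement",
]


def select_dets(det_table, alpha=0.01):
    """Retain records with ``p_value <= alpha``; split by annotation kind.

    Returns a dict with the full selection plus per-kind splits and
    per-kind/per-sign counts.
    """
    dets = det_table[det_table["p_value"] <= alpha].reset_index(drop=True)
    counts = {}
    for kind, grp in dets.groupby("kind", observed=True):
        counts[kind] = {
            "n": len(grp),
            "up": int((grp["ratio"] > 0).sum()),
            "down": int((grp["ratio"] < 0).sum()),
        }
    return {
        "all": dets,
        "gene": dets[dets["kind"] == "gene"].reset_index(drop=True),
        "TE": dets[dets["kind"] == "TE"].reset_index(drop=True),
        "counts": counts,
    }


def _bin_depth(code):
    return str(code).count(".") + 1


def assign_bins(transcript_ids, bin_map):
    """Map transcripts to their single most specific BIN.

    Transcripts mapping to several BINs keep the deepest code (most
    dot-separated levels); remaining ties keep the lexicographically smallest
    code.  Unmapped transcripts are absent from the result (they are excluded
    from every downstream classification).  Matching is case-insensitive.
    """
    ids = pd.Series(list(transcript_ids), dtype=str)
    lut = bin_map.assign(_depth=bin_map["bincode"].map(_bin_depth)).sort_values(
        ["identifier", "_depth", "bincode"], ascending=[True, False, True],
        kind="mergesort")
    best = lut.groupby("identifier", sort=False).head(1)
    assigned = pd.DataFrame({"transcript_id": ids, "_key": ids.str.lower()}).merge(
        best[["identifier", "bincode", "name"]],
        left_on="_key", right_on="identifier", how="inner")
    return assigned[["transcript_id", "bincode", "name"]].reset_index(drop=True)


def classify_bins(dets, bin_map, collapse_below=None):
    """Per-BIN counts and percentages of BIN-assigned DETs.

    ``dets`` is a DET DataFrame (or anything with ``transcript_id``).
    Percentages are over assigned DETs only and sum to 100.  With
    ``collapse_below`` (e.g. 5.0), classes under that share are pooled into
    ``"Other class"`` for reporting.
    """
    assigned = assign_bins(dets["transcript_id"], bin_map)
    if assigned.empty:
        return pd.DataFrame(columns=["bincode", "name", "count", "pct"])
    tab = (assigned.groupby(["bincode", "name"], observed=True)
           .size().reset_index(name="count"))
    tab["pct"] = 100.0 * tab["count"] / tab["count"].sum()
    tab = tab.sort_values("count", ascending=False, kind="mergesort",
                          ignore_index=True)
    if collapse_below is not None:
        small = tab["pct"] < collapse_below
        if small.any():
            other = pd.DataFrame([{
                "bincode": "other", "name": "Other class",
                "count": int(tab.loc[small, "count"].sum()),
                "pct": float(tab.loc[small, "pct"].sum()),
            }])
            tab = pd.concat([tab[~small], other], ignore_index=True)
    return tab


def enrichment(det_ids, background_ids, bin_map, q_threshold=0.05):
    """One-sided hypergeometric over-representation of BINs among DETs.

    For a BIN with ``K`` of the ``N`` background transcripts and ``k`` of the
    ``n`` DETs, ``p = P(X >= k)`` for X hypergeometric(N, K, n).  BH is
    applied over all tested BINs; ``enriched`` flags ``q <= q_threshold``.
    The DET set must be a subset of the background (same platform).
    """
    det_bins = assign_bins(det_ids, bin_map)
    bg_bins = assign_bins(background_ids, bin_map)
    n = len(det_bins)
    N = len(bg_bins)
    if n == 0 or N == 0:
        return pd.DataFrame(columns=["bincode", "name", "k", "n", "K", "N",
                                     "p_value", "q_value", "enriched"])
    K_per = bg_bins.groupby(["bincode", "name"], observed=True).size()
    k_per = det_bins.groupby(["bincode", "name"], observed=True).size()
    missing = set(k_per.index) - set(K_per.index)
    if missing:
        raise ValueError(
            f"BIN(s) {sorted(b for b, _ in missing)} present among DETs but absent "
            "from the background: inconsistent map")
    rows = []
    for (bincode, name), K in K_per.items():
        k = int(k_per.get((bincode, name), 0))
        p = stats.hypergeom.sf(k - 1, N, int(K), n)
        rows.append({"bincode": bincode, "name": name, "k": k, "n": n,
                     "K": int(K), "N": N, "p_value": float(p)})
    res = pd.DataFrame(rows).sort_values("bincode", kind="mergesort",
                                         ignore_index=True)
    res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["enriched"] = res["q_value"] <= q_threshold
    return res


def compare_contrasts(dets_1, dets_2):
    """Set comparison of two DET tables sharing an id namespace.

    Returns common/specific id sets and, within the common set, the counts of
    concordant-up, concordant-down and opposite-sign regulation.
    """
    s1 = dets_1.set_index("transcript_id")["ratio"]
    s2 = dets_2.set_index("transcript_id")["ratio"]
    common = s1.index.intersection(s2.index)
    sign1 = np.sign(s1.loc[common])
    sign2 = np.sign(s2.loc[common])
    concordant = sign1 == sign2
    return {
        "common": set(common),
        "specific_1": set(s1.index.difference(s2.index)),
        "specific_2": set(s2.index.difference(s1.index)),
        "concordant_up": int((concordant & (sign1 > 0)).sum()),
        "concordant_down": int((concordant & (sign1 < 0)).sum()),
        "opposite": int((~concordant).sum()),
    }


@dataclass
class QpcrMeasurement:
    """One sample's Ct values: the target gene and >= 1 reference genes."""

    sample_id: str
    target_ct: float
    reference_cts: dict  # gene name -> Ct
    efficiency: float = 2.0

    def __post_init__(self):
        if not self.reference_cts:
            raise ValueError(f"sample {self.sample_id!r}: no reference-gene Ct")
        if self.target_ct <= 0 or any(ct <= 0 for ct in self.reference_cts.values()):
            raise ValueError(f"sample {self.sample_id!r}: Ct values must be > 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("amplification efficiency must be in (1, 2]")


def ddct_quantify(measurements, calibrator_id):
    """Relative expression by the 2^-ddCt method with multi-reference correction.

    Per gene g and sample s, quantity Q = efficiency^(Ct_g(calibrator) -
    Ct_g(s)); the normalization factor is the geometric mean of the
    reference-gene quantities; normalized expression is
    Q_target / NF.  The calibrator maps to 1.0 by construction.  All
    samples must carry Cts for the same reference genes.
    """
    by_id = {m.sample_id: m for m in measurements}
    if calibrator_id not in by_id:
        raise ValueError(f"calibrator {calibrator_id!r} not among measurements")
    cal = by_id[calibrator_id]
    refs = sorted(cal.reference_cts)
    out = {}
    for m in measurements:
        missing = [g for g in refs if g not in m.reference_cts]
        if missing:
            raise ValueError(f"sample {m.sample_id!r} lacks reference Ct for {missing}")
        q_target = m.efficiency ** (cal.target_ct - m.target_ct)
        q_refs = [m.efficiency ** (cal.reference_cts[g] - m.reference_cts[g])
                  for g in refs]
        nf = float(np.exp(np.mean(np.log(q_refs))))
        out[m.sample_id] = q_target / nf
    return out
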