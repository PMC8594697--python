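"""Associate DMRs with nearby genes and transposable elements.

A DMR is linked to every feature whose span it overlaps or lies within
``flank`` bp of (closest-edge distance, 2000 bp by default, matching the
promoter/terminator width).  Each link is classified by where the DMR sits
relative to the strand-aware gene geometry: ``promoter`` (5' flank), ``body``
or ``terminator`` (3' flank) for genes, ``flank5``/``body``/``flank3`` for
TEs.  A DMR touching several regions takes the highest-priority class
(promoter > body > terminator by default).  ``dedupe_per_feature`` then
reduces the links to at most one DMR per feature, keeping the DMR with the
largest absolute methylation change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["AssocParams", "associate", "classify_position", "dedupe_per_feature"]

GENE_CLASSES = ("promoter", "body", "terminator")
TE_CLASSES = ("flank5", "body", "flank3")


@dataclass
class AssocParams:
    flank: int = 2000
    #: tie-break order over (5' flank, body, 3' flank), highest first
    position_priority: tuple = ("promoter", "body", "terminator")

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if set(self.position_priority) != set(GENE_CLASSES):
            raise ValueError("position_priority must permute promoter/body/terminator")


def _regions(feature, flank):
    """Strand-aware (class, start, end) regions of one feature row."""
    start, end, strand = feature.start, feature.end, feature.strand
    five, body, three = (GENE_CLASSES if feature.kind == "gene" else TE_CLASSES)
    if strand == "-":
        return {five: (end, end + flank), body: (start, end),
                three: (start - flank, start)}
    return {five: (start - flank, start), body: (start, end),
            three: (end, end + flank)}


def classify_position(dmr_start, dmr_end, feature, params=None):
    """Position class of a DMR interval relative to one feature.

    Checks intersection with the 5' flank, body and 3' flank regions and
    resolves multi-region hits by ``position_priority``.  A DMR that only
    touches the feature's neighbourhood at exactly ``flank`` bp (no region
    intersection) is assigned the flank class of its side.
    """
    params = params or AssocParams()
    regions = _regions(feature, params.flank)
    five, body, three = (GENE_CLASSES if feature.kind == "gene" else TE_CLASSES)
    by_generic = {GENE_CLASSES[i]: (five, body, three)[i] for i in range(3)}
    for generic in params.position_priority:
        cls = by_generic[generic]
        rs, re = regions[cls]
        if dmr_start < re and rs < dmr_end:
            return cls
    # boundary case: distance == flank, flush against the outer flank edge
    mid_feature = (feature.start + feature.end) / 2
    if dmr_end <= mid_feature:
        return five if feature.strand == "+" else three
    return three if feature.strand == "+" else five


def _edge_distance(dmr_start, dmr_end, f_start, f_end):
    """bp between closest interval edges; 0 when overlapping."""
    if dmr_start < f_end and f_start < dmr_end:
        return 0
    if dmr_end <= f_start:
        return int(f_start - dmr_end)
    return int(dmr_start - f_end)


def associate(dmrs, features, params=None):
    """Link every DMR to every feature within ``flank`` bp (or overlapping).

    Returns one row per (DMR, feature) pair with the DMR fields plus
    ``feature_id``, ``kind``, ``position_class`` and ``distance``.  A DMR may
    link to several features and a feature to several DMRs at this stage.
    """
    params = params or AssocParams()
    trees = {}
    feat_rows = {}
    for row in features.itertuples():
        # flank+1 expansion yields a candidate superset; exact distance filter below
        lo = row.start - params.flank - 1
        hi = row.end + params.flank + 1
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.Index)
        feat_rows[row.Index] = row

    out = []
    for dmr in dmrs.itertuples():
        tree = trees.get(dmr.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(dmr.start, dmr.end), key=lambda iv: iv.data):
            feature = feat_rows[iv.data]
            dist = _edge_distance(dmr.start, dmr.end, feature.start, feature.end)
            if dist > params.flank:
                continue
            out.append({
                "chrom": dmr.chrom, "dmr_start": dmr.start, "dmr_end": dmr.end,
                "context": dmr.context, "delta_mc": dmr.delta_mc,
                "direction": dmr.direction, "p_value": dmr.p_value,
                "feature_id": feature.feature_id, "kind": feature.kind,
                "position_class": classify_position(dmr.start, dmr.end, feature, params),
                "distance": dist,
            })
    cols = ["chrom", "dmr_start", "dmr_end", "context", "delta_mc", "direction",
            "p_value", "feature_id", "kind", "position_class", "distance"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out, columns=cols).sort_values(
        ["chrom", "dmr_start", "feature_id"], kind="mergesort", ignore_index=True)


def dedupe_per_feature(links):
    """Keep, per feature, the link whose DMR has maximal |delta_mC|.

    Ties break on smaller genomic start, then lexicographic context, so the
    result is deterministic.
    """
    if links.empty:
        return links.copy()
    ranked = links.assign(_abs=links["delta_mc"].abs()).sort_values(
        ["_abs", "dmr_start", "context"],
        ascending=[False, True, True], kind="mergesort")
    kept = ranked.groupby("feature_id", sort=False).head(1).drop(columns="_abs")
    return kept.sort_values(["chrom", "dmr_start", "feature_id"], kind="mergesort",
                            ignore_index=True)
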