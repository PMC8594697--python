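"""Readers and writers for the on-disk formats the pipeline consumes and emits.

All genomic intervals inside the package are 0-based half-open.  The two
1-based formats (per-cytosine call tables and GFF3) are converted exactly
once, here, at the I/O boundary:

* methylation-call tables keep their 1-based ``pos`` column (a cytosine is a
  point, not an interval); window arithmetic subtracts 1 where needed;
* GFF3 features are converted from 1-based inclusive to 0-based half-open.

Methylation-call dialect
------------------------
Tab-separated, one ``#``-prefixed header line, six columns::

    #chrom  pos  strand  context  n_meth  n_total

``pos`` is the 1-based coordinate of the cytosine, ``context`` is one of
CG/CHG/CHH, and the two counts are methylated and total read counts.  This is
a count-preserving reduction of a Bsmap ``methratio`` table: the native
``ratio`` and effective-CT columns are dropped because the counts allow exact
recomputation of every level downstream.
"""

from __future__ import annotations

import logging

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]

#: columns of the BED-like DMR table, in file order
DMR_COLUMNS = [
    "chrom", "start", "end", "context",
    "delta_mc", "p_value", "sda_ref", "sda_test", "direction",
]

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "kind", "class_label"]

DET_COLUMNS = ["transcript_id", "kind", "ratio", "p_value"]

#: GFF3 feature types accepted as transposable elements
TE_GFF_TYPES = {
    "transposable_element", "transposon_fragment", "transposable_element_gene",
    "repeat_region", "TE",
}
GENE_GFF_TYPES = {"gene"}


class FormatError(ValueError):
    """A malformed row or record in an input file."""


def _fail(path, lineno, message):
    raise FormatError(f"{path}:{lineno}: {message}")


def read_methylation_calls(path, sample_id=None, condition=None) -> pd.DataFrame:
    """Read one replicate's per-cytosine methylation calls.

    Returns a DataFrame with columns ``chrom, pos, strand, context, n_meth,
    n_total``; ``sample_id`` and ``condition`` are attached in ``df.attrs``.
    Rows with ``n_total == 0`` (uncovered cytosines) are dropped.  Any
    malformed row raises :class:`FormatError` naming the offending line.
    """
    raw = pd.read_csv(
        path, sep="\t", comment="#", names=CALL_COLUMNS, header=None, dtype=str,
        skip_blank_lines=True,
    )
    # line numbers: one header line plus 1-based offset
    lineno = raw.index.to_numpy() + 2

    if raw.isna().any(axis=None):
        bad = int(lineno[raw.isna().any(axis=1).to_numpy()][0])
        _fail(path, bad, "expected 6 tab-separated fields")

    out = pd.DataFrame({"chrom": raw["chrom"].astype(str)})
    for col in ("pos", "n_meth", "n_total"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        nonint = vals.isna() | (vals != np.floor(vals))
        if nonint.any():
            bad = int(lineno[nonint.to_numpy()][0])
            _fail(path, bad, f"non-integer value in column '{col}': {raw[col][nonint].iloc[0]!r}")
        out[col] = vals.astype(np.int64)

    out["strand"] = raw["strand"]
    out["context"] = raw["context"]

    bad_strand = ~out["strand"].isin(STRANDS)
    if bad_strand.any():
        _fail(path, int(lineno[bad_strand.to_numpy()][0]),
              f"unknown strand {out['strand'][bad_strand].iloc[0]!r}")
    bad_ctx = ~out["context"].isin(CONTEXTS)
    if bad_ctx.any():
        _fail(path, int(lineno[bad_ctx.to_numpy()][0]),
              f"unknown context {out['context'][bad_ctx].iloc[0]!r} (expected CG/CHG/CHH)")
    if (out["pos"] < 1).any():
        _fail(path, int(lineno[(out['pos'] < 1).to_numpy()][0]), "pos must be >= 1")
    if (out["n_meth"] < 0).any():
        _fail(path, int(lineno[(out['n_meth'] < 0).to_numpy()][0]), "n_meth must be >= 0")
    over = out["n_meth"] > out["n_total"]
    if over.any():
        row = out[over].iloc[0]
        _fail(path, int(lineno[over.to_numpy()][0]),
              f"n_meth ({row.n_meth}) exceeds n_total ({row.n_total})")

    out = out[out["n_total"] > 0].reset_index(drop=True)
    out = out[CALL_COLUMNS]
    out.attrs["sample_id"] = sample_id
    out.attrs["condition"] = condition
    return out


def write_methylation_calls(calls: pd.DataFrame, path) -> None:
    """Write calls in the canonical 6-column dialect (deterministic order)."""
    df = calls[CALL_COLUMNS].sort_values(["chrom", "pos", "strand"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALL_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_features(path) -> pd.DataFrame:
    """Read genes and transposable elements from a GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  Records whose type is neither gene- nor TE-like are
    skipped (a count is logged).  ``class_label`` is taken from a
    ``class``/``classification`` attribute when present.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows, skipped = [], 0
    for feat in db.all_features():
        if feat.featuretype in GENE_GFF_TYPES:
            kind = "gene"
        elif feat.featuretype in TE_GFF_TYPES:
            kind = "TE"
        else:
            skipped += 1
            continue
        if feat.end < feat.start:
            raise FormatError(
                f"{path}: feature {feat.id!r} has end < start ({feat.end} < {feat.start})")
        label = ""
        for key in ("class", "classification", "Class"):
            if key in feat.attributes:
                label = feat.attributes[key][0]
                break
        strand = feat.strand if feat.strand in STRANDS else "+"
        rows.append((feat.id, feat.seqid, feat.start - 1, feat.end, strand, kind, label))
    if skipped:
        logger.info("read_features(%s): skipped %d records of unhandled types", path, skipped)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["n_skipped"] = skipped
    return df


def write_features(features: pd.DataFrame, path, source="methylgraft") -> None:
    """Write a feature table as GFF3 (0-based half-open back to 1-based)."""
    type_of = {"gene": "gene", "TE": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.sort_values(["chrom", "start"], kind="mergesort").itertuples():
            attrs = f"ID={row.feature_id}"
            if row.class_label:
                attrs += f";class={row.class_label}"
            fh.write(
                f"{row.chrom}\t{source}\t{type_of[row.kind]}\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as the 9-column BED-like TSV, sorted by (chrom, start, context)."""
    df = dmrs.reindex(columns=DMR_COLUMNS)
    df = df.sort_values(["chrom", "start", "context"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_dmrs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", names=DMR_COLUMNS, header=None)
    for col in ("start", "end"):
        df[col] = df[col].astype(np.int64)
    return df


def read_det_table(path) -> pd.DataFrame:
    """Read a normalized differential-transcription table.

    Columns: ``transcript_id`` (str), ``kind`` (gene/TE/other), ``ratio``
    (signed log2 test-over-reference), ``p_value``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=DET_COLUMNS, header=None)
    df["transcript_id"] = df["transcript_id"].astype(str)
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise FormatError(f"{path}: p_value outside [0, 1]")
    return df


def write_det_table(dets: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DET_COLUMNS) + "\n")
        dets[DET_COLUMNS].to_csv(fh, sep="\t", header=False, index=False,
                                 float_format="%.10g")


def read_bin_map(path) -> pd.DataFrame:
    """Read a Mercator-style BIN map: columns bincode, name, identifier.

    Quotes around fields (as Mercator emits) are tolerated; identifiers are
    matched case-insensitively downstream, so they are lowercased here.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                     names=["bincode", "name", "identifier"], quotechar="'")
    for col in df.columns:
        df[col] = df[col].str.strip().str.strip("'\"")
    df = df.dropna(subset=["bincode", "identifier"])
    df = df[df["identifier"] != ""]
    df["identifier"] = df["identifier"].str.lower()
    return df.reset_index(drop=True)


def write_bin_map(bin_map: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#bincode\tname\tidentifier\n")
        bin_map[["bincode", "name", "identifier"]].to_csv(fh, sep="\t", header=False,
                                                          index=False)


def read_chrom_lengths(path) -> dict:
    """Two-column TSV (chrom, length) -> dict preserving file order."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_lengths(chrom_lengths: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tlength\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
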