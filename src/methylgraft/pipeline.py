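"""Configuration-driven orchestration of the full analysis.

One YAML config (see ``configs/``) names the inputs and every parameter; the
stages then run in a fixed order:

    global levels -> call DMRs -> summarize -> density -> annotate ->
    DET selection -> enrichment -> integration

Outputs are deterministic byte-for-byte given identical inputs and config; a
``manifest.json`` records parameter values and SHA-256 checksums of inputs
and outputs, which suffices to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr_caller, feature_annotation, integration, io, synthetic_data, \
    transcript_diff

logger = logging.getLogger(__name__)

STAGES = ["global_levels", "call_dmrs", "summarize", "density", "annotate",
          "dets", "enrich", "integrate"]


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg, base=Path(path).parent)
    return cfg


def validate_config(cfg, base=Path(".")):
    """Check presence and existence of inputs before any stage runs."""
    inputs = cfg.get("inputs", {})
    required = ["reference_calls", "test_calls", "features", "det_table",
                "bin_map", "chrom_lengths"]
    for key in required:
        if key not in inputs:
            raise ValueError(f"config missing inputs.{key}")
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not (base / p).exists():
                raise FileNotFoundError(f"inputs.{key}: no such file {p!r}")
    if len(inputs["reference_calls"]) < 2 or len(inputs["test_calls"]) < 2:
        raise ValueError("need >= 2 replicate call files per condition")
    return cfg


def params_from_config(cfg):
    d = dict(cfg.get("dmr", {}))
    if "sda_threshold" in d:
        d["sda_threshold"] = {k: float(v) for k, v in d["sda_threshold"].items()}
    call = dmr_caller.DmrCallParams(**d)
    assoc = feature_annotation.AssocParams(**cfg.get("association", {}))
    integ = integration.IntegrationParams(
        **{k: (tuple(v) if k == "contexts" else v)
           for k, v in cfg.get("integration", {}).items()})
    return call, assoc, integ


def _load_methylomes(base, cfg):
    inputs = cfg["inputs"]
    names = cfg.get("conditions", {"reference": "ref", "test": "test"})

    def load(paths, condition):
        samples = {}
        for i, p in enumerate(paths):
            sid = f"{condition}_rep{i + 1}"
            samples[sid] = io.read_methylation_calls(base / p, sample_id=sid,
                                                     condition=condition)
        return dmr_caller.MethylomeSet(condition=condition, samples=samples)

    return (load(inputs["reference_calls"], names.get("reference", "ref")),
            load(inputs["test_calls"], names.get("test", "test")))


def run_pipeline(cfg, outdir, base=Path(".")):
    """Run all stages; returns the manifest dict (also written as JSON)."""
    base = Path(base)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_config(cfg, base=base)
    call_params, assoc_params, integ_params = params_from_config(cfg)
    inputs = cfg["inputs"]
    outputs = {}

    def emit(name, filename):
        outputs[name] = str(outdir / filename)
        return outdir / filename

    try:
        stage = "load"
        ref, test = _load_methylomes(base, cfg)
        chrom_lengths = io.read_chrom_lengths(base / inputs["chrom_lengths"])
        features = io.read_features(base / inputs["features"])
        det_table = io.read_det_table(base / inputs["det_table"])
        bin_map = io.read_bin_map(base / inputs["bin_map"])

        stage = "global_levels"
        levels, level_tests = dmr_caller.global_methylation_levels(
            [ref, test], call_params.min_site_coverage)
        with open(emit(stage, "global_levels.tsv"), "w") as fh:
            fh.write("#condition\tsample_id\tcontext\tlevel\n")
            levels.to_csv(fh, sep="\t", header=False, index=False,
                          float_format="%.10g")

        stage = "call_dmrs"
        dmrs = dmr_caller.call_dmrs(ref, test, chrom_lengths, call_params)
        io.write_dmrs(dmrs, emit(stage, "dmrs.tsv"))

        stage = "summarize"
        summary = dmr_caller.summarize_dmrs(dmrs)
        with open(emit(stage, "dmr_summary.tsv"), "w") as fh:
            fh.write("#" + "\t".join(summary.as_frame().columns) + "\n")
            summary.as_frame().to_csv(fh, sep="\t", header=False, index=False,
                                      float_format="%.10g")

        stage = "density"
        track = dmr_caller.dmr_density(dmrs, chrom_lengths,
                                       bin_size=cfg.get("density", {}).get(
                                           "bin_size", 50_000))
        with open(emit(stage, "dmr_density.tsv"), "w") as fh:
            fh.write("#chrom\tbin_start\tcontext\tcount\thotspot\n")
            track.to_csv(fh, sep="\t", header=False, index=False)

        stage = "annotate"
        links = feature_annotation.associate(dmrs, features, assoc_params)
        deduped = feature_annotation.dedupe_per_feature(links)
        with open(emit(stage, "links.tsv"), "w") as fh:
            fh.write("#" + "\t".join(deduped.columns) + "\n")
            deduped.to_csv(fh, sep="\t", header=False, index=False,
                           float_format="%.10g")

        stage = "dets"
        sel = transcript_diff.select_dets(det_table,
                                          alpha=cfg.get("dets", {}).get("alpha", 0.01))
        io.write_det_table(sel["all"], emit(stage, "dets.tsv"))

        stage = "enrich"
        enr = transcript_diff.enrichment(sel["gene"]["transcript_id"],
                                         det_table[det_table["kind"] == "gene"]
                                         ["transcript_id"],
                                         bin_map)
        with open(emit(stage, "enrichment.tsv"), "w") as fh:
            fh.write("#" + "\t".join(enr.columns) + "\n")
            enr.to_csv(fh, sep="\t", header=False, index=False,
                       float_format="%.10g")

        stage = "integrate"
        records = integration.join_dtg_dmr(sel["all"], deduped, integ_params)
        with open(outdir / "dtg_dmr.tsv", "w") as fh:
            fh.write("#" + "\t".join(records.columns) + "\n")
            records.to_csv(fh, sep="\t", header=False, index=False,
                           float_format="%.10g")
        outputs["integrate"] = str(outdir / "dtg_dmr.tsv")
        quad = integration.quadrant_summary(records)
        summary_json = {"quadrants": quad, "correlation": {}}
        groups = {"all": records}
        for cls in sorted(records["position_class"].dropna().unique()):
            groups[cls] = records[records["position_class"] == cls]
        for name, grp in groups.items():
            if len(grp) >= 3 and grp["delta_mc"].var() > 0 and grp["ratio"].var() > 0:
                res = integration.correlation_test(grp, integ_params)
                summary_json["correlation"][name] = {
                    "n": res.n, "r_squared": res.r_squared, "r": res.r,
                    "t": res.t, "p_value": res.p_value,
                    "variance_test_p": res.variance_test_p,
                }
            else:
                summary_json["correlation"][name] = None
        with open(emit("integration_summary", "integration_summary.json"), "w") as fh:
            json.dump(summary_json, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
    except Exception as exc:  # noqa: BLE001 - stage-labelled abort is the contract
        raise StageError(stage, exc) from exc

    manifest = {
        "config": cfg,
        "input_checksums": {
            key: ([_sha256(base / p) for p in val] if isinstance(val, list)
                  else _sha256(base / val))
            for key, val in inputs.items()
        },
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_simulation(spec, outdir, n_coupled=40, n_uncoupled=60, delta=-30.0,
                     delta_coupled=(-9.0, -4.0), length=500):
    """Generate and write a complete simulated study to ``outdir``.

    Emits per-replicate call TSVs, features.gff3, det.tsv, bin_map.tsv,
    truth.tsv, chroms.tsv and a ready-to-run pipeline config, and returns the
    config dict.  Injections: ``n_coupled`` centred in gene promoters (these
    genes' expression is shifted; their deltas draw from the
    ``delta_coupled`` range to give the dose-response scatter leverage) and
    ``n_uncoupled`` elsewhere at the fixed ``delta``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    features = synthetic_data.simulate_features(spec)
    prom_inj, _coupled = synthetic_data.make_promoter_injections(
        spec, features, n_coupled, length=length, delta=delta_coupled)
    bg_inj = synthetic_data.make_injections(spec, n_uncoupled, length=length,
                                            delta=delta)
    # drop background injections colliding with promoter ones
    bg_inj = [i for i in bg_inj
              if not any(i.chrom == p.chrom and i.start < p.end and p.start < i.end
                         for p in prom_inj)]
    spec.injections = list(prom_inj) + list(bg_inj)
    spec._validate_injections()

    ref, test, truth = synthetic_data.simulate_methylomes(spec)
    dets = synthetic_data.simulate_expression(spec, features, truth)
    bin_map = synthetic_data.make_bin_map(spec, features)

    ref_paths, test_paths = [], []
    for mset, paths in ((ref, ref_paths), (test, test_paths)):
        for sid, df in mset.samples.items():
            p = outdir / f"calls_{sid}.tsv"
            io.write_methylation_calls(df, p)
            paths.append(p.name)
    io.write_features(features, outdir / "features.gff3")
    io.write_det_table(dets, outdir / "det.tsv")
    io.write_bin_map(bin_map, outdir / "bin_map.tsv")
    io.write_chrom_lengths(spec.chrom_lengths(), outdir / "chroms.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tcontext\tdelta\tdirection\n")
        truth.to_csv(fh, sep="\t", header=False, index=False,
                     float_format="%.10g")

    cfg = {
        "inputs": {
            "reference_calls": ref_paths,
            "test_calls": test_paths,
            "features": "features.gff3",
            "det_table": "det.tsv",
            "bin_map": "bin_map.tsv",
            "chrom_lengths": "chroms.tsv",
        },
        "conditions": {"reference": spec.condition_ref,
                       "test": spec.condition_test},
        "seed": spec.seed,
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg
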