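"""Shared paths and loaders for the numbered analysis scripts.

The simulated study lives under scratch/ (bulky, regenerated by
01_simulate.py); the tables each script reports live under results/.
"""

from pathlib import Path

import pandas as pd
import yaml

from methylgraft import dmr_caller, io

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"
RESULTS = ROOT / "results"
FIXTURE_CONFIG = ROOT / "configs" / "simulation_2mb.yaml"


def fixture_spec():
    from methylgraft import synthetic_data
    with open(FIXTURE_CONFIG) as fh:
        cfg = yaml.safe_load(fh)
    spec = synthetic_data.SimSpec(seed=cfg["seed"], n_chroms=cfg["n_chroms"],
                                  chrom_length=cfg["chrom_length"])
    return spec, cfg


def load_sim():
    """Load the simulated study written by 01_simulate.py."""
    if not (SIM_DIR / "pipeline.yaml").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    with open(SIM_DIR / "pipeline.yaml") as fh:
        cfg = yaml.safe_load(fh)

    def mset(paths, condition):
        samples = {}
        for i, p in enumerate(paths):
            sid = f"{condition}_rep{i + 1}"
            samples[sid] = io.read_methylation_calls(SIM_DIR / p, sample_id=sid,
                                                     condition=condition)
        return dmr_caller.MethylomeSet(condition, samples)

    return {
        "config": cfg,
        "ref": mset(cfg["inputs"]["reference_calls"],
                    cfg["conditions"]["reference"]),
        "test": mset(cfg["inputs"]["test_calls"], cfg["conditions"]["test"]),
        "chrom_lengths": io.read_chrom_lengths(SIM_DIR / "chroms.tsv"),
        "features": io.read_features(SIM_DIR / "features.gff3"),
        "det_table": io.read_det_table(SIM_DIR / "det.tsv"),
        "bin_map": io.read_bin_map(SIM_DIR / "bin_map.tsv"),
        "truth": pd.read_csv(SIM_DIR / "truth.tsv", sep="\t", comment="#",
                             header=None,
                             names=["chrom", "start", "end", "context", "delta",
                                    "direction"]),
    }


def write_tsv(df, path, float_format="%.10g"):
    RESULTS.mkdir(exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  float_format=float_format)
    print(f"  wrote {path.relative_to(ROOT)}")
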