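import numpy as np
import pandas as pd
import pytest

from methylgraft import dmr_caller, synthetic_data


@pytest.fixture(scope="session")
def tiny_sim():
    """A small seeded two-condition simulation with injected CHH DMRs."""
    spec = synthetic_data.SimSpec(seed=1, n_chroms=1, chrom_length=100_000,
                                  n_genes=10, n_tes=10)
    spec.injections = synthetic_data.make_injections(spec, 10, length=500,
                                                     context="CHH", delta=-30.0)
    ref, test, truth = synthetic_data.simulate_methylomes(spec)
    return {"spec": spec, "ref": ref, "test": test, "truth": truth}


@pytest.fixture()
def calls_frame():
    """A deterministic random call table (one replicate)."""
    rng = np.random.default_rng(42)
    n = 1000
    pos = np.sort(rng.choice(np.arange(1, 20_001), size=n, replace=False))
    total = rng.integers(1, 30, n)
    meth = rng.binomial(total, 0.3)
    return pd.DataFrame({
        "chrom": np.where(pos <= 10_000, "chr1", "chr2"),
        "pos": pos,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        "context": rng.choice(["CG", "CHG", "CHH"], n, p=[0.15, 0.15, 0.7]),
        "n_meth": meth.astype(np.int64),
        "n_total": total.astype(np.int64),
    })


def methylome_from_levels(levels_by_sample, chrom="chr1", context="CHH",
                          positions=None, coverage=10, condition="X"):
    """Build a MethylomeSet with exact per-site levels (no sampling noise)."""
    samples = {}
    for sid, level in levels_by_sample.items():
        pos = positions if positions is not None else np.arange(1, 11)
        lv = np.broadcast_to(np.asarray(level, float), (len(pos),))
        samples[sid] = pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": "+", "context": context,
            "n_meth": np.round(lv / 100.0 * coverage).astype(np.int64),
            "n_total": coverage,
        })
    return dmr_caller.MethylomeSet(condition=condition, samples=samples)
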