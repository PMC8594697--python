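"""Generate the simulated two-condition study the later scripts analyse.

A 2-Mb, two-chromosome genome with 3 replicates per condition at 14x mean
coverage; 100 injected 500-bp CHH hypomethylated regions (-30 pp), 40 of
them centred in gene promoters where they depress the promoter's methylation
and raise the gene's expression.  Bulky call files go under scratch/.
"""

import json

from methylgraft import pipeline

from _common import FIXTURE_CONFIG, RESULTS, SIM_DIR, fixture_spec

spec, cfg = fixture_spec()
print(f"simulating from {FIXTURE_CONFIG.name}: {spec.n_chroms} x "
      f"{spec.chrom_length/1e6:.0f} Mb, seed {spec.seed}")
pipe_cfg = pipeline.write_simulation(spec, SIM_DIR, n_coupled=cfg["n_coupled"],
                                     n_uncoupled=cfg["n_uncoupled"],
                                     delta=cfg["delta"])

n_sites = sum(1 for _ in open(SIM_DIR / "calls_OG_rep1.tsv")) - 1
report = {
    "seed": spec.seed,
    "genome_bp": spec.n_chroms * spec.chrom_length,
    "cytosines_per_replicate": n_sites,
    "replicates_per_condition": spec.n_replicates,
    "injected_regions": len(spec.injections),
    "promoter_coupled_genes": cfg["n_coupled"],
}
RESULTS.mkdir(exist_ok=True)
with open(RESULTS / "01_simulation.json", "w") as fh:
    json.dump(report, fh, indent=2)
    fh.write("\n")
print(json.dumps(report, indent=2))
print(f"call files and annotations in {SIM_DIR}")
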