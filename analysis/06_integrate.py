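"""Join differential transcription with gene-linked CHH DMRs; quadrants and
the methylation-expression correlation.

Keeps CHH-context links and |log2 ratio| >= 1.5, one DMR per gene.  The
generator couples promoter CHH hypomethylation to up-regulation, so the
promoter panel should concentrate in the (hypo, up) quadrant and the
regression of ratio on delta_mC should have a significant negative slope.
"""

import json

import pandas as pd

from methylgraft import feature_annotation, integration, io, transcript_diff

from _common import RESULTS, load_sim, write_tsv

sim = load_sim()
sel = transcript_diff.select_dets(sim["det_table"], alpha=0.01)
links = pd.read_csv(RESULTS / "04_links_deduped.tsv", sep="\t", comment="#",
                    header=None,
                    names=["chrom", "dmr_start", "dmr_end", "context",
                           "delta_mc", "direction", "p_value", "feature_id",
                           "kind", "position_class", "distance"])
params = integration.IntegrationParams()
records = integration.join_dtg_dmr(sel["all"], links, params)
print(f"{len(records)} DTG-DMR records (CHH context, |log2 ratio| >= "
      f"{params.min_abs_ratio})")
write_tsv(records, RESULTS / "06_dtg_dmr.tsv")

quad = integration.quadrant_summary(records)
out = {"quadrants": quad, "correlation": {}}
print("\nquadrant shares (% of records):")
for group, shares in quad.items():
    if shares is None:
        continue
    line = ", ".join(f"{k} {v:.0f}%" for k, v in shares.items())
    print(f"  {group}: {line}")

for group in ["all"] + sorted(records.position_class.dropna().unique()):
    grp = records if group == "all" else \
        records[records.position_class == group]
    if len(grp) >= 3 and grp.delta_mc.var() > 0 and grp.ratio.var() > 0:
        res = integration.correlation_test(grp, params)
        out["correlation"][group] = res.__dict__
        print(f"correlation [{group}]: n={res.n} r={res.r:.3f} "
              f"R2={res.r_squared:.3f} p={res.p_value:.2e}")
    else:
        out["correlation"][group] = None

with open(RESULTS / "06_integration.json", "w") as fh:
    json.dump(out, fh, indent=2)
    fh.write("\n")
print(f"  wrote {(RESULTS / '06_integration.json').name}")
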