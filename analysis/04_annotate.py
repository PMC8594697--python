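"""Associate DMRs with genes and TEs within 2 kb and deduplicate.

Counts Gene-DMRs and TE-DMRs (a DMR overlapping or within 2000 bp of the
feature) and the strand-aware promoter/body/terminator split, then keeps one
DMR per feature (largest |delta_mC|) for the integration step.
"""

import pandas as pd

from methylgraft import feature_annotation, io

from _common import RESULTS, load_sim, write_tsv

sim = load_sim()
dmrs = io.read_dmrs(RESULTS / "03_dmrs.tsv")
links = feature_annotation.associate(dmrs, sim["features"])

by_kind = links.groupby("kind")["feature_id"].nunique()
print(f"{len(links)} DMR-feature links within 2 kb")
for kind in ("gene", "TE"):
    n = int(by_kind.get(kind, 0))
    print(f"  {kind}-DMRs: {n} distinct features linked")

gene_links = links[links.kind == "gene"]
print("\nposition of gene-linked DMRs (CHH only):")
print(gene_links[gene_links.context == "CHH"]
      .position_class.value_counts().to_string())

deduped = feature_annotation.dedupe_per_feature(links)
print(f"\nafter one-DMR-per-feature dedupe: {len(deduped)} links")
write_tsv(links, RESULTS / "04_links_all.tsv")
write_tsv(deduped, RESULTS / "04_links_deduped.tsv")
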