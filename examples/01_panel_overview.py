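"""Load the packaged 46-mutation panel and show what it contains.

The panel targets hotspot mutations in BRAF, EGFR, KRAS and PIK3CA on short
amplicons; each mutation carries a published limit of detection (percent
allele fraction) as reference metadata.
"""

import pandas as pd

import panelcall as pc

panel = pc.load_builtin_panel()
print(f"{len(panel.mutations)} mutations in {len(panel.genes)} genes "
      f"({', '.join(sorted(panel.genes))}) on {len(panel.amplicons)} amplicons")

per_gene = pd.Series([m.gene for m in panel.mutations]).value_counts()
print("\nmutations per gene:")
print(per_gene.to_string())

print("\nexample entries (published LOD = % allele fraction the assay can reach):")
for mid in ("KRAS G12D", "KRAS G12V", "EGFR T790M", "PIK3CA E545K"):
    m = panel.mutation(mid)
    print(f"  {m.mutation_id:<14} {m.ref_allele}>{m.alt_allele or '-'} "
          f"on {m.amplicon_id} @ {m.offset}  LOD {m.published_lod_pct}%")

print("\nvalidation:", pc.validate_panel(panel) or "all invariants hold")
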