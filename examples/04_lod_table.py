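"""Estimate per-mutation limits of detection from wild-type background runs.

With realistic PCR error rates, occasional error reads mimic mutant clusters;
the LOD absorbs this as mean + 3 SD of the background abundance, floored at
the allele fraction of a single copy (100/G % for G genome equivalents).
"""

import panelcall as pc

panel = pc.load_builtin_panel()
cfg = pc.SimConfig(dna_mass_ng=300.0, reads_per_sample=10_000)  # default error rates

quants = []
for sim in pc.simulate_background(panel, cfg, n_runs=8, seed=21):
    clusters, _ = pc.process_pool(sim.r1, sim.r2, panel, {"BG": sim.config.barcode})
    quants.append(pc.quantify_sample(clusters, panel, "BG", 50, sim.input_genomes))

lods = pc.estimate_lod(quants, standard_input_genomes=100_000)
at_floor = (lods.lod_pct <= 0.001 + 1e-12).sum()
print(lods.sort_values("lod_pct", ascending=False).head(8).to_string(index=False))
print(f"\n{at_floor} of {len(lods)} mutations sit at the single-copy floor (0.001%).")
print("Any mutation with error-driven background clusters would instead carry a")
print("higher LOD of mean + 3 SD of that background; at this depth the per-read")
print("error hits translate to far less than one input copy, so the floor binds.")
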