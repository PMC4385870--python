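# panelcall

Simulation, read processing, spike-in-calibrated quantitation and
limit-of-detection calling for a multiplexed circulating-tumor-DNA (ctDNA)
amplicon panel.

## The problem

Tumor-derived DNA fragments circulate in plasma at minute fractions of the
total cell-free DNA — often a handful of mutant molecules against 10⁵
wild-type genome equivalents.  Assays that physically enrich mutant
sequences before sequencing can reach allele fractions around 0.001%, but
turning raw pooled reads into *mutant input copies* requires careful
bookkeeping: reads must be merged, demultiplexed and classified, the
per-mutation process yield must be measured inside every sample, and calls
must be made against mutation-specific background noise.

`panelcall` implements that analysis end to end for a 46-mutation hotspot
panel (BRAF, EGFR, KRAS, PIK3CA), together with a simulator of the wet-lab
front end so the whole pipeline is testable at desk scale.  It is intended
for method developers and students of molecular diagnostics, not for
clinical use.

## The model

Every sample is spiked with synthetic **internal positive controls (IPCs)**
— one species per panel mutation, carrying the mutant allele plus a random
identifier N-mer at a fixed amplicon position.  IPCs experience the same
PCR, enrichment and sequencing as genomic mutant molecules, so binning IPC
reads by their identifiers recovers founder molecules and the **cluster
yield**

&nbsp;&nbsp;&nbsp;&nbsp;*Y* = (IPC clusters) / (effective IPC founders),

where the founder count is corrected for identifier collisions
(E[distinct] = *M*(1 − (1 − 1/*M*)^*s*), *M* = 4^*L*) and for unobserved
founders (zero-truncated Poisson).  Mutant input copies, allele fraction and
plasma-normalized load follow as

&nbsp;&nbsp;&nbsp;&nbsp;*N* = *C* / *Y*, &nbsp; *A* = 100 · *N* / *G* %, &nbsp;
copies per 5 mL = *N* · 5 / *V*,

with *C* the mutant cluster count, *G* the input genome equivalents (from
DNA mass at 3.3 pg per haploid genome) and *V* the plasma volume in mL.
The per-mutation **limit of detection** is

&nbsp;&nbsp;&nbsp;&nbsp;LOD = max(100/*G*, mean + 3·SD)

of the background abundance over repeated wild-type runs, floored at the
allele fraction of a single copy; a mutation is called **positive** only
when *N* ≥ 1 and *A* > LOD.

The simulator models limited-cycle PCR as per-founder doubling, mutant
enrichment as independent per-cycle Bernoulli retention (expected
enrichment factor (*r*₊/*r*₋)^cycles), and substitution errors per read —
enough structure to generate the backgrounds the LOD machinery must absorb.

## Worked example

`examples/02_simulate_and_call.py` spikes 25 copies of KRAS G12D into 300 ng
of wild-type DNA (~90,909 genome equivalents) and runs the full pipeline:

```
LOD (clean background, 100k genome input): 0.001% for every mutation

simulated 30000 read pairs from 90909 genome equivalents (enrichment factor 12640)
read fate: 30000 merged / 30000 pairs; labels: WT=554 MUT=334 IPC=28148 UNASSIGNED=964

KRAS G12D: 25.6 estimated input copies (truth: 25), abundance 0.0282%, LOD 0.001%, call = positive
positive calls across the whole panel: 1 (should be 1)
```

The enrichment step leaves mostly mutant-like molecules (hence the large IPC
read share); calibrating with the IPC yield turns 334 mutant clusters into
25.6 estimated input copies, within sampling error of the 25 spiked, and the
only positive call on the 46-mutation panel is the spiked mutation.  The
other examples cover the panel definition (`01`), titration recovery (`03`),
background-derived LOD tables (`04`), two-assay concordance on the packaged
19-patient table (`05`), and longitudinal monitoring flags (`06`).

A thin CLI wraps the same functions:

```bash
panelcall simulate --config sim.json --out simout/
panelcall run --config simout/run_config.json
panelcall lod --quant q1.tsv --quant q2.tsv --standard-genomes 100000 --out lod.tsv
panelcall call --quant q1.tsv --lod lod.tsv --out calls.tsv
panelcall report concordance
```

## Layout

```
src/panelcall/
  panel.py      panel model, loading/validation, synthetic references
  simulate.py   assay simulator (PCR, enrichment, sequencing, ground truth)
  readproc.py   pair merging, demultiplexing, alignment, classification
  quant.py      IPC binning, yield calibration, copies/abundance
  calling.py    LOD estimation and the positive-call rule
  report.py     titration/concordance/monitoring summaries
  pipeline.py   orchestration with read-fate accounting
  cli.py        thin click CLI
  data/         packaged panel, barcodes, concordance fixture
```

See `docs/methods.md` for the model's assumptions, parameter choices and
limitations.
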