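# Methods

## Scope and data model

`panelcall` covers the dry half of a mutant-enrichment ctDNA assay: from
pooled paired-end amplicon reads to per-sample mutation calls and study-level
summaries.  The wet half — plasma preparation, extraction, the
electrophoretic enrichment device itself, library chemistry — is represented
only phenomenologically inside the simulator.

The unit of counting is the *cluster*: one merged read pair.  Three molecule
classes generate clusters on each amplicon:

* **WT** — wild-type genomic molecules, one per input genome equivalent;
* **MUT** — genomic molecules carrying a panel mutation's alt allele;
* **IPC** — internal positive controls: synthetic molecules carrying the alt
  allele *and* a random identifier N-mer (default N = 8) at a fixed amplicon
  region, spiked at a known copy number per mutation.

## Panel representation

Mutations are (offset, ref, alt) replacements on 150-nt amplicons,
coordinates 0-based half-open; pure deletions have an empty alt.  Complex
EGFR exon-19 indels use the same representation, so one classification code
path serves all 46 mutations.  The packaged panel pins the canonical hotspot
codon contexts (e.g. KRAS `GGT GGC` at codons 12/13, the exon-19 anchor
`AAGGAATTAAGAGAAGCAACATCTCCG` for residues 745–753); all other amplicon
bases are synthetic, drawn from a seeded generator, because the assay's true
primer/amplicon sequences are not public.  Users can substitute real
references via `load_panel(tsv, fasta, spans_json)`.  Validation enforces:
ref ≠ alt, ref spans inside the amplicon and matching its sequence, the IPC
identifier region disjoint from every variant locus (so identifier
coordinates are unshifted on mutant haplotypes), and unique mutation ids.

## Simulator

Per founder molecule, limited-cycle PCR followed by per-cycle Bernoulli
retention gives a surviving copy count

    copies ~ Binomial(2^c_pre, r^c_enr),

with retention `r = retain_mut` (0.9 default) for mutant/IPC molecules and
`retain_wt` (0.35) for wild-type; the expected mutant:WT enrichment factor is
`(retain_mut/retain_wt)^c_enr` (≈1.3 × 10⁴ at the defaults with 10 cycles),
consistent with the sub-0.01% detection limits the assay class reports.
Reads are allocated multinomially over surviving copies; each read inherits
its founder's template (barcode + amplicon haplotype; IPCs get a fresh
random identifier per founder) and receives independent substitution errors
at per-base probability `1 − (1 − e)^c_pre` (`e` = 10⁻⁴ per base per cycle,
a conservative Taq-class figure; PCR and sequencing errors are folded into
this one term).  Wild-type founders of one amplicon are exchangeable and are
therefore aggregated into a single ground-truth row; mutant and IPC founders
are tracked individually.

Defaults encode the assay's standard conditions: 300 ng input DNA
(~90,909 genome equivalents at 3.3 pg per haploid genome), 50 IPC copies per
mutation, 8 pre-enrichment PCR cycles, 5 mL plasma, 8-nt sample barcodes
(packaged set of six, minimum pairwise Hamming distance 4), 100-nt reads
whose geometry guarantees ≥ 20 nt of pair overlap.  Sequencing depth
defaults to 20,000 read pairs per sample — orders of magnitude below a real
sequencing lane, chosen so that full characterization batteries run on one
CPU in minutes; depth cancels out of the copy estimate by construction, and
the depth-invariance test verifies that directly.

What the simulator does **not** model: polymerase indels and stutter,
chimeras, quality-score miscalibration, jackpot errors shared across a
founder's descendants, GC/length amplification bias, and the hybridization
physics of the enrichment device.  Passing tests therefore demonstrate the
*analysis* is correct under a clean generative model, not that the wet assay
achieves these numbers.

## Read processing

*Merging* finds the best ungapped overlap of a read pair (≥ 20 nt, mismatch
fraction ≤ 0.1), maximizing matching bases with ties to the longer overlap,
then to the smaller offset; disagreements resolve toward the higher-quality
base.  *Demultiplexing* matches the 8-nt inline barcode with ≤ 1 mismatch,
valid only because the barcode set's minimum pairwise distance (4) exceeds
twice the tolerance; anything else is counted, never dropped silently.
*Alignment* picks the amplicon with the smallest global (Needleman–Wunsch)
edit distance via edlib, rejecting clusters beyond 0.2 × length; ties break
lexicographically and are flagged.  The 0.2 ceiling deliberately exceeds the
largest panel indel (24 nt on a 150-nt amplicon).

*Classification* is by exact context matching with 10-nt flanks: an allele
is present only when `flank + allele + flank` occurs in the cluster.  This
suppresses mutant calls from mis-merged or error-laden reads (a substitution
inside the window demotes to UNASSIGNED rather than risking a false MUT) and
handles indel coordinate shifts for free.  A cluster is IPC when a mutation's
alt context is present and the identifier region (located by its own flanks)
differs from reference; MUT when alt context is present and the identifier
region equals reference; WT when every variant locus and the identifier
region are reference.  Two special rules:

* **Near-reference identifiers.**  An identifier within Hamming distance 1 of
  the reference identifier-region sequence is scored UNASSIGNED.  Only 25 of
  4⁸ identifiers lie that close, so such a read is overwhelmingly a genomic
  read with one substitution error; without this rule those reads leak into
  IPC bins and bias copy recovery low by ~10% at high mutant load.
  Symmetrically, an IPC founder that genuinely draws the reference 8-mer
  (probability 4⁻⁸ per founder) is indistinguishable from genomic mutant
  DNA and surfaces as a rare near-single-copy false signal — part of the
  background the specificity analysis tolerates.
* **Multi-mutation clusters** carry one MUT label per detected mutation
  (quantitation is per mutation).  Alts closer than the flank width (e.g.
  KRAS codons 12 and 13) are mutually exclusive by construction, since each
  context window covers the other locus.

## Quantitation

IPC clusters are binned by (identifier, sample, mutation) after UMI-style
error absorption: identifiers within Hamming distance 1 of a more abundant
identifier are collapsed into it.  The cluster yield is
`Y = T / s_eff` with `T` the binned IPC cluster total and `s_eff` the
effective founder count, obtained from the observed bin count by

1. collision inversion — solve `k = M(1 − (1 − 1/M)^s)` for `s`
   (`M = 4^L`), capped at the known spike-in count;
2. dropout inversion — solve `s_obs = s(1 − e^{−T/s})` (zero-truncated
   Poisson) by bisection on `[s_obs, spiked]`.

Both corrections are small at routine depth and the naive `T / k` mode is
available (`correct=False`); the corrected mode is the default because both
biases point the same way at low depth.  When no IPC cluster is observed the
yield — and hence the copy estimate — is reported missing, never zero.
Copies `N = C/Y`, abundance `A = 100·N/G` (IPC spike-ins never enter the
denominator `G`), and plasma normalization `N·5/V` follow exactly; values
are kept unrounded, with display rounding left to reports.

## Calling

Backgrounds are estimated per mutation from ≥ 2 wild-type runs: mean and
sample SD (n−1) of the background abundance.  The reported LOD is
`max(100/G_std, mean + 3·SD)` with `G_std` the standard input in genome
equivalents (100,000 gives the 0.001% single-copy floor).  A call is
positive iff `N ≥ 1` (at least one estimated input copy) **and** `A > LOD`
(strict, per "greater than").  Missing-yield mutations are "not evaluable".
The raw margin `A − LOD` is always reported so near-threshold signals stay
visible.  A consequence worth stating plainly: a sample containing exactly
one mutant copy at the standard input sits exactly at the floor, so its
detection probability is near one half — the usual behavior of any assay
*at* its limit of detection; comfortably above the LOD, detection is
essentially certain.

## Reports

The titration report keeps one row per sample, routes zero-input samples to
a background table, and filters inputs below 10 copies (where Poisson
sampling of the input aliquot dominates).  Concordance counts a
discordance only when both assays report and differ; a not-analyzed
comparator counts with the concordant remainder (reproducing the 18/19
convention) and the stricter evaluable-only fraction is emitted alongside,
with directional counts (assay-A-only, assay-B-only, allele mismatch).
Monitoring series anchor day 0 at surgery and flag *re-emergence*
(pre-operative mutation cleared post-operatively, detected again later) and
*new alleles* (first detection after surgery given pre-operative sampling).

## Numerical and testing choices

All randomness flows from explicit integer seeds through numpy's
`SeedSequence`; reruns are byte-identical.  Characterization batteries in
the test suite run at reduced scale — 15,000–100,000 reads per sample,
2,000–100,000 genome equivalents — sized so the statistical assertions
(recovery within 10%, 3-standard-error enrichment checks, ≥ 85% specificity
over 47 wild-type samples) retain power while the whole suite runs on a
single CPU in a few minutes.  Merging, alignment and IPC binning are checked
for exact agreement against independent brute-force oracles (all-offsets
overlap search, full DP edit distance, ground-truth grouping).

## Known limitations

Synthetic amplicon context means k-mer-level artifacts of real genomic
sequence (homopolymers, paralogs, mappability) are absent.  Classification
is exact-match and conservative: clusters with errors near variant loci are
discarded rather than rescued by probabilistic models, which costs a few
percent of usable clusters and would understate yield-adjusted counts if
error rates were far above the defaults.  The enrichment model is
phenomenological; per-mutation enrichment heterogeneity (which drives the
spread of published LODs from 0.001% to 0.024%) must be supplied via
per-sample configs rather than emerging from physics.  Patient-cohort
quantities (stage-stratified tissue/plasma concordance, longitudinal
trajectories) depend on specimens and are covered only by arithmetic on
packaged tables and simulation-based properties.
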