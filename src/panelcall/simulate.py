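"""Assay simulator: pooled amplicon reads from WT, mutant, and IPC molecules.

Emulates the wet-lab front end of the assay at desk scale.  Each sample holds
three molecule classes per amplicon:

* wild-type genomic molecules (one per input genome equivalent),
* mutant genomic molecules at defined copy numbers,
* internal positive controls (IPCs): synthetic mutant molecules that carry a
  random identifier N-mer in the amplicon's IPC region, spiked at known copy
  numbers and used downstream to calibrate per-mutation cluster yield.

The model:

* limited-cycle PCR doubles every founder ``pcr_cycles_pre`` times;
* mutant enrichment (the electrophoretic capture step, modeled
  phenomenologically) retains each molecule copy independently per cycle —
  probability ``retain_mut`` for panel-mutant and IPC molecules, ``retain_wt``
  for wild-type — so a founder's surviving copy count is
  ``Binomial(2**pcr_cycles_pre, retain**enrich_cycles)`` and the expected
  mutant:WT enrichment factor is ``(retain_mut/retain_wt)**enrich_cycles``;
* ``reads_per_sample`` read pairs are drawn multinomially over surviving
  copies; substitution errors are applied per read at a per-base probability
  of ``1 - (1 - per_base_error_per_cycle)**pcr_cycles_pre`` (PCR and
  sequencing errors folded into one per-read term);
* read 1 starts with the sample barcode; read pairs cover the barcoded
  molecule from both ends with overlap, so merging is well-posed.

Everything is driven by one seed; a rerun with the same config is
byte-identical.  Full ground truth (per-founder surviving read counts, IPC
identifiers) is recorded for validation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import NUCLEOTIDES, Panel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Per-sample simulation parameters.

    ``input_genomes`` may be given directly or derived from ``dna_mass_ng``
    (300 ng at 3.3 pg per haploid genome ~ 90,909 genome equivalents, the
    assay's standard input).  ``mutant_copies`` and ``ipc_copies`` map
    mutation_id to founder copy counts; an int for ``ipc_copies`` spikes that
    many copies for every panel mutation.
    """

    input_genomes: int | None = None
    dna_mass_ng: float | None = 300.0
    mutant_copies: Mapping[str, int] = field(default_factory=dict)
    ipc_copies: Mapping[str, int] | int = 50
    pcr_cycles_pre: int = 8
    per_base_error_per_cycle: float = 1e-4
    enrich_cycles: int = 10
    retain_mut: float = 0.9
    retain_wt: float = 0.35
    reads_per_sample: int = 20_000
    read_len: int = 100
    barcode: str = "AATCGGGA"
    plasma_ml: float = 5.0
    seed: int = 0

    def resolve_input_genomes(self, panel: Panel) -> int:
        if self.input_genomes is not None:
            return int(self.input_genomes)
        if self.dna_mass_ng is None:
            raise ValueError("need input_genomes or dna_mass_ng")
        return int(round(panel.genomes_from_mass(self.dna_mass_ng)))

    def validate(self) -> None:
        for name in ("per_base_error_per_cycle", "retain_mut", "retain_wt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.retain_mut < self.retain_wt:
            raise ValueError("retain_mut must be >= retain_wt (enrichment enriches mutants)")
        if any(c < 0 for c in self.mutant_copies.values()):
            raise ValueError("mutant_copies must be >= 0")
        if self.reads_per_sample < 0 or self.read_len <= 0:
            raise ValueError("reads_per_sample >= 0 and read_len > 0 required")

    def ipc_copies_for(self, mutation_id: str) -> int:
        if isinstance(self.ipc_copies, int):
            return self.ipc_copies
        return int(self.ipc_copies.get(mutation_id, 0))

    @property
    def expected_enrichment_factor(self) -> float:
        if self.retain_wt == 0:
            return float("inf")
        return (self.retain_mut / self.retain_wt) ** self.enrich_cycles


#: a FASTQ record as (read_id, sequence, quality-string)
FastqRecord = tuple[str, str, str]


@dataclass
class SimSample:
    """One simulated sample: paired reads plus full ground truth."""

    config: SimConfig
    r1: list[FastqRecord]
    r2: list[FastqRecord]
    truth: pd.DataFrame
    input_genomes: int

    @property
    def sample_barcode(self) -> str:
        return self.config.barcode


TRUTH_COLUMNS = [
    "founder_id",
    "founder_class",  # WT | MUT | IPC
    "mutation_id",
    "amplicon_id",
    "identifier",
    "n_founders",  # >1 only for the aggregated WT pool of an amplicon
    "copies_post",
    "read_count",
]


def _apply_read_errors(template: str, n_reads: int, p_err: float, rng) -> list[str]:
    """Independent per-read substitution errors on a shared template."""
    if n_reads == 0:
        return []
    L = len(template)
    if p_err <= 0.0:
        return [template] * n_reads
    n_err = rng.binomial(L, p_err, size=n_reads)
    out: list[str] = []
    for k in n_err:
        if k == 0:
            out.append(template)
            continue
        arr = bytearray(template, "ascii")
        pos = rng.choice(L, size=k, replace=False)
        for p in pos:
            old = chr(arr[p])
            choices = [b for b in NUCLEOTIDES if b != old]
            arr[p] = ord(choices[rng.integers(0, 3)])
        out.append(arr.decode("ascii"))
    return out


def simulate_sample(panel: Panel, cfg: SimConfig) -> SimSample:
    """Simulate one sample end to end; deterministic for a fixed config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genomes = cfg.resolve_input_genomes(panel)
    n_amp = 2 ** cfg.pcr_cycles_pre
    p_wt = cfg.retain_wt ** cfg.enrich_cycles
    p_mut = cfg.retain_mut ** cfg.enrich_cycles
    p_err = 1.0 - (1.0 - cfg.per_base_error_per_cycle) ** cfg.pcr_cycles_pre

    # --- founders and their surviving copy counts ---------------------------
    rows: list[dict] = []
    templates: list[str] = []  # barcoded molecule per truth row
    fid = 0

    for amp in panel.amplicons:  # aggregated WT pool per amplicon
        copies = int(rng.binomial(genomes * n_amp, p_wt)) if genomes > 0 else 0
        rows.append(
            dict(
                founder_id=fid,
                founder_class="WT",
                mutation_id="",
                amplicon_id=amp.amplicon_id,
                identifier="",
                n_founders=genomes,
                copies_post=copies,
                read_count=0,
            )
        )
        templates.append(cfg.barcode + amp.sequence)
        fid += 1

    for m in panel.mutations:
        n_copies = int(cfg.mutant_copies.get(m.mutation_id, 0))
        if n_copies == 0:
            continue
        hap = cfg.barcode + panel.mutant_haplotype(m.mutation_id)
        surv = rng.binomial(n_amp, p_mut, size=n_copies)
        for c in surv:
            rows.append(
                dict(
                    founder_id=fid,
                    founder_class="MUT",
                    mutation_id=m.mutation_id,
                    amplicon_id=m.amplicon_id,
                    identifier="",
                    n_founders=1,
                    copies_post=int(c),
                    read_count=0,
                )
            )
            templates.append(hap)
            fid += 1

    for m in panel.mutations:
        n_ipc = cfg.ipc_copies_for(m.mutation_id)
        if n_ipc == 0:
            continue
        amp = panel.amplicon(m.amplicon_id)
        ilo, ihi = amp.ipc_identifier_span
        ident_len = ihi - ilo
        hap = panel.mutant_haplotype(m.mutation_id)
        # IPC ref span precedes the variant locus, so identifier coordinates
        # are unshifted in the mutant haplotype (enforced by panel validation)
        surv = rng.binomial(n_amp, p_mut, size=n_ipc)
        idents = rng.integers(0, 4, size=(n_ipc, ident_len))
        for c, ident_row in zip(surv, idents):
            ident = "".join(NUCLEOTIDES[b] for b in ident_row)
            rows.append(
                dict(
                    founder_id=fid,
                    founder_class="IPC",
                    mutation_id=m.mutation_id,
                    amplicon_id=m.amplicon_id,
                    identifier=ident,
                    n_founders=1,
                    copies_post=int(c),
                    read_count=0,
                )
            )
            templates.append(cfg.barcode + hap[:ilo] + ident + hap[ihi:])
            fid += 1

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # --- sequencing: multinomial read allocation over surviving copies -----
    copies = truth["copies_post"].to_numpy(dtype=np.float64)
    total = copies.sum()
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    if cfg.reads_per_sample > 0 and total > 0:
        counts = rng.multinomial(cfg.reads_per_sample, copies / total)
        truth["read_count"] = counts
        read_no = 0
        for i, n_reads in enumerate(counts):
            if n_reads == 0:
                continue
            for mol in _apply_read_errors(templates[i], int(n_reads), p_err, rng):
                rid = f"sim_{cfg.barcode}_{read_no}"
                fwd = mol[: cfg.read_len]
                rev = revcomp(mol)[: cfg.read_len]
                r1.append((rid, fwd, "I" * len(fwd)))
                r2.append((rid, rev, "I" * len(rev)))
                read_no += 1
    return SimSample(config=cfg, r1=r1, r2=r2, truth=truth, input_genomes=genomes)


# ---------------------------------------------------------------------------
# batteries of samples


@dataclass
class TitrationSample:
    mutation_id: str
    input_copies: int
    replicate: int
    sim: SimSample


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_titration(
    panel: Panel,
    cfg_base: SimConfig,
    mutation_id: str,
    copy_levels: Iterable[int],
    replicates: int,
    seed: int,
) -> list[TitrationSample]:
    """One sample per (copy level, replicate), sharing the WT background config."""
    levels = [int(c) for c in copy_levels]
    if any(c < 0 for c in levels):
        raise ValueError("copy_levels must be >= 0")
    seeds = _spawn_seeds(seed, len(levels) * replicates)
    out = []
    i = 0
    for level in levels:
        for rep in range(replicates):
            cfg = replace(
                cfg_base, mutant_copies={mutation_id: level} if level else {}, seed=seeds[i]
            )
            out.append(
                TitrationSample(
                    mutation_id=mutation_id,
                    input_copies=level,
                    replicate=rep,
                    sim=simulate_sample(panel, cfg),
                )
            )
            i += 1
    return out


def simulate_background(
    panel: Panel, cfg: SimConfig, n_runs: int, seed: int
) -> list[SimSample]:
    """Wild-type-only runs (IPCs still spiked) for background/LOD estimation."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (background SD is undefined for one run)")
    seeds = _spawn_seeds(seed, n_runs)
    return [
        simulate_sample(panel, replace(cfg, mutant_copies={}, seed=s)) for s in seeds
    ]


# ---------------------------------------------------------------------------
# FASTQ IO


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def pool_samples(samples: Iterable[SimSample]) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Concatenate per-sample read pairs into one pooled pair of FASTQ streams."""
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    for s in samples:
        r1.extend(s.r1)
        r2.extend(s.r2)
    return r1, r2
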