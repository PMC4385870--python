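"""End-to-end orchestration: FASTQ pairs -> classified clusters -> quant -> calls.

Stages are the module operations (merge, demultiplex, align, classify,
quantify, call) wired together with read-fate accounting so nothing is
silently dropped: merged + merge-failed = input pairs, and assigned +
unassigned = merged.  Identical read pairs are processed once through a
cache — simulator output and deep amplicon data are highly redundant, which
makes desk-scale runs cheap without changing any result.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import quant as quant_mod
from .calling import call_mutations, estimate_lod
from .panel import Panel, load_builtin_panel, load_panel
from .readproc import (
    LABEL_UNASSIGNED,
    ClusterClassifier,
    align_to_amplicons,
    assign_barcode,
    check_barcode_set,
    merge_pairs,
)
from .simulate import FastqRecord, read_fastq


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage and sample context."""


@dataclass
class ReadProcParams:
    """Tolerances for the read-processing stages (all config-overridable)."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    barcode_max_mismatch: int = 1
    max_edit_frac: float = 0.2
    flank_match: int = 10
    collapse_distance: int = 1

    def validate(self) -> None:
        if self.min_overlap < 1:
            raise PipelineError("min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_frac <= 1:
            raise PipelineError("max_mismatch_frac outside [0, 1]")
        if not 0 <= self.max_edit_frac <= 1:
            raise PipelineError("max_edit_frac outside [0, 1]")
        if self.barcode_max_mismatch < 0 or self.flank_match < 0:
            raise PipelineError("barcode_max_mismatch and flank_match must be >= 0")


CLUSTER_COLUMNS = [
    "read_id",
    "sample",
    "amplicon_id",
    "label",
    "mutations",
    "identifier",
    "edit_distance",
]


def process_pool(
    r1: list[FastqRecord],
    r2: list[FastqRecord],
    panel: Panel,
    barcodes: dict[str, str],
    params: ReadProcParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify a pooled read stream; returns (cluster table, QC accounting).

    Clusters that fail merging are counted; clusters that fail barcode
    assignment or amplicon alignment are retained in the table with
    ``sample``/``amplicon_id`` empty and the UNASSIGNED label.
    """
    params = params or ReadProcParams()
    params.validate()
    check_barcode_set(barcodes, params.barcode_max_mismatch)
    if len(r1) != len(r2):
        raise PipelineError(f"read-pair count mismatch: {len(r1)} vs {len(r2)}")
    bc_len = len(next(iter(barcodes.values())))
    classifier = ClusterClassifier(panel, flank=params.flank_match)

    merge_cache: dict[tuple, tuple | None] = {}
    rows = []
    qc = Counter(n_pairs=len(r1), n_merged=0, n_merge_failed=0)
    for (rid, s1, q1), (_rid2, s2, q2) in zip(r1, r2):
        key = (s1, q1, s2, q2)
        hit = merge_cache.get(key, "MISS")
        if hit == "MISS":
            m = merge_pairs(s1, q1, s2, q2, params.min_overlap, params.max_mismatch_frac)
            if m is None:
                hit = None
            else:
                sample = assign_barcode(m.sequence, barcodes, params.barcode_max_mismatch)
                if sample is None:
                    hit = ("", "", LABEL_UNASSIGNED, "", "", -1)
                else:
                    insert = m.sequence[bc_len:]
                    aln = align_to_amplicons(insert, panel, params.max_edit_frac)
                    if aln is None:
                        hit = (sample, "", LABEL_UNASSIGNED, "", "", -1)
                    else:
                        cls = classifier.classify(aln.amplicon_id, insert)
                        hit = (
                            sample,
                            aln.amplicon_id,
                            cls.label,
                            ";".join(cls.mutations),
                            cls.identifier or "",
                            aln.edit_distance,
                        )
            merge_cache[key] = hit
        if hit is None:
            qc["n_merge_failed"] += 1
            continue
        qc["n_merged"] += 1
        sample, amp_id, label, muts, ident, dist = hit
        if sample == "":
            qc["n_unassigned_barcode"] += 1
        else:
            qc["n_assigned"] += 1
        if amp_id == "" and sample != "":
            qc["n_unaligned"] += 1
        qc[f"label_{label}"] += 1
        rows.append((rid, sample, amp_id, label, muts, ident, dist))

    clusters = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    qc = dict(qc)
    qc["n_aligned"] = qc.get("n_assigned", 0) - qc.get("n_unaligned", 0)
    return clusters, qc


# ---------------------------------------------------------------------------
# configured end-to-end run


@dataclass
class SampleManifest:
    """Per-sample wet-lab metadata needed for quantitation."""

    sample_id: str
    barcode: str
    input_genomes: float | None = None
    dna_mass_ng: float | None = None
    plasma_ml: float = 5.0
    ipc_copies: dict[str, int] | int = 50

    def resolve_input_genomes(self, panel: Panel) -> float:
        if self.input_genomes is not None:
            return float(self.input_genomes)
        if self.dna_mass_ng is None:
            raise PipelineError(f"sample {self.sample_id}: need input_genomes or dna_mass_ng")
        return panel.genomes_from_mass(self.dna_mass_ng)


@dataclass
class RunConfig:
    """JSON-serializable configuration for one pooled run."""

    fastq_r1: str
    fastq_r2: str
    samples: list[SampleManifest]
    panel_table: str | None = None  # None -> packaged panel
    panel_fasta: str | None = None
    panel_spans: str | None = None
    lod_table: str | None = None
    out_dir: str = "panelcall_out"
    params: ReadProcParams = field(default_factory=ReadProcParams)
    correct_yield: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        samples = [SampleManifest(**s) for s in raw.pop("samples")]
        params = ReadProcParams(**raw.pop("params", {}))
        return cls(samples=samples, params=params, **raw)

    def to_json(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(json.dumps(raw, indent=1) + "\n")

    def load_panel(self) -> Panel:
        if self.panel_table is None:
            return load_builtin_panel()
        if self.panel_fasta is None:
            raise PipelineError("panel_table given without panel_fasta")
        return load_panel(self.panel_table, self.panel_fasta, self.panel_spans)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured run; writes per-stage outputs and returns them.

    Outputs under ``config.out_dir``: ``clusters.tsv``, ``qc.json``,
    per-sample ``quant_<sample>.tsv`` and (when an LOD table is supplied)
    ``calls_<sample>.tsv``.  Deterministic given inputs.
    """
    for path in (config.fastq_r1, config.fastq_r2):
        if not Path(path).exists():
            raise PipelineError(f"stage=input: FASTQ not found: {path}")
    panel = config.load_panel()
    r1 = read_fastq(config.fastq_r1)
    r2 = read_fastq(config.fastq_r2)
    barcodes = {s.sample_id: s.barcode for s in config.samples}
    try:
        clusters, qc = process_pool(r1, r2, panel, barcodes, config.params)
    except Exception as exc:  # annotate stage context
        raise PipelineError(f"stage=readproc: {exc}") from exc

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    (out / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True) + "\n")

    lods = None
    if config.lod_table is not None:
        lods = pd.read_csv(config.lod_table, sep="\t", comment="#")

    quants: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    for s in config.samples:
        try:
            q = quant_mod.quantify_sample(
                clusters,
                panel,
                s.sample_id,
                s.ipc_copies,
                s.resolve_input_genomes(panel),
                plasma_ml=s.plasma_ml,
                collapse_distance=config.params.collapse_distance,
                correct_yield=config.correct_yield,
            )
        except Exception as exc:
            raise PipelineError(f"stage=quant sample={s.sample_id}: {exc}") from exc
        quants[s.sample_id] = q
        q.to_csv(out / f"quant_{s.sample_id}.tsv", sep="\t", index=False)
        if lods is not None:
            try:
                c = call_mutations(q, lods)
            except Exception as exc:
                raise PipelineError(f"stage=calling sample={s.sample_id}: {exc}") from exc
            calls[s.sample_id] = c
            c.to_csv(out / f"calls_{s.sample_id}.tsv", sep="\t", index=False)
    return dict(clusters=clusters, qc=qc, quants=quants, calls=calls, panel=panel)


def lod_from_quant_tables(
    quant_paths: list[str | Path], standard_input_genomes: float
) -> pd.DataFrame:
    """Build an LOD table from background quant TSVs written by run_pipeline."""
    tables = [pd.read_csv(p, sep="\t", comment="#") for p in quant_paths]
    return estimate_lod(tables, standard_input_genomes)
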