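"""Mutation panel model: definitions, loading, validation and synthetic references.

The panel targets 46 hotspot mutations in four genes (BRAF, EGFR, KRAS,
PIK3CA) assayed on short multiplex-PCR amplicons.  Each amplicon carries an
internal-positive-control (IPC) identifier region: spiked synthetic control
molecules have a random N-mer there instead of the reference sequence, which
is how reads from controls are told apart from reads of genomic origin.

Coordinates are 0-based, half-open throughout.  Real amplicon sequences are
not published for this panel, so the packaged references are synthetic:
random sequence constrained so that every mutation's reference allele is
present at its stated offset (see :func:`synthesize_references`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"

#: mass of one haploid human genome, in picograms; converts DNA mass to
#: genome equivalents (300 ng -> ~90,909 genomes).
DEFAULT_GENOME_MASS_PG = 3.3

#: columns of the panel TSV, in order.
PANEL_COLUMNS = [
    "mutation_id",
    "gene",
    "amplicon_id",
    "offset",
    "ref_allele",
    "alt_allele",
    "published_lod_pct",
]

#: token used in the TSV alt_allele column for a pure deletion (empty alt).
DELETION_TOKEN = "-"


class PanelError(ValueError):
    """Schema or invariant violation in a panel definition."""


class PanelConflictError(PanelError):
    """Two mutations on one amplicon demand incompatible reference bases."""


@dataclass(frozen=True)
class MutationDef:
    """One panel mutation as an (offset, ref, alt) replacement on an amplicon.

    ``alt_allele`` may be the empty string (pure deletion).  ``published_lod_pct``
    is the assay's published limit of detection for this mutation, in percent
    allele fraction; it is reference metadata and plays no role in calling.
    """

    mutation_id: str
    gene: str
    amplicon_id: str
    offset: int
    ref_allele: str
    alt_allele: str
    published_lod_pct: float | None = None

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.offset, self.offset + len(self.ref_allele))


@dataclass(frozen=True)
class Amplicon:
    """A reference amplicon with primer spans and the IPC identifier region."""

    amplicon_id: str
    sequence: str
    primer_fwd_span: tuple[int, int]
    primer_rev_span: tuple[int, int]
    ipc_identifier_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def identifier_len(self) -> int:
        a, b = self.ipc_identifier_span
        return b - a


@dataclass
class Panel:
    """A validated mutation panel: mutations plus their reference amplicons."""

    mutations: list[MutationDef]
    amplicons: list[Amplicon]
    genome_mass_pg: float = DEFAULT_GENOME_MASS_PG
    _amplicon_index: dict[str, Amplicon] = field(init=False, repr=False)
    _mutation_index: dict[str, MutationDef] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._amplicon_index = {a.amplicon_id: a for a in self.amplicons}
        self._mutation_index = {m.mutation_id: m for m in self.mutations}

    def amplicon(self, amplicon_id: str) -> Amplicon:
        return self._amplicon_index[amplicon_id]

    def mutation(self, mutation_id: str) -> MutationDef:
        return self._mutation_index[mutation_id]

    @property
    def mutation_ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations]

    @property
    def genes(self) -> set[str]:
        return {m.gene for m in self.mutations}

    def mutations_on(self, amplicon_id: str) -> list[MutationDef]:
        return [m for m in self.mutations if m.amplicon_id == amplicon_id]

    def mutant_haplotype(self, mutation_id: str) -> str:
        """Amplicon sequence with the mutation's alt allele substituted."""
        m = self.mutation(mutation_id)
        seq = self.amplicon(m.amplicon_id).sequence
        lo, hi = m.ref_span
        return seq[:lo] + m.alt_allele + seq[hi:]

    def genomes_from_mass(self, dna_mass_ng: float) -> float:
        """Haploid genome equivalents in ``dna_mass_ng`` nanograms of DNA."""
        return dna_mass_ng * 1000.0 / self.genome_mass_pg


# ---------------------------------------------------------------------------
# validation


def validate_panel(panel: Panel) -> list[str]:
    """Check all panel invariants; returns a list of violations (empty = valid)."""
    problems: list[str] = []
    seen: set[str] = set()
    for m in panel.mutations:
        if m.mutation_id in seen:
            problems.append(f"duplicate mutation_id {m.mutation_id!r}")
        seen.add(m.mutation_id)
        if m.ref_allele == m.alt_allele:
            problems.append(f"{m.mutation_id}: ref_allele equals alt_allele")
        if not m.ref_allele:
            problems.append(f"{m.mutation_id}: empty ref_allele")
        for name, allele in (("ref", m.ref_allele), ("alt", m.alt_allele)):
            if any(b not in NUCLEOTIDES for b in allele):
                problems.append(f"{m.mutation_id}: non-ACGT {name}_allele {allele!r}")
        if m.amplicon_id not in panel._amplicon_index:
            problems.append(f"{m.mutation_id}: unknown amplicon {m.amplicon_id!r}")
            continue
        amp = panel.amplicon(m.amplicon_id)
        if m.offset < 0 or m.offset + len(m.ref_allele) > len(amp):
            problems.append(f"{m.mutation_id}: ref span {m.ref_span} outside amplicon")
            continue
        lo, hi = m.ref_span
        if amp.sequence[lo:hi] != m.ref_allele:
            problems.append(
                f"{m.mutation_id}: amplicon {m.amplicon_id} has "
                f"{amp.sequence[lo:hi]!r} at {m.ref_span}, expected {m.ref_allele!r}"
            )
        ilo, ihi = amp.ipc_identifier_span
        if lo < ihi and ilo < hi:
            problems.append(
                f"{m.mutation_id}: ref span {m.ref_span} overlaps IPC identifier "
                f"span {amp.ipc_identifier_span} on {m.amplicon_id}"
            )
    for a in panel.amplicons:
        if any(b not in NUCLEOTIDES for b in a.sequence):
            problems.append(f"{a.amplicon_id}: non-ACGT bases in sequence")
        for name, (lo, hi) in (
            ("primer_fwd_span", a.primer_fwd_span),
            ("primer_rev_span", a.primer_rev_span),
            ("ipc_identifier_span", a.ipc_identifier_span),
        ):
            if not (0 <= lo <= hi <= len(a)):
                problems.append(f"{a.amplicon_id}: {name} {(lo, hi)} outside sequence")
    return problems


# ---------------------------------------------------------------------------
# IO


def _parse_span(obj) -> tuple[int, int]:
    lo, hi = obj
    return (int(lo), int(hi))


def load_panel(
    panel_path: str | Path,
    fasta_path: str | Path,
    spans_path: str | Path | None = None,
    genome_mass_pg: float = DEFAULT_GENOME_MASS_PG,
) -> Panel:
    """Load and validate a panel from a mutation TSV + amplicon FASTA.

    ``spans_path`` is a JSON sidecar mapping amplicon_id to
    ``{"ipc_identifier_span": [lo, hi), "primer_fwd_span": ..., "primer_rev_span": ...}``;
    when omitted, ``<fasta_path>.spans.json`` is used if present, otherwise a
    spans file is required only if any amplicon is referenced.
    """
    panel_path = Path(panel_path)
    fasta_path = Path(fasta_path)
    if not panel_path.exists():
        raise PanelError(f"panel table not found: {panel_path}")
    if not fasta_path.exists():
        raise PanelError(f"amplicon FASTA not found: {fasta_path}")
    df = pd.read_csv(panel_path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel table missing columns: {missing}")

    if spans_path is None:
        candidate = fasta_path.with_suffix(fasta_path.suffix + ".spans.json")
        spans_path = candidate if candidate.exists() else None
    spans: dict = {}
    if spans_path is not None:
        spans = json.loads(Path(spans_path).read_text())

    amplicons = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        meta = spans.get(rec.id, {})
        seq = str(rec.seq).upper()
        amplicons.append(
            Amplicon(
                amplicon_id=rec.id,
                sequence=seq,
                primer_fwd_span=_parse_span(meta.get("primer_fwd_span", (0, 0))),
                primer_rev_span=_parse_span(meta.get("primer_rev_span", (len(seq), len(seq)))),
                ipc_identifier_span=_parse_span(meta.get("ipc_identifier_span", (0, 0))),
            )
        )
    amp_ids = {a.amplicon_id for a in amplicons}

    mutations = []
    for row in df.itertuples(index=False):
        alt = row.alt_allele.strip()
        lod = row.published_lod_pct
        mutations.append(
            MutationDef(
                mutation_id=row.mutation_id.strip(),
                gene=row.gene.strip(),
                amplicon_id=row.amplicon_id.strip(),
                offset=int(row.offset),
                ref_allele=row.ref_allele.strip().upper(),
                alt_allele="" if alt == DELETION_TOKEN else alt.upper(),
                published_lod_pct=float(lod) if pd.notna(lod) else None,
            )
        )
    for m in mutations:
        if m.amplicon_id not in amp_ids:
            raise PanelError(f"mutation {m.mutation_id}: no amplicon {m.amplicon_id!r} in FASTA")

    panel = Panel(mutations=mutations, amplicons=amplicons, genome_mass_pg=genome_mass_pg)
    problems = validate_panel(panel)
    if problems:
        raise PanelError("invalid panel:\n  " + "\n  ".join(problems))
    return panel


def write_panel(
    panel: Panel,
    panel_path: str | Path,
    fasta_path: str | Path,
    spans_path: str | Path | None = None,
) -> None:
    """Write a panel back to TSV + FASTA (+ spans JSON sidecar)."""
    rows = [
        {
            "mutation_id": m.mutation_id,
            "gene": m.gene,
            "amplicon_id": m.amplicon_id,
            "offset": m.offset,
            "ref_allele": m.ref_allele,
            "alt_allele": m.alt_allele if m.alt_allele else DELETION_TOKEN,
            "published_lod_pct": m.published_lod_pct,
        }
        for m in panel.mutations
    ]
    fasta_path = Path(fasta_path)
    with open(panel_path, "w") as fh:
        fh.write("# panel mutation table; coordinates 0-based half-open\n")
        pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(fh, sep="\t", index=False)
    records = [
        SeqRecord(Seq(a.sequence), id=a.amplicon_id, description="")
        for a in panel.amplicons
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if spans_path is None:
        spans_path = fasta_path.with_suffix(fasta_path.suffix + ".spans.json")
    spans = {
        a.amplicon_id: {
            "primer_fwd_span": list(a.primer_fwd_span),
            "primer_rev_span": list(a.primer_rev_span),
            "ipc_identifier_span": list(a.ipc_identifier_span),
        }
        for a in panel.amplicons
    }
    Path(spans_path).write_text(json.dumps(spans, indent=1) + "\n")


# ---------------------------------------------------------------------------
# synthetic references


def synthesize_references(
    panel_rows,
    identifier_len: int = 8,
    seed: int = 0,
    amplicon_len: int = 150,
    ipc_span_start: int = 20,
    primer_len: int = 20,
    genome_mass_pg: float = DEFAULT_GENOME_MASS_PG,
) -> Panel:
    """Build a Panel with seeded random amplicons consistent with every mutation.

    ``panel_rows`` is a DataFrame (or iterable of mapping rows) with the panel
    TSV columns.  Bases covered by any mutation's reference allele are pinned;
    everything else is drawn uniformly from ACGT with a generator seeded by
    ``seed``, so regeneration is bit-identical.  Overlapping reference spans
    on one amplicon must agree base-by-base or :class:`PanelConflictError`
    is raised.
    """
    if identifier_len < 6:
        raise PanelError("identifier_len must be >= 6")
    if isinstance(panel_rows, pd.DataFrame):
        rows = panel_rows.to_dict("records")
    else:
        rows = [dict(r) for r in panel_rows]

    mutations = []
    for r in rows:
        alt = str(r["alt_allele"]).strip()
        lod = r.get("published_lod_pct")
        mutations.append(
            MutationDef(
                mutation_id=str(r["mutation_id"]).strip(),
                gene=str(r["gene"]).strip(),
                amplicon_id=str(r["amplicon_id"]).strip(),
                offset=int(r["offset"]),
                ref_allele=str(r["ref_allele"]).strip().upper(),
                alt_allele="" if alt == DELETION_TOKEN else alt.upper(),
                published_lod_pct=float(lod) if lod is not None and pd.notna(lod) else None,
            )
        )

    ipc_span = (ipc_span_start, ipc_span_start + identifier_len)
    constraints: dict[str, dict[int, tuple[str, str]]] = {}
    for m in mutations:
        amp_constraints = constraints.setdefault(m.amplicon_id, {})
        if m.offset + len(m.ref_allele) > amplicon_len:
            raise PanelError(
                f"{m.mutation_id}: ref span {m.ref_span} exceeds amplicon_len {amplicon_len}"
            )
        if m.offset < ipc_span[1] and ipc_span[0] < m.offset + len(m.ref_allele):
            raise PanelError(f"{m.mutation_id}: ref span overlaps IPC identifier span")
        for i, base in enumerate(m.ref_allele):
            pos = m.offset + i
            prev = amp_constraints.get(pos)
            if prev is not None and prev[0] != base:
                raise PanelConflictError(
                    f"amplicon {m.amplicon_id} position {pos}: {m.mutation_id} wants "
                    f"{base!r} but {prev[1]} wants {prev[0]!r}"
                )
            amp_constraints[pos] = (base, m.mutation_id)

    rng = np.random.default_rng(seed)
    amplicons = []
    # iterate in first-appearance order for determinism
    seen_amps: list[str] = []
    for m in mutations:
        if m.amplicon_id not in seen_amps:
            seen_amps.append(m.amplicon_id)
    for amp_id in seen_amps:
        bases = rng.integers(0, 4, size=amplicon_len)
        seq = [NUCLEOTIDES[b] for b in bases]
        for pos, (base, _who) in constraints[amp_id].items():
            seq[pos] = base
        amplicons.append(
            Amplicon(
                amplicon_id=amp_id,
                sequence="".join(seq),
                primer_fwd_span=(0, primer_len),
                primer_rev_span=(amplicon_len - primer_len, amplicon_len),
                ipc_identifier_span=ipc_span,
            )
        )

    panel = Panel(mutations=mutations, amplicons=amplicons, genome_mass_pg=genome_mass_pg)
    problems = validate_panel(panel)
    if problems:
        raise PanelError("invalid synthesized panel:\n  " + "\n  ".join(problems))
    return panel


# ---------------------------------------------------------------------------
# packaged panel


def _data_path(name: str) -> Path:
    return Path(resources.files("panelcall") / "data" / name)


def builtin_panel_table() -> pd.DataFrame:
    """The packaged 46-mutation panel table (transcribed mutation list + LODs)."""
    return pd.read_csv(_data_path("hotspot_panel.tsv"), sep="\t", comment="#", dtype=str)


def load_builtin_panel() -> Panel:
    """Load the packaged 46-mutation panel with its synthetic amplicon references."""
    return load_panel(
        _data_path("hotspot_panel.tsv"),
        _data_path("amplicons_synthetic.fasta"),
        _data_path("amplicons_synthetic.fasta.spans.json"),
    )


def builtin_barcodes() -> list[str]:
    """The packaged sample barcode set (six 8-mers, min pairwise Hamming >= 3)."""
    df = pd.read_csv(_data_path("barcodes.tsv"), sep="\t", comment="#", dtype=str)
    return df["barcode"].tolist()
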