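"""Molecule-scale quantitation calibrated by spiked internal positive controls.

IPC molecules enter the assay at a known copy number and experience the same
PCR, enrichment and sequencing as genomic mutant molecules, so the average
number of clusters (merged reads) each IPC founder produces — the *cluster
yield* ``Y`` — converts an observed mutant cluster count ``C`` into an
estimate of mutant input copies ``N = C / Y``.  Because every IPC founder
carries its own random identifier, founders are recovered by binning IPC
clusters on the (identifier, sample barcode, mutation) key.

Two biases in the naive ``Y = clusters / observed bins`` are optionally
corrected:

* identifier collisions — two founders drawing the same N-mer fuse into one
  bin; the observed distinct-identifier count is inverted through
  ``E[distinct] = M * (1 - (1 - 1/M)**s)`` with ``M = 4**identifier_len``;
* founder dropout — founders that produced no sequenced cluster are unseen;
  the observed founder count is inverted through a zero-truncated Poisson
  model, bounded above by the known spike-in count.

Derived per-mutation quantities: abundance ``A = 100 * N / G`` (percent of
input genome equivalents ``G``) and plasma-normalized ``copies per 5 mL``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .panel import Panel
from .readproc import LABEL_IPC, LABEL_MUT, hamming


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class IpcBin:
    """Clusters sharing one (identifier, sample barcode, mutation) key."""

    identifier: str
    sample: str
    mutation_id: str
    cluster_count: int


def collapse_identifiers(counts: dict[str, int], max_distance: int = 1) -> dict[str, int]:
    """Absorb identifiers within ``max_distance`` of a more abundant identifier.

    Standard UMI-style error absorption: identifiers are visited in decreasing
    abundance (ties lexicographic); each is merged into the first already-kept
    identifier within Hamming distance ``max_distance``, else kept.
    """
    kept: dict[str, int] = {}
    for ident in sorted(counts, key=lambda k: (-counts[k], k)):
        for parent in kept:
            if len(parent) == len(ident) and hamming(parent, ident) <= max_distance:
                kept[parent] += counts[ident]
                break
        else:
            kept[ident] = counts[ident]
    return kept


def bin_ipcs(
    ipc_clusters: pd.DataFrame, collapse_distance: int = 1
) -> list[IpcBin]:
    """Group IPC-labeled clusters into identifier bins.

    ``ipc_clusters`` needs columns ``sample``, ``mutation_id``, ``identifier``
    (one row per cluster).  Identifier-collapse absorbs likely sequencing
    errors before bins are formed; pass ``collapse_distance=0`` to disable.
    """
    if len(ipc_clusters) == 0:
        return []
    bins: list[IpcBin] = []
    grouped = ipc_clusters.groupby(["sample", "mutation_id"], sort=True)
    for (sample, mutation_id), grp in grouped:
        counts = grp["identifier"].value_counts().to_dict()
        if collapse_distance > 0:
            counts = collapse_identifiers(counts, collapse_distance)
        for ident in sorted(counts):
            bins.append(IpcBin(ident, sample, mutation_id, int(counts[ident])))
    return bins


# ---------------------------------------------------------------------------
# yield estimation


def _invert_collisions(n_observed: int, identifier_len: int) -> float:
    """Distinct founders consistent with ``n_observed`` distinct identifiers."""
    M = 4.0 ** identifier_len
    if n_observed >= M:
        return M
    return float(np.log1p(-n_observed / M) / np.log1p(-1.0 / M))


def _invert_dropout(s_observed: float, total_clusters: int, spiked: int) -> float:
    """Total founders under a zero-truncated Poisson read-count model.

    Solves ``s_obs = s * (1 - exp(-T/s))`` for the founder count ``s``; the
    left side is the expected number of founders seen at least once when
    ``T`` clusters spread Poisson-wise over ``s`` founders.  Clamped to
    ``[s_observed, spiked]``.
    """
    if s_observed <= 0:
        return 0.0
    f = lambda s: s * (1.0 - np.exp(-total_clusters / s)) - s_observed
    if f(spiked) <= 0:  # even the full spike cannot explain the observations
        return float(spiked)
    lo = s_observed
    if f(lo) >= 0:
        return float(lo)
    return float(brentq(f, lo, spiked, xtol=1e-9))


@dataclass(frozen=True)
class YieldEstimate:
    mutation_id: str
    sample: str
    total_clusters: int
    observed_bins: int
    effective_founders: float
    cluster_yield: float | None  # None when no IPC cluster was observed

    @property
    def available(self) -> bool:
        return self.cluster_yield is not None


def estimate_yield(
    bins: list[IpcBin],
    mutation_id: str,
    sample: str,
    spiked_ipc_copies: int,
    identifier_len: int = 8,
    correct: bool = True,
) -> YieldEstimate:
    """Average cluster yield per IPC founder for one (mutation, sample).

    With ``correct=False`` the yield is simply clusters per observed bin;
    otherwise the founder count is corrected for identifier collisions and
    unobserved founders (see module docstring).  When no IPC cluster was
    observed, the yield is unavailable and quantitation must be reported as
    missing, not zero.
    """
    if spiked_ipc_copies <= 0:
        raise QuantError("spiked_ipc_copies must be > 0")
    mine = [b for b in bins if b.mutation_id == mutation_id and b.sample == sample]
    T = sum(b.cluster_count for b in mine)
    k = len(mine)
    if T == 0:
        return YieldEstimate(mutation_id, sample, 0, 0, 0.0, None)
    if not correct:
        eff = float(k)
    else:
        s_obs = min(_invert_collisions(k, identifier_len), float(spiked_ipc_copies))
        eff = _invert_dropout(s_obs, T, spiked_ipc_copies)
    return YieldEstimate(mutation_id, sample, T, k, eff, T / eff)


# ---------------------------------------------------------------------------
# copy-scale arithmetic


def estimate_copies(mutant_clusters: int, cluster_yield: float | None) -> float | None:
    """Input mutant copies N = C / Y; None when the yield is unavailable."""
    if mutant_clusters < 0:
        raise QuantError("mutant cluster count must be >= 0")
    if mutant_clusters == 0:
        return 0.0
    if cluster_yield is None:
        return None
    if cluster_yield <= 0:
        raise QuantError("cluster_yield must be > 0")
    return mutant_clusters / cluster_yield


def abundance(est_copies: float, input_genomes: float) -> float:
    """Mutant abundance as a percentage of all input genome equivalents."""
    if input_genomes <= 0:
        raise QuantError("input_genomes must be > 0")
    return 100.0 * est_copies / input_genomes


def normalize_per_5ml(est_copies: float, plasma_ml: float) -> float:
    """Copies normalized to a 5 mL plasma input volume."""
    if plasma_ml <= 0:
        raise QuantError("plasma_ml must be > 0")
    return est_copies * 5.0 / plasma_ml


# ---------------------------------------------------------------------------
# per-sample quantitation table


QUANT_COLUMNS = [
    "sample",
    "mutation_id",
    "mutant_clusters",
    "ipc_clusters",
    "ipc_bins",
    "cluster_yield",
    "est_copies",
    "input_genomes",
    "abundance_pct",
    "copies_per_5ml",
    "flags",
]


def quantify_sample(
    clusters: pd.DataFrame,
    panel: Panel,
    sample: str,
    ipc_spiked: dict[str, int] | int,
    input_genomes: float,
    plasma_ml: float = 5.0,
    collapse_distance: int = 1,
    correct_yield: bool = True,
) -> pd.DataFrame:
    """Per-mutation quantitation for one sample from classified clusters.

    ``clusters`` is the classified-cluster table (columns ``sample``,
    ``label``, ``mutations`` — semicolon-joined ids — and ``identifier``).
    IPC spike-ins never enter the abundance denominator: they are synthetic
    molecules, not input genomes.
    """
    if input_genomes <= 0:
        raise QuantError("input_genomes must be > 0")
    sub = clusters[clusters["sample"] == sample]
    mut_rows = sub[sub["label"] == LABEL_MUT]
    ipc_rows = sub[sub["label"] == LABEL_IPC]

    mut_counts: dict[str, int] = {m: 0 for m in panel.mutation_ids}
    for muts in mut_rows["mutations"]:
        for mid in str(muts).split(";"):
            if mid in mut_counts:
                mut_counts[mid] += 1

    ipc_expanded = []
    for row in ipc_rows.itertuples(index=False):
        for mid in str(row.mutations).split(";"):
            ipc_expanded.append((sample, mid, row.identifier))
    ipc_df = pd.DataFrame(ipc_expanded, columns=["sample", "mutation_id", "identifier"])
    bins = bin_ipcs(ipc_df, collapse_distance=collapse_distance)

    records = []
    for m in panel.mutations:
        spiked = ipc_spiked if isinstance(ipc_spiked, int) else int(ipc_spiked.get(m.mutation_id, 0))
        ident_len = panel.amplicon(m.amplicon_id).identifier_len
        flags = []
        if spiked > 0:
            ye = estimate_yield(
                bins, m.mutation_id, sample, spiked, identifier_len=ident_len, correct=correct_yield
            )
        else:
            ye = YieldEstimate(m.mutation_id, sample, 0, 0, 0.0, None)
            flags.append("no_ipc_spiked")
        C = mut_counts[m.mutation_id]
        if ye.available:
            N = estimate_copies(C, ye.cluster_yield)
        else:  # no calibration -> quantitation is missing, not zero
            N = None
            flags.append("yield_unavailable")
        if N is None:
            flags.append("copies_unavailable")
            A = cp5 = np.nan
        else:
            A = abundance(N, input_genomes)
            if A > 100.0:
                flags.append("abundance_clipped")
                A = 100.0
            cp5 = normalize_per_5ml(N, plasma_ml)
        records.append(
            dict(
                sample=sample,
                mutation_id=m.mutation_id,
                mutant_clusters=C,
                ipc_clusters=ye.total_clusters,
                ipc_bins=ye.observed_bins,
                cluster_yield=ye.cluster_yield if ye.available else np.nan,
                est_copies=N if N is not None else np.nan,
                input_genomes=float(input_genomes),
                abundance_pct=A,
                copies_per_5ml=cp5,
                flags=";".join(flags),
            )
        )
    return pd.DataFrame(records, columns=QUANT_COLUMNS)
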