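"""Read processing: pair merging, demultiplexing, amplicon alignment, classification.

A merged read pair is the assay's countable unit (a "cluster").  Each cluster
is assigned to a sample by its inline barcode, aligned to the best panel
amplicon by edit distance, and labeled:

* ``WT``   — reference at every panel variant locus and at the IPC region;
* ``MUT``  — a panel mutation's alt allele present with intact reference
  flanks and a reference IPC region (genomic mutant);
* ``IPC``  — alt allele present and a non-reference identifier in the IPC
  region (spiked internal control; the identifier is extracted);
* ``UNASSIGNED`` — anything that cannot be established confidently.

Classification is by exact context matching: a mutation is "present" when
``flank`` reference bases on each side of the alt allele match exactly.  This
is deliberately conservative — a substitution error inside the window
demotes the cluster to UNASSIGNED rather than risking a false mutant call,
and coordinate shifts from indel alleles are handled for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np

from .panel import Panel
from .simulate import revcomp

LABEL_WT = "WT"
LABEL_MUT = "MUT"
LABEL_IPC = "IPC"
LABEL_UNASSIGNED = "UNASSIGNED"


class BarcodeConfigError(ValueError):
    """Barcode set incompatible with the requested mismatch tolerance."""


# ---------------------------------------------------------------------------
# pair merging


@dataclass(frozen=True)
class MergeResult:
    sequence: str
    qualities: str
    offset: int  # start of reverse read relative to forward read
    overlap: int
    mismatches: int


def merge_pairs(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergeResult | None:
    """Merge a read pair by its best ungapped overlap, or None on failure.

    The reverse read is reverse-complemented and slid along the forward read;
    among offsets whose overlap is at least ``min_overlap`` with a mismatch
    fraction at most ``max_mismatch_frac``, the one with the most matching
    bases wins (ties: longer overlap, then smaller offset).  Overlap
    disagreements resolve toward the higher-quality base (forward read on
    quality ties); merged qualities take the per-base maximum in the overlap.
    """
    if not r1_seq or not r2_seq:
        return None
    s2 = revcomp(r2_seq)
    q2 = r2_qual[::-1]
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    L1, L2 = len(a1), len(a2)

    best = None  # (matches, overlap, -offset)
    best_k = None
    for k in range(-(L2 - min_overlap), L1 - min_overlap + 1):
        lo1, hi1 = max(0, k), min(L1, k + L2)
        ov = hi1 - lo1
        if ov < min_overlap:
            continue
        mism = int(np.count_nonzero(a1[lo1:hi1] != a2[lo1 - k : hi1 - k]))
        if mism > max_mismatch_frac * ov:
            continue
        key = (ov - mism, ov, -k)
        if best is None or key > best:
            best, best_k = key, k
    if best_k is None:
        return None

    k = best_k
    lo1, hi1 = max(0, k), min(L1, k + L2)
    seq: list[str] = []
    qual: list[str] = []
    if k > 0:
        seq.append(r1_seq[:k])
        qual.append(r1_qual[:k])
    elif k < 0:
        seq.append(s2[:-k])
        qual.append(q2[:-k])
    for i in range(lo1, hi1):
        b1, b2 = r1_seq[i], s2[i - k]
        c1, c2 = r1_qual[i], q2[i - k]
        if b1 == b2 or c1 >= c2:
            seq.append(b1)
        else:
            seq.append(b2)
        qual.append(max(c1, c2))
    if k + L2 > L1:
        seq.append(s2[L1 - k :])
        qual.append(q2[L1 - k :])
    elif hi1 < L1:
        seq.append(r1_seq[hi1:])
        qual.append(r1_qual[hi1:])
    mism = int(best[1] - best[0])
    return MergeResult(
        sequence="".join(seq),
        qualities="".join(qual),
        offset=k,
        overlap=int(best[1]),
        mismatches=mism,
    )


# ---------------------------------------------------------------------------
# demultiplexing


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def check_barcode_set(barcodes: dict[str, str], max_mismatch: int) -> None:
    """Demultiplexing is unambiguous only if min pairwise distance > 2*max_mismatch."""
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) > 1:
        raise BarcodeConfigError("barcodes must share one length")
    for (sa, ba), (sb, bb) in combinations(barcodes.items(), 2):
        d = hamming(ba, bb)
        if d <= 2 * max_mismatch:
            raise BarcodeConfigError(
                f"barcodes {sa}:{ba} and {sb}:{bb} at Hamming distance {d} "
                f"cannot tolerate {max_mismatch} mismatches"
            )


def assign_barcode(
    sequence: str, barcodes: dict[str, str], max_mismatch: int = 1
) -> str | None:
    """Sample id for the cluster's inline barcode prefix, or None."""
    bc_len = len(next(iter(barcodes.values())))
    prefix = sequence[:bc_len]
    if len(prefix) < bc_len:
        return None
    best_sample, best_d = None, None
    for sample, bc in barcodes.items():
        d = hamming(prefix, bc)
        if best_d is None or d < best_d:
            best_sample, best_d = sample, d
    return best_sample if best_d is not None and best_d <= max_mismatch else None


def demultiplex(
    sequences: list[str], barcodes: dict[str, str], max_mismatch: int = 1
) -> tuple[dict[str, list[int]], list[int]]:
    """Partition cluster indices by sample; returns (per-sample, unassigned)."""
    check_barcode_set(barcodes, max_mismatch)
    assigned: dict[str, list[int]] = {s: [] for s in barcodes}
    unassigned: list[int] = []
    for i, seq in enumerate(sequences):
        sample = assign_barcode(seq, barcodes, max_mismatch)
        if sample is None:
            unassigned.append(i)
        else:
            assigned[sample].append(i)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# amplicon alignment


@dataclass(frozen=True)
class AlignmentResult:
    amplicon_id: str
    edit_distance: int
    tie: bool


def align_to_amplicons(
    sequence: str, panel: Panel, max_edit_frac: float = 0.2
) -> AlignmentResult | None:
    """Best panel amplicon by global edit distance, or None if too divergent.

    Ties are broken toward the lexicographically smallest amplicon_id and
    flagged.  The acceptance threshold scales with the longer of the two
    sequences so short fragments are not spuriously assigned.
    """
    if not panel.amplicons:
        raise ValueError("panel has no amplicons")
    best: AlignmentResult | None = None
    for amp in sorted(panel.amplicons, key=lambda a: a.amplicon_id):
        d = edlib.align(sequence, amp.sequence, mode="NW")["editDistance"]
        if best is None or d < best.edit_distance:
            best = AlignmentResult(amp.amplicon_id, d, tie=False)
        elif d == best.edit_distance:
            best = AlignmentResult(best.amplicon_id, d, tie=True)
    amp_len = len(panel.amplicon(best.amplicon_id).sequence)
    if best.edit_distance > max_edit_frac * max(len(sequence), amp_len):
        return None
    return best


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class Classification:
    label: str  # WT | MUT | IPC | UNASSIGNED
    mutations: tuple[str, ...] = ()
    identifier: str | None = None


@dataclass
class _AmpliconContexts:
    mut_ctx: dict[str, str]
    wt_ctx: dict[str, str]
    ipc_left: str
    ipc_right: str
    ipc_ref: str
    ident_len: int


class ClusterClassifier:
    """Precomputed per-amplicon context tables plus a classification cache.

    ``flank`` reference bases on each side of an allele (and of the IPC
    identifier region) must match exactly for the feature to be scored.
    """

    def __init__(self, panel: Panel, flank: int = 10):
        self.panel = panel
        self.flank = flank
        self._ctx: dict[str, _AmpliconContexts] = {}
        self._cache: dict[tuple[str, str], Classification] = {}
        for amp in panel.amplicons:
            seq = amp.sequence
            ilo, ihi = amp.ipc_identifier_span
            mut_ctx, wt_ctx = {}, {}
            for m in panel.mutations_on(amp.amplicon_id):
                lo, hi = m.ref_span
                mut_ctx[m.mutation_id] = seq[max(0, lo - flank) : lo] + m.alt_allele + seq[hi : hi + flank]
                wt_ctx[m.mutation_id] = seq[max(0, lo - flank) : hi + flank]
            self._ctx[amp.amplicon_id] = _AmpliconContexts(
                mut_ctx=mut_ctx,
                wt_ctx=wt_ctx,
                ipc_left=seq[max(0, ilo - flank) : ilo],
                ipc_right=seq[ihi : ihi + flank],
                ipc_ref=seq[ilo:ihi],
                ident_len=ihi - ilo,
            )

    def _ipc_region(self, ctx: _AmpliconContexts, seq: str) -> tuple[str, str | None]:
        """('ref'|'alt'|'near_ref'|'unknown', identifier).

        An identifier within Hamming distance 1 of the reference sequence is
        overwhelmingly a genomic read carrying one substitution error rather
        than a genuine random identifier (25 of 4**8 identifiers fall that
        close); scoring it 'near_ref' keeps such reads out of both the mutant
        count and the IPC bins instead of contaminating the yield estimate.
        """
        if not ctx.ident_len:
            return "ref", None
        i = seq.find(ctx.ipc_left)
        if i < 0:
            return "unknown", None
        start = i + len(ctx.ipc_left)
        ident = seq[start : start + ctx.ident_len]
        right = seq[start + ctx.ident_len : start + ctx.ident_len + len(ctx.ipc_right)]
        if len(ident) < ctx.ident_len or right != ctx.ipc_right:
            return "unknown", None
        if ident == ctx.ipc_ref:
            return "ref", ident
        if hamming(ident, ctx.ipc_ref) <= 1:
            return "near_ref", ident
        return "alt", ident

    def classify(self, amplicon_id: str, sequence: str) -> Classification:
        key = (amplicon_id, sequence)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ctx = self._ctx[amplicon_id]
        muts = tuple(mid for mid, mc in ctx.mut_ctx.items() if mc in sequence)
        ipc_status, ident = self._ipc_region(ctx, sequence)
        if muts and ipc_status == "alt":
            res = Classification(LABEL_IPC, muts, ident)
        elif muts and ipc_status == "ref":
            res = Classification(LABEL_MUT, muts)
        elif (
            not muts
            and ipc_status == "ref"
            and all(wc in sequence for wc in ctx.wt_ctx.values())
        ):
            res = Classification(LABEL_WT)
        else:
            res = Classification(LABEL_UNASSIGNED)
        self._cache[key] = res
        return res


def classify_cluster(
    sequence: str, panel: Panel, amplicon_id: str, flank: int = 10
) -> Classification:
    """Classify one aligned cluster (convenience wrapper over ClusterClassifier)."""
    return ClusterClassifier(panel, flank).classify(amplicon_id, sequence)
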