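"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python loops over
every possibility, against which the optimized implementations are checked
for exact agreement.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_oracle(
    r1: str, q1: str, r2: str, q2: str, min_overlap: int, max_mismatch_frac: float
):
    """Exhaustive all-offsets ungapped overlap merge.

    Same ranking contract as the implementation: among offsets with
    overlap >= min_overlap and mismatches <= max_mismatch_frac * overlap,
    maximize (matches, overlap, -offset); consensus prefers the
    higher-quality base, forward read on ties.  Returns merged sequence
    or None.
    """
    if not r1 or not r2:
        return None
    s2, qq2 = rc(r2), q2[::-1]
    L1, L2 = len(r1), len(s2)
    best_key, best_k = None, None
    for k in range(-L2 + 1, L1):
        pairs = [
            (i, i - k)
            for i in range(max(0, k), min(L1, k + L2))
        ]
        ov = len(pairs)
        if ov < min_overlap:
            continue
        mism = sum(1 for i, j in pairs if r1[i] != s2[j])
        if mism > max_mismatch_frac * ov:
            continue
        key = (ov - mism, ov, -k)
        if best_key is None or key > best_key:
            best_key, best_k = key, k
    if best_k is None:
        return None
    k = best_k
    out = []
    for pos in range(min(0, k), max(L1, k + L2)):
        in1 = 0 <= pos < L1
        in2 = 0 <= pos - k < L2
        if in1 and in2:
            b1, b2 = r1[pos], s2[pos - k]
            c1, c2 = q1[pos], qq2[pos - k]
            out.append(b1 if (b1 == b2 or c1 >= c2) else b2)
        elif in1:
            out.append(r1[pos])
        else:
            out.append(s2[pos - k])
    return "".join(out)


def edit_distance_dp(a: str, b: str) -> int:
    """Classic full dynamic-programming Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def truth_ipc_bins(truth, panel) -> dict:
    """Brute-force grouping of simulator ground truth into expected IPC bins.

    Returns {(mutation_id, identifier): total reads} over IPC founders with
    at least one surviving read, merging founders that drew the same
    identifier and dropping identifiers within Hamming distance 1 of the
    reference identifier-region sequence (such reads are indistinguishable
    from genomic reads with one error and are excluded by classification).
    """
    bins: dict = {}
    for row in truth.itertuples(index=False):
        if row.founder_class != "IPC" or row.read_count == 0:
            continue
        amp = panel.amplicon(row.amplicon_id)
        lo, hi = amp.ipc_identifier_span
        ref_ident = amp.sequence[lo:hi]
        if hamming(row.identifier, ref_ident) <= 1:
            continue
        key = (row.mutation_id, row.identifier)
        bins[key] = bins.get(key, 0) + int(row.read_count)
    return bins
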