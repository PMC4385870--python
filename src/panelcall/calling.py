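"""Limits of detection from wild-type background runs, and mutation calling.

The per-mutation limit of detection (LOD) is the greater of

* the allele fraction of a single mutant copy at the assay's standard input
  (``100 / G`` percent for ``G`` genome equivalents), and
* three sample standard deviations above the mean background abundance
  observed across repeated wild-type-only runs.

A mutation is called positive in a sample only when at least one input
mutant copy is estimated (``est_copies >= 1``) and its abundance strictly
exceeds the LOD.  Mutations whose cluster yield could not be measured are
reported "not evaluable" — never negative.  Backgrounds are estimated per
mutation, not pooled: different mutations have very different error-driven
backgrounds, which is why published LODs span 0.001%–0.024%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOD_COLUMNS = [
    "mutation_id",
    "background_mean_pct",
    "background_sd_pct",
    "n_background_runs",
    "single_copy_fraction_pct",
    "lod_pct",
]

CALL_COLUMNS = [
    "sample",
    "mutation_id",
    "est_copies",
    "abundance_pct",
    "lod_pct",
    "margin_pct",
    "call",  # positive | negative | not_evaluable
]


class CallingError(ValueError):
    pass


def estimate_lod(
    background_quants: list[pd.DataFrame], standard_input_genomes: float
) -> pd.DataFrame:
    """Per-mutation LOD table from >= 2 background (wild-type run) quant tables.

    Each element of ``background_quants`` is a per-sample quantitation table
    (as produced by :func:`panelcall.quant.quantify_sample`); its
    ``abundance_pct`` column supplies one background observation per
    mutation.  SDs use the n-1 denominator.
    """
    if len(background_quants) < 2:
        raise CallingError("need >= 2 background runs (SD undefined otherwise)")
    if standard_input_genomes <= 0:
        raise CallingError("standard_input_genomes must be > 0")
    single_copy = 100.0 / standard_input_genomes
    stacked = pd.concat(background_quants, ignore_index=True)
    records = []
    for mutation_id, grp in stacked.groupby("mutation_id", sort=True):
        vals = grp["abundance_pct"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise CallingError(
                f"{mutation_id}: fewer than 2 evaluable background observations"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        records.append(
            dict(
                mutation_id=mutation_id,
                background_mean_pct=mean,
                background_sd_pct=sd,
                n_background_runs=len(vals),
                single_copy_fraction_pct=single_copy,
                lod_pct=max(single_copy, mean + 3.0 * sd),
            )
        )
    return pd.DataFrame(records, columns=LOD_COLUMNS)


def call_mutations(quant: pd.DataFrame, lods: pd.DataFrame) -> pd.DataFrame:
    """Apply the positive-call rule to one sample's quantitation table.

    Every quantified mutation is reported (negative calls included) with the
    raw margin ``abundance - LOD`` so near-threshold signals remain visible.
    """
    lod_map = dict(zip(lods["mutation_id"], lods["lod_pct"]))
    missing = [m for m in quant["mutation_id"] if m not in lod_map]
    if missing:
        raise CallingError(f"no LOD for mutations: {missing}")
    records = []
    for row in quant.itertuples(index=False):
        lod = float(lod_map[row.mutation_id])
        if np.isnan(row.est_copies):
            call, margin = "not_evaluable", np.nan
        else:
            margin = row.abundance_pct - lod
            positive = row.est_copies >= 1.0 and row.abundance_pct > lod
            call = "positive" if positive else "negative"
        records.append(
            dict(
                sample=row.sample,
                mutation_id=row.mutation_id,
                est_copies=row.est_copies,
                abundance_pct=row.abundance_pct,
                lod_pct=lod,
                margin_pct=margin,
                call=call,
            )
        )
    return pd.DataFrame(records, columns=CALL_COLUMNS)
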