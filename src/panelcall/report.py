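"""Presentation layers: titration tables, assay concordance, longitudinal series.

These operations assemble the downstream summaries a study reports: how well
detected copies track titrated input copies, how two assays (or tissue vs
plasma) agree across patients, and how per-mutation plasma copy levels evolve
around surgery relative to clinical markers such as CEA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# titration


def titration_report(
    samples: pd.DataFrame, min_input_copies: int | None = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split titration results into a titration table and a background table.

    ``samples`` needs columns ``sample``, ``input_copies``, ``detected_copies``
    and ``called`` (one row per sample).  Rows at zero input are routed to the
    background table; rows below ``min_input_copies`` are dropped from the
    titration table (the characterization convention that limits inputs to 10
    copies and greater, where sampling fluctuation is modest), never silently:
    the two tables plus the filter account for every input row.
    """
    required = {"sample", "input_copies", "detected_copies", "called"}
    missing = required - set(samples.columns)
    if missing:
        raise ReportError(f"titration table missing columns: {sorted(missing)}")
    background = samples[samples["input_copies"] == 0].reset_index(drop=True)
    nonzero = samples[samples["input_copies"] > 0]
    if min_input_copies is not None:
        nonzero = nonzero[nonzero["input_copies"] >= min_input_copies]
    return nonzero.reset_index(drop=True), background


# ---------------------------------------------------------------------------
# concordance

_NOT_ANALYZED = {"not analyzed", "not-analyzed", "na", "n/a", ""}


def _normalize_call(value) -> str | None:
    """Mutation label, 'WT', or None for a not-analyzed entry."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = re.sub(r"\(.*?\)", "", str(value)).strip()
    if text.lower() in _NOT_ANALYZED:
        return None
    return "WT" if text.upper() == "WT" else text


def concordance(inputs: pd.DataFrame) -> dict:
    """Patient-level agreement between two assays.

    ``inputs`` needs columns ``patient_id``, ``assay_a_call``, ``assay_b_call``
    whose values are a mutation label (optionally with a parenthesized
    abundance), ``WT``, or ``Not analyzed``.  A demonstrated discordance
    requires both assays to report and to differ; a not-analyzed comparator
    is counted with the concordant remainder (the convention under which 18
    of 19 cases agree when one comparator result is unavailable), and the
    stricter evaluable-only fraction is reported alongside.  Directional
    counts split discordances by which assay found the mutation.
    """
    if len(inputs) == 0:
        raise ReportError("concordance needs a non-empty input table")
    if inputs["patient_id"].duplicated().any():
        raise ReportError("patient_id values must be unique")
    n_total = len(inputs)
    n_evaluable = 0
    n_discordant = 0
    a_only = b_only = allele_mismatch = 0
    discordant_patients = []
    for row in inputs.itertuples(index=False):
        a = _normalize_call(row.assay_a_call)
        b = _normalize_call(row.assay_b_call)
        if a is None or b is None:
            continue
        n_evaluable += 1
        if a == b:
            continue
        n_discordant += 1
        discordant_patients.append(row.patient_id)
        if a != "WT" and b == "WT":
            a_only += 1
        elif a == "WT" and b != "WT":
            b_only += 1
        else:
            allele_mismatch += 1
    n_concordant = n_total - n_discordant
    return dict(
        n_total=n_total,
        n_evaluable=n_evaluable,
        n_discordant=n_discordant,
        n_concordant=n_concordant,
        pct_concordant=100.0 * n_concordant / n_total,
        n_concordant_evaluable=n_evaluable - n_discordant,
        pct_concordant_evaluable=(
            100.0 * (n_evaluable - n_discordant) / n_evaluable if n_evaluable else np.nan
        ),
        n_a_only=a_only,
        n_b_only=b_only,
        n_allele_mismatch=allele_mismatch,
        discordant_patients=discordant_patients,
    )


def load_builtin_concordance_table() -> pd.DataFrame:
    """The packaged 19-patient tissue KRAS two-assay comparison table."""
    path = Path(resources.files("panelcall") / "data" / "kras_tissue_concordance.tsv")
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# longitudinal monitoring


@dataclass
class LongitudinalSeries:
    """Per-patient time series of plasma mutation levels with event flags.

    Day 0 is surgery; negative/zero days are pre-operative.  ``table`` has one
    row per (day, mutation) with ``copies_per_5ml`` and ``positive``;
    ``events`` flags clonal dynamics: ``re_emergence`` (a pre-operatively
    detected mutation cleared post-operatively, then returned) and
    ``new_allele`` (a mutation first appearing after surgery).
    """

    patient_id: str
    table: pd.DataFrame
    cea: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    events: list[dict] = field(default_factory=list)

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.table["day"].unique().tolist())


def monitoring_series(
    calls: pd.DataFrame,
    patient_id: str,
    clinical: pd.DataFrame | None = None,
) -> LongitudinalSeries:
    """Merge per-timepoint call tables into one monitored series for a patient.

    ``calls`` needs columns ``patient_id``, ``day``, ``mutation_id``,
    ``copies_per_5ml``, ``positive``.  ``clinical`` (optional) carries
    ``day`` plus ``cea_ng_ml`` and/or ``event`` annotations.  Duplicate
    (day, mutation) rows are rejected.
    """
    sub = calls[calls["patient_id"] == patient_id].copy()
    if len(sub) == 0:
        raise ReportError(f"no timepoints for patient {patient_id!r}")
    if sub.duplicated(["day", "mutation_id"]).any():
        raise ReportError(f"duplicate (day, mutation) rows for {patient_id!r}")
    sub = sub.sort_values(["day", "mutation_id"]).reset_index(drop=True)

    events: list[dict] = []
    patient_has_pre = bool((sub["day"] <= 0).any())
    for mutation_id, grp in sub.groupby("mutation_id", sort=True):
        days = grp["day"].to_numpy(dtype=float)
        pos = grp["positive"].to_numpy(dtype=bool)
        pre = pos[days <= 0]
        post_days, post_pos = days[days > 0], pos[days > 0]
        if pre.size and pre.any():
            # cleared then returned?
            cleared_at = None
            for d, p in zip(post_days, post_pos):
                if not p and cleared_at is None:
                    cleared_at = d
                elif p and cleared_at is not None:
                    events.append(
                        dict(
                            event="re_emergence",
                            mutation_id=mutation_id,
                            cleared_day=float(cleared_at),
                            detected_day=float(d),
                        )
                    )
                    break
        elif patient_has_pre and not (pre.size and pre.any()) and post_pos.any():
            events.append(
                dict(
                    event="new_allele",
                    mutation_id=mutation_id,
                    detected_day=float(post_days[post_pos][0]),
                )
            )

    cea = None
    annotations = None
    if clinical is not None:
        if "cea_ng_ml" in clinical.columns:
            cea = clinical[["day", "cea_ng_ml"]].dropna().sort_values("day").reset_index(drop=True)
        if "event" in clinical.columns:
            annotations = clinical[["day", "event"]].dropna().sort_values("day").reset_index(drop=True)
    return LongitudinalSeries(
        patient_id=patient_id, table=sub, cea=cea, annotations=annotations, events=events
    )
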