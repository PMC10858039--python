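"""Somatic STR mutation calling from patient-matched healthy/tumour calls.

A locus is mutated when the biallelic allele-length multiset in the tumour
differs from the patient-matched healthy sample.  Tumour calls that are
homozygous for an allele absent from the healthy pair are excluded as
putative allele dropout (a heterozygous locus spuriously called homozygous
when one allele's reads are missed) and counted separately.  Per-allele step
sizes come from pairing the sorted healthy alleles with the sorted tumour
alleles positionally, which minimises the total absolute step for a diploid
pair.  Detection and per-patient fractions are locus-level; the step-size
histogram is per-allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

EVENT_COLUMNS = [
    "patient_id",
    "locus_id",
    "healthy_a",
    "healthy_b",
    "tumour_a",
    "tumour_b",
    "step_1",
    "step_2",
    "delta_mean",
    "has_insertion",
    "has_deletion",
]

COMPARISON_COLUMNS = [
    "patient_id",
    "locus_id",
    "healthy_a",
    "healthy_b",
    "tumour_a",
    "tumour_b",
    "mutated",
]


def select_healthy_reference(samples: pd.DataFrame) -> str:
    """Choose a patient's healthy reference sample.

    ``samples`` has columns sample_id, sample_type, n_calls for the healthy
    samples of one patient.  The sample with the most STR calls wins; ties
    prefer blood-derived normals, then the lexicographically smallest id.
    """
    healthy = samples[samples["sample_type"].isin(["blood_normal", "solid_tissue_normal"])]
    if healthy.empty:
        raise DataError("patient has no healthy sample to use as reference")
    ranked = healthy.assign(
        _blood=(healthy["sample_type"] == "blood_normal").astype(int)
    ).sort_values(
        ["n_calls", "_blood", "sample_id"], ascending=[False, False, True]
    )
    return str(ranked.iloc[0]["sample_id"])


def call_mutations(
    healthy_calls: pd.DataFrame,
    tumour_calls: pd.DataFrame,
    patient_id: str,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Compare matched calls at shared loci.

    Returns ``(events, comparisons, n_dropout)``: one event row per locus
    whose allele multisets differ, one comparison row per locus called in
    both samples and not excluded as dropout, and the count of excluded
    dropout candidates.
    """
    for name, frame in (("healthy", healthy_calls), ("tumour", tumour_calls)):
        if frame["locus_id"].duplicated().any():
            dup = frame["locus_id"][frame["locus_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate {name} call for locus {dup}")
    merged = healthy_calls.merge(
        tumour_calls, on="locus_id", suffixes=("_h", "_t"), how="inner"
    )
    ha = merged["allele_a_h"].to_numpy()
    hb = merged["allele_b_h"].to_numpy()
    ta = merged["allele_a_t"].to_numpy()
    tb = merged["allele_b_t"].to_numpy()
    # calls are stored sorted, so positional comparison == multiset comparison
    differs = (ha != ta) | (hb != tb)
    dropout = (ta == tb) & (ta != ha) & (ta != hb) & differs
    n_dropout = int(dropout.sum())
    keep = ~dropout
    step1 = ta - ha
    step2 = tb - hb
    comparisons = pd.DataFrame(
        {
            "patient_id": patient_id,
            "locus_id": merged["locus_id"],
            "healthy_a": ha,
            "healthy_b": hb,
            "tumour_a": ta,
            "tumour_b": tb,
            "mutated": differs,
        }
    )[keep].reset_index(drop=True)
    sel = differs & keep
    events = pd.DataFrame(
        {
            "patient_id": patient_id,
            "locus_id": merged["locus_id"][sel],
            "healthy_a": ha[sel],
            "healthy_b": hb[sel],
            "tumour_a": ta[sel],
            "tumour_b": tb[sel],
            "step_1": step1[sel],
            "step_2": step2[sel],
            "delta_mean": (step1[sel] + step2[sel]) / 2.0,
            "has_insertion": (step1[sel] > 0) | (step2[sel] > 0),
            "has_deletion": (step1[sel] < 0) | (step2[sel] < 0),
        }
    ).reset_index(drop=True)
    return events[EVENT_COLUMNS], comparisons[COMPARISON_COLUMNS], n_dropout


def call_cohort_mutations(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Run :func:`call_mutations` for every patient with a tumour and at least
    one healthy sample; the healthy reference is the healthy sample with the
    most calls.  Returns pooled events, pooled comparisons and per-patient
    dropout counts."""
    n_calls = calls.groupby("sample_id")["locus_id"].nunique()
    meta = metadata.assign(
        n_calls=metadata["sample_id"].map(n_calls).fillna(0).astype(int)
    )
    events_parts, comparison_parts, dropout = [], [], {}
    for patient_id, group in meta.groupby("patient_id", sort=True):
        tumours = group[group["sample_type"] == "primary_tumour"]
        healthy = group[group["sample_type"] != "primary_tumour"]
        if tumours.empty or healthy.empty or healthy["n_calls"].max() == 0:
            continue
        tumour_id = tumours.sort_values("n_calls", ascending=False).iloc[0]["sample_id"]
        healthy_id = select_healthy_reference(healthy)
        ev, comp, nd = call_mutations(
            calls[calls["sample_id"] == healthy_id],
            calls[calls["sample_id"] == tumour_id],
            str(patient_id),
        )
        events_parts.append(ev)
        comparison_parts.append(comp)
        dropout[str(patient_id)] = nd
    events = (
        pd.concat(events_parts, ignore_index=True)
        if events_parts
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    comparisons = (
        pd.concat(comparison_parts, ignore_index=True)
        if comparison_parts
        else pd.DataFrame(columns=COMPARISON_COLUMNS)
    )
    return events, comparisons, dropout


def step_size_histogram(
    events: pd.DataFrame, msi_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Probability mass of nonzero per-allele step sizes.

    With ``msi_labels`` (patient_id -> MSS/MSI) the mass is normalized within
    each group so each group's histogram sums to one; otherwise one pooled
    histogram is returned under group label "all".
    """
    steps = pd.concat(
        [
            events[["patient_id", "step_1"]].rename(columns={"step_1": "step"}),
            events[["patient_id", "step_2"]].rename(columns={"step_2": "step"}),
        ],
        ignore_index=True,
    )
    steps = steps[steps["step"] != 0]
    if msi_labels is not None:
        steps["group"] = steps["patient_id"].map(msi_labels)
    else:
        steps["group"] = "all"
    rows = []
    for group, sub in steps.groupby("group", sort=True):
        counts = sub["step"].value_counts().sort_index()
        total = counts.sum()
        for step, count in counts.items():
            rows.append(
                {"group": group, "step": int(step), "mass": count / total, "count": int(count)}
            )
    return pd.DataFrame(rows, columns=["group", "step", "mass", "count"])


@dataclass(frozen=True)
class PatientMutationSummary:
    patient_id: str
    msi_label: str | None
    n_compared: int
    n_mutated: int
    frac_mutated: float
    frac_with_insertion: float
    frac_with_deletion: float
    mean_abs_delta: float


def summarize_patient(
    events: pd.DataFrame,
    n_compared: int,
    patient_id: str,
    msi_label: str | None = None,
) -> PatientMutationSummary:
    """Per-patient mutation fractions over compared loci.

    A locus with both a positive and a negative allele step counts toward both
    the insertion and the deletion fraction.
    """
    if n_compared <= 0:
        raise DataError(f"patient {patient_id}: no compared loci to summarize")
    ev = events[events["patient_id"] == patient_id]
    n_mut = len(ev)
    return PatientMutationSummary(
        patient_id=patient_id,
        msi_label=msi_label,
        n_compared=n_compared,
        n_mutated=n_mut,
        frac_mutated=n_mut / n_compared,
        frac_with_insertion=float(ev["has_insertion"].sum()) / n_compared,
        frac_with_deletion=float(ev["has_deletion"].sum()) / n_compared,
        mean_abs_delta=float(np.abs(ev["delta_mean"]).mean()) if n_mut else 0.0,
    )


def summarize_cohort(
    events: pd.DataFrame,
    comparisons: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    labels = (
        metadata[metadata["sample_type"] == "primary_tumour"]
        .drop_duplicates("patient_id")
        .set_index("patient_id")["msi_label"]
    )
    rows = []
    for patient_id, comp in comparisons.groupby("patient_id", sort=True):
        summary = summarize_patient(
            events, len(comp), str(patient_id), labels.get(patient_id)
        )
        rows.append(summary.__dict__)
    return pd.DataFrame(rows)


def rank_patients_by_deletion(
    summaries: pd.DataFrame,
) -> tuple[pd.DataFrame, float | None]:
    """Order patients by their deletion fraction (descending) and report how
    concordant that ranking is with the MSI labels, as the AUC of the MSI
    label against the deletion fraction (Mann-Whitney U / (n_mss * n_msi)).
    Returns ``(ordered summaries, auc)``; auc is None for single-label cohorts.
    """
    if len(summaries) < 2:
        raise DataError("need at least two patients to rank")
    ordered = summaries.sort_values(
        "frac_with_deletion", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    msi = ordered[ordered["msi_label"] == "MSI"]["frac_with_deletion"].to_numpy()
    mss = ordered[ordered["msi_label"] == "MSS"]["frac_with_deletion"].to_numpy()
    if len(msi) == 0 or len(mss) == 0:
        return ordered, None
    u = stats.mannwhitneyu(msi, mss, alternative="two-sided").statistic
    return ordered, float(u / (len(msi) * len(mss)))
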