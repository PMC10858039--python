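"""Descriptive mutability statistics: MSI status, unit size, allele length.

Comparisons (one locus x patient healthy/tumour comparison each, with a
mutated flag) are pooled across patients and stratified by repeat unit size
and/or healthy allele length.  MSS-vs-MSI contrasts per stratum use
two-sided Fisher's exact tests on the pooled 2x2 table; pooling treats
comparisons as independent Bernoulli trials and ignores per-patient
clustering (a deliberate simplification, see docs).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


def _attach_context(
    comparisons: pd.DataFrame, panel: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    unit = panel.set_index("locus_id")["unit_size"]
    labels = (
        metadata[metadata["sample_type"] == "primary_tumour"]
        .drop_duplicates("patient_id")
        .set_index("patient_id")["msi_label"]
    )
    out = comparisons.copy()
    out["unit_size"] = out["locus_id"].map(unit)
    out["msi_label"] = out["patient_id"].map(labels)
    return out


def mutability_by_unit_size(
    comparisons: pd.DataFrame,
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Mutation frequency per (unit size, MSI group) plus a two-sided Fisher
    exact test contrasting MSS vs MSI within each unit size.

    Returns one row per unit size x group with columns n_compared, n_mutated,
    frequency, fisher_p (repeated across the two group rows; NaN when either
    group has no comparisons).
    """
    data = _attach_context(comparisons, panel, metadata)
    rows = []
    for unit_size, stratum in data.groupby("unit_size", sort=True):
        cells = {}
        for group in ("MSS", "MSI"):
            sub = stratum[stratum["msi_label"] == group]
            cells[group] = (int(sub["mutated"].sum()), int(len(sub)))
        if all(n > 0 for _, n in cells.values()):
            table = [
                [cells["MSS"][0], cells["MSS"][1] - cells["MSS"][0]],
                [cells["MSI"][0], cells["MSI"][1] - cells["MSI"][0]],
            ]
            fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            fisher_p = math.nan
        for group, (n_mut, n_comp) in cells.items():
            rows.append(
                {
                    "unit_size": int(unit_size),
                    "msi_group": group,
                    "n_compared": n_comp,
                    "n_mutated": n_mut,
                    "frequency": n_mut / n_comp if n_comp else math.nan,
                    "fisher_p": fisher_p,
                }
            )
    return pd.DataFrame(rows)


def healthy_mean_length(comparisons: pd.DataFrame) -> pd.Series:
    """Healthy allele length per comparison: mean of the healthy pair, rounded
    half-up to integer units."""
    mean = (comparisons["healthy_a"] + comparisons["healthy_b"]) / 2.0
    return np.floor(mean + 0.5).astype(int)


def mutability_by_allele_length(
    comparisons: pd.DataFrame,
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
    min_patients: int = 50,
) -> pd.DataFrame:
    """Mutation frequency by (unit size, healthy allele length, MSI group).

    Only strata in which a healthy/tumour comparison could be made in at
    least ``min_patients`` distinct patients are reported.
    """
    data = _attach_context(comparisons, panel, metadata)
    data["allele_length"] = healthy_mean_length(data)
    rows = []
    grouped = data.groupby(["unit_size", "allele_length", "msi_label"], sort=True)
    for (unit_size, length, group), stratum in grouped:
        n_patients = stratum["patient_id"].nunique()
        if n_patients < min_patients:
            continue
        n_comp = len(stratum)
        n_mut = int(stratum["mutated"].sum())
        rows.append(
            {
                "unit_size": int(unit_size),
                "allele_length": int(length),
                "msi_group": group,
                "n_patients": n_patients,
                "n_compared": n_comp,
                "n_mutated": n_mut,
                "frequency": n_mut / n_comp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_size",
            "allele_length",
            "msi_group",
            "n_patients",
            "n_compared",
            "n_mutated",
            "frequency",
        ],
    )


def stage_step_correlation(
    events: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[float, float]:
    """Spearman rank correlation between tumour stage and the absolute mean
    allele-length change of mutations in MSI tumours (tie-corrected p)."""
    tumours = metadata[metadata["sample_type"] == "primary_tumour"].drop_duplicates(
        "patient_id"
    )
    msi = tumours[tumours["msi_label"] == "MSI"].set_index("patient_id")
    stages = msi["tumour_stage"]
    data = events[events["patient_id"].isin(msi.index)].copy()
    data["stage"] = data["patient_id"].map(stages)
    data = data.dropna(subset=["stage"])
    if data["stage"].nunique() < 3:
        raise DataError("need at least 3 distinct tumour stages for a rank correlation")
    rho, p = stats.spearmanr(
        data["stage"].astype(float), np.abs(data["delta_mean"].astype(float))
    )
    return float(rho), float(p)


def compare_patient_fractions(
    summaries: pd.DataFrame, column: str
) -> tuple[float, float]:
    """Generic two-group Mann-Whitney U comparison of a per-patient fraction
    (e.g. ``frac_with_insertion``) between MSS and MSI patients.
    Returns (U, two-sided p)."""
    mss = summaries[summaries["msi_label"] == "MSS"][column].astype(float)
    msi = summaries[summaries["msi_label"] == "MSI"][column].astype(float)
    if mss.empty or msi.empty:
        raise DataError("both MSS and MSI patients are required for a comparison")
    res = stats.mannwhitneyu(msi, mss, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
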