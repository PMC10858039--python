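"""eSTR validation: predicting expression-change direction after mutation.

Held-out patients with matched healthy/tumour expression are mapped onto the
discovery cohort's normalized scale via stored per-gene reference quantiles.
For every somatic mutation at a significant eSTR, the sign of
``beta * delta_mean`` predicts whether expression should rise or fall; the
observed normalized change decides whether the prediction was correct.  The
expected impact of a mutation is ``|beta| * |delta_mean|`` — the predicted
magnitude of normalized-expression change — and accuracy is additionally
stratified by quartile of expected impact.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .mutations import call_cohort_mutations

RECORD_COLUMNS = [
    "patient_id",
    "locus_id",
    "gene_id",
    "beta",
    "delta_mean",
    "expected_impact",
    "observed_change",
    "predicted_sign",
    "correct",
]


def normalize_to_reference(value: float, reference: list[float]) -> float:
    """Map a raw TPM value onto the discovery cohort's normal scale.

    The empirical quantile within the sorted reference vector uses the
    mid-rank for exact matches and linear interpolation between neighbours,
    clamped to [0.5/n, 1 - 0.5/n] before applying Phi^-1 — so a discovery
    sample re-normalized through its own reference reproduces its
    inverse-normal score exactly (tie-free case).
    """
    n = len(reference)
    if n == 0:
        raise DataError("empty reference quantiles for gene")
    lo = bisect_left(reference, value)
    hi = bisect_right(reference, value)
    if lo != hi:  # exact match(es): average rank of the tied block
        rank = (lo + 1 + hi) / 2.0
        q = (rank - 0.5) / n
    elif lo == 0:
        q = 0.5 / n
    elif lo == n:
        q = 1.0 - 0.5 / n
    else:
        left, right = reference[lo - 1], reference[lo]
        frac = (value - left) / (right - left)
        q = ((lo - 0.5) + frac) / n
    q = min(max(q, 0.5 / n), 1.0 - 0.5 / n)
    return float(stats.norm.ppf(q))


def predict_direction(beta: float, delta_mean: float) -> str:
    """Predicted expression change: "increase" iff beta*delta > 0, "decrease"
    iff < 0, "undefined" when the product is zero (excluded from accuracy)."""
    product = beta * delta_mean
    if product > 0:
        return "increase"
    if product < 0:
        return "decrease"
    return "undefined"


def build_validation_records(
    associations: pd.DataFrame,
    calls: pd.DataFrame,
    tpm: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_quantiles: dict[str, list[float]],
) -> pd.DataFrame:
    """One record per somatic mutation at a significant eSTR in a validation
    patient with matched healthy/tumour expression."""
    meta = metadata.copy()
    if meta["cohort"].notna().any():
        meta = meta[meta["cohort"] == "validation"]
    if meta.empty:
        raise DataError("no validation samples in metadata")
    events, _, _ = call_cohort_mutations(
        calls[calls["sample_id"].isin(meta["sample_id"])], meta
    )
    sig = associations[associations["is_significant"]]
    estr_pairs = sig.set_index("locus_id")
    events = events[events["locus_id"].isin(estr_pairs.index)]

    tumour_of = meta[meta["sample_type"] == "primary_tumour"].set_index("patient_id")[
        "sample_id"
    ]
    healthy_of = meta[meta["sample_type"] != "primary_tumour"].set_index("patient_id")[
        "sample_id"
    ]
    rows = []
    for event in events.itertuples():
        pairs = sig[sig["locus_id"] == event.locus_id]
        t_sample = tumour_of.get(event.patient_id)
        h_sample = healthy_of.get(event.patient_id)
        if t_sample not in tpm.columns or h_sample not in tpm.columns:
            continue
        for pair in pairs.itertuples():
            reference = reference_quantiles.get(pair.gene_id)
            if reference is None or pair.gene_id not in tpm.index:
                continue
            observed = normalize_to_reference(
                float(tpm.at[pair.gene_id, t_sample]), reference
            ) - normalize_to_reference(float(tpm.at[pair.gene_id, h_sample]), reference)
            predicted = predict_direction(pair.beta, event.delta_mean)
            sign_obs = np.sign(observed)
            correct = (
                (predicted == "increase" and sign_obs > 0)
                or (predicted == "decrease" and sign_obs < 0)
            )
            rows.append(
                {
                    "patient_id": event.patient_id,
                    "locus_id": event.locus_id,
                    "gene_id": pair.gene_id,
                    "beta": pair.beta,
                    "delta_mean": event.delta_mean,
                    "expected_impact": abs(pair.beta) * abs(event.delta_mean),
                    "observed_change": observed,
                    "predicted_sign": predicted,
                    "correct": bool(correct),
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _usable(records: pd.DataFrame) -> pd.DataFrame:
    """Records with a defined prediction and nonzero observed change; ties in
    the observed change are excluded from accuracy and reported separately."""
    return records[
        (records["predicted_sign"] != "undefined") & (records["observed_change"] != 0)
    ]


def direction_accuracy(records: pd.DataFrame) -> tuple[float, float, int]:
    """Proportion of correctly predicted directions and the one-sided exact
    binomial p-value against guessing with probability 0.5.
    Returns (accuracy, p_value, n_usable)."""
    usable = _usable(records)
    n = len(usable)
    if n == 0:
        raise DataError("no usable validation records (all undefined or tied)")
    k = int(usable["correct"].sum())
    test = stats.binomtest(k, n, p=0.5, alternative="greater")
    return k / n, float(test.pvalue), n


def accuracy_by_impact_quartile(records: pd.DataFrame) -> pd.DataFrame:
    """Accuracy within quartiles of expected mutation impact (Q1 lowest).

    Records are sorted by expected impact with a stable sort (ties keep their
    input order) and split into four near-equal groups.
    """
    usable = _usable(records).reset_index(drop=True)
    if len(usable) < 4:
        raise DataError(f"need at least 4 usable records, got {len(usable)}")
    ordered = usable.sort_values("expected_impact", kind="mergesort").reset_index(
        drop=True
    )
    quartiles = np.array_split(np.arange(len(ordered)), 4)
    rows = []
    for i, idx in enumerate(quartiles, start=1):
        sub = ordered.iloc[idx]
        rows.append(
            {
                "quartile": i,
                "n": len(sub),
                "accuracy": float(sub["correct"].mean()),
                "mean_impact": float(sub["expected_impact"].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationSummary:
    n_records: int
    n_usable: int
    n_tied: int
    accuracy: float
    binomial_p: float
    quartiles: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_usable": self.n_usable,
            "n_tied": self.n_tied,
            "accuracy": self.accuracy,
            "binomial_p": self.binomial_p,
            "quartiles": self.quartiles.to_dict(orient="records"),
        }


def summarize_validation(records: pd.DataFrame) -> ValidationSummary:
    usable = _usable(records)
    accuracy, p, n = direction_accuracy(records)
    return ValidationSummary(
        n_records=len(records),
        n_usable=n,
        n_tied=int(
            ((records["predicted_sign"] != "undefined") & (records["observed_change"] == 0)).sum()
        ),
        accuracy=accuracy,
        binomial_p=p,
        quartiles=accuracy_by_impact_quartile(records),
    )
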