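"""Do eSTRs mutate more often than comparable non-eSTRs?

Because unit size and allele length dominate STR mutability, loci are grouped
into *repeat types* — (unit size, panel reference allele length) classes —
and within each type the fraction of mutated eSTR observations is compared
with the fraction of mutated non-eSTR observations.  One observation is one
locus x patient healthy/tumour comparison.  Types with fewer than 25
observations on either side are discarded; a fraction difference must exceed
0.05 to count as a difference (0.41 vs 0.38 is "no difference").  The
fraction of tested types where eSTRs are more mutable is compared against a
null built by globally shuffling the eSTR labels across the eligible loci
(10,000 permutations by default), with the add-one permutation p-value
``(1 + #{null >= observed}) / (1 + n_perm)``.  MSS and MSI cohorts are
analysed fully separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

VERDICTS = ("estr_more", "non_more", "no_difference", "discarded")


def classify_difference(
    frac_estr: float, frac_non: float, diff_threshold: float = 0.05
) -> str:
    """Verdict for one repeat type; "more mutable" requires the fraction
    difference to strictly exceed ``diff_threshold``."""
    if frac_estr - frac_non > diff_threshold:
        return "estr_more"
    if frac_non - frac_estr > diff_threshold:
        return "non_more"
    return "no_difference"


def _observation_table(
    comparisons: pd.DataFrame, panel: pd.DataFrame, eligible_ids=None
) -> pd.DataFrame:
    """Per-locus observation/mutation counts with repeat-type keys."""
    info = panel.set_index("locus_id")[["unit_size", "ref_length"]]
    data = comparisons.copy()
    if eligible_ids is not None:
        data = data[data["locus_id"].isin(set(eligible_ids))]
    grouped = data.groupby("locus_id", sort=True)["mutated"].agg(["count", "sum"])
    grouped.columns = ["n_obs", "n_mut"]
    grouped = grouped.join(info, how="inner")
    grouped["n_mut"] = grouped["n_mut"].astype(int)
    return grouped.reset_index()


def group_repeat_types(
    comparisons: pd.DataFrame,
    panel: pd.DataFrame,
    estr_ids,
    eligible_ids=None,
    min_obs: int = 25,
    diff_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-repeat-type eSTR/non-eSTR mutated fractions and verdicts.

    Types where either group has fewer than ``min_obs`` observations get the
    verdict "discarded".
    """
    estr_set = set(estr_ids)
    loci = _observation_table(comparisons, panel, eligible_ids)
    loci["is_estr"] = loci["locus_id"].isin(estr_set)
    rows = []
    for (unit_size, ref_length), group in loci.groupby(
        ["unit_size", "ref_length"], sort=True
    ):
        estr = group[group["is_estr"]]
        non = group[~group["is_estr"]]
        n_estr_obs = int(estr["n_obs"].sum())
        n_non_obs = int(non["n_obs"].sum())
        frac_estr = estr["n_mut"].sum() / n_estr_obs if n_estr_obs else np.nan
        frac_non = non["n_mut"].sum() / n_non_obs if n_non_obs else np.nan
        if min(n_estr_obs, n_non_obs) < min_obs:
            verdict = "discarded"
        else:
            verdict = classify_difference(frac_estr, frac_non, diff_threshold)
        rows.append(
            {
                "unit_size": int(unit_size),
                "ref_length": int(ref_length),
                "n_estr_obs": n_estr_obs,
                "n_non_obs": n_non_obs,
                "frac_estr_mut": frac_estr,
                "frac_non_mut": frac_non,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)


def _statistic_for_labels(
    type_idx: np.ndarray,
    n_types: int,
    obs: np.ndarray,
    mut: np.ndarray,
    total_obs: np.ndarray,
    total_mut: np.ndarray,
    is_estr: np.ndarray,
    min_obs: int,
    diff_threshold: float,
) -> tuple[float, float]:
    """(fraction of tested types with estr_more, with non_more) for one label
    assignment; NaN when no type passes the observation threshold."""
    estr_obs = np.bincount(type_idx[is_estr], weights=obs[is_estr], minlength=n_types)
    estr_mut = np.bincount(type_idx[is_estr], weights=mut[is_estr], minlength=n_types)
    non_obs = total_obs - estr_obs
    non_mut = total_mut - estr_mut
    tested = (estr_obs >= min_obs) & (non_obs >= min_obs)
    n_tested = int(tested.sum())
    if n_tested == 0:
        return np.nan, np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = estr_mut[tested] / estr_obs[tested] - non_mut[tested] / non_obs[tested]
    return (
        float((diff > diff_threshold).sum()) / n_tested,
        float((-diff > diff_threshold).sum()) / n_tested,
    )


@dataclass
class PermutationResult:
    observed_estr_more: float
    observed_non_more: float
    null_estr_more: np.ndarray
    null_non_more: np.ndarray
    p_estr_more: float
    p_non_more: float
    n_perm: int
    n_types_tested: int


def permutation_test(
    comparisons: pd.DataFrame,
    panel: pd.DataFrame,
    estr_ids,
    eligible_ids=None,
    n_perm: int = 10000,
    min_obs: int = 25,
    diff_threshold: float = 0.05,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Label-permutation test for elevated eSTR mutability.

    The statistic is the fraction of non-discarded repeat types whose eSTR
    mutated fraction exceeds the non-eSTR fraction by more than
    ``diff_threshold``.  Each permutation shuffles the eSTR labels globally
    across the eligible locus set (preserving the eSTR count) and recomputes
    the full analysis, including which types are discarded.  Null draws where
    no type passes the threshold contribute a statistic of 0.
    """
    if n_perm <= 0:
        raise DataError("n_perm must be positive")
    if rng is None:
        rng = np.random.default_rng()
    loci = _observation_table(comparisons, panel, eligible_ids)
    if loci.empty:
        raise DataError("no observations to analyse")
    estr_set = set(estr_ids)
    is_estr = loci["locus_id"].isin(estr_set).to_numpy()
    n_estr = int(is_estr.sum())
    if n_estr == 0 or n_estr == len(loci):
        raise DataError("need both eSTR and non-eSTR loci for a permutation test")
    type_key = loci["unit_size"].astype(str) + ":" + loci["ref_length"].astype(str)
    codes, _ = pd.factorize(type_key, sort=True)
    n_types = codes.max() + 1
    obs = loci["n_obs"].to_numpy(dtype=float)
    mut = loci["n_mut"].to_numpy(dtype=float)
    total_obs = np.bincount(codes, weights=obs, minlength=n_types)
    total_mut = np.bincount(codes, weights=mut, minlength=n_types)

    obs_stat, obs_stat_non = _statistic_for_labels(
        codes, n_types, obs, mut, total_obs, total_mut, is_estr, min_obs, diff_threshold
    )
    if np.isnan(obs_stat):
        raise DataError("zero repeat types pass the observation threshold")
    tested = group_repeat_types(
        comparisons, panel, estr_ids, eligible_ids, min_obs, diff_threshold
    )
    n_tested = int((tested["verdict"] != "discarded").sum())

    n_loci = len(loci)
    null_estr = np.empty(n_perm)
    null_non = np.empty(n_perm)
    labels = np.zeros(n_loci, dtype=bool)
    for i in range(n_perm):
        labels[:] = False
        labels[rng.choice(n_loci, size=n_estr, replace=False)] = True
        s_e, s_n = _statistic_for_labels(
            codes, n_types, obs, mut, total_obs, total_mut, labels, min_obs, diff_threshold
        )
        null_estr[i] = 0.0 if np.isnan(s_e) else s_e
        null_non[i] = 0.0 if np.isnan(s_n) else s_n
    p_estr = (1.0 + float((null_estr >= obs_stat).sum())) / (1.0 + n_perm)
    p_non = (1.0 + float((null_non >= obs_stat_non).sum())) / (1.0 + n_perm)
    return PermutationResult(
        observed_estr_more=obs_stat,
        observed_non_more=obs_stat_non,
        null_estr_more=null_estr,
        null_non_more=null_non,
        p_estr_more=p_estr,
        p_non_more=p_non,
        n_perm=n_perm,
        n_types_tested=n_tested,
    )


def permutation_test_by_msi(
    comparisons: pd.DataFrame,
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
    estr_ids,
    eligible_ids=None,
    n_perm: int = 10000,
    min_obs: int = 25,
    diff_threshold: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[str, PermutationResult]:
    """Run the permutation test separately for MSS and MSI patients."""
    labels = (
        metadata[metadata["sample_type"] == "primary_tumour"]
        .drop_duplicates("patient_id")
        .set_index("patient_id")["msi_label"]
    )
    results = {}
    groups = comparisons["patient_id"].map(labels)
    for group in ("MSS", "MSI"):
        sub = comparisons[groups == group]
        if sub.empty:
            continue
        results[group] = permutation_test(
            sub,
            panel,
            estr_ids,
            eligible_ids=eligible_ids,
            n_perm=n_perm,
            min_obs=min_obs,
            diff_threshold=diff_threshold,
            rng=rng,
        )
    return results
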