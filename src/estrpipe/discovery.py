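"""eSTR discovery: per-locus linear models between STR length and expression.

Expression (TPM) is filtered for expressed genes, rank-inverse-normal
transformed per gene, and regressed on the mean tumour STR genotype for
every eligible STR-gene pair.  Slope t-tests are corrected with
Benjamini-Hochberg across all pairs; a single permuted-genotype refit per
pair provides the negative-control p-value set for Q-Q calibration.

The per-gene sorted raw TPM vectors of the discovery samples are retained as
reference quantiles so held-out validation samples can later be mapped onto
the same normalized scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

ASSOCIATION_COLUMNS = [
    "locus_id",
    "gene_id",
    "beta",
    "se_beta",
    "t_stat",
    "p_value",
    "q_value",
    "n_samples",
    "is_significant",
    "in_gene_list",
]


def filter_expressed_genes(tpm: pd.DataFrame) -> pd.DataFrame:
    """Drop genes (rows) whose median TPM across samples is zero."""
    if tpm.empty:
        return tpm
    return tpm[tpm.median(axis=1) > 0]


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5) / n) with
    average ranks for ties.  Order-preserving; any strictly monotone
    transform of the input yields identical scores."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise DataError(f"inverse normal transform needs n >= 3, got {n}")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def normalize_expression(tpm: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[float]]]:
    """Per-gene inverse normal scores plus the reference quantiles (sorted raw
    values) needed to map held-out samples onto the same scale."""
    scores = pd.DataFrame(
        {gene: inverse_normal_transform(tpm.loc[gene].to_numpy()) for gene in tpm.index},
        index=tpm.columns,
    ).T
    reference = {gene: sorted(map(float, tpm.loc[gene])) for gene in tpm.index}
    return scores, reference


def mean_genotype(allele_a: float, allele_b: float) -> float:
    """Average of the two allele lengths, in repeat units."""
    return (allele_a + allele_b) / 2.0


def genotype_matrix(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Locus x patient matrix of mean tumour genotypes (NaN where uncalled)."""
    tumours = metadata[metadata["sample_type"] == "primary_tumour"]
    sample_to_patient = tumours.set_index("sample_id")["patient_id"]
    sub = calls[calls["sample_id"].isin(sample_to_patient.index)].copy()
    sub["patient_id"] = sub["sample_id"].map(sample_to_patient)
    sub["mean_genotype"] = (sub["allele_a"] + sub["allele_b"]) / 2.0
    return sub.pivot_table(
        index="locus_id", columns="patient_id", values="mean_genotype", aggfunc="first"
    )


def eligible_loci(
    genotypes: pd.DataFrame, min_patients: int = 50, min_distinct: int = 3
) -> list[str]:
    """Loci called in >= ``min_patients`` patients with >= ``min_distinct``
    distinct mean-genotype values."""
    n_called = genotypes.notna().sum(axis=1)
    n_distinct = genotypes.nunique(axis=1)
    keep = (n_called >= min_patients) & (n_distinct >= min_distinct)
    return sorted(genotypes.index[keep])


def pair_str_gene(
    panel: pd.DataFrame,
    gene_models: pd.DataFrame,
    promoter_bp: int = 5000,
    include_promoter: bool = True,
) -> pd.DataFrame:
    """(locus_id, gene_id) pairs for every gene whose body (optionally
    extended by the strand-aware promoter window) contains the locus; a locus
    inside overlapping genes yields one pair per gene."""
    from intervaltree import IntervalTree

    genes = gene_models[gene_models["feature"] == "gene"]
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        start, end = int(row.start), int(row.end)
        if include_promoter:
            if row.strand == "-":
                end += promoter_bp
            else:
                start = max(0, start - promoter_bp)
        trees.setdefault(row.chrom, IntervalTree()).addi(start, end, row.gene_id)
    pairs = []
    for row in panel.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row.start), int(row.end)), key=lambda h: h.data):
            pairs.append({"locus_id": row.locus_id, "gene_id": hit.data})
    return pd.DataFrame(pairs, columns=["locus_id", "gene_id"]).drop_duplicates(
        ignore_index=True
    )


@dataclass
class EstrFit:
    beta: float
    se_beta: float
    t_stat: float
    p_value: float
    n_samples: int


def fit_estr_model(x: np.ndarray, y: np.ndarray) -> EstrFit:
    """Ordinary least squares of normalized expression on mean genotype with a
    two-sided t-test of slope = 0 (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DataError(f"need at least 3 paired samples, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DataError("zero genotype variance; cannot fit")
    beta = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return EstrFit(beta=beta, se_beta=se, t_stat=float(t), p_value=p, n_samples=n)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone q-values and significance flags
    (significant iff q < alpha)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def fit_pairs(
    pairs: pd.DataFrame,
    genotypes: pd.DataFrame,
    normalized: pd.DataFrame,
    alpha: float = 0.05,
    min_patients: int = 50,
) -> pd.DataFrame:
    """Fit the eSTR model for every (locus, gene) pair and apply BH across all
    fitted pairs.  Pairs with zero genotype variance or fewer than
    ``min_patients`` overlapping samples are skipped."""
    rows = []
    patient_cols = list(normalized.columns)
    for row in pairs.itertuples():
        if row.locus_id not in genotypes.index or row.gene_id not in normalized.index:
            continue
        g = genotypes.loc[row.locus_id].reindex(patient_cols)
        mask = g.notna().to_numpy()
        if mask.sum() < max(3, min_patients):
            continue
        x = g.to_numpy(dtype=float)[mask]
        if np.unique(x).size < 2:
            continue
        y = normalized.loc[row.gene_id].to_numpy(dtype=float)[mask]
        fit = fit_estr_model(x, y)
        rows.append(
            {
                "locus_id": row.locus_id,
                "gene_id": row.gene_id,
                "beta": fit.beta,
                "se_beta": fit.se_beta,
                "t_stat": fit.t_stat,
                "p_value": fit.p_value,
                "n_samples": fit.n_samples,
            }
        )
    associations = pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "gene_id",
            "beta",
            "se_beta",
            "t_stat",
            "p_value",
            "n_samples",
        ],
    )
    q, sig = bh_fdr(associations["p_value"].to_numpy(), alpha=alpha)
    associations["q_value"] = q
    associations["is_significant"] = sig
    associations["in_gene_list"] = False
    return associations[ASSOCIATION_COLUMNS]


def permutation_control(
    pairs: pd.DataFrame,
    genotypes: pd.DataFrame,
    normalized: pd.DataFrame,
    rng: np.random.Generator,
    min_patients: int = 50,
) -> np.ndarray:
    """Negative control: per pair, permute the genotype vector across samples
    once and refit; returns the permuted p-value set for Q-Q comparison."""
    p_values = []
    patient_cols = list(normalized.columns)
    for row in pairs.itertuples():
        if row.locus_id not in genotypes.index or row.gene_id not in normalized.index:
            continue
        g = genotypes.loc[row.locus_id].reindex(patient_cols)
        mask = g.notna().to_numpy()
        if mask.sum() < max(3, min_patients):
            continue
        x = g.to_numpy(dtype=float)[mask]
        if np.unique(x).size < 2:
            continue
        y = normalized.loc[row.gene_id].to_numpy(dtype=float)[mask]
        p_values.append(fit_estr_model(rng.permutation(x), y).p_value)
    return np.asarray(p_values)


def annotate_gene_list(associations: pd.DataFrame, gene_list) -> pd.DataFrame:
    """Flag associations whose gene is in a user-supplied list (e.g. a cancer
    gene census); duplicates in the list are harmless."""
    genes = set(gene_list)
    out = associations.copy()
    out["in_gene_list"] = out["gene_id"].isin(genes)
    return out


@dataclass
class DiscoveryResult:
    associations: pd.DataFrame
    normalized: pd.DataFrame
    reference_quantiles: dict[str, list[float]] = field(repr=False, default_factory=dict)
    permuted_p: np.ndarray | None = None

    @property
    def estr_ids(self) -> list[str]:
        sig = self.associations[self.associations["is_significant"]]
        return sorted(sig["locus_id"].unique())


def discover_estrs(
    calls: pd.DataFrame,
    tpm: pd.DataFrame,
    metadata: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    min_patients: int = 50,
    min_distinct: int = 3,
    gene_list=None,
    rng: np.random.Generator | None = None,
) -> DiscoveryResult:
    """Run the full discovery stage on the discovery-cohort tumours.

    ``metadata`` rows with cohort == "discovery" (or all tumours when the
    cohort column is unset) define the discovery samples; expression columns
    are matched to tumour samples by patient.
    """
    meta = metadata.copy()
    if meta["cohort"].notna().any():
        meta = meta[(meta["cohort"] == "discovery") | (meta["sample_type"] != "primary_tumour")]
    tumours = meta[meta["sample_type"] == "primary_tumour"]
    expr_samples = [s for s in tumours["sample_id"] if s in tpm.columns]
    if not expr_samples:
        raise DataError("no discovery tumour sample has an expression column")
    sample_to_patient = tumours.set_index("sample_id")["patient_id"]
    tpm_disc = tpm[expr_samples].rename(columns=sample_to_patient)

    expressed = filter_expressed_genes(tpm_disc)
    normalized, reference = normalize_expression(expressed)
    genotypes = genotype_matrix(calls, tumours)
    genotypes = genotypes.reindex(columns=normalized.columns)
    loci = eligible_loci(genotypes, min_patients=min_patients, min_distinct=min_distinct)
    use_pairs = pairs[
        pairs["locus_id"].isin(loci) & pairs["gene_id"].isin(normalized.index)
    ].reset_index(drop=True)
    associations = fit_pairs(
        use_pairs, genotypes, normalized, alpha=alpha, min_patients=min_patients
    )
    if gene_list is not None:
        associations = annotate_gene_list(associations, gene_list)
    permuted = None
    if rng is not None:
        permuted = permutation_control(
            use_pairs, genotypes, normalized, rng, min_patients=min_patients
        )
    return DiscoveryResult(
        associations=associations,
        normalized=normalized,
        reference_quantiles=reference,
        permuted_p=permuted,
    )


def write_reference_quantiles(reference: dict[str, list[float]], path: str) -> None:
    with open(path, "w") as handle:
        json.dump(reference, handle)


def read_reference_quantiles(path: str) -> dict[str, list[float]]:
    with open(path) as handle:
        return json.load(handle)
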