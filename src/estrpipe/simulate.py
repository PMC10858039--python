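"""Synthetic matched-cohort generator with planted eSTR effects.

Generates everything the pipeline consumes — an STR panel laid out inside
synthetic gene bodies, matched healthy/tumour biallelic STR calls per
patient, MSS/MSI labels, per-tumour CNV segments, and a TPM-like expression
table with planted linear eSTR effects — together with the ground truth
needed for parameter-recovery tests.

The mutation model mirrors what is seen in mismatch-repair-deficient
colorectal tumours: per-allele mutation probability rises linearly with
allele length, the MSI phenotype multiplies the *deletion* rate only (the
insertion rate is untouched), and step sizes follow a geometric-like decay
favouring single-unit changes.  Planted eSTR genes receive expression
``intercept + beta * mean_allele_length + N(0, noise_sd)`` mapped to a
nonnegative TPM-like scale by a softplus; all other genes are independent of
genotype.  Random streams are split per patient so growing the cohort never
reshuffles earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import CALL_COLUMNS, METADATA_COLUMNS
from .panel import PANEL_COLUMNS, canonical_motif, is_primitive

GENE_SPACING = 10_000  # bp between synthetic gene starts; > promoter window
GENE_LENGTH = 4_000
LOCUS_OFFSET = 1_000  # locus start within its gene body
CHROM = "chrS"

_REGION_LABELS = ("intron", "UTR", "CDS", "promoter")
_REGION_PROBS = (0.78, 0.09, 0.08, 0.05)


def _default_step_distribution(decay: float = 0.55, max_step: int = 15) -> dict[int, float]:
    """Geometric-like decay over step magnitudes 1..max_step: most mutations
    are single-step, with P(k) proportional to decay * (1-decay)^(k-1)."""
    raw = {k: decay * (1 - decay) ** (k - 1) for k in range(1, max_step + 1)}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _default_length_ranges() -> dict[int, tuple[int, int]]:
    return {1: (9, 20), 2: (4, 15), 3: (3, 10), 4: (3, 8), 5: (3, 6), 6: (3, 6)}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Rates are per allele per locus; a locus mutates when either allele does.
    ``msi_deletion_multiplier`` scales only the deletion rate of MSI
    patients, so MSI insertion frequencies stay at the MSS level.
    """

    n_patients_mss: int = 120
    n_patients_msi: int = 25
    n_patients_validation: int = 16
    validation_msi_fraction: float = 0.5
    n_loci: int = 2000
    unit_size_distribution: tuple[float, ...] = (0.45, 0.25, 0.15, 0.08, 0.04, 0.03)
    reference_length_range: dict[int, tuple[int, int]] = field(
        default_factory=_default_length_ranges
    )
    base_mutation_rate_per_locus: float = 0.005
    length_rate_slope: float = 0.15
    msi_deletion_multiplier: float = 10.0
    insertion_bias: float = 0.5
    step_size_distribution: dict[int, float] = field(
        default_factory=_default_step_distribution
    )
    estr_mutation_multiplier: float = 1.0
    n_estr: int = 100
    beta_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 1.0
    n_genes: int | None = None
    frac_silent_genes: float = 0.05
    expression_intercept: float = 2.0
    expression_transform: str = "softplus"  # or "identity"
    germline_offset_probs: tuple[float, ...] = (0.05, 0.15, 0.6, 0.15, 0.05)
    dropout_fraction: float = 0.0
    call_rate: float = 1.0
    cnv_fraction_mss: float = 0.171
    cnv_fraction_msi: float = 0.013
    depth_mean: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        def _check_prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")

        for name in (
            "n_patients_mss",
            "n_patients_msi",
            "n_patients_validation",
            "n_loci",
            "n_estr",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in (
            "base_mutation_rate_per_locus",
            "insertion_bias",
            "validation_msi_fraction",
            "frac_silent_genes",
            "dropout_fraction",
            "call_rate",
            "cnv_fraction_mss",
            "cnv_fraction_msi",
        ):
            _check_prob(name, getattr(self, name))
        if abs(sum(self.unit_size_distribution) - 1.0) > 1e-9:
            raise ConfigurationError("unit_size_distribution must sum to 1")
        if any(p < 0 for p in self.unit_size_distribution):
            raise ConfigurationError("unit_size_distribution entries must be >= 0")
        if abs(sum(self.step_size_distribution.values()) - 1.0) > 1e-9:
            raise ConfigurationError("step_size_distribution must sum to 1")
        if any(k < 1 for k in self.step_size_distribution):
            raise ConfigurationError("step_size_distribution magnitudes must be >= 1")
        if self.msi_deletion_multiplier < 1.0:
            raise ConfigurationError("msi_deletion_multiplier must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.estr_mutation_multiplier < 0:
            raise ConfigurationError("estr_mutation_multiplier must be >= 0")
        if self.length_rate_slope < 0:
            raise ConfigurationError("length_rate_slope must be >= 0")
        if self.expression_transform not in {"softplus", "identity"}:
            raise ConfigurationError(
                f"expression_transform must be softplus or identity, got {self.expression_transform!r}"
            )
        n_genes = self.n_genes if self.n_genes is not None else self.n_loci
        if self.n_estr > min(self.n_loci, n_genes):
            raise ConfigurationError("n_estr cannot exceed n_loci or n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort for recovery tests."""

    planted_estr_ids: list[str]
    planted_betas: dict[str, float]
    planted_genes: dict[str, str]  # locus_id -> gene_id for planted eSTRs
    planted_mutations: list[dict]
    planted_dropout: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class SyntheticCohort:
    panel: pd.DataFrame
    gene_models: pd.DataFrame
    calls: pd.DataFrame
    expression: pd.DataFrame
    metadata: pd.DataFrame
    cnv_segments: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *tags])


def _random_primitive_motif(unit_size: int, rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        motif = "".join(bases[i] for i in rng.integers(0, 4, size=unit_size))
        if is_primitive(motif):
            return canonical_motif(motif)


def _generate_panel(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_loci
    unit_sizes = rng.choice(
        np.arange(1, 7), size=n, p=np.asarray(config.unit_size_distribution)
    )
    ref_lengths = np.empty(n, dtype=int)
    for u in range(1, 7):
        lo, hi = config.reference_length_range[u]
        sel = unit_sizes == u
        ref_lengths[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    regions = rng.choice(_REGION_LABELS, size=n, p=np.asarray(_REGION_PROBS))
    rows = []
    gene_rows = []
    n_genes = config.n_genes if config.n_genes is not None else config.n_loci
    for i in range(n):
        gene_idx = i % n_genes
        gene_start = gene_idx * GENE_SPACING
        start = gene_start + LOCUS_OFFSET + (i // n_genes) * 200
        end = start + int(unit_sizes[i]) * int(ref_lengths[i])
        motif = _random_primitive_motif(int(unit_sizes[i]), rng)
        rows.append(
            {
                "chrom": CHROM,
                "start": start,
                "end": end,
                "locus_id": f"{CHROM}:{start}-{end}:{motif}",
                "ref_length": int(ref_lengths[i]),
                "strand": ".",
                "motif": motif,
                "unit_size": int(unit_sizes[i]),
                "region": str(regions[i]),
            }
        )
    for g in range(n_genes):
        gene_start = g * GENE_SPACING
        gene_rows.append(
            {
                "feature": "gene",
                "chrom": CHROM,
                "start": gene_start,
                "end": gene_start + GENE_LENGTH,
                "strand": "+",
                "gene_id": f"G{g:05d}",
            }
        )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    gene_models = pd.DataFrame(
        gene_rows, columns=["feature", "chrom", "start", "end", "strand", "gene_id"]
    )
    gene_of_locus = {
        panel["locus_id"].iloc[i]: f"G{i % n_genes:05d}" for i in range(n)
    }
    return panel, gene_models, gene_of_locus


def _allele_mutation_rates(
    lengths: np.ndarray,
    unit_sizes: np.ndarray,
    is_msi: bool,
    is_estr: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(insertion rate, deletion rate) per allele; non-decreasing in length."""
    min_len = np.array(
        [0] + [config.reference_length_range[u][0] for u in range(1, 7)]
    )[unit_sizes]
    p = config.base_mutation_rate_per_locus * (
        1.0 + config.length_rate_slope * np.maximum(lengths - min_len, 0)
    )
    if is_msi and config.estr_mutation_multiplier != 1.0:
        p = np.where(is_estr, p * config.estr_mutation_multiplier, p)
    r_ins = p * config.insertion_bias
    r_del = p * (1.0 - config.insertion_bias)
    if is_msi:
        r_del = r_del * config.msi_deletion_multiplier
    total = r_ins + r_del
    over = total > 1.0
    if over.any():  # keep the ins/del odds, cap the total
        scale = np.where(over, 1.0 / total, 1.0)
        r_ins, r_del = r_ins * scale, r_del * scale
    return r_ins, r_del


def mutate_alleles(
    healthy: tuple[int, int],
    unit_size: int,
    ref_length_min: int | None,
    patient_is_msi: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    is_estr: bool = False,
) -> tuple[int, int]:
    """Apply the somatic mutation model to one biallelic genotype.

    Each allele mutates independently with a probability that is
    non-decreasing in its length; a mutated allele moves by a step drawn from
    the step-size distribution, and deletions never reduce an allele below
    one unit.
    """
    lengths = np.asarray(healthy, dtype=int)
    if (lengths < 1).any():
        raise ConfigurationError("allele lengths must be >= 1 unit")
    units = np.full(2, unit_size)
    cfg = config
    if ref_length_min is not None:
        # honour an explicit panel minimum instead of the config range
        base = dict(cfg.reference_length_range)
        base[unit_size] = (ref_length_min, base[unit_size][1])
        cfg = SimulationConfig(**{**asdict(cfg), "reference_length_range": base})
    r_ins, r_del = _allele_mutation_rates(
        lengths, units, patient_is_msi, np.full(2, is_estr), cfg
    )
    total = r_ins + r_del
    u = rng.random(2)
    mutates = u < total
    with np.errstate(invalid="ignore", divide="ignore"):
        p_del = np.where(total > 0, r_del / np.maximum(total, 1e-300), 0.0)
    deletes = rng.random(2) < p_del
    magnitudes = _draw_steps(rng, 2, cfg)
    out = lengths.copy()
    for i in range(2):
        if not mutates[i]:
            continue
        if deletes[i]:
            out[i] = max(1, out[i] - magnitudes[i])
        else:
            out[i] = out[i] + magnitudes[i]
    if out[0] == out[1] and out[0] not in lengths:
        # avoid emitting a genotype indistinguishable from allele dropout:
        # move the second allele one extra step in its own direction
        nudged = out[1] - 1 if deletes[1] else out[1] + 1
        out[1] = lengths[1] if nudged < 1 else nudged
    return int(min(out)), int(max(out))


def _draw_steps(rng: np.random.Generator, size: int, config: SimulationConfig) -> np.ndarray:
    magnitudes = np.array(sorted(config.step_size_distribution))
    probs = np.array([config.step_size_distribution[k] for k in magnitudes])
    return rng.choice(magnitudes, size=size, p=probs)


def _patient_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    idx = 0
    for _ in range(config.n_patients_mss):
        rows.append({"patient_id": f"P{idx:04d}", "msi_label": "MSS", "cohort": "discovery"})
        idx += 1
    for _ in range(config.n_patients_msi):
        rows.append({"patient_id": f"P{idx:04d}", "msi_label": "MSI", "cohort": "discovery"})
        idx += 1
    n_val_msi = int(round(config.n_patients_validation * config.validation_msi_fraction))
    for v in range(config.n_patients_validation):
        label = "MSI" if v < n_val_msi else "MSS"
        rows.append({"patient_id": f"P{idx:04d}", "msi_label": label, "cohort": "validation"})
        idx += 1
    return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full matched cohort; identical config and seed give
    byte-identical serialized outputs."""
    config.validate()
    panel, gene_models, gene_of_locus = _generate_panel(config, _rng(config, 0))
    n_loci = config.n_loci
    unit_sizes = panel["unit_size"].to_numpy()
    ref_lengths = panel["ref_length"].to_numpy()
    locus_ids = panel["locus_id"].to_numpy()

    rng_truth = _rng(config, 1)
    n_genes = config.n_genes if config.n_genes is not None else n_loci
    planted_idx = np.sort(
        rng_truth.choice(min(n_loci, n_genes), size=config.n_estr, replace=False)
    )
    lo, hi = config.beta_range
    betas = rng_truth.uniform(lo, hi, size=config.n_estr) * rng_truth.choice(
        [-1.0, 1.0], size=config.n_estr
    )
    is_estr = np.zeros(n_loci, dtype=bool)
    is_estr[planted_idx] = True
    planted_ids = [str(locus_ids[i]) for i in planted_idx]
    planted_betas = {lid: float(b) for lid, b in zip(planted_ids, betas)}
    planted_genes = {lid: gene_of_locus[lid] for lid in planted_ids}

    patients = _patient_ids(config)
    offsets = np.arange(-2, 3)
    offset_probs = np.asarray(config.germline_offset_probs)

    call_parts = []
    meta_rows = []
    cnv_rows = []
    planted_mutations: list[dict] = []
    planted_dropout: list[dict] = []
    mean_genotype = {}  # sample_id -> per-locus mean allele length array

    rng_meta = _rng(config, 2)
    stages = rng_meta.integers(1, 5, size=len(patients))

    for p_idx, patient in enumerate(patients.itertuples()):
        pid = patient.patient_id
        is_msi = patient.msi_label == "MSI"
        is_validation = patient.cohort == "validation"
        tumour_id = f"{pid}_T"
        healthy_id = f"{pid}_N" if is_validation else f"{pid}_B"
        healthy_type = "solid_tissue_normal" if is_validation else "blood_normal"

        rng_h = _rng(config, 10, p_idx)
        germline = rng_h.choice(offsets, size=(n_loci, 2), p=offset_probs)
        healthy = np.maximum(ref_lengths[:, None] + germline, 1)
        healthy.sort(axis=1)

        rng_t = _rng(config, 11, p_idx)
        r_ins, r_del = _allele_mutation_rates(
            healthy, unit_sizes[:, None], is_msi, is_estr[:, None], config
        )
        total = r_ins + r_del
        mutates = rng_t.random((n_loci, 2)) < total
        with np.errstate(invalid="ignore", divide="ignore"):
            p_del = np.where(total > 0, r_del / np.maximum(total, 1e-300), 0.0)
        deletes = rng_t.random((n_loci, 2)) < p_del
        magnitudes = _draw_steps(rng_t, 2 * n_loci, config).reshape(n_loci, 2)
        tumour = healthy.copy()
        del_mask = mutates & deletes
        ins_mask = mutates & ~deletes
        tumour[del_mask] = np.maximum(1, tumour[del_mask] - magnitudes[del_mask])
        tumour[ins_mask] = tumour[ins_mask] + magnitudes[ins_mask]
        # a true mutation that leaves the tumour homozygous for an allele
        # absent from the healthy pair would be indistinguishable from allele
        # dropout and removed downstream; in those rare double-hit collisions
        # push the second allele one extra step in its own direction so the
        # planted truth matches callable events exactly
        mimic = (
            (tumour[:, 0] == tumour[:, 1])
            & (tumour[:, 0] != healthy[:, 0])
            & (tumour[:, 0] != healthy[:, 1])
        )
        further = np.where(del_mask[:, 1], tumour[:, 1] - 1, tumour[:, 1] + 1)
        push = mimic & (further >= 1)
        tumour[push, 1] = further[push]
        fallback = mimic & ~push
        tumour[fallback, 1] = healthy[fallback, 1]
        tumour.sort(axis=1)

        # planted allele-dropout artifacts: a heterozygous healthy locus whose
        # tumour call is emitted homozygous for an allele absent from the pair
        if config.dropout_fraction > 0:
            rng_d = _rng(config, 12, p_idx)
            het = healthy[:, 0] != healthy[:, 1]
            drop = het & (rng_d.random(n_loci) < config.dropout_fraction)
            novel = healthy.max(axis=1) + 1
            tumour[drop, 0] = novel[drop]
            tumour[drop, 1] = novel[drop]
        else:
            drop = np.zeros(n_loci, dtype=bool)

        changed = (tumour != healthy).any(axis=1) & ~drop
        for i in np.flatnonzero(changed):
            planted_mutations.append(
                {
                    "patient_id": pid,
                    "locus_id": str(locus_ids[i]),
                    "healthy": [int(healthy[i, 0]), int(healthy[i, 1])],
                    "tumour": [int(tumour[i, 0]), int(tumour[i, 1])],
                }
            )
        for i in np.flatnonzero(drop):
            planted_dropout.append(
                {
                    "patient_id": pid,
                    "locus_id": str(locus_ids[i]),
                    "healthy": [int(healthy[i, 0]), int(healthy[i, 1])],
                    "tumour": [int(tumour[i, 0]), int(tumour[i, 1])],
                }
            )

        rng_q = _rng(config, 13, p_idx)
        for sample_id, alleles in ((healthy_id, healthy), (tumour_id, tumour)):
            depth = rng_q.poisson(config.depth_mean, size=n_loci) + 1
            keep = (
                rng_q.random(n_loci) < config.call_rate
                if config.call_rate < 1.0
                else np.ones(n_loci, dtype=bool)
            )
            call_parts.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "locus_id": locus_ids[keep],
                        "allele_a": alleles[keep, 0],
                        "allele_b": alleles[keep, 1],
                        "depth": depth[keep],
                    }
                )
            )
            mean_genotype[sample_id] = alleles.mean(axis=1)

        cnv_frac = config.cnv_fraction_msi if is_msi else config.cnv_fraction_mss
        k = int(round(cnv_frac * n_loci))
        if k > 0:
            rng_c = _rng(config, 14, p_idx)
            s = int(rng_c.integers(0, n_loci - k + 1))
            seg_start = int(panel["start"].iloc[s]) - LOCUS_OFFSET
            seg_end = int(panel["end"].iloc[s + k - 1]) + 1
            cnv_rows.append(
                {"chrom": CHROM, "start": seg_start, "end": seg_end, "sample_id": tumour_id}
            )

        meta_rows.append(
            {
                "sample_id": tumour_id,
                "patient_id": pid,
                "sample_type": "primary_tumour",
                "msi_label": patient.msi_label,
                "tumour_stage": int(stages[p_idx]),
                "cohort": patient.cohort,
            }
        )
        meta_rows.append(
            {
                "sample_id": healthy_id,
                "patient_id": pid,
                "sample_type": healthy_type,
                "msi_label": "",
                "tumour_stage": "",
                "cohort": patient.cohort,
            }
        )

    calls = pd.concat(call_parts, ignore_index=True)
    calls["depth"] = calls["depth"].astype("Int64")
    calls = calls[CALL_COLUMNS]
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    metadata["tumour_stage"] = pd.to_numeric(
        metadata["tumour_stage"], errors="coerce"
    ).astype("Int64")
    cnv_segments = pd.DataFrame(
        cnv_rows, columns=["chrom", "start", "end", "sample_id"]
    )

    truth = SyntheticTruth(
        planted_estr_ids=planted_ids,
        planted_betas=planted_betas,
        planted_genes=planted_genes,
        planted_mutations=planted_mutations,
        planted_dropout=planted_dropout,
    )

    expr_samples = [
        row.sample_id
        for row in metadata.itertuples()
        if row.sample_type == "primary_tumour" or row.cohort == "validation"
    ]
    genotype_frame = pd.DataFrame(
        {s: mean_genotype[s] for s in expr_samples}, index=locus_ids
    )
    expression = generate_expression(
        genotype_frame, truth, config, _rng(config, 3), gene_of_locus
    )

    return SyntheticCohort(
        panel=panel,
        gene_models=gene_models,
        calls=calls,
        expression=expression,
        metadata=metadata,
        cnv_segments=cnv_segments,
        truth=truth,
        config=config,
    )


def generate_expression(
    mean_genotypes: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_of_locus: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Gene x sample TPM-like expression (>= 0).

    ``mean_genotypes`` is a locus x sample frame of mean allele lengths.  For
    planted eSTR genes the latent expression is linear in the locus genotype;
    all other genes are genotype-independent noise around the intercept.  A
    random subset of non-planted genes is silent (all-zero) to exercise the
    expressed-gene filter.
    """
    n_genes = config.n_genes if config.n_genes is not None else config.n_loci
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    samples = list(mean_genotypes.columns)
    latent = np.full((n_genes, len(samples)), config.expression_intercept)
    if config.noise_sd > 0:
        latent = latent + rng.normal(0.0, config.noise_sd, size=latent.shape)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for locus_id, beta in truth.planted_betas.items():
        gene_id = truth.planted_genes[locus_id]
        g = mean_genotypes.loc[locus_id].to_numpy(dtype=float)
        latent[gene_index[gene_id]] += beta * g
    planted_gene_set = set(truth.planted_genes.values())
    n_silent = int(round(config.frac_silent_genes * n_genes))
    candidates = [g for g in gene_ids if g not in planted_gene_set]
    silent = set(
        rng.choice(candidates, size=min(n_silent, len(candidates)), replace=False)
    )
    if config.expression_transform == "softplus":
        values = np.logaddexp(0.0, latent)
    else:
        values = latent
    for g in silent:
        values[gene_index[g]] = 0.0
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)


# ---------------------------------------------------------------------------
# serialization


def write_gene_models_gff3(gene_models: pd.DataFrame, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for row in gene_models.itertuples():
            handle.write(
                "\t".join(
                    [
                        row.chrom,
                        "estrpipe",
                        row.feature,
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        f"ID={row.gene_id};gene_id={row.gene_id}",
                    ]
                )
                + "\n"
            )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a synthetic cohort to ``outdir`` in the same
    formats the real pipeline reads; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "panel.bed",
        "gene_models": outdir / "genes.gff3",
        "calls": outdir / "calls.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "cnv": outdir / "cnv.bed",
        "truth": outdir / "truth.json",
    }
    cohort.panel.to_csv(paths["panel"], sep="\t", header=False, index=False)
    write_gene_models_gff3(cohort.gene_models, paths["gene_models"])
    cohort.calls.to_csv(paths["calls"], sep="\t", index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.cnv_segments.to_csv(paths["cnv"], sep="\t", header=False, index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return paths
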