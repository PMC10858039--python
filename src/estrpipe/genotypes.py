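"""Reading, writing and quality-filtering biallelic STR length calls.

The on-disk dialect is a TSV with columns ``sample_id, locus_id, allele_a,
allele_b, depth`` — one row per called sample x locus, allele lengths in
repeat units.  The allele pair is unordered; rows are serialized with
``allele_a <= allele_b`` so genotype identity never depends on caller allele
order.  A minimal reader for GangSTR-style VCFs (per-sample ``REPCN`` field
with two integer repeat copy numbers) is provided for interoperability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError

CALL_COLUMNS = ["sample_id", "locus_id", "allele_a", "allele_b", "depth"]

METADATA_COLUMNS = [
    "sample_id",
    "patient_id",
    "sample_type",
    "msi_label",
    "tumour_stage",
    "cohort",
]

SAMPLE_TYPES = {"primary_tumour", "blood_normal", "solid_tissue_normal"}


def _normalise_allele_order(calls: pd.DataFrame) -> pd.DataFrame:
    a = calls[["allele_a", "allele_b"]].to_numpy()
    a.sort(axis=1)
    calls = calls.copy()
    calls["allele_a"] = a[:, 0]
    calls["allele_b"] = a[:, 1]
    return calls


def read_calls(path: str) -> pd.DataFrame:
    """Read an STR calls TSV; raises :class:`ParseError` naming the offending
    line for missing columns or non-integer alleles."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CALL_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise ParseError(f"calls file missing column(s): {', '.join(missing)}")
    if "depth" not in frame.columns:
        frame["depth"] = ""
    for column in ("allele_a", "allele_b"):
        values = frame[column]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-integer value {values.iloc[row]!r} in column {column}",
                line=row + 2,  # header is line 1
            )
        frame[column] = numeric.astype(int)
    depth = pd.to_numeric(frame["depth"].replace("", np.nan), errors="coerce")
    frame["depth"] = depth.astype("Int64")
    return _normalise_allele_order(frame[CALL_COLUMNS])


def write_calls(calls: pd.DataFrame, path: str) -> None:
    frame = _normalise_allele_order(calls[CALL_COLUMNS])
    frame.to_csv(path, sep="\t", index=False)


def read_gangstr_vcf(path: str, repcn_field: str = "REPCN") -> pd.DataFrame:
    """Minimal GangSTR VCF reader: one call per sample x site from the
    per-sample repeat-copy-number FORMAT field; missing genotypes skipped.

    Locus ids follow the panel convention ``chrom:start-end:motif`` built from
    POS (converted to 0-based), the RU INFO motif and the REF span.
    """
    from cyvcf2 import VCF

    from .panel import canonical_motif

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    for variant in vcf:
        try:
            repcn = variant.format(repcn_field)
        except KeyError:
            repcn = None
        if repcn is None:
            raise ParseError(
                f"record {variant.CHROM}:{variant.POS} lacks FORMAT field {repcn_field}"
            )
        motif = variant.INFO.get("RU")
        start = variant.POS - 1
        end = start + len(variant.REF)
        canon = canonical_motif(motif) if motif else "N"
        locus_id = f"{variant.CHROM}:{start}-{end}:{canon}"
        try:
            depths = variant.format("DP")
        except KeyError:
            depths = None
        for i, sample in enumerate(samples):
            raw = repcn[i]
            if raw is None:
                continue
            if isinstance(raw, bytes):
                raw = raw.decode()
            if isinstance(raw, str):
                if raw in {".", "", "./."}:
                    continue
                parts = raw.replace("|", ",").replace("/", ",").split(",")
                try:
                    alleles = [int(p) for p in parts[:2]]
                except ValueError:
                    continue
            else:  # numeric array
                alleles = [int(x) for x in np.asarray(raw).ravel()[:2]]
                if any(x < 0 for x in alleles):
                    continue
            depth = None
            if depths is not None:
                d = int(np.asarray(depths[i]).ravel()[0])
                depth = d if d >= 0 else None
            rows.append(
                {
                    "sample_id": sample,
                    "locus_id": locus_id,
                    "allele_a": min(alleles),
                    "allele_b": max(alleles),
                    "depth": depth,
                }
            )
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    frame["depth"] = frame["depth"].astype("Int64")
    return frame


# ---------------------------------------------------------------------------
# filters


def filter_call_depth(
    calls: pd.DataFrame, min_depth: int = 20, max_depth: int = 1000
) -> pd.DataFrame:
    """Keep calls with ``min_depth <= depth <= max_depth``; calls without a
    depth value pass unchanged."""
    depth = calls["depth"]
    keep = depth.isna() | ((depth >= min_depth) & (depth <= max_depth))
    return calls[keep.to_numpy(dtype=bool)].reset_index(drop=True)


def filter_low_call_samples(calls: pd.DataFrame, min_calls: int = 10000) -> list[str]:
    """Sample ids with at least ``min_calls`` called loci (others discarded)."""
    counts = calls.groupby("sample_id", sort=True)["locus_id"].nunique()
    return sorted(counts.index[counts >= min_calls])


def filter_cnv_overlap(
    tumour_calls: pd.DataFrame,
    panel: pd.DataFrame,
    cnv_segments: pd.DataFrame,
) -> pd.DataFrame:
    """Remove tumour calls whose locus overlaps (>= 1 bp, half-open) a somatic
    CNV segment of the same sample.  ``cnv_segments`` is BED4-shaped:
    columns chrom, start, end, sample_id.  Healthy calls are not this
    function's concern — pass tumour calls only."""
    if cnv_segments.empty:
        return tumour_calls.reset_index(drop=True)
    locus_pos = panel.set_index("locus_id")[["chrom", "start", "end"]]
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in cnv_segments.itertuples():
        if row.end > row.start:
            trees.setdefault((row.sample_id, row.chrom), IntervalTree()).addi(
                int(row.start), int(row.end)
            )
    keep_mask = []
    chrom = locus_pos["chrom"]
    start = locus_pos["start"]
    end = locus_pos["end"]
    for row in tumour_calls.itertuples():
        tree = trees.get((row.sample_id, chrom.get(row.locus_id)))
        if tree is None:
            keep_mask.append(True)
        else:
            keep_mask.append(
                not tree.overlap(int(start[row.locus_id]), int(end[row.locus_id]))
            )
    return tumour_calls[np.asarray(keep_mask)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# metadata and BED helpers


def read_metadata(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "patient_id", "sample_type") if c not in frame.columns]
    if missing:
        raise ParseError(f"metadata missing column(s): {', '.join(missing)}")
    for optional in ("msi_label", "tumour_stage", "cohort"):
        if optional not in frame.columns:
            frame[optional] = np.nan
    frame["tumour_stage"] = pd.to_numeric(frame["tumour_stage"], errors="coerce").astype(
        "Int64"
    )
    return frame[METADATA_COLUMNS]


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cnv_bed(path: str) -> pd.DataFrame:
    """BED4 per-sample CNV segments: chrom, start, end, sample_id."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "sample_id"]
    )
    return frame


def write_cnv_bed(segments: pd.DataFrame, path: str) -> None:
    segments[["chrom", "start", "end", "sample_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_mask_bed(path: str) -> list[tuple[str, int, int]]:
    frame = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2])
    return [(str(c), int(s), int(e)) for c, s, e in frame.itertuples(index=False)]
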