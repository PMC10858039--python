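"""STR panel construction: perfect-repeat detection, filtering and annotation.

A short tandem repeat (STR) is a run of consecutive copies of a 1-6 bp motif.
This module scans reference sequence for *perfect* maximal repeat runs, gives
every locus a strand-independent identity via motif canonicalization, removes
redundant/clustered loci, annotates each locus with the gene region it falls
in (CDS, UTR, intron or promoter), and applies interval/chromosome masks.
Allele lengths are expressed in repeat units throughout, never base pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError

#: minimum allele length (in units) for unit sizes 1..6
DEFAULT_MIN_LENGTHS: tuple[int, ...] = (9, 4, 4, 3, 3, 3)

#: sequence names excluded from the panel by default (non-autosomes)
DEFAULT_NON_AUTOSOMES: frozenset[str] = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)

REGION_PRIORITY = ("CDS", "UTR", "intron", "promoter")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PANEL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "locus_id",
    "ref_length",
    "strand",
    "motif",
    "unit_size",
    "region",
]


@dataclass(frozen=True)
class StrLocus:
    """One panel entry: a perfect STR run on a reference sequence.

    Coordinates are 0-based half-open base pairs; ``ref_length`` is the number
    of repeat units, so ``end - start == unit_size * ref_length`` always holds.
    ``motif`` is stored in canonical form (smallest rotation over both strands)
    so that a locus has the same identity regardless of reported strand.
    """

    chrom: str
    start: int
    end: int
    motif: str
    unit_size: int
    ref_length: int
    region: str = "unlabelled"

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"

    def __post_init__(self):
        if self.end - self.start != self.unit_size * self.ref_length:
            raise ValueError(
                f"span {self.end - self.start} != unit_size*ref_length for {self.chrom}:{self.start}"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat unit: the lexicographically smallest string
    among all rotations of the motif and all rotations of its reverse
    complement.  This makes locus identity independent of phase and strand
    (e.g. ``TTC`` -> ``AAG``)."""
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _segments_without_n(seq: str) -> Iterable[tuple[int, str]]:
    """Split a sequence at N bases, yielding (offset, segment) pairs."""
    start = None
    for i, base in enumerate(itertools.chain(seq, "N")):
        if base == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i


def detect_perfect_strs(
    sequence: str,
    min_lengths: Sequence[int] = DEFAULT_MIN_LENGTHS,
    chrom: str = "seq",
) -> list[StrLocus]:
    """Exhaustively detect maximal perfect STR runs in a sequence.

    For every unit size u in 1..6, maximal period-u stretches are located by a
    single linear scan (``seq[k] == seq[k - u]``), truncated to whole units,
    and reported when the run meets the unit-size-specific minimum length and
    its motif is primitive (non-primitive motifs are the same run seen at a
    multiple of its true period).  Runs containing N are broken at the N.

    Returns loci sorted by (start, unit_size); coordinates 0-based half-open.
    """
    seq = sequence.upper()
    if any(b not in "ACGTN" for b in seq):
        bad = sorted({b for b in seq if b not in "ACGTN"})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    loci: list[StrLocus] = []
    for offset, seg in _segments_without_n(seq):
        n = len(seg)
        for u, min_units in zip(range(1, 7), min_lengths):
            if n < u * min_units:
                continue
            run_start = 0
            k = u
            while True:
                if k >= n or seg[k] != seg[k - u]:
                    n_units = (k - run_start) // u
                    motif = seg[run_start : run_start + u]
                    if n_units >= min_units and is_primitive(motif):
                        loci.append(
                            StrLocus(
                                chrom=chrom,
                                start=offset + run_start,
                                end=offset + run_start + u * n_units,
                                motif=canonical_motif(motif),
                                unit_size=u,
                                ref_length=n_units,
                            )
                        )
                    if k >= n:
                        break
                    run_start = k - u + 1
                k += 1
    loci.sort(key=lambda l: (l.chrom, l.start, l.unit_size))
    return loci


def resolve_redundancy(loci: Sequence[StrLocus]) -> list[StrLocus]:
    """Select one representation per overlapping cluster.

    Candidates are ranked by smaller unit size, then longer span, then smaller
    start; a locus is kept only if it overlaps no higher-ranked kept locus.
    """
    kept: list[StrLocus] = []
    trees: dict[str, IntervalTree] = {}
    ranked = sorted(
        loci, key=lambda l: (l.unit_size, -(l.end - l.start), l.start, l.chrom)
    )
    for locus in ranked:
        tree = trees.setdefault(locus.chrom, IntervalTree())
        if not tree.overlap(locus.start, locus.end):
            tree.addi(locus.start, locus.end)
            kept.append(locus)
    kept.sort(key=lambda l: (l.chrom, l.start))
    return kept


def proximity_filter(loci: Sequence[StrLocus], min_gap_bp: int = 50) -> list[StrLocus]:
    """Remove every locus within ``min_gap_bp`` of another locus.

    Both members of a close pair are removed; "within" is inclusive, so a gap
    of exactly ``min_gap_bp`` base pairs still disqualifies the pair.  Input
    loci are assumed non-overlapping (run :func:`resolve_redundancy` first).
    """
    by_chrom: dict[str, list[StrLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    kept: list[StrLocus] = []
    for chrom_loci in by_chrom.values():
        chrom_loci.sort(key=lambda l: l.start)
        for i, locus in enumerate(chrom_loci):
            too_close = False
            if i > 0 and locus.start - chrom_loci[i - 1].end <= min_gap_bp:
                too_close = True
            if (
                i + 1 < len(chrom_loci)
                and chrom_loci[i + 1].start - locus.end <= min_gap_bp
            ):
                too_close = True
            if not too_close:
                kept.append(locus)
    kept.sort(key=lambda l: (l.chrom, l.start))
    return kept


# ---------------------------------------------------------------------------
# gene-model handling


def _validate_gff_lines(path: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, found {len(fields)}", lineno
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[3]!r}/{fields[4]!r}", lineno
                ) from None
            if start < 1 or end < start:
                raise ParseError(f"invalid coordinate range {start}-{end}", lineno)


def load_gene_models(path: str) -> pd.DataFrame:
    """Load gene/exon/CDS/UTR features from a GFF3 file.

    Returns a frame with columns feature, chrom, start, end, strand, gene_id
    (coordinates converted from GFF's 1-based closed to 0-based half-open).
    """
    import gffutils

    _validate_gff_lines(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    wanted = {
        "gene": "gene",
        "exon": "exon",
        "CDS": "CDS",
        "five_prime_UTR": "UTR",
        "three_prime_UTR": "UTR",
        "UTR": "UTR",
    }
    rows = []
    for feature in db.all_features():
        label = wanted.get(feature.featuretype)
        if label is None:
            continue
        gene_id = feature.attributes.get("gene_id", feature.attributes.get("ID", [""]))[0]
        rows.append(
            {
                "feature": label,
                "chrom": feature.seqid,
                "start": feature.start - 1,
                "end": feature.end,
                "strand": feature.strand,
                "gene_id": gene_id,
            }
        )
    frame = pd.DataFrame(rows, columns=["feature", "chrom", "start", "end", "strand", "gene_id"])
    # exons/CDS often carry transcript ids; map them onto their parent gene by
    # containment when the gene_id attribute is absent
    return frame


def _promoter_interval(gene_start: int, gene_end: int, strand: str, promoter_bp: int):
    if strand == "-":
        return gene_end, gene_end + promoter_bp
    return max(0, gene_start - promoter_bp), gene_start


def annotate_regions(
    loci: Sequence[StrLocus],
    gene_models: pd.DataFrame,
    promoter_bp: int = 5000,
) -> list[StrLocus]:
    """Label loci with the gene region they overlap and drop intergenic loci.

    Label priority when a locus touches several features: CDS > UTR > intron >
    promoter.  "Intron" is any overlap with a gene body not already explained
    by CDS/UTR; the promoter is the ``promoter_bp`` window upstream of the
    gene's strand-aware 5' end.  Loci outside every labelled region are
    removed, since only gene-associated sequence is genotyped.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}

    def tree(label: str, chrom: str) -> IntervalTree:
        return trees.setdefault((label, chrom), IntervalTree())

    for row in gene_models.itertuples():
        if row.feature == "gene":
            tree("gene", row.chrom).addi(row.start, row.end)
            p_start, p_end = _promoter_interval(
                row.start, row.end, row.strand, promoter_bp
            )
            if p_end > p_start:
                tree("promoter", row.chrom).addi(p_start, p_end)
        elif row.feature in {"CDS", "UTR"}:
            tree(row.feature, row.chrom).addi(row.start, row.end)

    annotated: list[StrLocus] = []
    for locus in loci:
        label = None
        for candidate, tree_label in (
            ("CDS", "CDS"),
            ("UTR", "UTR"),
            ("intron", "gene"),
            ("promoter", "promoter"),
        ):
            t = trees.get((tree_label, locus.chrom))
            if t is not None and t.overlap(locus.start, locus.end):
                label = candidate
                break
        if label is not None:
            annotated.append(replace(locus, region=label))
    return annotated


def apply_mask(
    loci: Sequence[StrLocus],
    mask: Sequence[tuple[str, int, int]] = (),
    non_autosomes: frozenset[str] = DEFAULT_NON_AUTOSOMES,
) -> list[StrLocus]:
    """Drop loci overlapping mask intervals (half-open, >=1 bp overlap) or
    lying on a non-autosomal sequence."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in mask:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for locus in loci:
        if locus.chrom in non_autosomes:
            continue
        tree = trees.get(locus.chrom)
        if tree is not None and tree.overlap(locus.start, locus.end):
            continue
        kept.append(locus)
    return kept


def build_panel(
    sequences: dict[str, str],
    gene_models: pd.DataFrame,
    min_lengths: Sequence[int] = DEFAULT_MIN_LENGTHS,
    min_gap_bp: int = 50,
    promoter_bp: int = 5000,
    mask: Sequence[tuple[str, int, int]] = (),
    non_autosomes: frozenset[str] = DEFAULT_NON_AUTOSOMES,
) -> list[StrLocus]:
    """Full panel pipeline: detect, de-duplicate, de-cluster, annotate, mask."""
    loci: list[StrLocus] = []
    for chrom, seq in sequences.items():
        loci.extend(detect_perfect_strs(seq, min_lengths, chrom=chrom))
    loci = resolve_redundancy(loci)
    loci = proximity_filter(loci, min_gap_bp=min_gap_bp)
    loci = annotate_regions(loci, gene_models, promoter_bp=promoter_bp)
    return apply_mask(loci, mask=mask, non_autosomes=non_autosomes)


# ---------------------------------------------------------------------------
# panel serialization (BED6+3)


def panel_to_frame(loci: Sequence[StrLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "locus_id": l.locus_id,
                "ref_length": l.ref_length,
                "strand": ".",
                "motif": l.motif,
                "unit_size": l.unit_size,
                "region": l.region,
            }
            for l in loci
        ],
        columns=PANEL_COLUMNS,
    )


def frame_to_panel(frame: pd.DataFrame) -> list[StrLocus]:
    return [
        StrLocus(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            motif=row.motif,
            unit_size=int(row.unit_size),
            ref_length=int(row.ref_length),
            region=row.region,
        )
        for row in frame.itertuples()
    ]


def write_panel(loci_or_frame, path: str) -> None:
    frame = (
        loci_or_frame
        if isinstance(loci_or_frame, pd.DataFrame)
        else panel_to_frame(loci_or_frame)
    )
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_panel(path: str) -> pd.DataFrame:
    """Read a panel BED6+3 file into a frame (columns as written)."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, names=PANEL_COLUMNS)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise ParseError(f"cannot read panel BED {path}: {exc}") from exc
    return frame
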