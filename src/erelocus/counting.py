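"""Unique-assignment read counting over locus and gene annotations.

Repetitive features make count allocation treacherous: a read touching two
features cannot be attributed with confidence, so the counting rule here is
deliberately strict — only primary alignments whose aligned blocks overlap
exactly one feature are counted; reads overlapping more than one feature
are discarded as ambiguous, and reads touching none are unassigned. This
underestimates total expression but guarantees that every count belongs to
the feature it is assigned to.

Genes and repeat loci are counted in two independent passes over the same
alignments, each against its own annotation, mirroring the two-GTF design
of the upstream pipeline.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .repeats import EreLocus, locus_class_label, read_gtf, _ATTR_RE, _as_lines

logger = logging.getLogger(__name__)

__all__ = [
    "AMBIGUOUS",
    "UNASSIGNED",
    "AlignedUnit",
    "Feature",
    "FeatureIndex",
    "CountMatrix",
    "build_index",
    "assign_unit",
    "count_sample",
    "count_experiment",
    "read_gene_features",
]


class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: a primary unit overlapping more than one feature — counted nowhere
AMBIGUOUS = _Sentinel("AMBIGUOUS")
#: a primary unit overlapping no feature
UNASSIGNED = _Sentinel("UNASSIGNED")


@dataclass(frozen=True)
class Feature:
    """A countable genomic feature: a merged repeat locus or a gene span."""

    feature_id: str
    query: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    class_label: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")


@dataclass(frozen=True)
class AlignedUnit:
    """One countable unit: a single-end read or a paired-end fragment.

    ``blocks`` are the 1-based inclusive aligned intervals (match/deletion
    segments); skipped introns between blocks are not part of the unit.
    """

    name: str
    reference: str
    blocks: tuple[tuple[int, int], ...]
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"unit {self.name}: no aligned blocks")
        if list(self.blocks) != sorted(self.blocks):
            raise ValueError(f"unit {self.name}: blocks must be sorted")


@dataclass
class FeatureIndex:
    """Per-reference interval index supporting >= 1 bp overlap queries."""

    trees: dict[str, IntervalTree]
    features: dict[str, Feature]

    def overlapping(self, reference: str, start: int, end: int) -> set[str]:
        """Feature ids whose span shares at least one base with [start, end]."""
        tree = self.trees.get(reference)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}

    def __len__(self) -> int:
        return len(self.features)


def build_index(features: Iterable[Feature | EreLocus]) -> FeatureIndex:
    """Index features for overlap lookup; duplicate feature ids are an error."""
    trees: dict[str, IntervalTree] = {}
    table: dict[str, Feature] = {}
    for feat in features:
        if isinstance(feat, EreLocus):
            feat = Feature(feat.locus_id, feat.query, feat.start, feat.end,
                           feat.strand, locus_class_label(feat))
        if feat.feature_id in table:
            raise ValueError(f"duplicate feature id {feat.feature_id!r}")
        table[feat.feature_id] = feat
        trees.setdefault(feat.query, IntervalTree()).addi(
            feat.start, feat.end + 1, feat.feature_id)
    return FeatureIndex(trees=trees, features=table)


def assign_unit(unit: AlignedUnit, index: FeatureIndex):
    """Assign a primary unit to a single feature, or AMBIGUOUS/UNASSIGNED.

    A unit is assigned iff the union of features overlapped by any of its
    aligned blocks contains exactly one feature id.
    """
    if not unit.is_primary:
        raise ValueError("only primary units are countable")
    hits: set[str] = set()
    for start, end in unit.blocks:
        hits |= index.overlapping(unit.reference, start, end)
        if len(hits) > 1:
            return AMBIGUOUS
    if not hits:
        return UNASSIGNED
    return next(iter(hits))


# ---------------------------------------------------------------------------
# SAM/BAM traversal
# ---------------------------------------------------------------------------

def _record_blocks(rec: pysam.AlignedSegment) -> tuple[tuple[int, int], ...]:
    # pysam blocks are 0-based half-open; deletions split blocks, which is
    # fine for >=1bp overlap testing (a deleted base overlaps nothing)
    return tuple((s + 1, e) for s, e in rec.get_blocks())


def iter_units(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    pairing: str = "fragment",
    min_mapq: int = 0,
):
    """Yield countable :class:`AlignedUnit` objects from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped. In
    ``fragment`` mode the primary records of both mates are unioned into
    one unit per template; in ``read`` mode each primary record is its own
    unit.
    """
    if pairing not in ("read", "fragment"):
        raise ValueError(f"pairing must be 'read' or 'fragment', got {pairing!r}")
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(os.fspath(alignments), check_sq=False)
        own = True
    try:
        pending: dict[str, AlignedUnit] = {}
        for i, rec in enumerate(alignments):
            try:
                if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                        or rec.mapping_quality < min_mapq):
                    continue
                unit = AlignedUnit(
                    name=rec.query_name or f"record_{i}",
                    reference=rec.reference_name,
                    blocks=_record_blocks(rec),
                )
            except Exception as exc:
                raise ValueError(f"unreadable alignment record {i}: {exc}") from exc
            if pairing == "read" or not rec.is_paired:
                yield unit
            elif unit.name in pending:
                mate = pending.pop(unit.name)
                if mate.reference == unit.reference:
                    merged = tuple(sorted(set(mate.blocks) | set(unit.blocks)))
                    yield AlignedUnit(unit.name, unit.reference, merged)
                else:
                    # discordant mates: keep the first mate's placement
                    yield mate
            else:
                pending[unit.name] = unit
        # unpaired leftovers (mate unmapped or absent) count as single units
        yield from pending.values()
    finally:
        if own:
            alignments.close()


def count_sample(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    index: FeatureIndex,
    pairing: str = "fragment",
    min_mapq: int = 0,
) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample against an index.

    Returns a per-feature integer Series (indexed by every feature in the
    index, zeros included) and a totals dict with keys ``assigned``,
    ``ambiguous`` and ``unassigned`` which sum to the number of countable
    primary units.
    """
    counts = dict.fromkeys(index.features, 0)
    totals = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    missing_refs: set[str] = set()
    for unit in iter_units(alignments, pairing=pairing, min_mapq=min_mapq):
        if unit.reference not in index.trees and unit.reference not in missing_refs:
            missing_refs.add(unit.reference)
            logger.warning("reference %r absent from annotation; reads there "
                           "counted as unassigned", unit.reference)
        hit = assign_unit(unit, index)
        if hit is AMBIGUOUS:
            totals["ambiguous"] += 1
        elif hit is UNASSIGNED:
            totals["unassigned"] += 1
        else:
            counts[hit] += 1
            totals["assigned"] += 1
    return pd.Series(counts, dtype=int), totals


@dataclass
class CountMatrix:
    """Feature x sample integer counts plus class labels and unit totals.

    ``totals`` has rows assigned/ambiguous/unassigned, one column per
    sample; per sample the three sum to the number of countable primary
    units in that sample's alignments.
    """

    counts: pd.DataFrame
    classes: pd.Series
    totals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.classes = self.classes.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, stream: TextIO | str | os.PathLike) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.classes)
        out.to_csv(stream, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, stream: TextIO | str | os.PathLike) -> "CountMatrix":
        df = pd.read_csv(stream, sep="\t", index_col="feature_id")
        classes = df.pop("class")
        return cls(counts=df.astype(int), classes=classes)


def read_gene_features(stream: str | TextIO | Iterable[str]) -> list[Feature]:
    """Read gene features from a standard GTF (class label ``gene``).

    Each ``gene_id`` becomes one feature spanning the min/max of its exon
    (or gene/transcript) lines.
    """
    spans: dict[str, list] = {}
    for line_no, line in _as_lines(stream):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GTF line {line_no}: expected 9 columns")
        if cols[2] not in ("exon", "gene", "transcript", "CDS"):
            continue
        attrs = dict(_ATTR_RE.findall(cols[8]))
        gid = attrs.get("gene_id")
        if gid is None:
            raise ValueError(f"GTF line {line_no}: missing gene_id")
        start, end = int(cols[3]), int(cols[4])
        strand = cols[6] if cols[6] in ("+", "-") else "+"
        rec = spans.get(gid)
        if rec is None:
            spans[gid] = [cols[0], start, end, strand]
        else:
            if rec[0] != cols[0]:
                raise ValueError(f"gene {gid!r} spans multiple references")
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
    return [Feature(gid, ref, s, e, strand, "gene")
            for gid, (ref, s, e, strand) in spans.items()]


def _sample_name(path: str | os.PathLike) -> str:
    name = Path(path).name
    for suffix in (".bam", ".sam", ".cram"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def count_experiment(
    samples: Sequence[str | os.PathLike],
    gene_gtf: str | os.PathLike | None,
    repeat_gtf: str | os.PathLike,
    pairing: str = "fragment",
    min_mapq: int = 0,
) -> tuple[CountMatrix | None, CountMatrix]:
    """Count an experiment: separate gene and repeat passes per sample.

    Returns ``(gene_matrix, repeat_matrix)``; the gene matrix is ``None``
    when no gene GTF is supplied. Column order follows the input sample
    order; sample names are the alignment file stems.
    """
    if not samples:
        raise ValueError("need at least one sample")
    for path in samples:
        if not Path(path).exists():
            raise FileNotFoundError(f"sample alignment file not found: {path}")

    with open(repeat_gtf) as fh:
        repeat_index = build_index(read_gtf(fh))
    gene_index = None
    if gene_gtf is not None:
        with open(gene_gtf) as fh:
            gene_index = build_index(read_gene_features(fh))

    def _run(index: FeatureIndex) -> CountMatrix:
        cols, tot = {}, {}
        for path in samples:
            name = _sample_name(path)
            series, totals = count_sample(path, index, pairing=pairing,
                                          min_mapq=min_mapq)
            cols[name], tot[name] = series, totals
        counts = pd.DataFrame(cols)
        classes = pd.Series({fid: f.class_label
                             for fid, f in index.features.items()})
        totals = pd.DataFrame(tot)
        logger.info("counted %d samples x %d features", counts.shape[1],
                    counts.shape[0])
        return CountMatrix(counts=counts, classes=classes, totals=totals)

    repeat_cm = _run(repeat_index)
    gene_cm = _run(gene_index) if gene_index is not None else None
    return gene_cm, repeat_cm
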