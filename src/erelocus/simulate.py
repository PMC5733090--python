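"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the structures the pipeline consumes:

* :func:`gen_rm_out` — RepeatMasker ``.out`` tables containing full
  LTR–internal–LTR proviruses (separate annotations per segment, as
  RepeatMasker emits them), solo LTRs, and interrupted LINEs whose
  fragments share a linkage ID;
* :func:`gen_sam` — SAM alignments placed on known features, including
  junction-spanning reads across the former LTR/internal divide,
  deliberately ambiguous reads straddling two features, multimapper
  secondary records and off-feature background;
* :func:`gen_counts` — negative-binomial count matrices with planted
  per-sample depth factors and group fold-changes.

Every generator is a pure function of its spec and a seed (NumPy
``default_rng``): the same seed yields byte-identical artifacts, and each
artifact ships with a machine-readable truth table so downstream recovery
tests never re-derive the ground truth.

None of this models sequencing error, splicing or a realistic genome
background — see the methods note for what that implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountMatrix

__all__ = [
    "ProvirusSpec",
    "SoloLtrSpec",
    "InterruptedLineSpec",
    "FixtureSpec",
    "ReadSpec",
    "CountModelSpec",
    "gen_rm_out",
    "gen_sam",
    "gen_counts",
    "xmv45_like_provirus",
    "b_cell_activation_fixture",
]


# ---------------------------------------------------------------------------
# element specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProvirusSpec:
    """A full LTR–internal–LTR provirus planted on one contig.

    RepeatMasker reports the three (or more) segments as separate
    annotations with distinct linkage IDs; ``gap`` is the spacing between
    consecutive segments and ``n_int_pieces`` splits the internal region
    into several fragments sharing one ID (an interrupted internal body).
    """

    query: str
    start: int
    strand: str = "+"
    ltr_name: str = "RLTR4_Mm"
    int_name: str = "MuLV-int"
    rep_class: str = "LTR/ERV1"
    ltr_len: int = 754
    int_len: int = 7059
    gap: int = 50
    n_int_pieces: int = 1

    @property
    def end(self) -> int:
        return self.start + 2 * self.ltr_len + self.int_len + 2 * self.gap - 1

    def segments(self) -> list[tuple[int, int, str, bool]]:
        """(start, end, rep_name, shares_previous_link_id) per fragment."""
        segs = [(self.start, self.start + self.ltr_len - 1, self.ltr_name, False)]
        pos = self.start + self.ltr_len + self.gap
        piece = self.int_len // self.n_int_pieces
        inter = 80  # spacing between pieces of the interrupted internal body
        remaining = self.int_len - inter * (self.n_int_pieces - 1)
        piece = remaining // self.n_int_pieces
        for i in range(self.n_int_pieces):
            plen = piece if i < self.n_int_pieces - 1 else (
                remaining - piece * (self.n_int_pieces - 1))
            segs.append((pos, pos + plen - 1, self.int_name, i > 0))
            pos += plen + inter
        # place the right LTR so the total span is independent of the split
        right = self.end - self.ltr_len + 1
        segs.append((right, self.end, self.ltr_name, False))
        return segs

    @property
    def junctions(self) -> tuple[int, ...]:
        """Boundary coordinates b such that a read covering b and b+1
        spans a former LTR/internal divide."""
        left_ltr_end = self.start + self.ltr_len - 1
        right_ltr_start = self.end - self.ltr_len + 1
        return (left_ltr_end, right_ltr_start - 1)

    @property
    def locus_id(self) -> str:
        return (f"{self.rep_class}|{self.int_name}~{self.ltr_name}|"
                f"{self.query}|{self.start}|{self.end}")


@dataclass(frozen=True)
class SoloLtrSpec:
    """A single-fragment solo LTR (recombination relic)."""

    query: str
    start: int
    strand: str = "+"
    name: str = "RLTR4_Mm"
    rep_class: str = "LTR/ERV1"
    length: int = 750

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def locus_id(self) -> str:
        return f"{self.rep_class}|{self.name}|{self.query}|{self.start}|{self.end}"


@dataclass(frozen=True)
class InterruptedLineSpec:
    """A LINE split into fragments that share one RepeatMasker ID."""

    query: str
    start: int
    strand: str = "+"
    name: str = "L1Md_A"
    rep_class: str = "LINE/L1"
    piece_lengths: tuple[int, ...] = (900, 1400)
    gap: int = 300

    @property
    def end(self) -> int:
        return (self.start + sum(self.piece_lengths)
                + self.gap * (len(self.piece_lengths) - 1) - 1)

    def segments(self) -> list[tuple[int, int]]:
        segs, pos = [], self.start
        for plen in self.piece_lengths:
            segs.append((pos, pos + plen - 1))
            pos += plen + self.gap
        return segs

    @property
    def locus_id(self) -> str:
        return f"{self.rep_class}|{self.name}|{self.query}|{self.start}|{self.end}"


@dataclass(frozen=True)
class FixtureSpec:
    """All planted elements of one synthetic repeat annotation."""

    contig_lengths: Mapping[str, int]
    proviruses: tuple[ProvirusSpec, ...] = ()
    solo_ltrs: tuple[SoloLtrSpec, ...] = ()
    lines: tuple[InterruptedLineSpec, ...] = ()
    allow_overlap: bool = False

    def elements(self):
        return list(self.proviruses) + list(self.solo_ltrs) + list(self.lines)


def xmv45_like_provirus() -> ProvirusSpec:
    """The xenotropic MLV provirus on chromosome 5 used as the canonical
    merge fixture: an RLTR4_Mm/MuLV-int/RLTR4_Mm provirus whose merged
    locus is LTR/ERV1|MuLV-int~RLTR4_Mm|5|23700579|23709245."""
    return ProvirusSpec(query="5", start=23700579, strand="-")


# ---------------------------------------------------------------------------
# RepeatMasker .out generation
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query     "
    "matching repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)   "
    "repeat   class/family  begin end  (left)  ID\n"
    "\n"
)


def _rm_line(rng: np.random.Generator, query: str, q_start: int, q_end: int,
             q_left: int, strand: str, name: str, rep_class: str,
             link_id: int) -> str:
    sw = int(rng.integers(300, 5000))
    div = round(float(rng.uniform(0.0, 25.0)), 1)
    dele = round(float(rng.uniform(0.0, 8.0)), 1)
    ins = round(float(rng.uniform(0.0, 8.0)), 1)
    rlen = q_end - q_start + 1
    if strand == "+":
        rep_fields = f"{1} {rlen} (0)"
        strand_tok = "+"
    else:
        rep_fields = f"(0) {rlen} {1}"
        strand_tok = "C"
    return (f"{sw:>5} {div:>5.1f} {dele:>4.1f} {ins:>4.1f}  {query:<8} "
            f"{q_start:>9} {q_end:>9} ({q_left}) {strand_tok} {name:<14} "
            f"{rep_class:<14} {rep_fields} {link_id:>6}\n")


def gen_rm_out(spec: FixtureSpec, seed: int = 0) -> tuple[str, pd.DataFrame]:
    """Render a fixture as RepeatMasker ``.out`` text plus its truth table.

    The truth table lists the loci the merger is expected to produce, one
    row per planted element, with columns locus_id, query, start, end,
    strand, rep_class, kind, n_fragments and junctions (provirus
    LTR/internal boundary coordinates, empty elsewhere).
    """
    elements = spec.elements()
    spans: list[tuple[str, int, int]] = []
    for el in elements:
        if el.query not in spec.contig_lengths:
            raise ValueError(f"element on unknown contig {el.query!r}")
        if el.end > spec.contig_lengths[el.query]:
            raise ValueError(f"element {el.locus_id} exceeds contig length")
        spans.append((el.query, el.start, el.end))
    if not spec.allow_overlap:
        spans.sort()
        for (q1, s1, e1), (q2, s2, e2) in zip(spans, spans[1:]):
            if q1 == q2 and s2 <= e1:
                raise ValueError(
                    f"planted elements overlap on {q1}: [{s1},{e1}] and "
                    f"[{s2},{e2}] (set allow_overlap=True to permit)")

    rng = np.random.default_rng(seed)
    lines = [_RM_HEADER]
    truth_rows = []
    link_id = 0
    for el in sorted(elements, key=lambda e: (e.query, e.start)):
        clen = spec.contig_lengths[el.query]
        if isinstance(el, ProvirusSpec):
            n_frags = 0
            for s, e, name, shares in el.segments():
                if not shares:
                    link_id += 1
                lines.append(_rm_line(rng, el.query, s, e, clen - e,
                                      el.strand, name, el.rep_class, link_id))
                n_frags += 1
            kind, junctions = "provirus", list(el.junctions)
        elif isinstance(el, SoloLtrSpec):
            link_id += 1
            lines.append(_rm_line(rng, el.query, el.start, el.end,
                                  clen - el.end, el.strand, el.name,
                                  el.rep_class, link_id))
            kind, junctions, n_frags = "solo_ltr", [], 1
        else:
            link_id += 1
            for s, e in el.segments():
                lines.append(_rm_line(rng, el.query, s, e, clen - e,
                                      el.strand, el.name, el.rep_class,
                                      link_id))
            kind, junctions = "line", []
            n_frags = len(el.piece_lengths)
        truth_rows.append({
            "locus_id": el.locus_id, "query": el.query, "start": el.start,
            "end": el.end, "strand": el.strand, "rep_class": el.rep_class,
            "kind": kind, "n_fragments": n_frags, "junctions": junctions,
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "locus_id", "query", "start", "end", "strand", "rep_class", "kind",
        "n_fragments", "junctions"])
    return "".join(lines), truth


# ---------------------------------------------------------------------------
# SAM generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSpec:
    """How many reads to place on each feature, and how.

    ``counts`` maps feature_id -> intended uniquely-assignable read (or
    fragment) count for one sample. Fractions are of the total intended
    count: ``junction_fraction`` of each provirus's reads straddle an
    LTR/internal boundary (still inside the merged locus);
    ``ambiguous_fraction`` adds reads straddling two nearby features;
    ``unassigned_fraction`` adds off-feature background;
    ``multimapper_fraction`` of assigned reads also emit one secondary
    alignment elsewhere.
    """

    counts: Mapping[str, int]
    read_length: int = 75
    paired: bool = False
    insert_size: int = 180
    junction_fraction: float = 0.0
    ambiguous_fraction: float = 0.0
    unassigned_fraction: float = 0.0
    multimapper_fraction: float = 0.0


_BASES = np.array(list("ACGT"))


def _seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _sam_header(contig_lengths: Mapping[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return "\n".join(lines) + "\n"


def _sam_record(qname: str, flag: int, ref: str, pos: int, cigar: str,
                seq: str, rnext: str = "*", pnext: int = 0,
                tlen: int = 0, mapq: int = 60) -> str:
    return (f"{qname}\t{flag}\t{ref}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t"
            f"{pnext}\t{tlen}\t{seq}\t{'I' * len(seq)}\n")


class _SpanLookup:
    """Vectorized per-contig overlap test against the feature table."""

    def __init__(self, features: pd.DataFrame):
        self._by_query: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for query, sub in features.groupby("query"):
            self._by_query[query] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["feature_id"].to_numpy(object),
            )

    def overlaps_other(self, query: str, start: int, end: int,
                       own_id: str) -> bool:
        entry = self._by_query.get(query)
        if entry is None:
            return False
        starts, ends, ids = entry
        hits = (starts <= end) & (ends >= start) & (ids != own_id)
        return bool(hits.any())


def _ambiguous_windows(features: pd.DataFrame, read_len: int):
    """Placement windows for reads straddling two consecutive features."""
    windows = []
    for _, chrom_df in features.groupby("query"):
        chrom_df = chrom_df.sort_values(["start", "end"])
        rows = chrom_df.to_dict("records")
        for left, right in zip(rows, rows[1:]):
            gap = right["start"] - left["end"] - 1
            if 0 <= gap <= read_len - 2:
                # p <= left.end keeps the read on the left feature,
                # p + L - 1 >= right.start puts it on the right one too
                lo = max(right["start"] - read_len + 1, left["start"])
                hi = left["end"]
                if lo <= hi:
                    windows.append((left["query"], lo, hi))
    return windows


def gen_sam(
    features: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    read_spec: ReadSpec,
    seed: int = 0,
    sample: str = "sample",
) -> tuple[str, pd.DataFrame]:
    """Place reads on known features and return (SAM text, placement table).

    ``features`` needs columns feature_id, query, start, end and
    optionally junctions (list of boundary coordinates). The placement
    table is exact ground truth: one row per countable unit with columns
    qname, category (``assigned``/``ambiguous``/``unassigned``) and
    feature_id (empty unless assigned).
    """
    required = {"feature_id", "query", "start", "end"}
    if not required <= set(features.columns):
        raise ValueError(f"features must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    L = read_spec.read_length
    records: list[str] = []
    placements: list[dict] = []
    feat_rows = features.set_index("feature_id")
    lookup = _SpanLookup(features)

    def emit_unit(qname: str, ref: str, pos: int,
                  max_end: int | None = None) -> None:
        """One countable unit at pos (1-based); paired mode emits mates.

        ``max_end`` caps the downstream mate so an assigned fragment stays
        inside its own feature.
        """
        if read_spec.paired:
            mate2 = pos + max(read_spec.insert_size - L, 0)
            clen = contig_lengths[ref]
            mate2 = min(mate2, clen - L + 1)
            if max_end is not None:
                mate2 = max(pos, min(mate2, max_end - L + 1))
            tlen = mate2 + L - pos
            records.append(_sam_record(qname, 99, ref, pos, f"{L}M",
                                       _seq(rng, L), "=", mate2, tlen))
            records.append(_sam_record(qname, 147, ref, mate2, f"{L}M",
                                       _seq(rng, L), "=", pos, -tlen))
        else:
            flag = 16 if rng.random() < 0.5 else 0
            records.append(_sam_record(qname, flag, ref, pos, f"{L}M",
                                       _seq(rng, L)))

    n_reads = 0
    assigned_positions: list[tuple[str, int]] = []
    for fid, n in read_spec.counts.items():
        if fid not in feat_rows.index:
            raise KeyError(f"no such feature {fid!r}")
        row = feat_rows.loc[fid]
        start, end, ref = int(row["start"]), int(row["end"]), row["query"]
        span = end - start + 1
        if L > span:
            raise ValueError(
                f"read length {L} exceeds feature {fid} span {span}")
        junctions = list(row.get("junctions") or [])
        n_junction = round(read_spec.junction_fraction * n) if junctions else 0
        for i in range(int(n)):
            qname = f"{sample}:{fid.replace('|', '_')}:{i}"
            if i < n_junction:
                b = junctions[i % len(junctions)]
                lo, hi = max(start, b - L + 2), min(b, end - L + 1)
                pos = int(rng.integers(lo, hi + 1)) if lo <= hi else start
            else:
                for _ in range(50):  # keep the read inside its own feature only
                    pos = int(rng.integers(start, end - L + 2))
                    if not lookup.overlaps_other(ref, pos, pos + L - 1, fid):
                        break
                else:
                    raise ValueError(
                        f"could not place a read uniquely inside {fid}")
            emit_unit(qname, ref, pos, max_end=end)
            assigned_positions.append((ref, pos))
            placements.append({"qname": qname, "category": "assigned",
                               "feature_id": fid})
            n_reads += 1

    total_intended = sum(int(v) for v in read_spec.counts.values())
    n_ambiguous = round(read_spec.ambiguous_fraction * total_intended)
    if n_ambiguous:
        windows = _ambiguous_windows(features, L)
        if not windows:
            raise ValueError(
                "ambiguous_fraction > 0 but no two features lie within a "
                "read length of each other")
        for i in range(n_ambiguous):
            ref, lo, hi = windows[i % len(windows)]
            pos = int(rng.integers(lo, hi + 1))
            qname = f"{sample}:ambig:{i}"
            emit_unit(qname, ref, pos)
            placements.append({"qname": qname, "category": "ambiguous",
                               "feature_id": ""})

    n_unassigned = round(read_spec.unassigned_fraction * total_intended)
    for i in range(n_unassigned):
        for _ in range(200):
            ref = list(contig_lengths)[int(rng.integers(len(contig_lengths)))]
            pos = int(rng.integers(1, contig_lengths[ref] - L + 2))
            if not lookup.overlaps_other(ref, pos, pos + L - 1, ""):
                break
        else:
            raise ValueError("could not find an off-feature placement")
        qname = f"{sample}:bg:{i}"
        emit_unit(qname, ref, pos)
        placements.append({"qname": qname, "category": "unassigned",
                           "feature_id": ""})

    # secondary alignments for a fraction of assigned reads: same name,
    # flag 0x100, placed anywhere — counters must skip them
    n_multi = round(read_spec.multimapper_fraction * len(assigned_positions))
    for i in range(n_multi):
        ref, pos = assigned_positions[i % len(assigned_positions)]
        alt_ref = list(contig_lengths)[int(rng.integers(len(contig_lengths)))]
        alt_pos = int(rng.integers(1, contig_lengths[alt_ref] - L + 2))
        records.append(_sam_record(f"{sample}:multi:{i}", 256, alt_ref,
                                   alt_pos, f"{L}M", _seq(rng, L), mapq=0))

    placement = pd.DataFrame(placements,
                             columns=["qname", "category", "feature_id"])
    return _sam_header(contig_lengths) + "".join(records), placement


# ---------------------------------------------------------------------------
# negative-binomial count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountModelSpec:
    """Negative-binomial count model with planted effects.

    ``dispersion`` is the NB overdispersion alpha in
    Var = mu + alpha * mu^2; ``planted_log2_fc`` maps feature index ->
    log2 fold-change applied to group B; ``depth_factors`` multiply every
    feature's mean in the corresponding sample (library-size variation).
    """

    n_features: int = 2000
    n_group_a: int = 3
    n_group_b: int = 3
    mean_log: float = 3.5
    mean_sdlog: float = 1.2
    dispersion: float = 0.1
    depth_factors: tuple[float, ...] | None = None
    planted_log2_fc: Mapping[int, float] = field(default_factory=dict)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.6, "LTR": 0.25, "LINE": 0.15})

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        n = self.n_group_a + self.n_group_b
        if self.depth_factors is not None and len(self.depth_factors) != n:
            raise ValueError("depth_factors must have one entry per sample")


def gen_counts(spec: CountModelSpec, seed: int = 0,
               ) -> tuple[CountMatrix, dict]:
    """Simulate a count matrix; returns (matrix, truth).

    Truth carries base_means, the planted log2 fold-changes, the depth
    factors and the group sample names.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_group_a + spec.n_group_b
    samples = ([f"a{i + 1}" for i in range(spec.n_group_a)]
               + [f"b{i + 1}" for i in range(spec.n_group_b)])
    depth = np.asarray(spec.depth_factors
                       if spec.depth_factors is not None else np.ones(n))

    base = rng.lognormal(mean=spec.mean_log, sigma=spec.mean_sdlog,
                         size=spec.n_features)
    lfc = np.zeros(spec.n_features)
    for idx, value in spec.planted_log2_fc.items():
        lfc[idx] = value

    mu = np.outer(base, depth)
    mu[:, spec.n_group_a:] *= (2.0 ** lfc)[:, None]
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    features = [f"feat{i:05d}" for i in range(spec.n_features)]
    labels = list(spec.class_proportions)
    probs = np.array(list(spec.class_proportions.values()), dtype=float)
    classes = pd.Series(rng.choice(labels, size=spec.n_features,
                                   p=probs / probs.sum()), index=features)
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        classes=classes,
    )
    truth = {
        "base_means": pd.Series(base, index=features),
        "log2_fc": pd.Series(lfc, index=features),
        "depth_factors": pd.Series(depth, index=samples),
        "group_a": samples[: spec.n_group_a],
        "group_b": samples[spec.n_group_a:],
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# the canned end-to-end scenario
# ---------------------------------------------------------------------------

def _activation_fixture_spec() -> FixtureSpec:
    contigs = {"1": 172_000_000, "5": 24_000_000}
    proviruses = (
        xmv45_like_provirus(),                                   # induced
        ProvirusSpec(query="1", start=171_481_146, strand="+"),
        ProvirusSpec(query="1", start=170_941_521, strand="+"),
    )
    solo_ltrs = (
        SoloLtrSpec(query="1", start=5_000_000, name="RLTR4_Mm"),
        SoloLtrSpec(query="1", start=5_100_000, name="RLTR6_Mm"),
        # a deliberately close pair (40 bp apart, non-mergeable: no
        # internal model) so ambiguous reads have somewhere to land
        SoloLtrSpec(query="1", start=5_200_000, name="ORR1A0",
                    rep_class="LTR/ERVL-MaLR", length=350),
        SoloLtrSpec(query="1", start=5_200_390, name="ORR1A0",
                    rep_class="LTR/ERVL-MaLR", length=350),
        SoloLtrSpec(query="5", start=1_000_000, name="RLTR4_Mm", strand="-"),
    )
    lines = (
        InterruptedLineSpec(query="1", start=6_000_000),
        InterruptedLineSpec(query="1", start=6_200_000, strand="-"),
        InterruptedLineSpec(query="5", start=2_000_000, name="L1Md_T"),
    )
    return FixtureSpec(contig_lengths=contigs, proviruses=proviruses,
                       solo_ltrs=solo_ltrs, lines=lines)


def _activation_genes(contigs: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    for i in range(8):
        start = 10_000_000 + i * 200_000
        rows.append({"feature_id": f"Gene{i + 1:04d}", "query": "1",
                     "start": start, "end": start + 20_000, "strand": "+",
                     "junctions": []})
    return pd.DataFrame(rows)


def b_cell_activation_fixture(outdir, seed: int = 0, induced_fold: float = 20.0,
                              base_depth: int = 60) -> dict:
    """Write the canned B-cell activation scenario to ``outdir``.

    Emulates a resting-vs-activated contrast in which one MLV provirus
    (the chromosome 5 element) is induced ``induced_fold``-fold while most
    repeat loci barely move — the situation in which locus-level merging
    and unique counting must single out one provirus. Three resting and
    three activated samples are written as SAM, alongside the RepeatMasker
    table, a synthetic gene GTF and truth tables.

    Returns a dict with keys rm_out, gene_gtf, samples (list of SAM
    paths), truth_loci (DataFrame), induced_locus (locus_id), group_a /
    group_b (sample names) and contig_lengths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = _activation_fixture_spec()

    rm_text, truth = gen_rm_out(spec, seed=seed)
    rm_out = outdir / "repeats.rm.out"
    rm_out.write_text(rm_text)

    genes = _activation_genes(spec.contig_lengths)
    gene_gtf = outdir / "genes.gtf"
    with gene_gtf.open("w") as fh:
        for _, g in genes.iterrows():
            attrs = (f'gene_id "{g.feature_id}"; '
                     f'transcript_id "{g.feature_id}.1";')
            fh.write("\t".join([g.query, "synthetic", "exon", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")

    features = pd.concat([
        truth.rename(columns={"locus_id": "feature_id"})[
            ["feature_id", "query", "start", "end", "strand", "junctions"]],
        genes,
    ], ignore_index=True)

    induced = xmv45_like_provirus().locus_id
    repeat_ids = list(truth["locus_id"])
    base = {fid: int(rng.integers(20, base_depth + 1)) for fid in repeat_ids}
    gene_base = {g: int(rng.integers(80, 200)) for g in genes["feature_id"]}
    up_genes = list(genes["feature_id"][:3])  # activation-induced genes

    groups = {"a": [f"rest_{i + 1}" for i in range(3)],
              "b": [f"act_{i + 1}" for i in range(3)]}
    sample_paths = []
    for gi, (group, names) in enumerate(groups.items()):
        for name in names:
            counts = {}
            for fid in repeat_ids:
                mean = base[fid]
                if group == "b" and fid == induced:
                    mean = mean * induced_fold
                counts[fid] = max(1, int(rng.poisson(mean)))
            for g, mean in gene_base.items():
                if group == "b" and g in up_genes:
                    mean = mean * 4
                counts[g] = max(1, int(rng.poisson(mean)))
            read_spec = ReadSpec(counts=counts, read_length=75,
                                 junction_fraction=0.15,
                                 ambiguous_fraction=0.02,
                                 unassigned_fraction=0.05,
                                 multimapper_fraction=0.05)
            sam_text, _ = gen_sam(features, spec.contig_lengths, read_spec,
                                  seed=int(rng.integers(2 ** 31)),
                                  sample=name)
            path = outdir / f"{name}.sam"
            path.write_text(sam_text)
            sample_paths.append(path)

    return {
        "rm_out": rm_out,
        "gene_gtf": gene_gtf,
        "samples": sample_paths,
        "truth_loci": truth,
        "induced_locus": induced,
        "group_a": groups["a"],
        "group_b": groups["b"],
        "contig_lengths": dict(spec.contig_lengths),
    }
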