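"""RepeatMasker annotation parsing and locus-level feature assembly.

RepeatMasker reports each repeat as one or more tabular annotation lines.
Two kinds of fragmentation stand between those lines and a biologically
meaningful feature:

* an element interrupted by a later insertion is reported as several
  fragments sharing the integer ID in the last column;
* a proviral LTR element is reported as separate long-terminal-repeat and
  internal-region annotations (e.g. ``RLTR4_Mm`` flanking ``MuLV-int``),
  each with its own ID, even though reads routinely span the junctions.

This module parses the ``.out`` dialect, groups fragments by ID linkage,
merges adjacent LTR/internal annotations into single provirus loci, and
round-trips the resulting loci through a composite locus identifier and
GTF so that standard read counters can consume them.

All coordinates are 1-based inclusive, matching both the RepeatMasker and
GTF conventions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "RepeatFragment",
    "EreLocus",
    "MergePolicy",
    "RmOutParseError",
    "LocusIdError",
    "parse_rm_out",
    "link_fragments",
    "assemble_loci",
    "format_locus_id",
    "parse_locus_id",
    "write_gtf",
    "read_gtf",
]

# the printed separator between model names in a composite locus name;
# U+223C shows up in typeset material, ASCII '~' is what we emit
_NAME_SEP = "~"
_NAME_SEP_ALIASES = ("~", "∼")


class RmOutParseError(ValueError):
    """A RepeatMasker ``.out`` line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class LocusIdError(ValueError):
    """A locus identifier string is malformed."""


@dataclass(frozen=True)
class RepeatFragment:
    """One RepeatMasker annotation line.

    ``r_start``/``r_end`` are consensus coordinates, stored with
    ``r_start <= r_end`` regardless of strand; ``link_id`` is the integer
    ID linking fragments of one interrupted element; ``overlapped`` is the
    trailing ``*`` flag marking a hit overlapped by a higher-scoring one.
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query: str
    q_start: int
    q_end: int
    strand: str
    rep_name: str
    rep_class: str
    r_start: int
    r_end: int
    r_left: int
    link_id: int
    overlapped: bool = False

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"q_start {self.q_start} > q_end {self.q_end} for {self.rep_name}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.link_id < 1:
            raise ValueError(f"link_id must be >= 1, got {self.link_id}")
        if min(self.pct_div, self.pct_del, self.pct_ins) < 0:
            raise ValueError("percentage fields must be non-negative")

    @property
    def span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)


@dataclass(frozen=True)
class EreLocus:
    """A locus-level retroelement feature assembled from one or more fragments.

    ``name_chain`` lists the constituent repeat models, internal model(s)
    first then LTR model(s), de-duplicated — e.g. ``("MuLV-int",
    "RLTR4_Mm")`` for a full MLV provirus. The composite ``locus_id``
    (``class|names|query|start|end``) is stable across runs and is used as
    the gene_id in emitted GTF.
    """

    rep_class: str
    name_chain: tuple[str, ...]
    query: str
    start: int
    end: int
    strand: str
    fragments: tuple[RepeatFragment, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.name_chain:
            raise ValueError("name_chain must not be empty")
        if self.fragments:
            if self.start != min(f.q_start for f in self.fragments):
                raise ValueError("start must equal min fragment q_start")
            if self.end != max(f.q_end for f in self.fragments):
                raise ValueError("end must equal max fragment q_end")
            if any(f.query != self.query for f in self.fragments):
                raise ValueError("all fragments must share the locus query")

    @property
    def locus_id(self) -> str:
        return format_locus_id(self)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class MergePolicy:
    """Rules deciding when adjacent fragment groups form one locus.

    ``max_gap`` is the largest tolerated distance (bp) between consecutive
    groups; ``internal_suffixes`` mark internal-region model names (one of
    the pair must be internal — two neighbouring solo LTRs never merge);
    ``merge_scope`` restricts adjacency merging to LTR classes (default)
    or applies it to every class; ``drop_overlapped`` discards fragments
    flagged ``*`` before assembly.
    """

    max_gap: int = 100
    require_same_strand: bool = True
    internal_suffixes: tuple[str, ...] = ("-int", "_I", "-I", "_int")
    merge_scope: str = "ltr_only"
    drop_overlapped: bool = False

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if self.merge_scope not in ("ltr_only", "all_classes"):
            raise ValueError(f"unknown merge_scope {self.merge_scope!r}")

    def is_internal(self, rep_name: str) -> bool:
        return any(rep_name.endswith(suf) for suf in self.internal_suffixes)


DEFAULT_POLICY = MergePolicy()


def _is_ltr_class(rep_class: str) -> bool:
    return rep_class.split("/", 1)[0].upper() == "LTR"


# ---------------------------------------------------------------------------
# .out parsing
# ---------------------------------------------------------------------------

def _as_lines(stream: str | TextIO | Iterable[str]) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for i, line in enumerate(stream, start=1):
        yield i, line.rstrip("\n")


def parse_rm_out(stream: str | TextIO | Iterable[str]) -> list[RepeatFragment]:
    """Parse RepeatMasker ``.out`` text into :class:`RepeatFragment` records.

    Handles the standard dialect: header lines, whitespace-separated
    columns, parenthesised "left" fields, ``C`` for complement strand
    (consensus coordinates are reordered so ``r_start <= r_end``), and an
    optional trailing ``*``.
    """
    fragments: list[RepeatFragment] = []
    seen_data = False
    for line_no, line in _as_lines(stream):
        tokens = line.split()
        if not tokens:
            continue
        try:
            int(tokens[0])
        except ValueError:
            if seen_data:
                raise RmOutParseError(f"unparseable line {line!r}", line_no)
            continue  # header
        seen_data = True
        if len(tokens) == 14:
            raise RmOutParseError(
                "line has 14 columns: the ID (linkage) column appears to be "
                "missing; rerun RepeatMasker without -no_id", line_no,
            )
        if len(tokens) < 15:
            raise RmOutParseError(
                f"expected >= 15 whitespace-separated columns, got {len(tokens)}",
                line_no,
            )
        try:
            strand_token = tokens[8]
            if strand_token == "C":
                strand = "-"
                # complement hits print consensus fields as (left) end begin
                r_left = int(tokens[11].strip("()"))
                r_end = int(tokens[12])
                r_start = int(tokens[13])
            elif strand_token == "+":
                strand = "+"
                r_start = int(tokens[11])
                r_end = int(tokens[12])
                r_left = int(tokens[13].strip("()"))
            else:
                raise ValueError(f"unknown strand token {strand_token!r}")
            fragment = RepeatFragment(
                sw_score=int(tokens[0]),
                pct_div=float(tokens[1]),
                pct_del=float(tokens[2]),
                pct_ins=float(tokens[3]),
                query=tokens[4],
                q_start=int(tokens[5]),
                q_end=int(tokens[6]),
                strand=strand,
                rep_name=tokens[9],
                rep_class=tokens[10],
                r_start=min(r_start, r_end),
                r_end=max(r_start, r_end),
                r_left=r_left,
                link_id=int(tokens[14]),
                overlapped=len(tokens) > 15 and tokens[15] == "*",
            )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, RmOutParseError):
                raise
            raise RmOutParseError(str(exc), line_no) from exc
        fragments.append(fragment)
    return fragments


# ---------------------------------------------------------------------------
# fragment linkage and locus assembly
# ---------------------------------------------------------------------------

def link_fragments(
    fragments: Iterable[RepeatFragment],
) -> list[tuple[RepeatFragment, ...]]:
    """Group fragments of one interrupted element by ``(query, link_id)``.

    Every fragment lands in exactly one group; groups are returned sorted
    by query then leftmost genomic start.
    """
    groups: dict[tuple[str, int], list[RepeatFragment]] = {}
    for frag in fragments:
        groups.setdefault((frag.query, frag.link_id), []).append(frag)
    out = [
        tuple(sorted(g, key=lambda f: (f.q_start, f.q_end)))
        for g in groups.values()
    ]
    out.sort(key=lambda g: (g[0].query, g[0].q_start, g[-1].q_end))
    return out


@dataclass
class _Group:
    """Working view of one ID-linked fragment group during assembly."""

    fragments: tuple[RepeatFragment, ...]

    @property
    def query(self) -> str:
        return self.fragments[0].query

    @property
    def strand(self) -> str:
        return self.fragments[0].strand

    @property
    def rep_class(self) -> str:
        return self.fragments[0].rep_class

    @property
    def start(self) -> int:
        return min(f.q_start for f in self.fragments)

    @property
    def end(self) -> int:
        return max(f.q_end for f in self.fragments)

def _pair_mergeable(prev: _Group, nxt: _Group, running_end: int,
                    policy: MergePolicy) -> bool:
    """Decide whether two consecutive groups belong to one element.

    The internal-model requirement looks at the two fragments facing the
    junction (rightmost of the left group, leftmost of the right group):
    an LTR merges with a neighbouring internal region, but two solo LTRs
    — or two already-complete proviruses, whose facing fragments are both
    terminal repeats — never fuse. That boundary rule is what makes
    merging idempotent.
    """
    if prev.query != nxt.query:
        return False
    if policy.require_same_strand and prev.strand != nxt.strand:
        return False
    if policy.merge_scope == "ltr_only":
        if not (_is_ltr_class(prev.rep_class) and _is_ltr_class(nxt.rep_class)):
            return False
    else:  # all_classes: same top-level class on both sides
        if prev.rep_class.split("/", 1)[0] != nxt.rep_class.split("/", 1)[0]:
            return False
    gap = nxt.start - running_end - 1
    if gap > policy.max_gap:
        return False
    return (policy.is_internal(prev.fragments[-1].rep_name)
            or policy.is_internal(nxt.fragments[0].rep_name))


def _name_chain(fragments: Sequence[RepeatFragment],
                policy: MergePolicy) -> tuple[str, ...]:
    # internal models first, then LTR/terminal models, each de-duplicated
    # in order of first genomic appearance — matches the printed
    # "MuLV-int~RLTR4_Mm" ordering
    internals: list[str] = []
    others: list[str] = []
    for frag in sorted(fragments, key=lambda f: (f.q_start, f.q_end)):
        bucket = internals if policy.is_internal(frag.rep_name) else others
        if frag.rep_name not in bucket:
            bucket.append(frag.rep_name)
    return tuple(internals + others)


def _locus_from_fragments(fragments: Sequence[RepeatFragment],
                          policy: MergePolicy) -> EreLocus:
    frags = tuple(sorted(fragments, key=lambda f: (f.q_start, f.q_end)))
    return EreLocus(
        rep_class=frags[0].rep_class,
        name_chain=_name_chain(frags, policy),
        query=frags[0].query,
        start=min(f.q_start for f in frags),
        end=max(f.q_end for f in frags),
        strand=frags[0].strand,
        fragments=frags,
    )


def assemble_loci(
    groups: Iterable[tuple[RepeatFragment, ...]],
    policy: MergePolicy = DEFAULT_POLICY,
) -> list[EreLocus]:
    """Merge ID-linked fragment groups into locus-level features.

    Consecutive groups (sorted by genomic position) are merged when the
    policy's adjacency rules hold; under the defaults that means both
    groups are LTR-class, on the same strand, within ``max_gap`` bp, and
    at least one of the pair is an internal model — i.e. LTR–internal–LTR
    proviruses collapse to one locus while neighbouring solo LTRs stay
    apart. Output is sorted by (query, start).
    """
    work: list[_Group] = []
    for g in groups:
        frags = tuple(sorted(g, key=lambda f: (f.q_start, f.q_end)))
        if policy.drop_overlapped:
            frags = tuple(f for f in frags if not f.overlapped)
            if not frags:
                continue
        work.append(_Group(frags))
    work.sort(key=lambda g: (g.query, g.start, g.end))

    loci: list[EreLocus] = []
    current: list[_Group] = []
    current_end = 0
    for grp in work:
        if current and _pair_mergeable(current[-1], grp, current_end, policy):
            current.append(grp)
            current_end = max(current_end, grp.end)
        else:
            if current:
                loci.append(_locus_from_fragments(
                    [f for g in current for f in g.fragments], policy))
            current = [grp]
            current_end = grp.end
    if current:
        loci.append(_locus_from_fragments(
            [f for g in current for f in g.fragments], policy))
    loci.sort(key=lambda l: (l.query, l.start, l.end))
    return loci


def merge_rm_out(
    stream: str | TextIO | Iterable[str],
    policy: MergePolicy = DEFAULT_POLICY,
) -> list[EreLocus]:
    """Convenience: parse ``.out`` text and assemble loci in one call."""
    return assemble_loci(link_fragments(parse_rm_out(stream)), policy)


# ---------------------------------------------------------------------------
# locus ID codec
# ---------------------------------------------------------------------------

def format_locus_id(locus: EreLocus) -> str:
    """Render the composite ``class|names|query|start|end`` identifier."""
    return "|".join([
        locus.rep_class,
        _NAME_SEP.join(locus.name_chain),
        locus.query,
        str(locus.start),
        str(locus.end),
    ])


def parse_locus_id(locus_id: str) -> tuple[str, tuple[str, ...], str, int, int]:
    """Invert :func:`format_locus_id`.

    Returns ``(rep_class, name_chain, query, start, end)``; accepts both
    the ASCII ``~`` and the typeset ``∼`` name separator.
    """
    parts = locus_id.split("|")
    if len(parts) != 5:
        raise LocusIdError(
            f"expected 5 '|'-separated fields, got {len(parts)}: {locus_id!r}")
    rep_class, names, query, start_s, end_s = parts
    chain = tuple(re.split("|".join(map(re.escape, _NAME_SEP_ALIASES)), names))
    if not all(chain) or not rep_class or not query:
        raise LocusIdError(f"empty field in locus id {locus_id!r}")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise LocusIdError(f"non-integer coordinates in {locus_id!r}") from exc
    return rep_class, chain, query, start, end


def locus_from_id(locus_id: str, strand: str = "+") -> EreLocus:
    """Build a fragment-less :class:`EreLocus` from its identifier."""
    rep_class, chain, query, start, end = parse_locus_id(locus_id)
    return EreLocus(rep_class=rep_class, name_chain=chain, query=query,
                    start=start, end=end, strand=strand)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_GTF_SOURCE = "erelocus"


def write_gtf(loci: Iterable[EreLocus], stream: TextIO) -> int:
    """Write one ``exon`` feature line per locus (GTF 2.2, 1-based inclusive).

    ``gene_id`` and ``transcript_id`` both carry the composite locus_id so
    that read counters aggregate by locus. Returns the number of lines
    written.
    """
    n = 0
    for locus in loci:
        if locus.start > locus.end:
            raise ValueError(f"refusing to write locus with start > end: {locus}")
        lid = locus.locus_id
        attrs = f'gene_id "{lid}"; transcript_id "{lid}";'
        stream.write("\t".join([
            locus.query, _GTF_SOURCE, "exon", str(locus.start),
            str(locus.end), ".", locus.strand, ".", attrs,
        ]) + "\n")
        n += 1
    return n


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(stream: str | TextIO | Iterable[str]) -> list[EreLocus]:
    """Read locus features back from GTF written by :func:`write_gtf`.

    Fragment-level detail is not stored in GTF, so returned loci carry an
    empty ``fragments`` tuple.
    """
    loci = []
    for line_no, line in _as_lines(stream):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GTF line {line_no}: expected 9 columns")
        attrs = dict(_ATTR_RE.findall(cols[8]))
        if "gene_id" not in attrs:
            raise ValueError(f"GTF line {line_no}: missing gene_id")
        rep_class, chain, query, start, end = parse_locus_id(attrs["gene_id"])
        strand = cols[6] if cols[6] in ("+", "-") else "+"
        loci.append(EreLocus(rep_class=rep_class, name_chain=chain,
                             query=query, start=start, end=end, strand=strand))
    return loci


def locus_class_label(locus: EreLocus) -> str:
    """Map a locus to the coarse feature class used in summaries.

    LTR-class repeats (ERVs, MaLRs, solo LTRs) → ``LTR``; LINEs → ``LINE``;
    everything else → ``other``.
    """
    top = locus.rep_class.split("/", 1)[0].upper()
    if top == "LTR":
        return "LTR"
    if top == "LINE":
        return "LINE"
    return "other"
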