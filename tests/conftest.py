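import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erelocus.repeats import MergePolicy, RepeatFragment
from erelocus.simulate import b_cell_activation_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def activation_fixture(tmp_path_factory):
    """The canned B-cell activation scenario, generated once per session."""
    outdir = tmp_path_factory.mktemp("activation")
    return b_cell_activation_fixture(outdir, seed=7)


# ---------------------------------------------------------------------------
# random fragment tables for merge-oracle tests
# ---------------------------------------------------------------------------

_LTR_MODELS = [("RLTR4_Mm", "MuLV-int", "LTR/ERV1"),
               ("RLTR6_Mm", "ERVB4_2-I", "LTR/ERVK"),
               ("ORR1A0", "ORR1A0-int", "LTR/ERVL-MaLR")]
_OTHER_MODELS = [("L1Md_A", "LINE/L1"), ("B1_Mus1", "SINE/Alu"),
                 ("L1Md_T", "LINE/L1")]


def random_fragment_table(rng: np.random.Generator, max_fragments: int = 200):
    """A random, non-overlapping RepeatMasker-like fragment table.

    Mixes solo LTRs, full proviruses, lone internal segments, interrupted
    elements sharing a linkage ID, LINEs and SINEs, with inter-element
    gaps straddling the default 100 bp merge threshold.
    """

    def frag(query, start, end, strand, name, cls, link_id):
        return RepeatFragment(
            sw_score=int(rng.integers(200, 5000)),
            pct_div=float(rng.uniform(0, 30)), pct_del=float(rng.uniform(0, 8)),
            pct_ins=float(rng.uniform(0, 8)), query=query, q_start=start,
            q_end=end, strand=strand, rep_name=name, rep_class=cls,
            r_start=1, r_end=end - start + 1, r_left=0, link_id=link_id)

    fragments = []
    link_id = 0
    n_target = int(rng.integers(1, max_fragments + 1))
    for query in ("1", "2"):
        pos = int(rng.integers(1, 5000))
        while len(fragments) < n_target:
            strand = "+" if rng.random() < 0.5 else "-"
            kind = rng.random()
            link_id += 1
            if kind < 0.35:  # full or partial provirus: LTR / int / [LTR]
                ltr, internal, cls = _LTR_MODELS[int(rng.integers(3))]
                seg_names = [ltr, internal] + ([ltr] if rng.random() < 0.7 else [])
                for j, name in enumerate(seg_names):
                    if j > 0:
                        pos += int(rng.integers(0, 250))  # may exceed max_gap
                        link_id += 1
                    length = int(rng.integers(200, 800))
                    fragments.append(frag(query, pos, pos + length - 1,
                                          strand, name, cls, link_id))
                    pos += length
            elif kind < 0.55:  # solo LTR or lone internal segment
                ltr, internal, cls = _LTR_MODELS[int(rng.integers(3))]
                name = internal if rng.random() < 0.3 else ltr
                length = int(rng.integers(150, 900))
                fragments.append(frag(query, pos, pos + length - 1, strand,
                                      name, cls, link_id))
                pos += length
            elif kind < 0.75:  # interrupted element: fragments share the ID
                name, cls = _OTHER_MODELS[int(rng.integers(3))]
                for j in range(int(rng.integers(2, 4))):
                    if j > 0:
                        pos += int(rng.integers(50, 400))
                    length = int(rng.integers(200, 1000))
                    fragments.append(frag(query, pos, pos + length - 1,
                                          strand, name, cls, link_id))
                    pos += length
            else:  # simple non-LTR element
                name, cls = _OTHER_MODELS[int(rng.integers(3))]
                length = int(rng.integers(100, 600))
                fragments.append(frag(query, pos, pos + length - 1, strand,
                                      name, cls, link_id))
                pos += length
            pos += int(rng.integers(0, 300))  # inter-element gap
        if len(fragments) >= n_target:
            break
    return fragments[:n_target]


def bruteforce_merge_spans(fragments, policy: MergePolicy):
    """Independent gap-clustering oracle for locus boundaries.

    Groups fragments by (query, linkage ID), then walks the groups in
    genomic order clustering consecutive mergeable pairs, using its own
    plain-dict bookkeeping. Returns sorted (query, start, end, strand)
    tuples of the expected loci.
    """
    groups: dict[tuple, list] = {}
    for f in fragments:
        if policy.drop_overlapped and f.overlapped:
            continue
        groups.setdefault((f.query, f.link_id), []).append(f)
    entries = []
    for frags in groups.values():
        frags = sorted(frags, key=lambda f: (f.q_start, f.q_end))
        entries.append({
            "query": frags[0].query,
            "strand": frags[0].strand,
            "cls": frags[0].rep_class,
            "start": frags[0].q_start,
            "end": max(f.q_end for f in frags),
            "first_name": frags[0].rep_name,
            "last_name": frags[-1].rep_name,
        })
    entries.sort(key=lambda e: (e["query"], e["start"], e["end"]))

    def is_ltr(cls):
        return cls.split("/")[0].upper() == "LTR"

    def pair_ok(left, right, cluster_end):
        if left["query"] != right["query"]:
            return False
        if policy.require_same_strand and left["strand"] != right["strand"]:
            return False
        if policy.merge_scope == "ltr_only":
            if not (is_ltr(left["cls"]) and is_ltr(right["cls"])):
                return False
        elif left["cls"].split("/")[0] != right["cls"].split("/")[0]:
            return False
        if right["start"] - cluster_end - 1 > policy.max_gap:
            return False
        return (policy.is_internal(left["last_name"])
                or policy.is_internal(right["first_name"]))

    clusters = []
    for entry in entries:
        if clusters and pair_ok(clusters[-1]["members"][-1], entry,
                                clusters[-1]["end"]):
            clusters[-1]["members"].append(entry)
            clusters[-1]["end"] = max(clusters[-1]["end"], entry["end"])
        else:
            clusters.append({"members": [entry], "end": entry["end"]})
    spans = []
    for cluster in clusters:
        members = cluster["members"]
        spans.append((members[0]["query"],
                      min(m["start"] for m in members),
                      cluster["end"],
                      members[0]["strand"]))
    return sorted(spans)
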