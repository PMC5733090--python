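"""Interval index, unique read assignment, and SAM counting against truth."""

import numpy as np
import pandas as pd
import pytest

from erelocus.counting import (
    AMBIGUOUS,
    UNASSIGNED,
    AlignedUnit,
    CountMatrix,
    Feature,
    assign_unit,
    build_index,
    count_experiment,
    count_sample,
    iter_units,
)
from erelocus.repeats import MergePolicy, link_fragments, assemble_loci, \
    parse_rm_out, write_gtf
from erelocus.simulate import (FixtureSpec, InterruptedLineSpec, ProvirusSpec,
                               ReadSpec, SoloLtrSpec, gen_rm_out, gen_sam)


def _features(*spans, query="1"):
    return [Feature(f"f{i}", query, s, e) for i, (s, e) in enumerate(spans)]


class TestBuildIndex:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index([Feature("x", "1", 1, 10), Feature("x", "1", 20, 30)])

    def test_disjoint_probe_hits_nothing(self):
        index = build_index(_features((100, 200), (300, 400)))
        assert index.overlapping("1", 210, 290) == set()
        assert index.overlapping("2", 100, 200) == set()

    def test_probe_equal_to_span_hits_it(self):
        index = build_index(_features((100, 200)))
        assert index.overlapping("1", 100, 200) == {"f0"}
        # single-base overlap at either edge counts
        assert index.overlapping("1", 50, 100) == {"f0"}
        assert index.overlapping("1", 200, 250) == {"f0"}
        assert index.overlapping("1", 201, 250) == set()

    def test_random_probes_match_allpairs_scan(self):
        rng = np.random.default_rng(3)
        feats = []
        for i in range(100):
            start = int(rng.integers(1, 10_000))
            feats.append(Feature(f"f{i}", str(rng.integers(1, 3)), start,
                                 start + int(rng.integers(1, 500))))
        index = build_index(feats)
        for _ in range(1000):
            ref = str(rng.integers(1, 3))
            start = int(rng.integers(1, 10_500))
            end = start + int(rng.integers(0, 300))
            expected = {f.feature_id for f in feats
                        if f.query == ref and f.start <= end and f.end >= start}
            assert index.overlapping(ref, start, end) == expected


class TestAssignUnit:
    index = build_index(_features((1000, 2000), (2100, 3000)))

    def test_read_inside_one_locus(self):
        unit = AlignedUnit("r1", "1", ((1200, 1274),))
        assert assign_unit(unit, self.index) == "f0"

    def test_read_overlapping_no_feature(self):
        unit = AlignedUnit("r2", "1", ((5000, 5074),))
        assert assign_unit(unit, self.index) is UNASSIGNED

    def test_read_spanning_two_features_is_ambiguous(self):
        unit = AlignedUnit("r3", "1", ((1990, 2110),))
        assert assign_unit(unit, self.index) is AMBIGUOUS

    def test_spliced_blocks_skipping_a_feature(self):
        # two blocks both inside f0: the skipped gap does not hit f1
        unit = AlignedUnit("r4", "1", ((1000, 1030), (1500, 1530)))
        assert assign_unit(unit, self.index) == "f0"

    def test_junction_read_on_merged_provirus_counts_once(self):
        # the merged locus is one feature: a read across the former
        # LTR/internal divide is uniquely assigned, not split or ambiguous
        provirus = ProvirusSpec(query="1", start=10_000)
        spec = FixtureSpec(contig_lengths={"1": 100_000}, proviruses=(provirus,))
        text, _ = gen_rm_out(spec, seed=0)
        loci = assemble_loci(link_fragments(parse_rm_out(text)))
        index = build_index(loci)
        boundary = provirus.junctions[0]
        unit = AlignedUnit("r5", "1", ((boundary - 30, boundary + 45),))
        assert assign_unit(unit, index) == provirus.locus_id

    def test_non_primary_unit_is_a_contract_violation(self):
        unit = AlignedUnit("r6", "1", ((1000, 1074),), is_primary=False)
        with pytest.raises(ValueError, match="primary"):
            assign_unit(unit, self.index)


@pytest.fixture(scope="module")
def small_fixture(tmp_path_factory):
    """One provirus, two solo LTRs (one close pair), one LINE, plus reads."""
    outdir = tmp_path_factory.mktemp("counting")
    spec = FixtureSpec(
        contig_lengths={"1": 200_000},
        proviruses=(ProvirusSpec(query="1", start=10_000),),
        solo_ltrs=(SoloLtrSpec(query="1", start=30_000),
                   SoloLtrSpec(query="1", start=30_790, name="RLTR6_Mm"),
                   SoloLtrSpec(query="1", start=50_000, name="ORR1A0",
                               rep_class="LTR/ERVL-MaLR")),
        lines=(InterruptedLineSpec(query="1", start=80_000),),
    )
    rm_text, truth = gen_rm_out(spec, seed=11)
    features = truth.rename(columns={"locus_id": "feature_id"})
    counts = {fid: 200 for fid in features["feature_id"]}
    read_spec = ReadSpec(counts=counts, read_length=75, junction_fraction=0.2,
                         ambiguous_fraction=0.1, unassigned_fraction=0.1,
                         multimapper_fraction=0.1)
    sam, placement = gen_sam(features, spec.contig_lengths, read_spec, seed=12)
    sam_path = outdir / "sample.sam"
    sam_path.write_text(sam)
    loci = assemble_loci(link_fragments(parse_rm_out(rm_text)))
    return {"spec": spec, "rm_text": rm_text, "truth": truth,
            "features": features, "sam_path": sam_path,
            "placement": placement, "loci": loci, "outdir": outdir}


class TestCountSample:
    def test_counts_equal_generator_placement_table(self, small_fixture):
        index = build_index(small_fixture["loci"])
        counts, totals = count_sample(small_fixture["sam_path"], index)
        placement = small_fixture["placement"]
        expected = placement[placement["category"] == "assigned"] \
            .groupby("feature_id").size()
        for fid in counts.index:
            assert counts[fid] == expected.get(fid, 0)
        assert totals["assigned"] == int(expected.sum())
        assert totals["ambiguous"] == (placement["category"] == "ambiguous").sum()
        assert totals["unassigned"] == (placement["category"] == "unassigned").sum()

    def test_conservation_of_countable_units(self, small_fixture):
        index = build_index(small_fixture["loci"])
        _, totals = count_sample(small_fixture["sam_path"], index)
        n_units = sum(1 for _ in iter_units(small_fixture["sam_path"]))
        assert sum(totals.values()) == n_units
        # secondary (multimapper) records were emitted but never counted
        assert n_units == len(small_fixture["placement"])

    def test_counting_is_deterministic(self, small_fixture):
        index = build_index(small_fixture["loci"])
        first, t1 = count_sample(small_fixture["sam_path"], index)
        second, t2 = count_sample(small_fixture["sam_path"], index)
        assert first.equals(second) and t1 == t2

    def test_counts_match_bruteforce_per_read_scan(self, small_fixture):
        index = build_index(small_fixture["loci"])
        counts, _ = count_sample(small_fixture["sam_path"], index)
        feats = [Feature(l.locus_id, l.query, l.start, l.end)
                 for l in small_fixture["loci"]]
        brute = dict.fromkeys(counts.index, 0)
        for unit in iter_units(small_fixture["sam_path"]):
            hits = {f.feature_id for f in feats
                    if f.query == unit.reference and any(
                        b[0] <= f.end and b[1] >= f.start for b in unit.blocks)}
            if len(hits) == 1:
                brute[hits.pop()] += 1
        assert counts.to_dict() == brute

    def test_empty_alignment_stream_gives_zero_column(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:1\tLN:1000\n")
        index = build_index(_features((100, 200)))
        counts, totals = count_sample(path, index)
        assert (counts == 0).all()
        assert totals == {"assigned": 0, "ambiguous": 0, "unassigned": 0}

    def test_unknown_reference_counts_unassigned(self, tmp_path):
        path = tmp_path / "other.sam"
        path.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:9\tLN:1000\n"
                        "r1\t0\t9\t100\t60\t50M\t*\t0\t0\t" + "A" * 50
                        + "\t" + "I" * 50 + "\n")
        index = build_index(_features((100, 200)))
        _, totals = count_sample(path, index)
        assert totals == {"assigned": 0, "ambiguous": 0, "unassigned": 1}


@pytest.fixture(scope="module")
def paired_sam(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("paired")
    spec = FixtureSpec(
        contig_lengths={"1": 100_000},
        solo_ltrs=(SoloLtrSpec(query="1", start=10_000, length=2000),
                   SoloLtrSpec(query="1", start=50_000, length=2000)),
    )
    rm_text, truth = gen_rm_out(spec, seed=2)
    features = truth.rename(columns={"locus_id": "feature_id"})
    counts = {fid: 50 for fid in features["feature_id"]}
    read_spec = ReadSpec(counts=counts, read_length=75, paired=True,
                         insert_size=180)
    sam, placement = gen_sam(features, spec.contig_lengths, read_spec, seed=3)
    path = outdir / "paired.sam"
    path.write_text(sam)
    loci = assemble_loci(link_fragments(parse_rm_out(rm_text)))
    return path, build_index(loci), placement


class TestPairedCounting:
    def test_fragment_mode_counts_templates_once(self, paired_sam):
        path, index, placement = paired_sam
        counts, totals = count_sample(path, index, pairing="fragment")
        assert totals["assigned"] == len(placement)
        assert counts.sum() == 100

    def test_read_mode_counts_each_mate(self, paired_sam):
        path, index, _ = paired_sam
        counts, _ = count_sample(path, index, pairing="read")
        assert counts.sum() == 200


class TestMergedVsUnmergedCounts:
    def test_junction_reads_are_lost_without_merging(self, small_fixture):
        """With junction-spanning reads present, the merged provirus locus
        collects strictly more reads than the sum of its pre-merge LTR and
        internal features (junction reads are ambiguous pre-merge)."""
        rm_text = small_fixture["rm_text"]
        fragments = parse_rm_out(rm_text)
        merged = assemble_loci(link_fragments(fragments))
        # disabling the internal-suffix heuristic leaves each ID-linked
        # group as its own feature: the unmerged annotation
        unmerged = assemble_loci(link_fragments(fragments),
                                 MergePolicy(internal_suffixes=()))
        assert len(unmerged) > len(merged)
        provirus_id = ProvirusSpec(query="1", start=10_000).locus_id
        m_counts, _ = count_sample(small_fixture["sam_path"],
                                   build_index(merged))
        u_counts, _ = count_sample(small_fixture["sam_path"],
                                   build_index(unmerged))
        provirus = next(l for l in merged if l.locus_id == provirus_id)
        parts = [l.locus_id for l in unmerged
                 if l.start >= provirus.start and l.end <= provirus.end]
        assert len(parts) == 3
        assert m_counts[provirus_id] > sum(u_counts[p] for p in parts)


class TestCountExperiment:
    def test_three_samples_three_columns(self, small_fixture, tmp_path):
        features = small_fixture["features"]
        spec = small_fixture["spec"]
        paths = []
        for i, name in enumerate(["s1", "s2", "s3"]):
            counts = {fid: 30 for fid in features["feature_id"]}
            sam, _ = gen_sam(features, spec.contig_lengths,
                             ReadSpec(counts=counts), seed=20 + i, sample=name)
            path = tmp_path / f"{name}.sam"
            path.write_text(sam)
            paths.append(path)
        repeat_gtf = tmp_path / "loci.gtf"
        with repeat_gtf.open("w") as fh:
            write_gtf(small_fixture["loci"], fh)
        gene_gtf = tmp_path / "genes.gtf"
        gene_gtf.write_text(
            '1\tsrc\texon\t150000\t160000\t.\t+\t.\tgene_id "GeneA";\n')
        gene_cm, repeat_cm = count_experiment(paths, gene_gtf, repeat_gtf)
        assert repeat_cm.samples == ["s1", "s2", "s3"]
        assert gene_cm.samples == ["s1", "s2", "s3"]
        assert set(repeat_cm.classes.unique()) <= {"LTR", "LINE", "other"}
        assert (gene_cm.classes == "gene").all()
        # disjoint gene/repeat coordinates: nothing counted in both passes
        assert gene_cm.counts.to_numpy().sum() == 0
        assert (repeat_cm.counts.sum() > 0).all()
        # per-sample conservation in both passes
        for cm in (gene_cm, repeat_cm):
            per_sample_units = cm.totals.sum(axis=0)
            assert (per_sample_units == per_sample_units.iloc[0]).all()

    def test_planted_depth_ratios_recovered(self, small_fixture, tmp_path):
        features = small_fixture["features"]
        spec = small_fixture["spec"]
        fid = features["feature_id"].iloc[0]
        paths = []
        for i, depth in enumerate([100, 200, 400]):
            sam, _ = gen_sam(features, spec.contig_lengths,
                             ReadSpec(counts={fid: depth}), seed=30 + i,
                             sample=f"d{i}")
            path = tmp_path / f"d{i}.sam"
            path.write_text(sam)
            paths.append(path)
        repeat_gtf = tmp_path / "loci.gtf"
        with repeat_gtf.open("w") as fh:
            write_gtf(small_fixture["loci"], fh)
        _, repeat_cm = count_experiment(paths, None, repeat_gtf)
        sums = repeat_cm.counts.sum()
        assert list(sums) == [100, 200, 400]

    def test_missing_sample_file_is_named(self, small_fixture, tmp_path):
        repeat_gtf = tmp_path / "loci.gtf"
        with repeat_gtf.open("w") as fh:
            write_gtf(small_fixture["loci"], fh)
        with pytest.raises(FileNotFoundError, match="nope.sam"):
            count_experiment([tmp_path / "nope.sam"], None, repeat_gtf)


class TestCountMatrixTsv:
    def test_tsv_roundtrip(self, tmp_path):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [1, 2], "s2": [3, 0]},
                                index=["fA", "fB"]),
            classes=pd.Series({"fA": "LTR", "fB": "gene"}))
        path = tmp_path / "counts.tsv"
        cm.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        assert back.counts.equals(cm.counts)
        assert back.classes.equals(cm.classes)
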