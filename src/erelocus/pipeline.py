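"""End-to-end orchestration: annotation merging → counting → statistics.

One :func:`run_pipeline` call chains the individual stages on disk,
writing every intermediate so a run can be audited or resumed by hand:

    loci.gtf        merged repeat loci
    counts.tsv      gene + repeat raw counts (one table, class column)
    de.tsv          differential table between the two sample groups
    zscores.tsv     per-feature standardized expression (heat-map input)
    enrichment.tsv  repeat-group over-representation among induced LTR loci
    run.json        parameters, stage tallies and per-class summary
    run.log         line-oriented progress log

Defaults mirror the thresholds used throughout the differential
summaries: >= 2-fold change at p < 0.05.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .counting import CountMatrix, count_experiment
from .enrichment import enrichment
from .repeats import (MergePolicy, assemble_loci, link_fragments,
                      parse_rm_out, write_gtf)
from .stats import (differential, drop_unexpressed, normalize, size_factors,
                    summarize_by_class, zscores)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    rm_out: str
    alignments: Sequence[str]
    group_a: Sequence[str]
    group_b: Sequence[str]
    output_dir: str
    gene_gtf: str | None = None
    max_gap: int = 100
    merge_scope: str = "ltr_only"
    drop_overlapped: bool = False
    pairing: str = "fragment"
    min_mapq: int = 0
    fold_threshold: float = 2.0
    alpha: float = 0.05
    enrichment_level: str = "family"
    correction: str = "bh"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("fold_threshold must be > 0 and 0 < alpha < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merge_policy(self) -> MergePolicy:
        return MergePolicy(max_gap=self.max_gap, merge_scope=self.merge_scope,
                           drop_overlapped=self.drop_overlapped)


def _check_inputs(config: RunConfig) -> None:
    paths = [config.rm_out, *config.alignments]
    if config.gene_gtf is not None:
        paths.append(config.gene_gtf)
    for path in paths:
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the run summary that is also written as JSON.

    Outputs are deterministic for identical inputs and configuration.
    """
    _check_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("erelocus")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "parameters": asdict(config),
                     "stages": {}}
    try:
        # stage 1: merge the repeat annotation
        policy = config.merge_policy()
        with open(config.rm_out) as fh:
            fragments = parse_rm_out(fh)
        groups = link_fragments(fragments)
        loci = assemble_loci(groups, policy)
        loci_gtf = outdir / "loci.gtf"
        with loci_gtf.open("w") as fh:
            write_gtf(loci, fh)
        stage = {"fragments": len(fragments), "groups": len(groups),
                 "loci": len(loci), "merges": len(groups) - len(loci)}
        summary["stages"]["annotation"] = stage
        logger.info("annotation: %(fragments)d fragments -> %(groups)d "
                    "ID-linked groups -> %(loci)d loci", stage)

        # stage 2: count genes and repeats in separate passes
        gene_cm, repeat_cm = count_experiment(
            list(config.alignments), config.gene_gtf, loci_gtf,
            pairing=config.pairing, min_mapq=config.min_mapq)
        frames = [repeat_cm.counts] if gene_cm is None else [
            gene_cm.counts, repeat_cm.counts]
        classes = pd.concat([repeat_cm.classes] if gene_cm is None else
                            [gene_cm.classes, repeat_cm.classes])
        counts = pd.concat(frames)
        combined = CountMatrix(counts=counts, classes=classes)
        combined.to_tsv(outdir / "counts.tsv")
        summary["stages"]["counting"] = {
            "samples": combined.samples,
            "features": int(counts.shape[0]),
            "repeat_totals": repeat_cm.totals.to_dict(),
        }

        # stage 3: filter, normalize, differential calls, z-scores
        expressed = drop_unexpressed(combined.counts)
        factors = size_factors(expressed)
        norm = normalize(expressed, factors)
        table = differential(norm, config.group_a, config.group_b,
                             fold_threshold=config.fold_threshold,
                             alpha=config.alpha, classes=combined.classes)
        table.to_csv(outdir / "de.tsv", sep="\t", index_label="feature_id")
        zscores(norm).to_csv(outdir / "zscores.tsv", sep="\t",
                             index_label="feature_id")
        by_class = summarize_by_class(table)
        summary["stages"]["expression"] = {
            "expressed_features": int(expressed.shape[0]),
            "size_factors": factors.round(6).to_dict(),
            "significant_by_class": by_class.astype(object).where(
                by_class.notna(), None).to_dict(orient="records"),
        }

        # stage 4: LTR-group enrichment among induced loci, against all
        # expressed LTR loci as background
        ltr = table[table["class"] == "LTR"]
        background = list(ltr.index)
        subset = list(ltr.index[ltr["significant"]
                                & (ltr["direction"] == "up")])
        if background:
            enr = enrichment(subset, background,
                             level=config.enrichment_level,
                             alpha=config.alpha,
                             correction=config.correction)
        else:
            enr = pd.DataFrame(columns=["group", "a", "b", "c", "d", "chi2",
                                        "p", "p_adj", "enriched"])
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrichment"] = {
            "subset_size": len(subset), "background_size": len(background),
            "enriched_groups": list(enr.loc[enr["enriched"], "group"])
            if not enr.empty else [],
        }
        summary["status"] = "ok"
    except Exception:
        summary["status"] = "failed"
        logger.exception("pipeline stage failed; partial outputs in %s", outdir)
        raise
    finally:
        with (outdir / "run.json").open("w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        root.removeHandler(handler)
        handler.close()
    logger.info("pipeline complete: %s", outdir)
    return summary
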