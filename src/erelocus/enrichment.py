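"""Repeat-group composition and over-representation testing.

Given a subset of loci singled out by some contrast (e.g. the LTR
elements induced by type I interferon) and the background of all
expressed loci, each repeat group is tested for over-representation with
a 2x2 chi-square test on

    (in group / out of group) x (subset / background minus subset)

with Benjamini-Hochberg correction across groups. A group is flagged
enriched when its corrected p falls below alpha AND its subset frequency
exceeds its background frequency (over-representation only).

Groups are formed at two levels: ``family`` takes the token after '/' in
the class string ("LTR/ERV1" -> "ERV1"); ``subgroup`` uses the LTR model
name from the locus name chain (e.g. "MER41D").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .repeats import DEFAULT_POLICY, EreLocus, locus_from_id

__all__ = [
    "GroupComposition",
    "compose",
    "chi2_2x2",
    "enrichment",
]


@dataclass
class GroupComposition:
    """Group label -> locus count at one grouping level."""

    counts: dict[str, int]
    level: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _as_locus(item: EreLocus | str) -> EreLocus:
    return item if isinstance(item, EreLocus) else locus_from_id(item)


def group_label(locus: EreLocus | str, level: str) -> str:
    """The repeat-group label of one locus at the requested level."""
    locus = _as_locus(locus)
    if level == "family":
        parts = locus.rep_class.split("/", 1)
        return parts[1] if len(parts) == 2 and parts[1] else "unclassified"
    if level == "subgroup":
        # the terminal-repeat model names the subgroup; internal models
        # (MuLV-int and friends) are fallbacks for internal-only loci
        for name in locus.name_chain:
            if not DEFAULT_POLICY.is_internal(name):
                return name
        return locus.name_chain[0]
    raise ValueError(f"level must be 'family' or 'subgroup', got {level!r}")


def compose(loci: Iterable[EreLocus | str], level: str = "family",
            ) -> GroupComposition:
    """Tally loci into repeat groups (accepts loci or locus-id strings)."""
    counts: dict[str, int] = {}
    for item in loci:
        label = group_label(item, level)
        counts[label] = counts.get(label, 0) + 1
    return GroupComposition(counts=counts, level=level)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

        chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))

    A zero margin leaves the statistic undefined: returns (nan, 1.0) with
    a warning.
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        warnings.warn("2x2 table has a zero margin; chi-square undefined, "
                      "reporting p = 1", stacklevel=2)
        return float("nan"), 1.0
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(sps.chi2.sf(stat, df=1))


def enrichment(
    subset: Iterable[EreLocus | str],
    background: Iterable[EreLocus | str],
    level: str = "family",
    alpha: float = 0.05,
    correction: str = "bh",
    fisher_fallback: bool = False,
) -> pd.DataFrame:
    """Test every repeat group in the background for over-representation.

    ``subset`` must be contained in ``background`` (checked by locus id).
    ``correction`` is ``"bh"`` (Benjamini-Hochberg, default) or
    ``"bonferroni"``. With ``fisher_fallback`` a group whose 2x2 table has
    an expected cell below 5 is tested with Fisher's exact test instead
    (a warning is logged either way).

    Returns one row per background group: a, b, c, d, chi2, p, p_adj,
    enriched.
    """
    subset = [_as_locus(x) for x in subset]
    background = [_as_locus(x) for x in background]
    subset_ids = {l.locus_id for l in subset}
    background_ids = {l.locus_id for l in background}
    if not subset_ids <= background_ids:
        missing = sorted(subset_ids - background_ids)[:3]
        raise ValueError(f"subset loci absent from background, e.g. {missing}")

    sub_comp = compose(subset, level)
    bg_comp = compose(background, level)
    n_sub, n_bg = sub_comp.total, bg_comp.total

    rows = []
    for group in sorted(bg_comp.counts):
        a = sub_comp.counts.get(group, 0)          # in group, in subset
        b = n_sub - a                              # out of group, in subset
        c = bg_comp.counts[group] - a              # in group, rest of background
        d = (n_bg - bg_comp.counts[group]) - b     # out of group, rest
        expected_min = _min_expected(a, b, c, d)
        if expected_min < 5:
            warnings.warn(
                f"group {group!r}: smallest expected cell {expected_min:.2f} "
                "< 5; chi-square approximation is poor"
                + (" — using Fisher's exact test" if fisher_fallback else ""),
                stacklevel=2)
        if fisher_fallback and expected_min < 5:
            stat = float("nan")
            _, p = sps.fisher_exact([[a, b], [c, d]])
        else:
            stat, p = chi2_2x2(a, b, c, d)
        rows.append({"group": group, "a": a, "b": b, "c": c, "d": d,
                     "chi2": stat, "p": p})
    table = pd.DataFrame(rows, columns=["group", "a", "b", "c", "d",
                                        "chi2", "p"])
    if table.empty:
        table["p_adj"] = pd.Series(dtype=float)
        table["enriched"] = pd.Series(dtype=bool)
        return table

    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ValueError(f"correction must be 'bh' or 'bonferroni', "
                         f"got {correction!r}")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method=method)[1]
    sub_freq = table["a"] / n_sub if n_sub else 0.0
    bg_freq = (table["a"] + table["c"]) / n_bg
    table["enriched"] = (table["p_adj"] < alpha) & (sub_freq > bg_freq)
    return table


def _min_expected(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    if n == 0:
        return 0.0
    rows = np.array([a + b, c + d], dtype=float)
    cols = np.array([a + c, b + d], dtype=float)
    return float(np.outer(rows, cols).min() / n)
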