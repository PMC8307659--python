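"""Overlay DMRs and significant CpGs on genomic feature layouts.

Supports the two counting units of the analysis — whole DMRs (promoter /
enhancer / CpG-island splits) and individually significant CpGs (ChromHMM
states, TF binding-site clusters) — through one interval-overlap code path.
Proportions of hyper-methylated events, #hyper / (#hyper + #hypo), come with
Wilson score confidence intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .diff import STATE_HYPER, STATE_HYPO
from .dmr import DMR
from .io import FeatureSet, ValidationError

DEFAULT_PRIORITY = ("promoter", "5UTR", "exon", "intron", "3UTR")


@dataclasses.dataclass
class FeatureProfile:
    """Hyper/hypo event counts within one feature class.

    ``prop_hyper`` = n_hyper / (n_hyper + n_hypo), NaN when no events;
    ``ci_low``/``ci_high`` are Wilson score bounds; ``p`` is the state-level
    significance (ChromHMM mode only, NaN elsewhere).
    """

    class_name: str
    n_hyper: int
    n_hypo: int
    prop_hyper: float
    ci_low: float
    ci_high: float
    p: float = float("nan")


def _as_interval_frame(items) -> pd.DataFrame:
    """Coerce DMRs / a DataFrame / (chrom, start, end) tuples to an interval frame.

    Positions (chrom, pos) become length-1 intervals [pos, pos + 1).
    """
    if isinstance(items, pd.DataFrame):
        df = items
        if "start" in df.columns and "end" in df.columns:
            return df[["chrom", "start", "end"]].reset_index(drop=True)
        if "pos" in df.columns:
            out = df[["chrom", "pos"]].rename(columns={"pos": "start"}).reset_index(drop=True)
            out["end"] = out["start"] + 1
            return out
        raise ValueError("DataFrame needs (chrom, start, end) or (chrom, pos) columns")
    rows = []
    for it in items:
        if isinstance(it, DMR):
            rows.append((it.chrom, it.start, it.end))
        elif len(it) == 3:
            rows.append((it[0], int(it[1]), int(it[2])))
        else:
            rows.append((it[0], int(it[1]), int(it[1]) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_interval_index(features: FeatureSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in features.intervals.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end, label in zip(grp["start"], grp["end"], grp["label"]):
            tree.addi(int(start), int(end), label if label is not None else features.class_name)
        trees[chrom] = tree
    return trees


def annotate_overlap(items, features: FeatureSet) -> list[list[str]]:
    """Per-item labels of features overlapping it by >= 1 bp (half-open).

    ``items`` may be DMRs, (chrom, start, end) tuples, (chrom, pos) pairs or
    a DataFrame. Returns one (possibly empty) label list per item; unlabeled
    features report their class_name.
    """
    frame = _as_interval_frame(items)
    trees = build_interval_index(features)
    out: list[list[str]] = []
    for chrom, start, end in frame.itertuples(index=False):
        tree = trees.get(chrom)
        if tree is None:
            out.append([])
        else:
            hits = tree.overlap(int(start), int(end))
            out.append(sorted((h.data for h in hits), key=str))
    return out


def overlaps_any(items, features: FeatureSet) -> np.ndarray:
    """Boolean per item: does it overlap at least one feature interval?"""
    return np.array([len(labels) > 0 for labels in annotate_overlap(items, features)])


def hyper_fraction(n_hyper: int, n_hypo: int, ci_level: float = 0.95, class_name: str = "") -> FeatureProfile:
    """Proportion of hyper-methylated events with a Wilson score CI.

    With no events the proportion and CI are NaN (missing, not zero).
    """
    if n_hyper < 0 or n_hypo < 0:
        raise ValidationError("counts must be non-negative")
    n = n_hyper + n_hypo
    if n == 0:
        return FeatureProfile(class_name, 0, 0, float("nan"), float("nan"), float("nan"))
    prop = n_hyper / n
    lo, hi = proportion_confint(n_hyper, n, alpha=1 - ci_level, method="wilson")
    return FeatureProfile(class_name, int(n_hyper), int(n_hypo), prop, float(lo), float(hi))


def dmr_direction_split(dmrs: Sequence[DMR], features: FeatureSet, ci_level: float = 0.95) -> FeatureProfile:
    """Hyper/hypo split of the DMRs that overlap a feature class."""
    if len(dmrs) == 0:
        return hyper_fraction(0, 0, ci_level, features.class_name)
    hit = overlaps_any(list(dmrs), features)
    n_hyper = int(sum(1 for d, h in zip(dmrs, hit) if h and d.direction == STATE_HYPER))
    n_hypo = int(sum(1 for d, h in zip(dmrs, hit) if h and d.direction == STATE_HYPO))
    return hyper_fraction(n_hyper, n_hypo, ci_level, features.class_name)


def _significant_sites(diffsites: pd.DataFrame) -> pd.DataFrame:
    return diffsites[diffsites["state"].isin([STATE_HYPER, STATE_HYPO])]


def _label_sites(diffsites: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    """Explode tested CpGs over the labels of the features covering them."""
    tested = diffsites[diffsites["state"] != "filtered"].reset_index(drop=True)
    labels = annotate_overlap(tested, features)
    rows = [(i, lab) for i, labs in enumerate(labels) for lab in labs]
    if not rows:
        return tested.iloc[0:0].assign(label=pd.Series(dtype=object))
    idx, labs = zip(*rows)
    out = tested.iloc[list(idx)].copy()
    out["label"] = labs
    return out


def state_methylation_profile(
    diffsites: pd.DataFrame,
    chromhmm: FeatureSet,
    ci_level: float = 0.95,
    min_chroms: int = 5,
) -> pd.DataFrame:
    """Per-chromatin-state hyper/hypo profile of significantly altered CpGs.

    For each segmentation label: counts of hyper and hypo CpGs, their ratios
    to all tested CpGs in the state, prop_hyper with Wilson CI, and a paired
    two-sided t-test across chromosomes of the per-chromosome hyper fraction
    versus hypo fraction (NaN unless >= ``min_chroms`` chromosomes carry
    tested CpGs of the state). CpGs outside the segmentation are ignored.
    """
    labelled = _label_sites(diffsites, chromhmm)
    rows = []
    for label, grp in labelled.groupby("label", sort=True):
        n_all = len(grp)
        n_hyper = int((grp["state"] == STATE_HYPER).sum())
        n_hypo = int((grp["state"] == STATE_HYPO).sum())
        prof = hyper_fraction(n_hyper, n_hypo, ci_level, str(label))
        per_chrom = grp.groupby("chrom").agg(
            hyper=("state", lambda s: (s == STATE_HYPER).mean()),
            hypo=("state", lambda s: (s == STATE_HYPO).mean()),
            n=("state", "size"),
        )
        informative = per_chrom[per_chrom["n"] > 0]
        p = float("nan")
        if len(informative) >= min_chroms:
            d = informative["hyper"] - informative["hypo"]
            if not np.allclose(d.std(ddof=1), 0.0):
                p = float(stats.ttest_rel(informative["hyper"], informative["hypo"])[1])
        rows.append(
            {
                "class_name": str(label),
                "n_cpg_tested": n_all,
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "ratio_hyper_all": n_hyper / n_all if n_all else float("nan"),
                "ratio_hypo_all": n_hypo / n_all if n_all else float("nan"),
                "prop_hyper": prof.prop_hyper,
                "ci_low": prof.ci_low,
                "ci_high": prof.ci_high,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def tf_site_profile(diffsites: pd.DataFrame, tfbs: FeatureSet, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-TF hyper/hypo proportion among significantly altered CpGs.

    A CpG inside the clustered binding sites of several TFs counts once per
    TF. TFs whose intervals contain no significant CpG report NaN
    proportions. Rows are ranked by prop_hyper (descending, NaN last).
    """
    sig = _significant_sites(diffsites).reset_index(drop=True)
    labels = annotate_overlap(sig, tfbs)
    all_tfs = sorted(set(str(x) for x in tfbs.intervals["label"].dropna().unique())) or [tfbs.class_name]
    counts: dict[str, list[int]] = {tf: [0, 0] for tf in all_tfs}
    states = sig["state"].to_numpy()
    for labs, state in zip(labels, states):
        for lab in labs:
            c = counts.setdefault(str(lab), [0, 0])
            c[0 if state == STATE_HYPER else 1] += 1
    rows = []
    for tf, (nh, nl) in counts.items():
        prof = hyper_fraction(nh, nl, ci_level, tf)
        rows.append(
            {
                "class_name": tf,
                "n_hyper": nh,
                "n_hypo": nl,
                "prop_hyper": prof.prop_hyper,
                "ci_low": prof.ci_low,
                "ci_high": prof.ci_high,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("prop_hyper", ascending=False, na_position="last", kind="mergesort").reset_index(drop=True)


def partition_by_activity(features: FeatureSet, peaks: FeatureSet) -> tuple[FeatureSet, FeatureSet]:
    """Split features into (active, inactive) by overlap with >= 1 peak.

    Typical use: enhancers vs H3K27ac peak calls. The two outputs partition
    the input.
    """
    if len(features) == 0:
        empty = features.intervals.iloc[0:0]
        return FeatureSet(f"{features.class_name}_active", empty), FeatureSet(
            f"{features.class_name}_inactive", empty.copy()
        )
    hit = overlaps_any(features.intervals, peaks)
    active = features.intervals[hit].reset_index(drop=True)
    inactive = features.intervals[~hit].reset_index(drop=True)
    return (
        FeatureSet(f"{features.class_name}_active", active),
        FeatureSet(f"{features.class_name}_inactive", inactive),
    )


def assign_priority(
    items,
    feature_sets: Iterable[FeatureSet],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    fallback: str = "intergenic",
) -> list[str]:
    """Single-class assignment: the first class in ``priority`` that overlaps wins."""
    by_name = {fs.class_name: fs for fs in feature_sets}
    frame = _as_interval_frame(items)
    assigned = [fallback] * len(frame)
    undecided = np.ones(len(frame), dtype=bool)
    for name in priority:
        if name not in by_name or not undecided.any():
            continue
        hit = overlaps_any(frame, by_name[name])
        for i in np.flatnonzero(hit & undecided):
            assigned[i] = name
        undecided &= ~hit
    return assigned


def promoters_from_tss(tss: Sequence[tuple[str, int]], window: int = 1000) -> FeatureSet:
    """Default promoter intervals, TSS +/- window bp, when no promoter BED is supplied."""
    rows = [(chrom, max(0, int(pos) - window), int(pos) + window, None) for chrom, pos in tss]
    return FeatureSet("promoter", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def profiles_to_tsv(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False, float_format="%.6f")
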