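"""Score called DMRs against simulator ground truth.

A truth region is recovered when a called DMR of the same direction overlaps
it by >= 1 bp; a called DMR is a true positive when it overlaps a truth
region of its direction. Sensitivity and precision follow from those counts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from intervaltree import IntervalTree

from .dmr import DMR
from .simulate import TruthSet


@dataclasses.dataclass
class RecoveryScore:
    n_truth: int
    n_called: int
    n_recovered: int
    n_true_positive: int
    recovered_by_direction: dict[str, int]

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_true_positive / self.n_called if self.n_called else float("nan")


def score_recovery(dmrs: Sequence[DMR], truth: TruthSet) -> RecoveryScore:
    called: dict[tuple[str, str], IntervalTree] = {}
    for d in dmrs:
        called.setdefault((d.chrom, d.direction), IntervalTree()).addi(d.start, d.end)
    truthtree: dict[tuple[str, str], IntervalTree] = {}
    for r in truth.regions.itertuples(index=False):
        truthtree.setdefault((r.chrom, r.direction), IntervalTree()).addi(r.start, r.end)
    recovered = 0
    by_dir = {"hyper": 0, "hypo": 0}
    for r in truth.regions.itertuples(index=False):
        tree = called.get((r.chrom, r.direction))
        if tree is not None and tree.overlap(r.start, r.end):
            recovered += 1
            by_dir[r.direction] += 1
    tp = 0
    for d in dmrs:
        tree = truthtree.get((d.chrom, d.direction))
        if tree is not None and tree.overlap(d.start, d.end):
            tp += 1
    return RecoveryScore(
        n_truth=int(len(truth.regions)),
        n_called=len(dmrs),
        n_recovered=recovered,
        n_true_positive=tp,
        recovered_by_direction=by_dir,
    )
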