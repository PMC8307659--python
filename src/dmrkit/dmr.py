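"""Merge runs of consecutive, same-direction significant CpGs into DMRs.

A DMR is a maximal run of CpGs all in the same significant state (hyper or
hypo) that is not interrupted by any *tested* CpG of another state. Untested
(coverage-filtered) CpGs are transparent: they neither join nor break a run.
Two extra, configurable guards shape the literal run rule:

* ``min_cpg`` — minimum member count ("consecutive CpGs", plural, implies at
  least two);
* ``max_gap`` — maximum genomic distance in bp between successive member
  CpGs, preventing a run from spanning a coverage desert
  (``max_gap=None`` disables the cap).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diff import STATE_FILTERED, STATE_HYPER, STATE_HYPO

DEFAULT_MIN_CPG = 2
DEFAULT_MAX_GAP = 1000


@dataclasses.dataclass(frozen=True)
class DMR:
    """A differentially methylated region spanning its member CpGs.

    ``start``/``end`` are 0-based half-open from the first member CpG to one
    past the last; ``mean_delta`` is the mean member delta and ``min_q`` the
    smallest member q.
    """

    chrom: str
    start: int
    end: int
    n_cpg: int
    direction: str
    mean_delta: float
    min_q: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty DMR span {self.start}..{self.end}")
        if self.direction not in (STATE_HYPER, STATE_HYPO):
            raise ValueError(f"bad direction {self.direction!r}")


def call_dmrs(
    sites: pd.DataFrame,
    min_cpg: int = DEFAULT_MIN_CPG,
    max_gap: int | None = DEFAULT_MAX_GAP,
) -> list[DMR]:
    """Call DMRs from a classified DiffSite table (sorted by chrom, pos)."""
    if min_cpg < 1:
        raise ValueError("min_cpg must be >= 1")
    order = sites[["chrom", "pos"]]
    if not order.equals(order.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("sites must be sorted by (chrom, pos)")
    tested = sites[sites["state"] != STATE_FILTERED]
    dmrs: list[DMR] = []
    for chrom, grp in tested.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        state = grp["state"].to_numpy()
        delta = grp["delta"].to_numpy()
        q = grp["q"].to_numpy()
        run: list[int] = []
        run_state = None

        def flush():
            if run_state in (STATE_HYPER, STATE_HYPO) and len(run) >= min_cpg:
                members = np.array(run)
                dmrs.append(
                    DMR(
                        chrom=chrom,
                        start=int(pos[members[0]]),
                        end=int(pos[members[-1]]) + 1,
                        n_cpg=len(members),
                        direction=run_state,
                        mean_delta=float(delta[members].mean()),
                        min_q=float(q[members].min()),
                    )
                )

        for i in range(len(pos)):
            s = state[i]
            if s not in (STATE_HYPER, STATE_HYPO):
                flush()
                run, run_state = [], None
                continue
            gap_broken = bool(run) and max_gap is not None and pos[i] - pos[run[-1]] > max_gap
            if s != run_state or gap_broken:
                flush()
                run, run_state = [i], s
            else:
                run.append(i)
        flush()
    return dmrs


def summarize_dmrs(dmrs: list[DMR]) -> dict[str, int]:
    """Count DMRs by direction; n_total = n_hyper + n_hypo always."""
    n_hyper = sum(1 for d in dmrs if d.direction == STATE_HYPER)
    n_hypo = sum(1 for d in dmrs if d.direction == STATE_HYPO)
    return {"n_total": n_hyper + n_hypo, "n_hyper": n_hyper, "n_hypo": n_hypo}


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_cpg", "direction", "mean_delta", "min_q"]
    return pd.DataFrame([dataclasses.asdict(d) for d in dmrs], columns=cols)
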