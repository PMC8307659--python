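"""Per-CpG differential methylation testing and genome-wide shift estimation.

The statistical recipe: keep CpGs covered by at least ``min_cov`` reads in
every replicate of both conditions, pool replicate counts within each
condition, run a Pearson chi-squared test (df = 1, no continuity correction)
on the 2x2 table of methylated/unmethylated read counts, adjust p-values
genome-wide with Benjamini-Hochberg, and call a site hyper-methylated when
q < fdr_threshold and delta > min_delta (hypo for delta < -min_delta), where
delta = pooled level in condition B minus condition A.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Methylome

STATE_HYPER = "hyper"
STATE_HYPO = "hypo"
STATE_NS = "not_significant"
STATE_FILTERED = "filtered"

DIFFSITE_COLUMNS = ["chrom", "pos", "meth_a", "meth_b", "delta", "chi2", "p", "q", "state"]

DEFAULT_MIN_COV = 4
DEFAULT_FDR = 0.2
DEFAULT_MIN_DELTA = 0.1


def filter_coverage(coverages: Sequence[Sequence[int]] | np.ndarray, min_cov: int = DEFAULT_MIN_COV):
    """Testability of sites: coverage >= min_cov in EVERY replicate of both conditions.

    1-D input is the per-replicate coverages of a single site (returns bool);
    2-D input is (n_replicates_total, n_sites), all replicates of both
    conditions stacked (returns a boolean array over sites).
    """
    arr = np.asarray(coverages)
    if arr.ndim == 1:
        return bool((arr >= min_cov).all())
    return np.all(arr >= min_cov, axis=0)


def chi_square_sites(
    meth_a: np.ndarray, unmeth_a: np.ndarray, meth_b: np.ndarray, unmeth_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson chi-squared on 2x2 tables of pooled read counts.

    Returns (chi2, p, delta). A degenerate table (any zero marginal) gets
    chi2 = 0, p = 1. delta = meth_b/cov_b - meth_a/cov_a; rows with zero
    pooled coverage in a condition get delta = NaN.
    """
    ma = np.asarray(meth_a, dtype=float)
    ua = np.asarray(unmeth_a, dtype=float)
    mb = np.asarray(meth_b, dtype=float)
    ub = np.asarray(unmeth_b, dtype=float)
    na = ma + ua
    nb = mb + ub
    n = na + nb
    cm = ma + mb
    cu = ua + ub
    denom = na * nb * cm * cu
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (ma * ub - ua * mb) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
        level_a = np.where(na > 0, ma / np.where(na > 0, na, 1.0), np.nan)
        level_b = np.where(nb > 0, mb / np.where(nb > 0, nb, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(denom > 0, p, 1.0)
    return chi2, p, level_b - level_a


def chi_square_site(pooled_a: tuple[int, int], pooled_b: tuple[int, int]) -> tuple[float, float, float]:
    """Scalar convenience wrapper around :func:`chi_square_sites`."""
    if pooled_a[0] + pooled_a[1] <= 0 or pooled_b[0] + pooled_b[1] <= 0:
        raise ValueError("both conditions need pooled coverage > 0")
    chi2, p, delta = chi_square_sites(
        np.array([pooled_a[0]]), np.array([pooled_a[1]]), np.array([pooled_b[0]]), np.array([pooled_b[1]])
    )
    return float(chi2[0]), float(p[0]), float(delta[0])


def adjust_bh(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_sites(
    sites: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> pd.DataFrame:
    """Assign hyper / hypo / not_significant states to tested sites.

    Thresholds are strict: hyper iff q < fdr_threshold and delta > min_delta;
    hypo iff q < fdr_threshold and delta < -min_delta. Filtered sites keep
    their state. Returns a copy.
    """
    out = sites.copy()
    tested = out["state"] != STATE_FILTERED
    q = out["q"].to_numpy()
    delta = out["delta"].to_numpy()
    sig = tested.to_numpy() & (q < fdr_threshold)
    state = np.where(
        sig & (delta > min_delta),
        STATE_HYPER,
        np.where(sig & (delta < -min_delta), STATE_HYPO, STATE_NS),
    )
    out.loc[tested, "state"] = state[tested.to_numpy()]
    return out


def _aligned_counts(methylomes: Sequence[Methylome]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Outer-align replicate tables on (chrom, pos).

    Returns (index frame, meth matrix, coverage matrix), each matrix
    (n_replicates, n_sites); missing sites count as coverage 0.
    """
    frames = []
    for i, m in enumerate(methylomes):
        df = m.sites.set_index(["chrom", "pos"])
        df.columns = pd.MultiIndex.from_product([[i], df.columns])
        frames.append(df)
    wide = pd.concat(frames, axis=1).sort_index()
    meth = np.stack([wide[(i, "n_meth")].fillna(0).to_numpy() for i in range(len(methylomes))])
    unmeth = np.stack([wide[(i, "n_unmeth")].fillna(0).to_numpy() for i in range(len(methylomes))])
    idx = wide.index.to_frame(index=False)
    return idx, meth, meth + unmeth


def test_methylomes(
    methylomes_a: Sequence[Methylome],
    methylomes_b: Sequence[Methylome],
    min_cov: int = DEFAULT_MIN_COV,
    fdr_threshold: float = DEFAULT_FDR,
    min_delta: float = DEFAULT_MIN_DELTA,
    exclude_chroms: Sequence[str] = (),
) -> pd.DataFrame:
    """Run the full per-CpG pipeline and return the DiffSite table.

    Columns: chrom, pos, meth_a, meth_b, delta, chi2, p, q, state. Sites
    failing the per-replicate coverage rule are state ``filtered`` with NaN
    statistics; BH is applied once over all tested sites genome-wide.
    """
    if not methylomes_a or not methylomes_b:
        raise ValueError("need >= 1 replicate per condition")
    idx, meth_all, cov_all = _aligned_counts(list(methylomes_a) + list(methylomes_b))
    if exclude_chroms:
        keep = ~idx["chrom"].isin(exclude_chroms).to_numpy()
        idx = idx[keep].reset_index(drop=True)
        meth_all = meth_all[:, keep]
        cov_all = cov_all[:, keep]
    na = len(methylomes_a)
    testable = np.all(cov_all >= min_cov, axis=0)
    ma = meth_all[:na].sum(axis=0)
    ua = cov_all[:na].sum(axis=0) - ma
    mb = meth_all[na:].sum(axis=0)
    ub = cov_all[na:].sum(axis=0) - mb
    # guard min_cov = 0: a pooled-empty condition is untestable, not degenerate
    testable &= (ma + ua > 0) & (mb + ub > 0)
    chi2, p, delta = chi_square_sites(ma, ua, mb, ub)
    out = pd.DataFrame(
        {
            "chrom": idx["chrom"],
            "pos": idx["pos"].astype(np.int64),
            "meth_a": np.where(ma + ua > 0, ma / np.maximum(ma + ua, 1), np.nan),
            "meth_b": np.where(mb + ub > 0, mb / np.maximum(mb + ub, 1), np.nan),
            "delta": delta,
            "chi2": chi2,
            "p": p,
            "q": np.nan,
            "state": STATE_FILTERED,
        }
    )
    out.loc[~testable, ["meth_a", "meth_b", "delta", "chi2", "p"]] = np.nan
    q = np.full(len(out), np.nan)
    q[testable] = adjust_bh(p[testable]) if testable.any() else []
    out["q"] = q
    out.loc[testable, "state"] = STATE_NS
    return classify_sites(out, fdr_threshold=fdr_threshold, min_delta=min_delta)


@dataclasses.dataclass
class GlobalShiftResult:
    """Genome-wide methylation difference between conditions.

    ``mean_a``/``mean_b`` are unbinned means of per-CpG pooled levels over
    testable CpGs; the significance test is a paired two-sided t-test of
    per-bin mean levels across ``n_bins`` genomic bins of ``bin_size`` bp.
    ``degenerate`` flags a zero-variance bin difference (p undefined).
    """

    mean_a: float
    mean_b: float
    n_cpg_used: int
    bin_size: int
    n_bins: int
    statistic: float
    p: float
    degenerate: bool = False

    @property
    def mean_difference(self) -> float:
        return self.mean_b - self.mean_a


def global_methylation_shift(
    methylomes_a: Sequence[Methylome],
    methylomes_b: Sequence[Methylome],
    bin_size: int = 1_000_000,
    min_cov: int = DEFAULT_MIN_COV,
    exclude_chroms: Sequence[str] = (),
) -> GlobalShiftResult:
    """Estimate and test the genome-wide methylation shift (condition B - A)."""
    levels = _paired_levels(methylomes_a, methylomes_b, min_cov, exclude_chroms)
    if len(levels) == 0:
        raise ValueError("no testable CpGs; lower min_cov")
    bins = levels.groupby(["chrom", levels["pos"] // bin_size], observed=True)[["level_a", "level_b"]].mean()
    if len(bins) < 2:
        raise ValueError(f"only {len(bins)} usable bin(s); use a smaller bin_size")
    diffs = bins["level_b"] - bins["level_a"]
    degenerate = bool(np.allclose(diffs.std(ddof=1), 0.0))
    if degenerate:
        stat, p = 0.0, np.nan
    else:
        stat, p = stats.ttest_rel(bins["level_b"], bins["level_a"])
    return GlobalShiftResult(
        mean_a=float(levels["level_a"].mean()),
        mean_b=float(levels["level_b"].mean()),
        n_cpg_used=int(len(levels)),
        bin_size=bin_size,
        n_bins=int(len(bins)),
        statistic=float(stat),
        p=float(p) if p == p else float("nan"),
        degenerate=degenerate,
    )


def methylation_hexbin(
    methylomes_a: Sequence[Methylome] | Methylome,
    methylomes_b: Sequence[Methylome] | Methylome,
    n_bins: int = 50,
    min_cov: int = DEFAULT_MIN_COV,
    exclude_chroms: Sequence[str] = (),
) -> np.ndarray:
    """2-D histogram of paired per-CpG pooled levels on an n_bins x n_bins grid over [0,1]^2.

    counts[i, j] counts CpGs with level_a in bin i and level_b in bin j; the
    total equals the number of CpGs passing the coverage rule in both
    conditions (level 1.0 falls in the last bin).
    """
    if isinstance(methylomes_a, Methylome):
        methylomes_a = [methylomes_a]
    if isinstance(methylomes_b, Methylome):
        methylomes_b = [methylomes_b]
    levels = _paired_levels(methylomes_a, methylomes_b, min_cov, exclude_chroms)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _, _ = np.histogram2d(levels["level_a"], levels["level_b"], bins=[edges, edges])
    return counts.astype(np.int64)


def _paired_levels(
    methylomes_a: Sequence[Methylome],
    methylomes_b: Sequence[Methylome],
    min_cov: int,
    exclude_chroms: Sequence[str] = (),
) -> pd.DataFrame:
    idx, meth_all, cov_all = _aligned_counts(list(methylomes_a) + list(methylomes_b))
    na = len(methylomes_a)
    keep = np.all(cov_all >= min_cov, axis=0)
    ca = cov_all[:na].sum(axis=0)
    cb = cov_all[na:].sum(axis=0)
    keep &= (ca > 0) & (cb > 0)
    if exclude_chroms:
        keep &= ~idx["chrom"].isin(exclude_chroms).to_numpy()
    return pd.DataFrame(
        {
            "chrom": idx["chrom"][keep].to_numpy(),
            "pos": idx["pos"][keep].to_numpy(),
            "level_a": meth_all[:na].sum(axis=0)[keep] / ca[keep],
            "level_b": meth_all[na:].sum(axis=0)[keep] / cb[keep],
        }
    )


def write_diffsites_tsv(sites: pd.DataFrame, path) -> None:
    """Write the DiffSite table with deterministic column order and 6-decimal floats."""
    sites[DIFFSITE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_diffsites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
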