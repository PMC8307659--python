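"""Readers and writers for per-CpG count tables and genomic-interval files.

All coordinates are 0-based half-open internally; only the I/O layer converts.
Two count-table dialects are supported:

* ``bismark_cov`` — the Bismark coverage format: TAB-separated
  ``chrom  start  end  percent_methylated  count_methylated  count_unmethylated``
  with 1-based inclusive coordinates.
* ``bedgraph_counts`` — ``chrom  start  end  count_methylated  count_unmethylated``
  with 0-based half-open coordinates.

The percent column of ``bismark_cov`` is ignored on input and recomputed from
counts on output, so counts are always the source of truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

DIALECTS = ("bismark_cov", "bedgraph_counts")


class ParseError(ValueError):
    """A row of an input file could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant (negative counts, start >= end, ...)."""


class CpGSiteCounts(NamedTuple):
    """Methylated/unmethylated read counts at one CpG (0-based plus-strand C position)."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        cov = self.coverage
        return self.n_meth / cov if cov > 0 else float("nan")


@dataclasses.dataclass
class Methylome:
    """One sample's CpG count table, sorted by (chrom, pos) with no duplicates.

    ``sites`` is a DataFrame with columns chrom, pos, n_meth, n_unmeth.
    """

    sample_id: str
    condition: str
    replicate: int
    sites: pd.DataFrame

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValidationError(f"sites table missing columns {missing}")
        self.sites = _normalize_sites(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def iter_sites(self) -> Iterable[CpGSiteCounts]:
        for row in self.sites.itertuples(index=False):
            yield CpGSiteCounts(row.chrom, int(row.pos), int(row.n_meth), int(row.n_unmeth))


@dataclasses.dataclass
class FeatureSet:
    """Named genomic intervals of one class (promoter, enhancer, ChromHMM state, ...).

    ``intervals`` has columns chrom, start, end, label (label may be None) in
    0-based half-open coordinates, sorted by (chrom, start, end).
    """

    class_name: str
    intervals: pd.DataFrame

    def __post_init__(self):
        df = self.intervals.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"FeatureSet intervals missing column {col!r}")
        if "label" not in df.columns:
            df["label"] = None
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(f"interval with start >= end at row {bad}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.intervals = df[["chrom", "start", "end", "label"]]

    def __len__(self) -> int:
        return len(self.intervals)


def _normalize_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = df[SITE_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    if len(df):
        if (df["pos"] < 0).any():
            raise ValidationError("negative position in site table")
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValidationError("negative count in site table")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValidationError(f"duplicate site {dup['chrom']}:{dup['pos']}")
    return df


def _numeric_or_raise(path, raw: pd.Series, colname: str, offset_lines: int = 0) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    if vals.isna().any():
        line = int(vals.index[vals.isna()][0]) + 1 + offset_lines
        raise ParseError(path, line, f"cannot parse column {colname!r} as a number")
    return vals


def read_cpg_counts(
    path,
    dialect: str = "bismark_cov",
    sample_id: str | None = None,
    condition: str = "",
    replicate: int = 1,
) -> Methylome:
    """Read a per-CpG count table into a :class:`Methylome`.

    Positions are converted to 0-based; the bismark_cov percent column is
    discarded. Rows with zero coverage are retained (the coverage filter is a
    downstream, reportable step). Unsorted input is sorted.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    ncol = 6 if dialect == "bismark_cov" else 5
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(ncol))
    if len(raw) and raw.shape[1] != ncol:
        raise ParseError(path, 1, f"expected {ncol} TAB-separated columns, found {raw.shape[1]}")
    raw = raw.reset_index(drop=True)
    if dialect == "bismark_cov":
        start = _numeric_or_raise(path, raw[1], "start")
        n_meth = _numeric_or_raise(path, raw[4], "count_methylated")
        n_unmeth = _numeric_or_raise(path, raw[5], "count_unmethylated")
        pos = start.astype(np.int64) - 1  # 1-based inclusive -> 0-based
    else:
        start = _numeric_or_raise(path, raw[1], "start")
        n_meth = _numeric_or_raise(path, raw[3], "count_methylated")
        n_unmeth = _numeric_or_raise(path, raw[4], "count_unmethylated")
        pos = start.astype(np.int64)
    if len(raw) and ((n_meth < 0).any() or (n_unmeth < 0).any()):
        bad = int(np.argmax((n_meth < 0) | (n_unmeth < 0))) + 1
        raise ParseError(path, bad, "negative read count")
    sites = pd.DataFrame(
        {
            "chrom": raw[0] if len(raw) else pd.Series(dtype=str),
            "pos": pos,
            "n_meth": n_meth.astype(np.int64),
            "n_unmeth": n_unmeth.astype(np.int64),
        }
    )
    return Methylome(
        sample_id=sample_id if sample_id is not None else path.stem,
        condition=condition,
        replicate=replicate,
        sites=sites,
    )


def write_cpg_counts(methylome: Methylome, path, dialect: str = "bismark_cov") -> None:
    """Write a Methylome back to disk in either supported dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = methylome.sites
    cov = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    with open(path, "w") as fh:
        if dialect == "bismark_cov":
            pct = np.where(cov > 0, 100.0 * df["n_meth"].to_numpy() / np.maximum(cov, 1), 0.0)
            for (chrom, pos, m, u), p in zip(df.itertuples(index=False), pct):
                fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{p:.6g}\t{m}\t{u}\n")
        else:
            for chrom, pos, m, u in df.itertuples(index=False):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{m}\t{u}\n")


def merge_strands(
    methylome: Methylome,
    reference_cpg_positions: dict[str, Sequence[int]] | None = None,
) -> Methylome:
    """Collapse plus/minus strand records of one CpG dyad into a single record.

    A CpG measured on both strands appears as two rows at positions p (the C)
    and p+1 (the G, i.e. the C of the reverse strand). Their counts are summed
    into one record at p. With ``reference_cpg_positions`` (per-chromosome
    plus-strand C positions), a row at p+1 merges into p exactly when p is a
    known CpG and p+1 is not. Without a reference, adjacent positions differing
    by exactly 1 are paired greedily left to right. Unpaired rows pass through.
    Total read counts are conserved; the operation is idempotent.
    """
    out_rows: list[tuple] = []
    for chrom, grp in methylome.sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        m = grp["n_meth"].to_numpy()
        u = grp["n_unmeth"].to_numpy()
        ref = None
        if reference_cpg_positions is not None:
            ref = set(int(p) for p in reference_cpg_positions.get(chrom, ()))
        i = 0
        n = len(pos)
        while i < n:
            p = int(pos[i])
            pairable = i + 1 < n and int(pos[i + 1]) == p + 1
            if pairable and ref is not None:
                pairable = p in ref and (p + 1) not in ref
            if pairable:
                out_rows.append((chrom, p, int(m[i] + m[i + 1]), int(u[i] + u[i + 1])))
                i += 2
            else:
                if ref is not None and p - 1 in ref and p not in ref:
                    # lone minus-strand record: re-anchor to the plus-strand C
                    out_rows.append((chrom, p - 1, int(m[i]), int(u[i])))
                else:
                    out_rows.append((chrom, p, int(m[i]), int(u[i])))
                i += 1
    sites = pd.DataFrame(out_rows, columns=SITE_COLUMNS)
    if not out_rows:
        sites = methylome.sites.iloc[0:0]
    # re-anchoring may collide with an existing plus-strand row: sum them
    sites = sites.groupby(["chrom", "pos"], as_index=False, sort=False).sum()
    return Methylome(
        sample_id=methylome.sample_id,
        condition=methylome.condition,
        replicate=methylome.replicate,
        sites=sites,
    )


def read_bed_features(path, class_name: str) -> FeatureSet:
    """Read a BED3/BED4/BED6 file (0-based half-open) into a sorted FeatureSet.

    Column 4, when present, is kept as the per-interval label (ChromHMM state
    codes, TF names). Extra BED columns are ignored.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return FeatureSet(class_name, pd.DataFrame(columns=["chrom", "start", "end", "label"]))
    if raw.shape[1] < 3:
        raise ParseError(path, 1, f"BED needs >= 3 columns, found {raw.shape[1]}")
    start = _numeric_or_raise(path, raw[1], "start").astype(np.int64)
    end = _numeric_or_raise(path, raw[2], "end").astype(np.int64)
    bad = start >= end
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 1
        raise ParseError(path, line, f"start >= end ({start[bad].iloc[0]} >= {end[bad].iloc[0]})")
    df = pd.DataFrame(
        {
            "chrom": raw[0],
            "start": start,
            "end": end,
            "label": raw[3] if raw.shape[1] >= 4 else None,
        }
    )
    return FeatureSet(class_name, df)


def write_bed_features(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in features.intervals.itertuples(index=False):
            if label is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED6: name is the direction, score = round(1000*|mean delta|) capped."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000, int(round(1000 * abs(d.mean_delta))))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t{score}\t.\n")


def strip_chr_prefix(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


def add_chr_prefix(name: str) -> str:
    return name if name.startswith("chr") else f"chr{name}"


def normalize_chrom_names(df: pd.DataFrame, style: str | None) -> pd.DataFrame:
    """Optionally harmonize 'chr' prefixes; style is None (leave), 'chr' or 'plain'."""
    if style is None:
        return df
    func = add_chr_prefix if style == "chr" else strip_chr_prefix
    out = df.copy()
    out["chrom"] = out["chrom"].map(func)
    return out
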