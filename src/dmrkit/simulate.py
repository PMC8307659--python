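"""Synthetic two-condition WGBS methylomes with known truth, plus amplicon reads.

The generator emulates the statistical structure of a two-condition,
two-replicate whole-genome bisulfite experiment at desk scale:

* a genome with a CpG-island organization — CpG-dense islands with low
  baseline methylation inside a CpG-sparse background with high baseline
  methylation (the usual bimodal vertebrate methylome);
* negative-binomial per-CpG read coverage (WGBS coverage is overdispersed
  relative to Poisson);
* replicate-to-replicate wobble of the methylation level on the logit scale;
* spiked hyper-/hypo-methylated regions of known location, direction and
  effect size (the ground truth for recovery benchmarks);
* an optional mild global methylation offset in the second condition;
* imperfect bisulfite conversion (an unconverted unmethylated C reads as
  methylated, inflating apparent methylation) and a fully unmethylated
  spike-in contig for conversion-efficiency QC, standing in for the lambda
  phage DNA conventionally added to WGBS libraries;
* single-amplicon bisulfite read sets at specified per-CpG methylation.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import FeatureSet, Methylome, SITE_COLUMNS

SPIKEIN_CHROM = "spikein_lambda"

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent or infeasible."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic methylome experiment.

    Defaults describe a 10 Mb single-chromosome genome (~1e5 CpGs), two
    conditions ("WT" and "KO") with two replicates each, mean coverage 10,
    a mild +0.015 global methylation offset in KO and 50+50 spiked regions
    of five CpGs at |delta| = 0.4, with 99.5% bisulfite conversion.
    """

    n_chrom: int = 1
    chrom_length: int = 10_000_000
    cpg_background_rate: float = 0.01
    n_islands: int = 50
    island_length: int = 1_000
    island_cpg_rate: float = 0.10
    baseline_meth_island: tuple[float, float] = (1.0, 9.0)
    baseline_meth_background: tuple[float, float] = (6.0, 1.5)
    coverage_mean: float = 10.0
    coverage_dispersion: float = 5.0
    n_replicates_per_condition: int = 2
    replicate_noise_sd: float = 0.1
    n_hyper_dmr: int = 50
    n_hypo_dmr: int = 50
    dmr_n_cpg: int = 5
    dmr_delta: float = 0.4
    global_shift: float = 0.015
    conversion_efficiency: float = 0.995
    spikein_length: int = 5_000
    spikein_cpg_rate: float = 0.02
    condition_a: str = "WT"
    condition_b: str = "KO"
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ConfigError("need >= 1 chromosome of positive length")
        for name in ("cpg_background_rate", "island_cpg_rate", "spikein_cpg_rate"):
            r = getattr(self, name)
            if not 0 < r <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {r}")
        if not 0 < self.conversion_efficiency <= 1:
            raise ConfigError("conversion_efficiency must be in (0, 1]")
        if not 0 < self.dmr_delta < 1:
            raise ConfigError("dmr_delta must be in (0, 1)")
        if abs(self.global_shift) >= 1:
            raise ConfigError("global_shift must be in (-1, 1)")
        if self.n_replicates_per_condition < 1:
            raise ConfigError("need >= 1 replicate per condition")
        if self.replicate_noise_sd < 0 or self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ConfigError("noise sd must be >= 0 and coverage parameters > 0")
        if self.n_islands * self.island_length > 0.5 * self.n_chrom * self.chrom_length:
            raise ConfigError("islands would cover more than half the genome; shrink them")
        if self.dmr_n_cpg < 1 or self.n_hyper_dmr < 0 or self.n_hypo_dmr < 0:
            raise ConfigError("bad spiked-region counts")


@dataclasses.dataclass
class ReferenceMap:
    """CpG layout produced by :func:`simulate_reference`."""

    cpg_positions: dict[str, np.ndarray]
    island_mask: dict[str, np.ndarray]
    islands: FeatureSet
    spikein_positions: np.ndarray
    spikein_chrom: str = SPIKEIN_CHROM

    @property
    def n_cpg(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))


@dataclasses.dataclass
class TruthSet:
    """Simulator ground truth for parameter-recovery benchmarks.

    ``regions`` has columns chrom, start, end, direction, true_delta, sorted;
    ``true_levels`` maps chromosome -> DataFrame(pos, mu_a, mu_b).
    """

    regions: pd.DataFrame
    global_shift: float
    true_levels: dict[str, pd.DataFrame]

    def __post_init__(self):
        if len(self.regions):
            hyper_neg = (self.regions["direction"] == "hyper") & (self.regions["true_delta"] <= 0)
            hypo_pos = (self.regions["direction"] == "hypo") & (self.regions["true_delta"] >= 0)
            if hyper_neg.any() or hypo_pos.any():
                raise ConfigError("truth region direction inconsistent with true_delta sign")
            self.regions = self.regions.sort_values(["chrom", "start"]).reset_index(drop=True)

    def to_json(self, path) -> None:
        payload = {
            "global_shift": self.global_shift,
            "regions": self.regions.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> ReferenceMap:
    """Lay out CpG positions and island intervals on a synthetic genome.

    Island intervals are disjoint; CpG counts follow a binomial process at
    ``island_cpg_rate`` inside islands and ``cpg_background_rate`` outside.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config.n_chrom)
    per_chrom_islands = _split_count(config.n_islands, config.n_chrom)
    cpg_positions: dict[str, np.ndarray] = {}
    island_mask: dict[str, np.ndarray] = {}
    island_rows: list[tuple] = []
    for chrom, n_isl in zip(chroms, per_chrom_islands):
        L = config.chrom_length
        starts = _place_disjoint(rng, L, n_isl, config.island_length)
        isl_pos: list[np.ndarray] = []
        for s in starts:
            island_rows.append((chrom, int(s), int(s + config.island_length), "CpG_island"))
            n = rng.binomial(config.island_length, config.island_cpg_rate)
            p = np.sort(rng.choice(config.island_length - 1, size=min(n, config.island_length - 1), replace=False)) + s
            isl_pos.append(p)
        in_island = np.zeros(L, dtype=bool)
        for s in starts:
            in_island[s : s + config.island_length] = True
        bg_space = int(L - 1 - in_island[: L - 1].sum())
        n_bg = rng.binomial(bg_space, config.cpg_background_rate)
        bg_candidates = np.flatnonzero(~in_island[: L - 1])
        bg_pos = np.sort(rng.choice(bg_candidates, size=min(n_bg, len(bg_candidates)), replace=False))
        pos = np.unique(np.concatenate([bg_pos] + isl_pos)) if isl_pos else bg_pos
        cpg_positions[chrom] = pos.astype(np.int64)
        island_mask[chrom] = in_island[pos]
    n_spike = rng.binomial(config.spikein_length - 1, config.spikein_cpg_rate)
    spikein = np.sort(rng.choice(config.spikein_length - 1, size=n_spike, replace=False)).astype(np.int64)
    islands = FeatureSet("CpG_island", pd.DataFrame(island_rows, columns=["chrom", "start", "end", "label"]))
    return ReferenceMap(cpg_positions, island_mask, islands, spikein)


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _place_disjoint(rng: np.random.Generator, length: int, n: int, width: int) -> np.ndarray:
    """Place n disjoint width-bp intervals uniformly in [0, length)."""
    if n == 0:
        return np.array([], dtype=np.int64)
    free = length - n * width
    if free < 0:
        raise ConfigError(f"cannot place {n} islands of {width} bp in {length} bp")
    gaps = np.sort(rng.choice(free + 1, size=n, replace=True))
    starts = gaps + width * np.arange(n)
    return starts.astype(np.int64)


def _pick_spike_regions(
    rng: np.random.Generator,
    refmap: ReferenceMap,
    config: SimConfig,
    buffer_cpgs: int = 5,
) -> list[tuple[str, int, int, str]]:
    """Choose disjoint runs of ``dmr_n_cpg`` consecutive background CpGs.

    Returns (chrom, start_index, end_index, direction) with a ``buffer_cpgs``
    exclusion zone around every chosen run so neighbouring truth regions
    cannot fuse into one called region. Spikes live only in the background
    compartment, leaving island methylation independently controllable.
    """
    n_total = config.n_hyper_dmr + config.n_hypo_dmr
    if n_total == 0:
        return []
    k = config.dmr_n_cpg
    candidates: list[tuple[str, int]] = []
    for chrom, mask in refmap.island_mask.items():
        bg = ~mask
        if len(bg) < k:
            continue
        ok = np.ones(len(bg) - k + 1, dtype=bool)
        for j in range(k):
            ok &= bg[j : j + len(ok)]
        for idx in np.flatnonzero(ok):
            candidates.append((chrom, int(idx)))
    order = rng.permutation(len(candidates))
    taken: dict[str, set[int]] = {c: set() for c in refmap.cpg_positions}
    chosen: list[tuple[str, int]] = []
    for oi in order:
        chrom, idx = candidates[oi]
        span = range(idx - buffer_cpgs, idx + k + buffer_cpgs)
        if any(j in taken[chrom] for j in span):
            continue
        taken[chrom].update(span)
        chosen.append((chrom, idx))
        if len(chosen) == n_total:
            break
    if len(chosen) < n_total:
        raise ConfigError(
            f"could only place {len(chosen)} of {n_total} spiked regions; "
            "reduce their number/size or enlarge the genome"
        )
    directions = ["hyper"] * config.n_hyper_dmr + ["hypo"] * config.n_hypo_dmr
    rng.shuffle(directions)
    return [(c, i, i + k, d) for (c, i), d in zip(chosen, directions)]


def simulate_methylomes(
    refmap: ReferenceMap, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[Methylome], list[Methylome], TruthSet]:
    """Draw replicate count tables for both conditions plus the ground truth.

    Per CpG i a true level mu_i is drawn from the island or background Beta;
    condition-B levels are clip(mu_i + global_shift, 0, 1) except inside
    spiked regions, where the pair (mu_a, mu_b) is drawn so that the full
    ``dmr_delta`` is expressed: the baseline is sampled uniformly from the
    band that keeps both levels inside [0.05, 0.95]. Replicate levels wobble
    on the logit scale; coverage is negative binomial; observed methylated
    counts are binomial at the conversion-adjusted level
    p_obs = level + (1 - level) * (1 - conversion_efficiency).
    The spike-in contig is fully unmethylated in both conditions.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    margin = 0.05
    if config.dmr_delta > 1 - 2 * margin:
        raise ConfigError(f"dmr_delta must be <= {1 - 2 * margin} to fit the sampling band")
    spikes = _pick_spike_regions(rng, refmap, config)

    mu_a: dict[str, np.ndarray] = {}
    mu_b: dict[str, np.ndarray] = {}
    for chrom, pos in refmap.cpg_positions.items():
        isl = refmap.island_mask[chrom]
        a_i, b_i = config.baseline_meth_island
        a_b, b_b = config.baseline_meth_background
        mu = np.where(isl, rng.beta(a_i, b_i, size=len(pos)), rng.beta(a_b, b_b, size=len(pos)))
        mu_a[chrom] = mu
        mu_b[chrom] = np.clip(mu + config.global_shift, 0.0, 1.0)

    region_rows: list[tuple] = []
    for chrom, i0, i1, direction in spikes:
        pos = refmap.cpg_positions[chrom]
        k = i1 - i0
        if direction == "hyper":
            base = rng.uniform(margin, 1 - margin - config.dmr_delta, size=k)
            mu_a[chrom][i0:i1] = base
            mu_b[chrom][i0:i1] = base + config.dmr_delta
            delta = config.dmr_delta
        else:
            base = rng.uniform(margin + config.dmr_delta, 1 - margin, size=k)
            mu_a[chrom][i0:i1] = base
            mu_b[chrom][i0:i1] = base - config.dmr_delta
            delta = -config.dmr_delta
        region_rows.append((chrom, int(pos[i0]), int(pos[i1 - 1]) + 1, direction, delta))
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "direction", "true_delta"])

    def _draw_condition(mu: dict[str, np.ndarray], condition: str) -> list[Methylome]:
        reps = []
        for r in range(1, config.n_replicates_per_condition + 1):
            frames = []
            for chrom, pos in refmap.cpg_positions.items():
                level = _wobble(rng, mu[chrom], config.replicate_noise_sd)
                frames.append(_draw_counts(rng, chrom, pos, level, config))
            frames.append(
                _draw_counts(
                    rng,
                    refmap.spikein_chrom,
                    refmap.spikein_positions,
                    np.zeros(len(refmap.spikein_positions)),
                    config,
                )
            )
            sites = pd.concat(frames, ignore_index=True)
            reps.append(
                Methylome(
                    sample_id=f"{condition}_rep{r}", condition=condition, replicate=r, sites=sites
                )
            )
        return reps

    meth_a = _draw_condition(mu_a, config.condition_a)
    meth_b = _draw_condition(mu_b, config.condition_b)
    truth = TruthSet(
        regions=regions,
        global_shift=config.global_shift,
        true_levels={
            chrom: pd.DataFrame(
                {"pos": refmap.cpg_positions[chrom], "mu_a": mu_a[chrom], "mu_b": mu_b[chrom]}
            )
            for chrom in refmap.cpg_positions
        },
    )
    return meth_a, meth_b, truth


def _wobble(rng: np.random.Generator, mu: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0 or len(mu) == 0:
        return mu
    eps = 1e-6
    z = logit(np.clip(mu, eps, 1 - eps)) + rng.normal(0.0, sd, size=len(mu))
    level = expit(z)
    # exact 0/1 levels stay exact: wobble models biology, not conversion
    return np.where((mu <= 0) | (mu >= 1), mu, level)


def _draw_counts(
    rng: np.random.Generator, chrom: str, pos: np.ndarray, level: np.ndarray, config: SimConfig
) -> pd.DataFrame:
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    cov = rng.negative_binomial(k, p_nb, size=len(pos))
    p_obs = level + (1.0 - level) * (1.0 - config.conversion_efficiency)
    n_meth = rng.binomial(cov, p_obs)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "n_meth": n_meth.astype(np.int64),
            "n_unmeth": (cov - n_meth).astype(np.int64),
        }
    )[SITE_COLUMNS]


def spikein_conversion_efficiency(
    methylomes: Sequence[Methylome], spikein_chrom: str = SPIKEIN_CHROM
) -> float:
    """Estimate bisulfite conversion efficiency from the unmethylated spike-in.

    Every methylated call on the fully unmethylated contig is a conversion
    failure, so efficiency = 1 - pooled n_meth / pooled coverage.
    """
    m = u = 0
    for meth in methylomes:
        sub = meth.sites[meth.sites["chrom"] == spikein_chrom]
        m += int(sub["n_meth"].sum())
        u += int(sub["n_unmeth"].sum())
    if m + u == 0:
        raise ValueError(f"no reads on spike-in contig {spikein_chrom!r}")
    return 1.0 - m / (m + u)


# ---------------------------------------------------------------------------
# amplicon read simulation


def random_amplicon(
    length: int, n_cpg: int, rng: np.random.Generator, gc: float = 0.5
) -> str:
    """A random amplicon sequence containing exactly ``n_cpg`` CpG dinucleotides."""
    if length < 2 * n_cpg + 2:
        raise ConfigError("amplicon too short for requested CpG count")
    while True:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(_BASES, size=length, p=p)
        # scrub accidental CpGs, then stamp the requested ones
        for i in range(length - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                seq[i + 1] = "A"
        slots = np.sort(rng.choice((length - 2) // 2, size=n_cpg, replace=False)) * 2
        for s in slots:
            seq[s], seq[s + 1] = "C", "G"
        s = "".join(seq)
        if _cpg_offsets(s).size == n_cpg:
            return s


def _cpg_offsets(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def simulate_amplicon_reads(
    ref_seq: str,
    cpg_meth_probs: Sequence[float] | float,
    n_reads: int,
    read_length: int | None = None,
    conversion_efficiency: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """Simulate top-strand bisulfite reads of one amplicon.

    Each read starts at offset 0 and covers ``read_length`` bases. A CpG
    cytosine stays C with its methylation probability (else T); every other
    cytosine stays C with probability 1 - conversion_efficiency (else T).
    Returns the reads and the per-read truth patterns over the CpGs covered
    by the read ('M' methylated / 'U' unmethylated / 'N' not covered).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ref_seq = ref_seq.upper()
    offsets = _cpg_offsets(ref_seq)
    if offsets.size == 0:
        raise ValueError("reference contains no CpG")
    if read_length is None:
        read_length = len(ref_seq)
    if read_length > len(ref_seq):
        raise ValueError("read_length exceeds amplicon length")
    probs = np.asarray(
        np.broadcast_to(np.asarray(cpg_meth_probs, dtype=float), offsets.shape), dtype=float
    )
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("CpG methylation probabilities must lie in [0, 1]")
    if not 0 < conversion_efficiency <= 1:
        raise ValueError("conversion_efficiency must be in (0, 1]")
    arr = np.frombuffer(ref_seq.encode(), dtype="S1")[:read_length]
    is_c = arr == b"C"
    covered = offsets[offsets < read_length]
    non_cpg_c = np.flatnonzero(is_c)
    non_cpg_c = non_cpg_c[~np.isin(non_cpg_c, covered)]
    reads: list[str] = []
    patterns: list[str] = []
    for _ in range(n_reads):
        base = arr.copy()
        meth = rng.random(covered.size) < probs[: covered.size]
        base[covered[~meth]] = b"T"
        fail = rng.random(non_cpg_c.size) < (1.0 - conversion_efficiency)
        base[non_cpg_c[~fail]] = b"T"
        reads.append(base.tobytes().decode())
        pat = np.where(meth, "M", "U")
        patterns.append("".join(pat) + "N" * (offsets.size - covered.size))
    return reads, patterns


def write_fastq(reads: Sequence[str], path, name_prefix: str = "read") -> None:
    """Write reads as a 4-line-record FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{name_prefix}_{i}\n{r}\n+\n{'I' * len(r)}\n")
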