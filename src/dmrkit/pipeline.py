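"""End-to-end orchestration: simulate or ingest, test, call DMRs, contextualize, report.

``run_pipeline`` writes a reproducible bundle under the output directory:

* ``diffsites.tsv`` — the per-CpG DiffSite table
* ``dmrs.bed`` + ``dmr_summary.tsv`` — called regions and the direction split
* ``global_shift.tsv`` — genome-wide means and the binned paired test
* ``hexbin.tsv`` — the 2-D level histogram
* ``feature_profile_<class>.tsv`` — one per supplied feature file
* ``truth_regions.bed`` / ``truth.json`` — simulator ground truth (simulate mode)
* ``manifest.json`` — config echo, seed, stage counts

All randomness flows from the single config seed; two runs with the same
config produce byte-identical text outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, diff, dmr as dmr_mod, features as feat_mod, io as mio, simulate as sim

log = logging.getLogger("dmrkit")


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds default to the analysis convention: coverage >= 4 reads in
    every replicate, FDR < 0.2, |delta| > 0.1, >= 2 consecutive CpGs."""

    simulate: bool = False
    sim: sim.SimConfig = dataclasses.field(default_factory=sim.SimConfig)
    condition_a_paths: list[str] = dataclasses.field(default_factory=list)
    condition_b_paths: list[str] = dataclasses.field(default_factory=list)
    dialect: str = "bismark_cov"
    min_cov: int = diff.DEFAULT_MIN_COV
    fdr_threshold: float = diff.DEFAULT_FDR
    min_delta: float = diff.DEFAULT_MIN_DELTA
    min_cpg: int = dmr_mod.DEFAULT_MIN_CPG
    max_gap: int | None = dmr_mod.DEFAULT_MAX_GAP
    bin_size: int = 1_000_000
    hexbin_bins: int = 50
    feature_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    chromhmm_path: str | None = None
    tfbs_path: str | None = None
    out_dir: str = "dmrkit_out"
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.simulate and (self.condition_a_paths or self.condition_b_paths):
            raise ConfigurationError("simulate=true contradicts explicit input paths")
        if not self.simulate and not (self.condition_a_paths and self.condition_b_paths):
            raise ConfigurationError(
                "need either simulate=true or count tables in both "
                "condition_a_paths and condition_b_paths"
            )
        if self.min_cov < 0:
            raise ConfigurationError(f"min_cov must be >= 0, got {self.min_cov}")
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigurationError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")
        if not 0 <= self.min_delta < 1:
            raise ConfigurationError(f"min_delta must be in [0, 1), got {self.min_delta}")
        if self.min_cpg < 1:
            raise ConfigurationError(f"min_cpg must be >= 1, got {self.min_cpg}")
        if self.max_gap is not None and self.max_gap <= 0:
            raise ConfigurationError("max_gap must be positive (or null for no cap)")
        if self.bin_size < 1 or self.hexbin_bins < 1:
            raise ConfigurationError("bin_size and hexbin_bins must be positive")
        if self.dialect not in mio.DIALECTS:
            raise ConfigurationError(f"dialect must be one of {mio.DIALECTS}")


_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimConfig)}
_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file path or a plain dict.

    Unknown keys raise a warning naming the closest known key; type errors
    and contradictory settings are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "sim":
            unknown_sim = set(value) - _SIM_KEYS
            for k in unknown_sim:
                _warn_unknown(k, _SIM_KEYS)
            kwargs["sim"] = sim.SimConfig(**{k: v for k, v in value.items() if k in _SIM_KEYS})
        elif key in _TOP_KEYS:
            kwargs[key] = value
        else:
            _warn_unknown(key, _TOP_KEYS)
    try:
        config = PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    config.validate()
    if config.simulate:
        config.sim.validate()
    return config


def _warn_unknown(key: str, known: set[str]) -> None:
    near = difflib.get_close_matches(key, known, n=1)
    hint = f"; did you mean {near[0]!r}?" if near else ""
    log.warning("unknown config key %r ignored%s", key, hint)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}

    truth = None
    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        log.info("simulating reference and methylomes (seed=%d)", config.seed)
        refmap = sim.simulate_reference(sim_cfg)
        meth_a, meth_b, truth = sim.simulate_methylomes(refmap, sim_cfg)
        counts["n_cpg_reference"] = refmap.n_cpg
        mio.write_bed_features(refmap.islands, out / "islands.bed")
        mio.write_dmr_bed(
            [
                dmr_mod.DMR(r.chrom, r.start, r.end, sim_cfg.dmr_n_cpg, r.direction, r.true_delta, 0.0)
                for r in truth.regions.itertuples(index=False)
            ],
            out / "truth_regions.bed",
        )
        truth.to_json(out / "truth.json")
        conv = sim.spikein_conversion_efficiency(meth_a + meth_b)
        counts["spikein_conversion_efficiency"] = conv
        log.info("spike-in conversion efficiency: %.4f", conv)
        exclude = [refmap.spikein_chrom]
    else:
        log.info("reading %d + %d count tables", len(config.condition_a_paths), len(config.condition_b_paths))
        meth_a = [
            mio.read_cpg_counts(p, config.dialect, condition="A", replicate=i + 1)
            for i, p in enumerate(config.condition_a_paths)
        ]
        meth_b = [
            mio.read_cpg_counts(p, config.dialect, condition="B", replicate=i + 1)
            for i, p in enumerate(config.condition_b_paths)
        ]
        exclude = []

    log.info("stage: per-CpG differential testing")
    sites = diff.test_methylomes(
        meth_a,
        meth_b,
        min_cov=config.min_cov,
        fdr_threshold=config.fdr_threshold,
        min_delta=config.min_delta,
        exclude_chroms=exclude,
    )
    state_counts = sites["state"].value_counts().to_dict()
    counts["n_cpg_total"] = int(len(sites))
    counts["n_filtered"] = int(state_counts.get(diff.STATE_FILTERED, 0))
    counts["n_tested"] = counts["n_cpg_total"] - counts["n_filtered"]
    counts["n_hyper_cpg"] = int(state_counts.get(diff.STATE_HYPER, 0))
    counts["n_hypo_cpg"] = int(state_counts.get(diff.STATE_HYPO, 0))
    assert counts["n_filtered"] + counts["n_tested"] == counts["n_cpg_total"]
    log.info(
        "CpGs: %d total, %d tested, %d hyper, %d hypo",
        counts["n_cpg_total"],
        counts["n_tested"],
        counts["n_hyper_cpg"],
        counts["n_hypo_cpg"],
    )
    diff.write_diffsites_tsv(sites, out / "diffsites.tsv")

    log.info("stage: DMR calling (min_cpg=%d, max_gap=%s)", config.min_cpg, config.max_gap)
    dmrs = dmr_mod.call_dmrs(sites, min_cpg=config.min_cpg, max_gap=config.max_gap)
    summary = dmr_mod.summarize_dmrs(dmrs)
    counts.update({f"dmr_{k}": v for k, v in summary.items()})
    log.info("DMRs: %(n_total)d total = %(n_hyper)d hyper + %(n_hypo)d hypo", summary)
    mio.write_dmr_bed(dmrs, out / "dmrs.bed")
    with open(out / "dmr_summary.tsv", "w") as fh:
        fh.write("n_total\tn_hyper\tn_hypo\n")
        fh.write(f"{summary['n_total']}\t{summary['n_hyper']}\t{summary['n_hypo']}\n")

    log.info("stage: global methylation shift (bin_size=%d)", config.bin_size)
    try:
        shift = diff.global_methylation_shift(
            meth_a, meth_b, bin_size=config.bin_size, min_cov=config.min_cov, exclude_chroms=exclude
        )
        with open(out / "global_shift.tsv", "w") as fh:
            fh.write("mean_a\tmean_b\tmean_difference\tn_cpg_used\tbin_size\tn_bins\tstatistic\tp\n")
            fh.write(
                f"{shift.mean_a:.6f}\t{shift.mean_b:.6f}\t{shift.mean_difference:.6f}\t"
                f"{shift.n_cpg_used}\t{shift.bin_size}\t{shift.n_bins}\t"
                f"{shift.statistic:.6f}\t{shift.p:.6g}\n"
            )
        counts["global_mean_difference"] = shift.mean_difference
        counts["global_shift_p"] = shift.p
    except ValueError as exc:
        log.warning("global shift skipped: %s", exc)

    hexbin = diff.methylation_hexbin(
        meth_a, meth_b, n_bins=config.hexbin_bins, min_cov=config.min_cov, exclude_chroms=exclude
    )
    np.savetxt(out / "hexbin.tsv", hexbin, fmt="%d", delimiter="\t")

    for class_name, path in sorted(config.feature_paths.items()):
        fs = mio.read_bed_features(path, class_name)
        prof = feat_mod.dmr_direction_split(dmrs, fs)
        feat_mod.profiles_to_tsv(
            pd.DataFrame([dataclasses.asdict(prof)]), out / f"feature_profile_{class_name}.tsv"
        )
        log.info("feature %s: %d hyper / %d hypo DMRs", class_name, prof.n_hyper, prof.n_hypo)
    if config.chromhmm_path:
        fs = mio.read_bed_features(config.chromhmm_path, "chromhmm")
        prof = feat_mod.state_methylation_profile(sites, fs)
        feat_mod.profiles_to_tsv(prof, out / "feature_profile_chromhmm.tsv")
    if config.tfbs_path:
        fs = mio.read_bed_features(config.tfbs_path, "tfbs")
        prof = feat_mod.tf_site_profile(sites, fs)
        feat_mod.profiles_to_tsv(prof, out / "feature_profile_tfbs.tsv")

    manifest = {
        "dmrkit_version": __version__,
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_to_jsonable(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["sim"]["baseline_meth_island"] = list(d["sim"]["baseline_meth_island"])
    d["sim"]["baseline_meth_background"] = list(d["sim"]["baseline_meth_background"])
    return d
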