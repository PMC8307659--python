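"""Interval overlap engine, proportion statistics, and feature profiles."""

import numpy as np
import pandas as pd
import pytest

from dmrkit import features as feat
from dmrkit.dmr import DMR
from dmrkit.io import FeatureSet, ValidationError


def fs(rows, class_name="x"):
    return FeatureSet(class_name, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def overlap_oracle(items, intervals):
    """All-pairs half-open intersection test."""
    out = []
    for chrom, s, e in items:
        hits = [lab for c2, s2, e2, lab in intervals if c2 == chrom and s < e2 and s2 < e]
        out.append(sorted(hits, key=str))
    return out


class TestAnnotateOverlap:
    def test_one_bp_intersection(self):
        f = fs([("chr1", 199, 300, "f")])
        assert feat.annotate_overlap([("chr1", 100, 200)], f) == [["f"]]

    def test_half_open_shared_endpoint_no_overlap(self):
        f = fs([("chr1", 200, 300, "f")])
        assert feat.annotate_overlap([("chr1", 100, 200)], f) == [[]]

    def test_position_is_length_one_interval(self):
        f = fs([("chr1", 100, 200, "f")])
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [199, 200]})
        assert feat.annotate_overlap(df, f) == [["f"], []]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n_items, n_feats = rng.integers(1, 25, 2)
            grid = 40  # coarse grid forces shared endpoints
            items = []
            for _ in range(n_items):
                s = int(rng.integers(0, grid))
                items.append((rng.choice(["chr1", "chr2"]), s, s + int(rng.integers(1, 8))))
            ivs = []
            for i in range(n_feats):
                s = int(rng.integers(0, grid))
                ivs.append((rng.choice(["chr1", "chr2"]), s, s + int(rng.integers(1, 8)), f"f{i}"))
            f = fs(ivs)
            assert feat.annotate_overlap(items, f) == overlap_oracle(items, ivs)


class TestHyperFraction:
    def test_promoter_worked_counts(self):
        prof = feat.hyper_fraction(89, 48)
        assert prof.prop_hyper == pytest.approx(89 / 137, abs=1e-12)
        assert prof.ci_low <= prof.prop_hyper <= prof.ci_high

    def test_island_worked_counts(self):
        prof = feat.hyper_fraction(99, 29)
        assert prof.prop_hyper == pytest.approx(99 / 128, abs=1e-12)

    def test_all_hypo_boundary(self):
        prof = feat.hyper_fraction(0, 10)
        assert prof.prop_hyper == 0.0
        assert prof.ci_low == 0.0

    def test_empty_is_missing_not_zero(self):
        prof = feat.hyper_fraction(0, 0)
        assert np.isnan(prof.prop_hyper) and np.isnan(prof.ci_low)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            feat.hyper_fraction(-1, 5)

    def test_ci_narrows_with_n_point_estimate_invariant(self):
        small = feat.hyper_fraction(6, 4)
        big = feat.hyper_fraction(600, 400)
        assert small.prop_hyper == pytest.approx(big.prop_hyper)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)


def diffsites(rows):
    """rows: (chrom, pos, state)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "state"])
    df["delta"] = df["state"].map({"hyper": 0.3, "hypo": -0.3}).fillna(0.0)
    df["q"] = 0.05
    return df


class TestStateProfile:
    def build(self, rng, n_per_chrom=400, n_chroms=8, hypo_state_frac=0.8):
        """One state ('Skew') dominated by hypo CpGs, one balanced ('Flat')."""
        rows, ivs = [], []
        for ci in range(n_chroms):
            chrom = f"chr{ci + 1}"
            ivs.append((chrom, 0, 10_000, "Skew"))
            ivs.append((chrom, 10_000, 20_000, "Flat"))
            for i in range(n_per_chrom):
                pos = int(rng.integers(0, 10_000))
                state = "hypo" if rng.random() < hypo_state_frac * 0.2 else (
                    "hyper" if rng.random() < 0.05 else "not_significant"
                )
                rows.append((chrom, pos, state))
            for i in range(n_per_chrom):
                pos = int(rng.integers(10_000, 20_000))
                r = rng.random()
                state = "hyper" if r < 0.05 else ("hypo" if r < 0.10 else "not_significant")
                rows.append((chrom, pos, state))
        return diffsites(rows), fs(ivs, "chromhmm")

    def test_skewed_state_detected(self, rng):
        sites, seg = self.build(rng)
        prof = feat.state_methylation_profile(sites, seg).set_index("class_name")
        assert prof.loc["Skew", "prop_hyper"] < 0.5
        assert prof.loc["Skew", "p"] < 0.05
        assert prof.loc["Skew", "n_hyper"] + prof.loc["Skew", "n_hypo"] <= prof.loc["Skew", "n_cpg_tested"]

    def test_state_without_significant_cpgs_is_missing(self):
        sites = diffsites([("chr1", 5, "not_significant"), ("chr1", 15, "hyper")])
        seg = fs([("chr1", 0, 10, "Empty"), ("chr1", 10, 20, "Hit")], "chromhmm")
        prof = feat.state_methylation_profile(sites, seg).set_index("class_name")
        assert np.isnan(prof.loc["Empty", "prop_hyper"]) and np.isnan(prof.loc["Empty", "p"])
        assert prof.loc["Hit", "n_hyper"] == 1

    def test_tiling_states_conserve_counts(self, rng):
        sites, seg = self.build(rng)
        prof = feat.state_methylation_profile(sites, seg)
        sig = sites[sites["state"].isin(["hyper", "hypo"])]
        assert (prof["n_hyper"] + prof["n_hypo"]).sum() == len(sig)

    def test_permuted_labels_approach_genome_fraction(self, rng):
        sites, seg = self.build(rng)
        shuffled = sites.copy()
        shuffled["pos"] = rng.permutation(shuffled["pos"].to_numpy())
        shuffled = shuffled.sort_values(["chrom", "pos"]).reset_index(drop=True)
        prof = feat.state_methylation_profile(shuffled, seg).set_index("class_name")
        sig = sites[sites["state"].isin(["hyper", "hypo"])]
        genome_frac = (sig["state"] == "hyper").mean()
        for state in ("Skew", "Flat"):
            assert prof.loc[state, "prop_hyper"] == pytest.approx(genome_frac, abs=0.1)


class TestTfProfile:
    def test_tf_over_hypo_sites_ranks_low(self):
        sites = diffsites(
            [("chr1", p, "hypo") for p in range(0, 50, 10)]
            + [("chr1", p, "hyper") for p in range(100, 150, 10)]
        )
        tfbs = fs([("chr1", 0, 50, "OCT4"), ("chr1", 100, 150, "CTCF")], "tfbs")
        prof = feat.tf_site_profile(sites, tfbs).set_index("class_name")
        assert prof.loc["OCT4", "prop_hyper"] == 0.0
        assert prof.loc["CTCF", "prop_hyper"] == 1.0
        assert list(prof.index) == ["CTCF", "OCT4"]  # ranked by prop_hyper

    def test_tf_without_sites_missing(self):
        sites = diffsites([("chr1", 5, "hyper")])
        tfbs = fs([("chr2", 0, 10, "NANOG")], "tfbs")
        prof = feat.tf_site_profile(sites, tfbs).set_index("class_name")
        assert np.isnan(prof.loc["NANOG", "prop_hyper"])

    def test_overlapping_tfbs_counted_per_tf(self):
        sites = diffsites([("chr1", 5, "hyper")])
        tfbs = fs([("chr1", 0, 10, "A"), ("chr1", 0, 10, "B")], "tfbs")
        prof = feat.tf_site_profile(sites, tfbs)
        assert (prof["n_hyper"] + prof["n_hypo"]).sum() == 2


class TestPartitionByActivity:
    def test_peak_overlap_makes_active(self):
        enh = fs([("chr1", 0, 500, None)], "enhancer")
        peaks = fs([("chr1", 100, 200, None)], "H3K27ac")
        active, inactive = feat.partition_by_activity(enh, peaks)
        assert len(active) == 1 and len(inactive) == 0

    def test_no_peaks_all_inactive(self):
        enh = fs([("chr1", 0, 500, None), ("chr2", 0, 100, None)], "enhancer")
        peaks = FeatureSet("H3K27ac", pd.DataFrame(columns=["chrom", "start", "end", "label"]))
        active, inactive = feat.partition_by_activity(enh, peaks)
        assert len(active) == 0 and len(inactive) == 2

    def test_partition_conserves_input(self, rng):
        ivs = []
        for i in range(60):
            s = int(rng.integers(0, 5_000))
            ivs.append(("chr1", s, s + int(rng.integers(1, 100)), None))
        enh = fs(ivs, "enhancer")
        pk = fs([("chr1", 1000, 1500, None)], "pk")
        active, inactive = feat.partition_by_activity(enh, pk)
        assert len(active) + len(inactive) == len(enh)


def test_promoters_from_tss_window_clipped_at_zero():
    fs_out = feat.promoters_from_tss([("chr1", 500), ("chr1", 5000)], window=1000)
    ivs = fs_out.intervals
    assert ivs[["start", "end"]].values.tolist() == [[0, 1500], [4000, 6000]]
    assert fs_out.class_name == "promoter"


class TestPriorityAssignment:
    def test_first_matching_class_wins(self):
        promoter = fs([("chr1", 0, 100, None)], "promoter")
        intron = fs([("chr1", 50, 400, None)], "intron")
        dmrs = [DMR("chr1", 60, 80, 2, "hyper", 0.2, 0.1), DMR("chr1", 200, 300, 2, "hypo", -0.2, 0.1)]
        out = feat.assign_priority(dmrs, [promoter, intron])
        assert out == ["promoter", "intron"]

    def test_fallback_is_intergenic(self):
        promoter = fs([("chr1", 0, 100, None)], "promoter")
        out = feat.assign_priority([DMR("chr2", 0, 10, 2, "hyper", 0.2, 0.1)], [promoter])
        assert out == ["intergenic"]
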