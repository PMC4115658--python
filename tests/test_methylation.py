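"""Windowed methylation, DMR calling, merging and profiles."""

import numpy as np
import pandas as pd
import pytest

from imprintomics.methylation import (
    annotate_dmrs,
    compare_windows,
    compare_strain_feature_methylation,
    merge_dmrs,
    metaprofile,
    region_wmeth,
    window_methylation,
)
from test_stats import oracle_fisher


class TestWindowMethylation:
    def test_single_site(self, cytosines_factory):
        cyt = cytosines_factory([("chr1", 50, "+", 5, 5, "CG")])
        out = window_methylation(cyt, context="CG")
        assert out["wmeth"].tolist() == [0.5]

    def test_weighted_not_per_site_mean(self, cytosines_factory):
        cyt = cytosines_factory(
            [("chr1", 50, "+", 4, 1, "CG"), ("chr1", 60, "+", 1, 19, "CG")]
        )
        out = window_methylation(cyt, context="CG")
        assert out["wmeth"].iloc[0] == pytest.approx(5 / 25)  # not 0.425

    def test_low_coverage_site_excluded(self, cytosines_factory):
        cyt = cytosines_factory(
            [("chr1", 50, "+", 4, 0, "CG"), ("chr1", 60, "+", 0, 10, "CG")]
        )
        out = window_methylation(cyt, context="CG")
        assert out["n_informative"].iloc[0] == 1
        assert out["wmeth"].iloc[0] == 0.0

    def test_overlapping_grid_membership(self, cytosines_factory):
        # site at 1-based 250 (0-based 249) belongs to windows [0,300) and [200,500)
        cyt = cytosines_factory([("chr1", 250, "+", 10, 0, "CG")])
        out = window_methylation(cyt, context="CG")
        assert set(zip(out["start"], out["end"])) == {(0, 300), (200, 500)}

    def test_split_records_aggregate(self, cytosines_factory):
        whole = cytosines_factory([("chr1", 50, "+", 6, 6, "CG")])
        split = cytosines_factory(
            [("chr1", 50, "+", 2, 4, "CG"), ("chr1", 50, "+", 4, 2, "CG")]
        )
        a = window_methylation(whole, context="CG")
        b = window_methylation(split, context="CG")
        pd.testing.assert_frame_equal(a, b)

    def test_bad_window_params(self, cytosines_factory):
        cyt = cytosines_factory([("chr1", 50, "+", 5, 5, "CG")])
        with pytest.raises(ValueError):
            window_methylation(cyt, window=0)


class TestCompareWindows:
    def make_pair(self, sites_a, sites_b, cytosines_factory):
        return cytosines_factory(sites_a), cytosines_factory(sites_b)

    def test_identical_samples_no_dmr(self, cytosines_factory):
        sites = [("chr1", p, "+", 8, 2, "CG") for p in (10, 50, 90)]
        a, b = self.make_pair(sites, sites, cytosines_factory)
        out = compare_windows(a, b, "CG")
        assert (out["diff"] == 0).all()
        np.testing.assert_allclose(out["p_raw"], 1.0, atol=1e-9)
        assert not out["is_dmr"].any()

    def test_clear_cg_dmr(self, cytosines_factory):
        a = cytosines_factory([("chr1", p, "+", 10, 0, "CG") for p in (10, 50, 90)])
        b = cytosines_factory([("chr1", p, "+", 0, 10, "CG") for p in (10, 50, 90)])
        out = compare_windows(a, b, "CG")
        row = out.iloc[0]
        assert row["diff"] == pytest.approx(1.0)
        assert row["n_shared"] == 3
        assert row["p_raw"] == pytest.approx(oracle_fisher(30, 0, 0, 30), rel=1e-9)
        assert bool(row["is_dmr"])

    def test_chh_needs_ten_shared_sites(self, cytosines_factory):
        # 9 shared CHH sites, diff well above 0.10 -> still no DMR
        a = cytosines_factory([("chr1", p, "+", 10, 0, "CHH") for p in range(10, 100, 10)])
        b = cytosines_factory([("chr1", p, "+", 0, 10, "CHH") for p in range(10, 100, 10)])
        out = compare_windows(a, b, "CHH")
        assert (out["n_shared"] == 9).all()
        assert not out["is_dmr"].any()

    def test_shared_site_restriction(self, cytosines_factory):
        # site at 90 informative only in sample a -> excluded from both sides
        a = cytosines_factory(
            [("chr1", 10, "+", 10, 0, "CG"), ("chr1", 90, "+", 10, 0, "CG")]
        )
        b = cytosines_factory(
            [("chr1", 10, "+", 0, 10, "CG"), ("chr1", 90, "+", 1, 3, "CG")]
        )
        out = compare_windows(a, b, "CG")
        assert (out["n_shared"] == 1).all()
        assert out["wmeth_a"].iloc[0] == 1.0

    def test_antisymmetry(self, rng, cytosines_factory):
        rows_a, rows_b = [], []
        for p in range(10, 2000, 37):
            rows_a.append(("chr1", p, "+", int(rng.integers(0, 12)), int(rng.integers(1, 12)), "CG"))
            rows_b.append(("chr1", p, "+", int(rng.integers(0, 12)), int(rng.integers(1, 12)), "CG"))
        a, b = cytosines_factory(rows_a), cytosines_factory(rows_b)
        ab = compare_windows(a, b, "CG")
        ba = compare_windows(b, a, "CG")
        np.testing.assert_allclose(ab["diff"], -ba["diff"], atol=1e-14)
        np.testing.assert_allclose(ab["p_raw"], ba["p_raw"], atol=1e-12)

    def test_thresholds_hold_on_output(self, rng, cytosines_factory):
        rows_a, rows_b = [], []
        for p in range(10, 5000, 23):
            level_a = 0.9 if (p // 600) % 2 else 0.1
            cov = int(rng.poisson(12)) + 5
            ma = rng.binomial(cov, level_a)
            mb = rng.binomial(cov, 0.1)
            rows_a.append(("chr1", p, "+", int(ma), int(cov - ma), "CG"))
            rows_b.append(("chr1", p, "+", int(mb), int(cov - mb), "CG"))
        out = compare_windows(cytosines_factory(rows_a), cytosines_factory(rows_b), "CG")
        called = out[out["is_dmr"]]
        assert len(called) > 0
        assert (called["q"] < 0.01).all()
        assert (called["diff"].abs() >= 0.35).all()
        assert (called["n_shared"] >= 3).all()


class TestMergeDmrs:
    def mk(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "context", "direction", "q", "diff"]
        ).assign(is_dmr=True)

    def test_overlap_union(self):
        out = merge_dmrs(self.mk([("chr1", 0, 300, "CG", 1, 1e-5, 0.5),
                                  ("chr1", 200, 500, "CG", 1, 1e-7, 0.6)]))
        assert out[["start", "end"]].values.tolist() == [[0, 500]]
        assert out["q"].iloc[0] == 1e-7
        assert out["max_abs_diff"].iloc[0] == 0.6

    def test_book_ended_merge(self):
        out = merge_dmrs(self.mk([("chr1", 0, 300, "CG", 1, 1e-5, 0.5),
                                  ("chr1", 300, 600, "CG", 1, 1e-5, 0.5)]))
        assert out[["start", "end"]].values.tolist() == [[0, 600]]

    def test_disjoint_stay_separate(self):
        out = merge_dmrs(self.mk([("chr1", 0, 300, "CG", 1, 1e-5, 0.5),
                                  ("chr1", 400, 700, "CG", 1, 1e-5, 0.5)]))
        assert len(out) == 2

    def test_opposite_directions_not_merged(self):
        out = merge_dmrs(self.mk([("chr1", 0, 300, "CG", 1, 1e-5, 0.5),
                                  ("chr1", 200, 500, "CG", -1, 1e-5, -0.5)]))
        assert len(out) == 2


class TestAnnotateDmrs:
    features = pd.DataFrame(
        {
            "feature_id": ["gene1", "te1"],
            "chrom": ["chr1", "chr1"],
            "start": [1000, 2000],
            "end": [2000, 2500],
            "feature_class": ["gene", "TE"],
        }
    )

    def dmrs(self, start, end):
        return pd.DataFrame(
            {"dmr_id": ["d1"], "chrom": ["chr1"], "start": [start], "end": [end]}
        )

    def test_inside_gene(self):
        annotated, summary = annotate_dmrs(self.dmrs(1200, 1500), self.features)
        assert annotated["features"].iloc[0] == "gene1"
        assert summary.set_index("feature_class").loc["gene", "n_features"] == 1

    def test_boundary_spanning_hits_both(self):
        annotated, _ = annotate_dmrs(self.dmrs(1900, 2100), self.features)
        assert set(annotated["features"].iloc[0].split(",")) == {"gene1", "te1"}

    def test_intergenic(self):
        annotated, summary = annotate_dmrs(self.dmrs(5000, 5300), self.features)
        assert annotated["features"].iloc[0] == ""
        assert summary.set_index("feature_class").loc["intergenic", "n_features"] == 1


class TestRegionWmeth:
    def test_two_sites(self, cytosines_factory):
        cyt = cytosines_factory(
            [("chr1", 11, "+", 10, 0, "CG"), ("chr1", 21, "+", 0, 10, "CG")]
        )
        assert region_wmeth(cyt, "chr1", 0, 100) == 0.5

    def test_all_below_coverage_missing(self, cytosines_factory):
        cyt = cytosines_factory([("chr1", 11, "+", 2, 1, "CG")])
        assert np.isnan(region_wmeth(cyt, "chr1", 0, 100))

    def test_single_site(self, cytosines_factory):
        cyt = cytosines_factory([("chr1", 11, "+", 7, 3, "CG")])
        assert region_wmeth(cyt, "chr1", 0, 100) == pytest.approx(0.7)

    def test_empty_region_raises(self, cytosines_factory):
        cyt = cytosines_factory([("chr1", 11, "+", 7, 3, "CG")])
        with pytest.raises(ValueError):
            region_wmeth(cyt, "chr1", 100, 100)


class TestMetaprofile:
    def asymmetric_sites(self, feature_start, feature_end):
        # increasing methylation left to right across flank+body+flank
        rows = []
        span_start = feature_start - 2000
        span_end = feature_end + 2000
        for i, p in enumerate(range(span_start, span_end, 100)):
            level = i / ((span_end - span_start) // 100)
            meth = int(round(level * 20))
            rows.append(("chr1", p + 1, "+", meth, 20 - meth, "CG"))
        return rows

    def test_single_plus_feature_identity(self, cytosines_factory):
        feats = pd.DataFrame(
            {"feature_id": ["f"], "chrom": ["chr1"], "start": [3000], "end": [5000],
             "strand": ["+"]}
        )
        cyt = cytosines_factory(self.asymmetric_sites(3000, 5000))
        prof = metaprofile(cyt, feats)
        vals = prof["wmeth"].to_numpy()
        assert (np.diff(vals[~np.isnan(vals)]) >= 0).all()

    def test_mean_of_two_features(self, cytosines_factory):
        feats = pd.DataFrame(
            {"feature_id": ["f1", "f2"], "chrom": ["chr1", "chr1"],
             "start": [3000, 13000], "end": [5000, 15000], "strand": ["+", "+"]}
        )
        rows = [("chr1", p + 1, "+", 4, 16, "CG") for p in range(1000, 7000, 50)]
        rows += [("chr1", p + 1, "+", 8, 12, "CG") for p in range(11000, 17000, 50)]
        prof = metaprofile(cytosines_factory(rows), feats)
        np.testing.assert_allclose(prof["wmeth"], 0.3, atol=1e-12)

    def test_minus_strand_reversed(self, cytosines_factory):
        cyt = cytosines_factory(self.asymmetric_sites(3000, 5000))
        plus = pd.DataFrame(
            {"feature_id": ["f"], "chrom": ["chr1"], "start": [3000], "end": [5000],
             "strand": ["+"]}
        )
        minus = plus.assign(strand="-")
        p_plus = metaprofile(cyt, plus)["wmeth"].to_numpy()
        p_minus = metaprofile(cyt, minus)["wmeth"].to_numpy()
        np.testing.assert_allclose(p_plus, p_minus[::-1], atol=1e-12)


class TestStrainComparison:
    def test_identical_strains_not_significant(self, rng):
        base = rng.uniform(0.2, 0.8, size=40)
        df = pd.DataFrame({"s1": base, "s2": base, "s3": base})
        out = compare_strain_feature_methylation(df)
        assert (out["mean_scaled_diff"] == 0).all()
        assert not out["significant"].any()

    def test_scaling_identity_half_level(self, rng):
        base = rng.uniform(0.4, 0.8, size=60)
        df = pd.DataFrame({"ref": base, "half": base * 0.5})
        out = compare_strain_feature_methylation(df, reference="ref")
        row = out.iloc[0]
        # relative difference of -50% of the reference mean
        assert row["mean_scaled_diff"] == pytest.approx(
            0.5 * base.mean() / base.mean(), rel=1e-12
        )
        assert row["significant"]

    def test_planted_reduction_recovered(self, rng):
        from imprintomics.synthetic import TruthConfig, simulate_methylome_pair

        cfg = TruthConfig(seed=11, chrom_length=60_000,
                          site_density={"CG": 0.05},
                          background_levels={"CG": 0.5})
        samples, _ = simulate_methylome_pair(cfg)
        # plant a 56% genome-wide reduction in the second sample
        reduced = samples["sample_b"].copy()
        keep = rng.random(len(reduced)) < 0.44
        reduced["count_unmethylated"] += np.where(keep, 0, reduced["count_methylated"])
        reduced["count_methylated"] = np.where(keep, reduced["count_methylated"], 0)
        feats = pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(30)], "chrom": "chr1",
             "start": np.arange(30) * 2000, "end": np.arange(30) * 2000 + 1500}
        )
        vals = {}
        for name, cyt in (("ref", samples["sample_a"]), ("low", reduced)):
            vals[name] = [
                region_wmeth(cyt, "chr1", int(f.start), int(f.end)) for f in feats.itertuples()
            ]
        out = compare_strain_feature_methylation(pd.DataFrame(vals), reference="ref")
        row = out.iloc[0]
        assert row["significant"]
        assert row["mean_scaled_diff"] == pytest.approx(0.56, abs=0.08)

    def test_too_few_features_raises(self):
        with pytest.raises(ValueError):
            compare_strain_feature_methylation(pd.DataFrame({"a": [0.5], "b": [0.4]}))
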