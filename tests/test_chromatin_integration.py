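"""Z-score standardization and Z-weighted nucleosome summaries."""

import numpy as np
import pandas as pd
import pytest

from methnuc import chromatin_integration as ci


def bedgraph(values, bin_width=200, chrom="chr1"):
    edges = np.arange(len(values) + 1) * bin_width
    return pd.DataFrame(
        {"chrom": chrom, "start": edges[:-1], "end": edges[1:], "value": values}
    )


class TestGenomeZscores:
    def test_two_bin_standardization(self):
        lengths = {"chr1": 400}
        zt = ci.genome_zscores(bedgraph([2, 4]), bedgraph([1, 1]), lengths)
        assert np.allclose(zt.bins["chr1"], [-1.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, 50)
        lengths = {"chr1": 50 * 200}
        zt = ci.genome_zscores(bedgraph(vals), bedgraph(np.ones(50)), lengths)
        z = zt.bins["chr1"]
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_location_invariance(self):
        lengths = {"chr1": 600}
        a = ci.genome_zscores(bedgraph([1, 5, 3]), bedgraph([1, 1, 1]), lengths)
        b = ci.genome_zscores(bedgraph([11, 15, 13]), bedgraph([11, 11, 11]), lengths)
        assert np.allclose(a.bins["chr1"], b.bins["chr1"])

    def test_zero_variance_rejected(self):
        lengths = {"chr1": 400}
        with pytest.raises(ValueError, match="variance"):
            ci.genome_zscores(bedgraph([1, 1]), bedgraph([1, 1]), lengths)

    def test_lookup_at_positions(self):
        lengths = {"chr1": 400}
        zt = ci.genome_zscores(bedgraph([2, 4]), bedgraph([1, 1]), lengths)
        assert np.allclose(zt.at("chr1", [0, 199, 200, 399]), [-1, -1, 1, 1])


class TestWeightedMeans:
    def test_single_worked_example(self):
        assert ci.weighted_mean_single([2, 5, 4], [1, 0, 3]) == pytest.approx(3.5)

    def test_equal_positive_z_reduces_to_arithmetic_mean(self):
        x = [1.0, 2.0, 6.0]
        assert ci.weighted_mean_single(x, [2, 2, 2]) == pytest.approx(np.mean(x))

    def test_no_positive_z_rejected(self):
        with pytest.raises(ValueError):
            ci.weighted_mean_single([1, 2], [-1, 0])

    def test_pair_worked_example(self):
        assert ci.weighted_mean_pair([1, 3], [2, 1], [1, 4]) == pytest.approx(2.0)

    def test_pair_reduces_to_single_when_z_equal(self):
        rng = np.random.default_rng(1)
        x, z = rng.normal(size=50), rng.normal(size=50)
        if not (z > 0).any():
            z[0] = 1.0
        assert ci.weighted_mean_pair(x, z, z) == pytest.approx(
            ci.weighted_mean_single(x, z), abs=1e-12
        )

    def test_pair_gating_excludes_nonpositive_either_side(self):
        # second entry has zA = 0 and is excluded despite zB > 0
        assert ci.weighted_mean_pair([1, 100], [2, 0], [1, 5]) == 1.0

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            n = rng.integers(2, 30)
            x = rng.normal(size=n)
            za = rng.normal(size=n)
            zb = rng.normal(size=n)
            if (za > 0).any():
                num = den = 0.0
                for i in range(n):
                    if za[i] > 0:
                        num += x[i] * za[i]
                        den += za[i]
                assert ci.weighted_mean_single(x, za) == pytest.approx(
                    num / den, abs=1e-12
                )
            if ((za > 0) & (zb > 0)).any():
                num = den = 0.0
                for i in range(n):
                    if za[i] > 0 and zb[i] > 0:
                        w = min(za[i], zb[i])
                        num += x[i] * w
                        den += w
                assert ci.weighted_mean_pair(x, za, zb) == pytest.approx(
                    num / den, abs=1e-12
                )

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x, za, zb = rng.normal(size=40), rng.normal(size=40), rng.normal(size=40)
        za[0] = zb[0] = 1.0
        for c in (0.5, 3.0, 1e6):
            assert ci.weighted_mean_single(x, c * za) == pytest.approx(
                ci.weighted_mean_single(x, za), rel=1e-12
            )
            assert ci.weighted_mean_pair(x, c * za, c * zb) == pytest.approx(
                ci.weighted_mean_pair(x, za, zb), rel=1e-12
            )


class TestSummaryTable:
    def make_features(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        mcpg = rng.integers(0, 6, size=n)
        occ = 0.2 + 0.1 * mcpg + rng.normal(0, 0.01, n)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n) * 200 + 100,
                "u_gch_core": occ,
                "mcpg_int": mcpg,
                "m_hcg_core": 0.5,
                "excluded": False,
            }
        )

    def ztrack_on(self, mask, n=200):
        z = np.where(mask, 2.0, -1.0)
        # already standardized enough for weighting semantics
        return ci.ZScoreTrack({"chr1": z}, 200, 0.0, 1.0)

    def test_painted_mark_tops_both_columns(self):
        feats = self.make_features()
        high = (feats["mcpg_int"] >= 4).to_numpy()
        low = (feats["mcpg_int"] <= 1).to_numpy()
        table = ci.modification_summary_table(
            feats, {"high_mark": self.ztrack_on(high), "low_mark": self.ztrack_on(low)},
            pairs=[],
        )
        table = table.set_index("name")
        assert table.loc["high_mark", "w_mcpg"] > table.loc["low_mark", "w_mcpg"]
        assert table.loc["high_mark", "w_occupancy"] > table.loc["low_mark", "w_occupancy"]

    def test_all_nonpositive_mark_has_no_row(self):
        feats = self.make_features()
        never = self.ztrack_on(np.zeros(len(feats), dtype=bool))
        table = ci.modification_summary_table(feats, {"dead": never}, pairs=[])
        assert len(table) == 0

    def test_self_pair_equals_single(self):
        feats = self.make_features()
        mask = (feats["mcpg_int"] >= 2).to_numpy()
        zt = self.ztrack_on(mask)
        table = ci.modification_summary_table(
            feats, {"a": zt, "b": zt}, pairs=[("a", "b")]
        ).set_index("name")
        assert table.loc["a+b", "w_mcpg"] == pytest.approx(table.loc["a", "w_mcpg"])

    def test_outlier_mark_flagged_by_studentized_residual(self):
        feats = self.make_features(n=400)
        # decoupled subpopulation: low mCpG yet high occupancy
        decoupled_rows = feats.index[-40:]
        feats.loc[decoupled_rows, "mcpg_int"] = 0
        feats.loc[decoupled_rows, "u_gch_core"] = 0.75
        marks = {
            f"band{k}": self.ztrack_on(
                ((feats["mcpg_int"] == k)
                 & ~feats.index.isin(decoupled_rows)).to_numpy()
            )
            for k in range(6)
        }
        marks["decoupled"] = self.ztrack_on(feats.index.isin(decoupled_rows))
        table = ci.modification_summary_table(feats, marks, pairs=[])
        flagged = ci.regression_outliers(table)
        by_name = flagged.set_index("name")
        assert by_name.loc["decoupled", "outlier"]
        assert not by_name.drop("decoupled")["outlier"].any()
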