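"""Core/linker per-nucleosome statistics and the mCpG density ratio."""

import numpy as np
import pandas as pd
import pytest

from methnuc import (
    genome_context as gc,
    nucleosome_features as nf,
    read_midpoints as rm,
)


def genome_around_core(core_seq, pad="A", flank=200):
    """123-bp core embedded so that the dyad sits at position flank+61."""
    assert len(core_seq) == nf.CORE_BP
    seq = pad * flank + core_seq + pad * flank
    return gc.GenomeAssembly({"chr1": seq}), flank + nf.CORE_HALF


class TestCoreComposition:
    @pytest.mark.parametrize(
        "core,expected",
        [
            ("G" * 123, (0, 123, 123)),
            ("CG" * 61 + "C", (61, 123, 1)),
            ("A" * 123, (0, 0, 0)),
        ],
    )
    def test_counting_definitions(self, core, expected):
        genome, dyad = genome_around_core(core)
        assert nf.core_composition(dyad, "chr1", genome) == expected

    def test_truncated_window_rejected(self):
        genome = gc.GenomeAssembly({"chr1": "A" * 200})
        with pytest.raises(ValueError):
            nf.core_composition(30, "chr1", genome)

    def test_vectorized_features_match_scalar_reference(self, sim, sim_midpoints):
        feats = nf.compute_features(sim_midpoints, sim.genome, sim.hcg.iloc[:0])
        rng = np.random.default_rng(1)
        for i in rng.choice(len(feats), size=10, replace=False):
            row = feats.iloc[i]
            ref = nf.core_composition(int(row["pos"]), row["chrom"], sim.genome)
            assert (row["n_cpg_core"], row["gc_core"], row["gc_minus_cpg_core"]) == ref


class TestCoreMethylation:
    def build(self, hcg_rows, gch_rows=None):
        genome, dyad = genome_around_core("A" * 123)
        mids = rm.MidpointSet(
            pd.DataFrame({"chrom": ["chr1"], "pos": [dyad], "weight": [1.0]})
        )
        cols = ["chrom", "pos", "strand", "context", "meth", "total"]
        gch_rows = gch_rows or [
            ["chr1", dyad - 5, "+", "GCH", 1, 2],
            ["chr1", dyad + 5, "+", "GCH", 1, 2],
        ]
        records = pd.DataFrame(hcg_rows + gch_rows, columns=cols)
        return nf.compute_features(mids, genome, records), dyad

    def test_pooled_count_fraction(self):
        feats, dyad = self.build(
            [["chr1", dyad_off, "+", "HCG", m, t]
             for dyad_off, m, t in [(261 - 10, 1, 2), (261 + 10, 2, 2)]]
        )
        assert feats["m_hcg_core"].iloc[0] == pytest.approx(0.75)
        assert not feats["excluded"].iloc[0]

    def test_single_informative_hcg_site_excluded(self):
        feats, dyad = self.build([["chr1", 261, "+", "HCG", 1, 2]])
        assert feats["excluded"].iloc[0]

    def test_zero_coverage_excluded(self):
        feats, dyad = self.build([])
        assert feats["excluded"].iloc[0]
        assert np.isnan(feats["m_hcg_core"].iloc[0])

    def test_occupancy_proxy_is_unmethylated_gch_fraction(self):
        feats, dyad = self.build(
            [["chr1", 261 - 3, "+", "HCG", 1, 2], ["chr1", 261 + 3, "+", "HCG", 1, 2]],
            gch_rows=[
                ["chr1", 261 - 5, "+", "GCH", 1, 4],
                ["chr1", 261 + 5, "+", "GCH", 0, 4],
            ],
        )
        assert feats["u_gch_core"].iloc[0] == pytest.approx(7 / 8)


class TestIntegerMcpg:
    @pytest.mark.parametrize(
        "n,f,expected",
        [
            (4, 1.0, (4, 0)),
            (5, 0.52, (3, 2)),   # 2.6 -> 3, 2.4 -> 2
            (3, 0.0, (0, 3)),
            (1, 0.5, (1, 1)),    # ties round half away from zero
        ],
    )
    def test_rounding_rule(self, n, f, expected):
        m, u = nf.integer_mcpg(n, f)
        assert (int(m), int(u)) == expected

    def test_sum_within_one_of_cpg_count(self, sim_features):
        ok = sim_features[~sim_features["excluded"]]
        diff = ok["mcpg_int"] + ok["ucpg_int"] - ok["n_cpg_core"]
        assert diff.abs().max() <= 1


class TestDensityRatio:
    def test_equal_densities_cancel_exactly(self):
        # identical per-bp CpG density (0.1/bp) and equal fractions
        assert nf.density_ratio(0.6, 12.3, 0.6, 6.2) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example(self):
        ratio = nf.density_ratio(0.8, 6, 0.4, 2)
        assert ratio == pytest.approx((4.8 / 123) / (0.8 / 62), abs=1e-12)
        assert round(ratio, 3) == 3.024

    def test_zero_linker_methylation_undefined(self):
        assert np.isnan(nf.density_ratio(0.8, 6, 0.0, 2))

    def test_ratio_exclusion_flags_on_simulated_data(self, sim_features):
        bad = sim_features["ratio_excluded"]
        assert sim_features.loc[bad, "density_ratio"].isna().all()
        good = sim_features.loc[~bad]
        assert (good["density_ratio"] > 0).all()
        assert (good["informative_hcg_linker"] >= 2).all()
        assert (good["n_cpg_linker"] >= 1).all()


class TestPartition:
    def test_bin_membership_and_overflow(self, sim_features):
        bins = nf.partition_by_core_cpg(sim_features)
        assert (bins["3"]["n_cpg_core"] == 3).all()
        assert (bins[">=10"]["n_cpg_core"] >= 10).all()

    def test_partition_is_disjoint_and_exhaustive(self, sim_features):
        bins = nf.partition_by_core_cpg(sim_features)
        total = sum(len(b) for b in bins.values())
        assert total == len(sim_features)
        all_idx = np.concatenate([b.index.to_numpy() for b in bins.values()])
        assert len(np.unique(all_idx)) == total


class TestDistributionSummary:
    def test_interpolated_quartiles(self):
        s = nf.distribution_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert s.n_outliers == 0

    def test_single_value(self):
        s = nf.distribution_summary([7.0])
        assert (s.q1, s.median, s.q3, s.whisker_lo, s.whisker_hi) == (7, 7, 7, 7, 7)

    def test_constant_list_has_no_outliers(self):
        s = nf.distribution_summary([2.0] * 10)
        assert s.q3 - s.q1 == 0 and s.n_outliers == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nf.distribution_summary([])


def test_gc_definitions_reconcile(sim, sim_midpoints):
    """G+C bases split exactly into CpG-participating and CpG-free bases;
    the two CpG-free definitions differ only by window-straddling CpGs."""
    empty = sim.hcg.iloc[:0]
    genome_def = nf.compute_features(sim_midpoints, sim.genome, empty)
    window_def = nf.compute_features(
        sim_midpoints, sim.genome, empty, gc_within_window_only=True
    )
    assert (window_def["gc_minus_cpg_core"]
            == window_def["gc_core"] - 2 * window_def["n_cpg_core"]).all()
    diff = window_def["gc_minus_cpg_core"] - genome_def["gc_minus_cpg_core"]
    assert diff.between(0, 2).all()


def test_occupancy_independent_of_linker_cpg_density(sim, sim_features):
    """At fixed true core methylated-CpG count, the occupancy proxy does not
    track linker CpG density (core mCpG, not linker, drives occupancy)."""
    from scipy import stats

    dyads = np.array(sim.truth["dyads"])
    mcpg_true = np.array(sim.truth["mcpg_true"])
    ok = sim_features[~sim_features["excluded"]]
    idx = np.clip(np.searchsorted(dyads, ok["pos"].to_numpy()), 1, len(dyads) - 1)
    left = idx - 1
    nearer_right = np.abs(dyads[idx] - ok["pos"].to_numpy()) < np.abs(
        dyads[left] - ok["pos"].to_numpy()
    )
    nearest = np.where(nearer_right, idx, left)
    # the heterochromatin-like subpopulation is the planted exception where
    # occupancy is decoupled from methylation; exclude it here
    hetero = np.array(sim.truth["heterochromatin"])[nearest]
    ok = ok.assign(truth_m=mcpg_true[nearest], nuc=nearest)[~hetero]
    # one row per nucleosome: reads of the same nucleosome share evidence
    ok = ok.groupby("nuc").first()
    rhos, sizes = [], []
    for m, grp in ok.groupby("truth_m"):
        if len(grp) < 50:
            continue
        rho, _ = stats.spearmanr(grp["n_cpg_linker"], grp["u_gch_core"])
        rhos.append(rho)
        sizes.append(len(grp))
    assert sum(sizes) > 500
    combined = np.average(rhos, weights=sizes)
    assert abs(combined) < 0.08
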