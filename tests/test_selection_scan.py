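import numpy as np
import pandas as pd
import pytest

from acidpipe import selection_scan as ss
from acidpipe import synthetic_data as sd
from acidpipe.io_core import GeneModel, PopulationMap, VariantTable


def make_variants(genotypes, pos=None, chrom="chr1", qual=None, info=None):
    g = np.asarray(genotypes, dtype=np.int8)
    n = g.shape[0]
    if pos is None:
        pos = np.arange(1, n + 1) * 100
    individuals = [f"i{k}" for k in range(g.shape[1])]
    if info is None:
        info = pd.DataFrame(
            {k: [np.nan] * n for k in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")}
        )
    return VariantTable(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
        genotypes=g,
        individuals=individuals,
        qual=np.asarray(qual if qual is not None else [100.0] * n, dtype=float),
        info=info,
    )


def two_pop_map(n_a, n_b):
    return PopulationMap(
        {f"i{k}": ("A" if k < n_a else "B") for k in range(n_a + n_b)}
    )


def wc_theta_oracle(ga, gb):
    """Independent transcription of the 1984 two-population components."""
    ga = [g for g in ga if g >= 0]
    gb = [g for g in gb if g >= 0]
    n1, n2 = len(ga), len(gb)
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestHardFilter:
    def base_info(self, n):
        return pd.DataFrame(
            {
                "QD": [10.0] * n,
                "FS": [5.0] * n,
                "MQ": [55.0] * n,
                "MQRankSum": [0.0] * n,
                "ReadPosRankSum": [0.0] * n,
            }
        )

    def test_low_mq_dropped(self):
        info = self.base_info(2)
        info.loc[0, "MQ"] = 39.9
        vt = make_variants(np.zeros((2, 4)), info=info)
        passing, counts = ss.hard_filter(vt)
        assert passing.n_sites == 1
        assert counts["MQ"] == 1

    def test_boundary_values_kept(self):
        info = pd.DataFrame(
            {
                "QD": [2.0],
                "FS": [60.0],
                "MQ": [40.0],
                "MQRankSum": [-12.5],
                "ReadPosRankSum": [-8.0],
            }
        )
        vt = make_variants(np.zeros((1, 4)), qual=[30.0], info=info)
        passing, counts = ss.hard_filter(vt)
        assert passing.n_sites == 1
        assert counts["total_dropped"] == 0

    def test_missing_annotation_passes(self):
        vt = make_variants(np.zeros((3, 4)))  # all INFO NaN
        passing, counts = ss.hard_filter(vt)
        assert passing.n_sites == 3

    def test_synthetic_labels_match_exactly(self):
        spec = sd.SimulationSpec(
            n_genes=400, module_sizes=(60, 50), n_snps=800,
            n_tca_genes=15, n_transporter_genes=8, n_tf=20, rng_seed=7,
        )
        vt, popmap, truth = sd.simulate_genotypes(spec)
        passing, counts = ss.hard_filter(vt)
        expected_drop = sum(1 for lbl in truth.info_fail_label if lbl)
        assert counts["total_dropped"] == expected_drop
        keep_mask = np.array([not lbl for lbl in truth.info_fail_label])
        np.testing.assert_array_equal(passing.pos, vt.pos[keep_mask])


class TestWcFst:
    def test_complete_fixation(self):
        g = np.array([[0] * 10 + [2] * 10])
        vt = make_variants(g)
        out = ss.wc_fst_per_snp(vt, two_pop_map(10, 10), "A", "B")
        assert out.theta.iloc[0] == pytest.approx(1.0)

    def test_identical_configurations(self):
        # identical genotype configurations: no among-population variance
        # (s2 = 0), so the finite-sample estimate is non-positive and small
        # at realistic sample sizes
        g = np.array([[0, 1, 2] * 10 + [0, 1, 2] * 10])
        vt = make_variants(g)
        out = ss.wc_fst_per_snp(vt, two_pop_map(30, 30), "A", "B")
        a, b, c = wc_theta_oracle(g[0, :30], g[0, 30:])
        assert out.a.iloc[0] == pytest.approx(a, abs=1e-12)
        assert out.theta.iloc[0] <= 0.0
        assert abs(out.theta.iloc[0]) < 0.05

    def test_monomorphic_undefined(self):
        g = np.zeros((1, 8))
        vt = make_variants(g)
        out = ss.wc_fst_per_snp(vt, two_pop_map(4, 4), "A", "B")
        assert not out.defined.iloc[0]

    def test_random_sites_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_a, n_b = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            g = rng.integers(0, 3, size=(1, n_a + n_b))
            if len(set(g.flatten())) == 1 and g.flatten()[0] != 1:
                continue
            vt = make_variants(g)
            out = ss.wc_fst_per_snp(vt, two_pop_map(n_a, n_b), "A", "B")
            a, b, c = wc_theta_oracle(g[0, :n_a], g[0, n_a:])
            assert out.a.iloc[0] == pytest.approx(a, abs=1e-10)
            assert out.b.iloc[0] == pytest.approx(b, abs=1e-10)
            assert out.c.iloc[0] == pytest.approx(c, abs=1e-10)
            if (a + b + c) != 0:
                assert out.theta.iloc[0] == pytest.approx(a / (a + b + c), abs=1e-10)
                assert out.theta.iloc[0] <= 1.0 + 1e-12

    def test_missing_genotypes_excluded(self):
        g = np.array([[0, 0, -1, 2, 2, -1]])
        vt = make_variants(g)
        out = ss.wc_fst_per_snp(vt, two_pop_map(3, 3), "A", "B")
        a, b, c = wc_theta_oracle([0, 0], [2, 2])
        assert out.theta.iloc[0] == pytest.approx(a / (a + b + c), abs=1e-10)


class TestWindowedScan:
    def per_snp_frame(self, pos, a, b, c):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(pos),
                "pos": pos,
                "a": a,
                "b": b,
                "c": c,
                "theta": np.array(a) / (np.array(a) + np.array(b) + np.array(c)),
                "defined": [True] * len(pos),
            }
        )

    def test_window_enumeration(self):
        per = self.per_snp_frame([100], [1.0], [0.0], [1.0])
        scan = ss.windowed_fst_scan(per, {"chr1": 12_000}, 10_000, 1_000, 1)
        assert len(scan.windows) == 12
        starts = scan.windows.start.tolist()
        assert starts == list(range(1, 12000, 1000))
        assert scan.windows.end.iloc[-1] == 12_000  # truncated
        assert scan.windows.end.iloc[0] == 10_000

    def test_ratio_of_sums(self):
        pos = [500, 1500, 2500, 3500]
        per = self.per_snp_frame(pos, [1.0] * 4, [0.0] * 4, [1.0] * 4)
        scan = ss.windowed_fst_scan(per, {"chr1": 4000}, 4000, 4000, 3)
        assert scan.windows.value.iloc[0] == pytest.approx(0.5)

    def test_min_snps_rule(self):
        per = self.per_snp_frame([100], [1.0], [0.0], [1.0])
        scan = ss.windowed_fst_scan(per, {"chr1": 5000}, 5000, 5000, 3)
        assert not scan.windows.defined.iloc[0]

    def test_matches_brute_force_window_construction(self):
        rng = np.random.default_rng(1)
        n = 60
        pos = np.sort(rng.choice(np.arange(1, 30_001), size=n, replace=False))
        a = rng.uniform(0, 1, n)
        b = rng.uniform(0, 1, n)
        c = rng.uniform(0, 1, n)
        per = self.per_snp_frame(pos, a, b, c)
        scan = ss.windowed_fst_scan(per, {"chr1": 30_000}, 10_000, 2_000, 2)
        for row in scan.windows.itertuples():
            in_win = (pos >= row.start) & (pos <= row.end)
            if in_win.sum() >= 2 and (a[in_win] + b[in_win] + c[in_win]).sum() != 0:
                expected = a[in_win].sum() / (a + b + c)[in_win].sum()
                assert row.value == pytest.approx(expected)
                assert row.n_snps == in_win.sum()
            else:
                assert not row.defined


@pytest.fixture(scope="module")
def genotype_fixture():
    spec = sd.SimulationSpec(rng_seed=1)
    vt, popmap, truth = sd.simulate_genotypes(spec)
    passing, _ = ss.hard_filter(vt)
    return spec, passing, popmap, truth


class TestXpclr:
    def test_identical_populations_zero(self, genotype_fixture):
        spec, passing, popmap, _ = genotype_fixture
        # object pop == reference pop -> matched frequencies -> all scores 0
        scan = ss.xpclr_window_score(
            passing,
            popmap,
            {"chr1": spec.chromosome_length_bp},
            ref_pop="POP_BRET",
            obj_pop="POP_BRET",
            omega=0.1,
        )
        defined = scan.windows[scan.windows.defined]
        assert np.allclose(defined.value, 0.0)

    def test_doubling_omega_keeps_matched_scores_at_zero(self, genotype_fixture):
        spec, passing, popmap, _ = genotype_fixture
        cl = {"chr1": spec.chromosome_length_bp}
        s1 = ss.xpclr_window_score(passing, popmap, cl, ref_pop="POP_BRET",
                                   obj_pop="POP_BRET", omega=0.1)
        s2 = ss.xpclr_window_score(passing, popmap, cl, ref_pop="POP_BRET",
                                   obj_pop="POP_BRET", omega=0.2)
        d1 = s1.windows[s1.windows.defined].value
        d2 = s2.windows[s2.windows.defined].value
        assert (d2 <= d1 + 1e-9).all()

    def test_score_nonnegative_and_order_invariant(self, genotype_fixture):
        spec, passing, popmap, _ = genotype_fixture
        scan = ss.xpclr_window_score(passing, popmap, {"chr1": spec.chromosome_length_bp})
        defined = scan.windows[scan.windows.defined]
        assert (defined.value >= 0).all()

    def test_planted_sweep_center_recovered(self):
        hits = 0
        n_seeds = 8
        for seed in range(1, n_seeds + 1):
            spec = sd.SimulationSpec(rng_seed=seed)
            vt, popmap, truth = sd.simulate_genotypes(spec)
            passing, _ = ss.hard_filter(vt)
            scan = ss.xpclr_window_score(
                passing, popmap, {"chr1": spec.chromosome_length_bp}
            )
            d = scan.windows[scan.windows.defined]
            best = d.loc[d.value.idxmax()]
            lo, hi = truth.sweep_interval
            hits += (best.start <= hi) and (best.end >= lo)
        assert hits >= 0.9 * n_seeds


class TestLdDecay:
    def test_duplicated_snp_full_r2(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 12)
        g = np.vstack([col, col])
        vt = make_variants(g, pos=[1000, 6000])
        popmap = PopulationMap({f"i{k}": "P" for k in range(12)})
        curve = ss.ld_decay(vt, popmap, "P", max_dist_bp=10_000, bin_bp=1000)
        assert curve.mean_r2.iloc[0] == pytest.approx(1.0)
        assert curve.bin_midpoint_bp.iloc[0] == 4500.0

    def test_independent_snps_near_bias_floor(self):
        rng = np.random.default_rng(1)
        n_ind = 30
        n_snp = 80
        g = rng.binomial(2, 0.5, size=(n_snp, n_ind)).astype(np.int8)
        vt = make_variants(g, pos=np.arange(1, n_snp + 1) * 10)
        popmap = PopulationMap({f"i{k}": "P" for k in range(n_ind)})
        curve = ss.ld_decay(vt, popmap, "P", max_dist_bp=1000, bin_bp=1000)
        floor = 1.0 / (n_ind - 1)
        assert curve.n_pairs.sum() >= 1000
        mean = (curve.mean_r2 * curve.n_pairs).sum() / curve.n_pairs.sum()
        assert mean == pytest.approx(floor, abs=0.01)

    def test_domesticated_decays_slower_than_wild(self, genotype_fixture):
        spec, passing, popmap, _ = genotype_fixture
        hd = {}
        for pop in ("POP_BRET", "WILD"):
            curve = ss.ld_decay(passing, popmap, pop, max_dist_bp=300_000, bin_bp=5000)
            hd[pop] = ss.half_decay_distance(curve)
        assert hd["POP_BRET"] > hd["WILD"]


class TestCallSweeps:
    def scan_from_values(self, values):
        n = len(values)
        windows = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 10_000 + 1,
                "end": np.arange(n) * 10_000 + 10_000,
                "n_snps": [5] * n,
                "value": values,
                "defined": [True] * n,
            }
        )
        return ss.GenomeScan(statistic="FST", windows=windows)

    def test_nearest_rank_count(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(100).astype(float)
        regions = ss.call_sweeps(self.scan_from_values(values), 0.05)
        assert regions.regions.n_windows.sum() == 5

    def test_all_equal_all_selected(self):
        regions = ss.call_sweeps(self.scan_from_values([1.0] * 20), 0.05)
        assert regions.regions.n_windows.sum() == 20

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, 200)
        scan = self.scan_from_values(values)
        small = ss.call_sweeps(scan, 0.01).regions.n_windows.sum()
        large = ss.call_sweeps(scan, 0.10).regions.n_windows.sum()
        assert small <= large

    def test_overlapping_windows_merged(self):
        windows = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [1, 1001, 50_001, 80_001],
                "end": [10_000, 11_000, 60_000, 90_000],
                "n_snps": [5] * 4,
                "value": [9.0, 8.0, 7.0, 1.0],
                "defined": [True] * 4,
            }
        )
        scan = ss.GenomeScan(statistic="FST", windows=windows)
        regions = ss.call_sweeps(scan, 0.75).regions  # top 3 of 4 windows
        assert len(regions) == 2
        assert regions.iloc[0].end == 11_000

    def test_all_undefined_rejected(self):
        scan = self.scan_from_values([1.0])
        scan.windows["defined"] = False
        with pytest.raises(ValueError):
            ss.call_sweeps(scan, 0.05)


class TestGenesInRegions:
    def region_set(self, intervals):
        return ss.SweepRegionSet(
            statistic="FST",
            threshold=1.0,
            top_fraction=0.05,
            regions=pd.DataFrame(
                [("chr1", s, e, 1) for s, e in intervals],
                columns=["chrom", "start", "end", "n_windows"],
            ),
        )

    def test_partial_overlap_selected(self):
        genes = [GeneModel("g", "chr1", 5000, 8000)]
        out = ss.genes_in_regions(genes, self.region_set([(7500, 17_500)]))
        assert list(out.gene_id) == ["g"]

    def test_adjacent_not_selected(self):
        genes = [GeneModel("g", "chr1", 5000, 8000)]
        out = ss.genes_in_regions(genes, self.region_set([(8001, 9000)]))
        assert out.empty

    def test_random_toys_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            genes = []
            for k in range(10):
                s = int(rng.integers(1, 50_000))
                genes.append(GeneModel(f"g{k}", "chr1", s, s + int(rng.integers(100, 5000))))
            intervals = []
            cursor = 1
            for _ in range(4):
                cursor += int(rng.integers(1000, 20_000))
                end = cursor + int(rng.integers(500, 8000))
                intervals.append((cursor, end))
                cursor = end + 2
            out = set(ss.genes_in_regions(genes, self.region_set(intervals)).gene_id)
            brute = {
                g.gene_id
                for g in genes
                if any(g.start <= e and g.end >= s for s, e in intervals)
            }
            assert out == brute
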