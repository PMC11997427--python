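"""SNP filters, pi, Weir-Cockerham Fst, windows and sweep regions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pavscan import (
    GeneModel,
    GenotypeMatrix,
    UndefinedStatisticError,
    annotate_regions,
    filter_snps,
    fst_weir_cockerham,
    gene_flank_stats,
    merge_window_runs,
    nucleotide_diversity,
    read_vcf,
    select_and_merge,
    window_aggregate,
    write_vcf,
)

MISS = -1


def make_gm(geno, positions=None, chrom="chr1", populations=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_snps, n_samples = geno.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=samples,
        chromosomes=np.array([chrom] * n_snps, dtype=object),
        positions=np.asarray(positions),
        genotypes=geno,
        populations=populations or {},
    )


def pi_oracle(geno, length):
    """Brute force: enumerate every pair of non-missing haploid alleles."""
    total = 0.0
    for site in geno:
        alleles = []
        for g in site:
            if g != MISS:
                alleles += [1] * g + [0] * (2 - g)
        if len(alleles) < 2:
            continue
        pairs = list(combinations(range(len(alleles)), 2))
        diffs = sum(alleles[i] != alleles[j] for i, j in pairs)
        total += diffs / len(pairs)
    return total / length


def wc_oracle(geno_a, geno_b):
    """Scalar per-site Weir & Cockerham (1984) components, summed then ratioed."""
    num = den = 0.0
    r = 2
    for sa, sb in zip(geno_a, geno_b):
        stats = []
        for site in (sa, sb):
            obs = [g for g in site if g != MISS]
            if not obs:
                stats = None
                break
            n_i = len(obs)
            p_i = sum(obs) / (2 * n_i)
            h_i = sum(1 for g in obs if g == 1) / n_i
            stats.append((n_i, p_i, h_i))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFilters:
    def test_hand_labelled_toy(self):
        # 10 loci x 10 samples; engineered pass/fail per filter
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 2, size=(10, 10)).astype(np.int8)  # ~50% AF
        geno[1] = MISS  # missing rate 1.0 -> removed (missingness)
        geno[2, :2] = (1, 1)
        geno[2, 2:] = 0  # AF = 2/20 = 0.10 -> retained
        geno[3] = 0
        geno[3, 0] = 1  # AF = 1/20 = 0.05 -> retained (boundary)
        geno[4] = 0  # monomorphic, AF 0 -> removed (AF)
        geno[5, :] = MISS
        geno[5, 0] = 1  # missing 0.9 retained, but AF on 1 sample = 0.5 kept
        depth = np.array([10, 10, 10, 10, 10, 10, 1, 60, 2, 50.0])  # 1 and 60 fail
        gm = make_gm(geno)
        out, report = filter_snps(gm, mean_depth=depth)
        assert report["removed_depth"] == 2
        assert report["removed_missing"] == 1
        kept = set(out.positions.tolist())
        assert 20 not in kept and 50 not in kept and 70 not in kept and 80 not in kept
        assert 30 in kept and 40 in kept and 60 in kept

    def test_af_boundary(self):
        geno = np.zeros((2, 50), dtype=np.int8)
        geno[0, :4] = 1  # AF 4/100 = 0.04 -> removed
        geno[1, :5] = 1  # AF 5/100 = 0.05 -> retained
        out, report = filter_snps(make_gm(geno))
        assert out.positions.tolist() == [20]
        assert report["removed_af"] == 1

    def test_missing_rate_boundary(self):
        geno = np.full((2, 20), MISS, dtype=np.int8)
        geno[0, :2] = (0, 2)  # missing 0.9 -> retained, AF 0.5
        geno[1, 0] = 1  # missing 0.95 -> removed
        out, report = filter_snps(make_gm(geno))
        assert report["removed_missing"] == 1
        assert out.positions.tolist() == [10]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        geno = rng.choice([0, 1, 2, MISS], size=(50, 30), p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        once, _ = filter_snps(make_gm(geno))
        twice, report = filter_snps(once)
        assert twice.n_snps == once.n_snps
        assert report["removed_missing"] == report["removed_af"] == 0

    def test_zero_locus_matrix_warns(self):
        gm = make_gm(np.zeros((0, 5), dtype=np.int8), positions=np.array([], dtype=np.int64))
        with pytest.warns(UserWarning):
            out, _ = filter_snps(gm)
        assert out.n_snps == 0


class TestPi:
    def test_monomorphic_region_zero(self):
        gm = make_gm(np.zeros((3, 4), dtype=np.int8))
        assert nucleotide_diversity(gm, "chr1", 0, 100) == 0.0

    def test_hand_pairwise_example(self):
        # one SNP, dosages (0, 2): 4 alleles, 4 of 6 pairs differ, region 100 bp
        gm = make_gm([[0, 2]])
        assert nucleotide_diversity(gm, "chr1", 0, 100) == pytest.approx(4 / 6 / 100)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        geno = rng.choice([0, 1, 2, MISS], size=(50, 20), p=[0.35, 0.3, 0.25, 0.1]).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 5001), 50, replace=False))
        gm = make_gm(geno, positions=positions)
        assert nucleotide_diversity(gm, "chr1", 0, 5000) == pytest.approx(
            pi_oracle(geno, 5000), abs=1e-12
        )

    def test_undefined_when_no_usable_site(self):
        geno = np.full((2, 3), MISS, dtype=np.int8)
        geno[:, 0] = 1  # single non-missing sample -> 2 alleles? n=2 usable!
        geno[0, 0] = MISS
        geno[1, 0] = MISS
        gm = make_gm(geno)
        with pytest.raises(UndefinedStatisticError):
            nucleotide_diversity(gm, "chr1", 0, 100)

    def test_region_length_validation(self):
        gm = make_gm([[0, 1]])
        with pytest.raises(ValueError):
            nucleotide_diversity(gm, "chr1", 5, 5)


class TestFst:
    def pops(self, n_a, n_b):
        a = [f"s{i}" for i in range(n_a)]
        b = [f"s{i}" for i in range(n_a, n_a + n_b)]
        return a, b

    def test_fixed_difference_gives_one(self):
        geno = np.array([[2] * 5 + [0] * 5] * 3, dtype=np.int8)
        gm = make_gm(geno)
        a, b = self.pops(5, 5)
        assert fst_weir_cockerham(gm, a, b) == pytest.approx(1.0)

    def test_matches_scalar_oracle_with_missing_data(self):
        rng = np.random.default_rng(11)
        geno = rng.choice([0, 1, 2, MISS], size=(50, 20), p=[0.35, 0.3, 0.25, 0.1]).astype(np.int8)
        gm = make_gm(geno)
        a, b = self.pops(12, 8)
        expected = wc_oracle(geno[:, :12], geno[:, 12:])
        assert fst_weir_cockerham(gm, a, b) == pytest.approx(expected, abs=1e-12)

    def test_null_regions_centred_on_zero(self):
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(100):
            freq = rng.uniform(0.2, 0.8, size=20)
            geno = rng.binomial(2, freq[:, None], size=(20, 60)).astype(np.int8)
            gm = make_gm(geno)
            a, b = self.pops(30, 30)
            ests.append(fst_weir_cockerham(gm, a, b))
        assert abs(np.mean(ests)) <= 0.02

    def test_monomorphic_region_undefined(self):
        gm = make_gm(np.zeros((3, 10), dtype=np.int8))
        a, b = self.pops(5, 5)
        with pytest.raises(UndefinedStatisticError):
            fst_weir_cockerham(gm, a, b)

    def test_shared_samples_rejected(self):
        gm = make_gm(np.zeros((1, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="share"):
            fst_weir_cockerham(gm, ["s0", "s1"], ["s1", "s2"])


class TestGeneFlankStats:
    def test_gene_at_chromosome_start_truncates_upstream(self):
        gene = GeneModel("g", "chr1", "+", ((0, 1000),))
        geno = np.array([[0, 1, 2, 1]], dtype=np.int8)
        pops = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        gm = make_gm(geno, positions=np.array([500]), populations=pops)
        df = gene_flank_stats(gene, gm, "A", "B").set_index("part")
        up = df.loc["upstream"]
        assert up["truncated"] and up["end"] - up["start"] == 0
        assert np.isnan(up["fst"])

    def test_planted_low_diversity_body_in_one_population(self):
        rng = np.random.default_rng(9)
        n_a, n_b = 20, 20
        pops = {f"s{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
        # body SNPs: monomorphic in A, polymorphic in B; flanks polymorphic in both
        body = np.hstack(
            [np.zeros((10, n_a), dtype=np.int8),
             rng.binomial(2, 0.5, size=(10, n_b)).astype(np.int8)]
        )
        flank = rng.binomial(2, 0.5, size=(20, n_a + n_b)).astype(np.int8)
        geno = np.vstack([flank[:10], body, flank[10:]])
        positions = np.concatenate(
            [np.linspace(1000, 3900, 10), np.linspace(4100, 7900, 10),
             np.linspace(8100, 11000, 10)]
        ).astype(np.int64)
        gene = GeneModel("g", "chr1", "+", ((4000, 8000),))
        gm = make_gm(geno, positions=positions, populations=pops)
        df = gene_flank_stats(gene, gm, "A", "B").set_index("part")
        assert df.loc["gene_body", "pi_A"] < df.loc["gene_body", "pi_B"]
        assert df.loc["gene_body", "fst"] > 0.1

    def test_uniform_data_gives_comparable_parts(self):
        rng = np.random.default_rng(21)
        n = 30
        pops = {f"s{i}": ("A" if i < 15 else "B") for i in range(n)}
        geno = rng.binomial(2, 0.5, size=(120, n)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 12001), 120, replace=False))
        gene = GeneModel("g", "chr1", "+", ((4000, 8000),))
        gm = make_gm(geno, positions=positions, populations=pops)
        df = gene_flank_stats(gene, gm, "A", "B").set_index("part")
        pis = df["pi_A"]
        assert pis.max() / pis.min() < 2.0  # same generating process everywhere


class TestWindows:
    lengths = {"chr1": 100_000}

    def test_constant_score_field(self):
        pos = np.arange(0, 100_000, 500)
        w = window_aggregate(["chr1"] * pos.size, pos, np.full(pos.size, 5.0), self.lengths)
        assert np.allclose(w["score"], 5.0)
        assert len(w) == 10

    def test_mean_of_two_sites(self):
        w = window_aggregate(["chr1", "chr1"], np.array([100, 200]),
                             np.array([2.0, 4.0]), self.lengths)
        assert len(w) == 1 and w["score"].iloc[0] == 3.0 and w["n_sites"].iloc[0] == 2

    def test_boundary_site_goes_right(self):
        w = window_aggregate(["chr1"], np.array([10_000]), np.array([1.0]), self.lengths)
        assert w["start"].iloc[0] == 10_000

    def test_site_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            window_aggregate(["chr1"], np.array([100_000]), np.array([1.0]), self.lengths)

    def test_terminal_partial_window_flagged(self):
        w = window_aggregate(["chr1"], np.array([95_001]), np.array([1.0]),
                             {"chr1": 95_002})
        assert w["terminal"].iloc[0] and w["end"].iloc[0] == 95_002


def windows_frame(scores, window=10_000):
    n = len(scores)
    return pd.DataFrame(
        {
            "chromosome": ["chr1"] * n,
            "start": np.arange(n) * window,
            "end": (np.arange(n) + 1) * window,
            "score": scores,
            "n_sites": 1,
            "terminal": False,
        }
    )


class TestSelectAndMerge:
    def test_hand_worked_merge_rule(self):
        """Selected indexes {5, 6, 8, 12}: a single intervening window (7)
        merges, a three-window gap does not -> regions {5-8} and {12}."""
        scores = np.linspace(0.01, 0.56, 60)  # distinct small backgrounds
        for i, s in zip((5, 6, 8, 12), (10.0, 11.0, 13.0, 12.0)):
            scores[i] = s
        regions = select_and_merge(windows_frame(scores), quantile=0.95)
        assert len(regions) == 2
        first, second = regions.iloc[0], regions.iloc[1]
        assert (first["start"], first["end"]) == (50_000, 90_000)
        assert first["region_score"] == 13.0  # max member score
        assert (second["start"], second["end"]) == (120_000, 130_000)
        assert second["n_windows"] == 1

    def test_single_selected_window(self):
        # n = 10 and q = 0.95: nearest rank is the maximum, so exactly one
        # window is selected and forms a region equal to itself
        scores = np.append(np.linspace(0.1, 0.9, 9), [5.0])
        regions = select_and_merge(windows_frame(scores), quantile=0.95)
        assert len(regions) == 1
        assert (regions["start"].iloc[0], regions["end"].iloc[0]) == (90_000, 100_000)
        assert regions["region_score"].iloc[0] == 5.0

    def test_merge_runs_idempotent(self):
        runs = merge_window_runs([5, 6, 8, 12])
        assert runs == [(5, 8), (12, 12)]
        for first, last in runs:
            assert merge_window_runs(range(first, last + 1)) == [(first, last)]

    def test_planted_run_recovery(self, small_config):
        from pavscan import simulate_window_scores

        df, truth = simulate_window_scores(small_config, n_windows=1000, n_planted=12)
        regions = select_and_merge(df, quantile=0.95)
        covered = set()
        for _, r in regions.iterrows():
            covered.update(range(r["start"] // 10_000, r["end"] // 10_000))
        sens = len(covered & truth.planted_window_indexes) / len(truth.planted_window_indexes)
        assert sens >= 0.95

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            select_and_merge(windows_frame([])[:0])


class TestAnnotateRegions:
    def regions(self):
        return pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr2"],
                "start": [0, 50_000, 10_000],
                "end": [20_000, 80_000, 30_000],
            }
        )

    def test_overlap_conventions(self):
        models = [
            GeneModel("inside", "chr1", "+", ((5_000, 6_000),)),
            GeneModel("abutting", "chr1", "+", ((20_000, 21_000),)),  # half-open: no
            GeneModel("spanning", "chr1", "+", ((19_999, 20_500),)),  # 1 bp overlap
            GeneModel("elsewhere", "chr2", "+", ((40_000, 41_000),)),
        ]
        out = annotate_regions(self.regions(), models)
        assert out["genes"].iloc[0] == ["inside", "spanning"]

    def test_matches_interval_sweep_oracle(self):
        rng = np.random.default_rng(13)
        models = []
        for i in range(10):
            chrom = "chr1" if i % 2 else "chr2"
            s = int(rng.integers(0, 90_000))
            models.append(GeneModel(f"g{i}", chrom, "+", ((s, s + int(rng.integers(500, 5000))),)))
        out = annotate_regions(self.regions(), models)
        for _, row in out.iterrows():
            expected = sorted(
                g.gene_id for g in models
                if g.chromosome == row["chromosome"]
                and max(g.start, row["start"]) < min(g.end, row["end"])
            )
            assert sorted(row["genes"]) == expected

    def test_unknown_chromosome_warns(self):
        models = [GeneModel("g", "chr9", "+", ((0, 10),))]
        with pytest.warns(UserWarning):
            out = annotate_regions(self.regions(), models)
        assert out["n_genes"].sum() == 0


class TestVcfIo:
    def test_round_trip_through_cyvcf2(self, tmp_path, small_config):
        from pavscan import simulate_genotypes

        gm, _ = simulate_genotypes(small_config)
        # plant a missing call to exercise ./. handling
        gm.genotypes[0, 0] = MISS
        path = tmp_path / "g.vcf"
        write_vcf(gm, path, {"chr1": small_config.chromosome_length})
        back, skipped = read_vcf(path, gm.populations)
        assert skipped == 0
        assert back.sample_ids == gm.sample_ids
        np.testing.assert_array_equal(back.genotypes, gm.genotypes)
        np.testing.assert_array_equal(back.positions, gm.positions)
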