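"""Haploid genotype I/O, filtering, diversity, F_ST and MLG statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from _oracles import random_genotype_matrix, wc_theta_oracle

from landgen import (
    MISSING,
    GenotypeMatrix,
    diversity_stats,
    locus_filter,
    multilocus_genotypes,
    pairwise_fst,
    read_genotypes,
    write_genotype_csv,
    write_vcf,
)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_csv_parse_with_missing(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "individual,population,L1,L2\nind1,A,0,1\nind2,A,1,0\nind3,B,0,\n"
        )
        gm = read_genotypes(path, "genotype-csv")
        assert gm.individuals == ["ind1", "ind2", "ind3"]
        assert gm.calls[2, 1] == MISSING
        assert gm.calls[2, 0] == 0

    def test_vcf_haploid_parse(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t1\ts1\tA\tG\t.\t.\t.\tGT\t0\t1\n"
            "1\t2\ts2\tA\tG\t.\t.\t.\tGT\t.\t0\n"
            "1\t3\ts3\tA\tG\t.\t.\t.\tGT\t1\t1\n"
            "1\t4\ts4\tA\tG\t.\t.\t.\tGT\t0\t.\n"
        )
        pm = tmp_path / "pm.csv"
        pm.write_text("individual,population\na,P1\nb,P2\n")
        gm = read_genotypes(vcf, "vcf-haploid", pm)
        assert gm.n_loci == 4
        assert gm.calls[0, 1] == MISSING
        assert gm.calls[1, 3] == MISSING
        assert list(gm.populations) == ["P1", "P2"]

    def test_vcf_diploid_rejected(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t1\ts1\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        pm = tmp_path / "pm.csv"
        pm.write_text("individual,population\na,P1\n")
        with pytest.raises(ValueError, match="haploid"):
            read_genotypes(vcf, "vcf-haploid", pm)

    def test_unknown_individual_named_in_error(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual,population,L1\nind1,A,0\nind2,A,1\n")
        pm = tmp_path / "pm.csv"
        pm.write_text("individual,population\nind1,A\n")
        with pytest.raises(ValueError, match="ind2"):
            read_genotypes(path, "genotype-csv", pm)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual,population,L1\n")
        with pytest.raises(ValueError):
            read_genotypes(path, "genotype-csv")

    @pytest.mark.parametrize("via", ["csv", "vcf"])
    def test_roundtrip(self, tmp_path, toy_gm, via):
        if via == "csv":
            path = tmp_path / "g.csv"
            write_genotype_csv(toy_gm, path)
            gm2 = read_genotypes(path, "genotype-csv")
        else:
            path = tmp_path / "g.vcf"
            write_vcf(toy_gm, path)
            pm = tmp_path / "pm.csv"
            pd.DataFrame(
                {"individual": toy_gm.individuals, "population": toy_gm.populations}
            ).to_csv(pm, index=False)
            gm2 = read_genotypes(path, "vcf-haploid", pm)
        assert gm2.individuals == toy_gm.individuals
        assert list(gm2.populations) == list(toy_gm.populations)
        assert gm2.loci == toy_gm.loci
        np.testing.assert_array_equal(gm2.calls, toy_gm.calls)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestLocusFilter:
    def _matrix(self, cols):
        calls = np.array(cols, dtype=np.int16).T
        n = calls.shape[0]
        return GenotypeMatrix(
            [f"i{k}" for k in range(n)],
            np.array(["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object),
            [f"L{k}" for k in range(calls.shape[1])],
            calls,
        )

    def test_missingness_and_monomorphic_dropped(self):
        M = MISSING
        gm = self._matrix(
            [
                [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],   # keep
                [M, M, M, 1, 0, 1, 0, 1, 0, 1],   # 30% missing -> drop
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # monomorphic -> drop
                [1, 0, 1, 0, 1, 0, 1, 0, 1, 0],   # keep
                [M, M, 0, 1, 0, 1, 0, 1, 0, 1],   # 20% missing -> keep
            ]
        )
        out, report = locus_filter(gm, max_missing=0.25)
        assert out.loci == ["L0", "L3", "L4"]
        assert sorted(report["locus"]) == ["L1", "L2"]
        assert "monomorphic" in report.set_index("locus").at["L2", "reason"]

    def test_clean_matrix_unchanged(self, toy_gm):
        out, report = locus_filter(toy_gm, max_missing=0.25)
        assert out.loci == toy_gm.loci[:5]  # L5 is monomorphic in the fixture
        out2, report2 = locus_filter(toy_gm, max_missing=0.25, drop_monomorphic=False)
        assert out2.loci == toy_gm.loci
        assert len(report2) == 0

    def test_all_removed_is_error(self):
        gm = self._matrix([[0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="all loci"):
            locus_filter(gm)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_closed_form_single_locus(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            np.array(["P"] * 4, dtype=object),
            ["L1"],
            np.array([[0], [0], [1], [1]], dtype=np.int16),
        )
        tab = diversity_stats(gm)
        assert tab.at["P", "H_S"] == pytest.approx(4 / 3 * 0.5)
        assert tab.at["P", "PL"] == 100.0
        assert tab.at["P", "n_a"] == 2.0

    def test_hand_oracle_with_missing(self, toy_gm):
        """Every statistic equals an explicit per-locus hand computation."""
        tab = diversity_stats(toy_gm)
        for pop in ["popA", "popB", "popC"]:
            sel = toy_gm.populations == pop
            calls = toy_gm.calls[sel]
            hs_terms, poly, typed, k_sum = [], 0, 0, 0
            for locus in range(calls.shape[1]):
                obs = [c for c in calls[:, locus] if c != MISSING]
                k_sum += len(set(obs))
                if obs:
                    typed += 1
                    if len(set(obs)) >= 2:
                        poly += 1
                n = len(obs)
                if n >= 2:
                    freqs = [obs.count(a) / n for a in set(obs)]
                    hs_terms.append(n / (n - 1) * (1 - sum(f**2 for f in freqs)))
            assert tab.at[pop, "PL"] == pytest.approx(100 * poly / typed)
            assert tab.at[pop, "n_a"] == pytest.approx(k_sum / calls.shape[1])
            assert tab.at[pop, "H_S"] == pytest.approx(np.mean(hs_terms))

    def test_na_below_one_when_locus_untyped(self):
        M = MISSING
        gm = GenotypeMatrix(
            ["a", "b"],
            np.array(["P", "P"], dtype=object),
            ["L1", "L2"],
            np.array([[0, M], [0, M]], dtype=np.int16),
        )
        tab = diversity_stats(gm)
        assert tab.at["P", "n_a"] == 0.5  # untyped locus contributes 0 alleles
        assert tab.at["P", "H_S"] == 0.0

    def test_population_duplication_invariance(self, toy_gm):
        dup = GenotypeMatrix(
            toy_gm.individuals + [i + "_d" for i in toy_gm.individuals[:4]],
            np.append(toy_gm.populations, np.array(["popD"] * 4, dtype=object)),
            toy_gm.loci,
            np.vstack([toy_gm.calls, toy_gm.calls[:4]]),
        )
        a = diversity_stats(toy_gm)
        b = diversity_stats(dup)
        pd.testing.assert_frame_equal(a, b.loc[a.index])
        assert b.loc["popD", "H_S"] == pytest.approx(a.loc["popA", "H_S"])


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def test_fixed_difference_theta_one(self):
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(8)],
            np.array(["A"] * 4 + ["B"] * 4, dtype=object),
            ["L1", "L2"],
            np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=np.int16),
        )
        res = pairwise_fst(gm)
        assert res.matrix.at["A", "B"] == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        rng = np.random.default_rng(0)
        block = (rng.uniform(size=(6, 8)) < 0.5).astype(np.int16)
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(12)],
            np.array(["A"] * 6 + ["B"] * 6, dtype=object),
            [f"L{k}" for k in range(8)],
            np.vstack([block, block]),
        )
        res = pairwise_fst(gm)
        assert res.matrix.at["A", "B"] <= 0.0

    def test_matches_anova_oracle_unequal_n(self):
        rng = np.random.default_rng(3)
        calls = np.vstack(
            [
                (rng.uniform(size=(4, 3)) < 0.3).astype(np.int16),
                (rng.uniform(size=(6, 3)) < 0.7).astype(np.int16),
            ]
        )
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(10)],
            np.array(["A"] * 4 + ["B"] * 6, dtype=object),
            ["L1", "L2", "L3"],
            calls,
        )
        got = pairwise_fst(gm).matrix.at["A", "B"]
        want = wc_theta_oracle(gm.calls, gm.populations, "A", "B")
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_genotype_matrix(rng)
        res = pairwise_fst(gm)
        for a, b in itertools.combinations(gm.population_ids, 2):
            want = wc_theta_oracle(gm.calls, gm.populations, a, b)
            got = res.matrix.at[a, b]
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_individual_permutation_invariance(self, toy_gm):
        rng = np.random.default_rng(1)
        perm = rng.permutation(toy_gm.n_individuals)
        shuffled = GenotypeMatrix(
            [toy_gm.individuals[i] for i in perm],
            toy_gm.populations[perm],
            toy_gm.loci,
            toy_gm.calls[perm],
        )
        a, b = pairwise_fst(toy_gm), pairwise_fst(shuffled)
        np.testing.assert_allclose(
            a.matrix.to_numpy(), b.matrix.loc[a.matrix.index, a.matrix.columns].to_numpy()
        )
        pd.testing.assert_frame_equal(
            diversity_stats(toy_gm), diversity_stats(shuffled).loc[["popA", "popB", "popC"]]
        )

    def test_single_population_rejected(self):
        gm = GenotypeMatrix(
            ["a", "b"], np.array(["P", "P"], dtype=object), ["L1"],
            np.array([[0], [1]], dtype=np.int16),
        )
        with pytest.raises(ValueError, match="two populations"):
            pairwise_fst(gm)


# ---------------------------------------------------------------------------
# Multilocus genotypes
# ---------------------------------------------------------------------------

class TestMlg:
    def test_hand_counted_pairs(self):
        M = MISSING
        calls = np.array(
            [
                [0, 0, 1],
                [0, 0, 1],   # same as row 0 -> one MLG
                [0, 1, 1],
                [M, 0, 1],
            ],
            dtype=np.int16,
        )
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            np.array(["P1", "P2", "P1", "P1"], dtype=object),
            ["L1", "L2", "L3"],
            calls,
        )
        s = multilocus_genotypes(gm)
        assert s.n_mlg == 3
        assert s.shared_across_populations == 1  # the (0,0,1) clone spans P1+P2
        # pairs among distinct MLGs (0,0,1),(0,1,1),(M,0,1):
        # d(v1,v2)=1/3; d(v1,v3)=0/2; d(v2,v3)=1/2
        assert s.mean_pairwise_diff == pytest.approx((1 / 3 + 0 + 1 / 2) / 3)

    def test_all_identical_gives_na(self):
        gm = GenotypeMatrix(
            ["a", "b"], np.array(["P1", "P2"], dtype=object), ["L1"],
            np.array([[1], [1]], dtype=np.int16),
        )
        s = multilocus_genotypes(gm)
        assert s.n_mlg == 1
        assert np.isnan(s.mean_pairwise_diff)

    def test_locus_order_invariance_and_monotonicity(self, toy_gm):
        s = multilocus_genotypes(toy_gm)
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = GenotypeMatrix(
            toy_gm.individuals, toy_gm.populations,
            [toy_gm.loci[k] for k in perm], toy_gm.calls[:, perm],
        )
        assert multilocus_genotypes(shuffled).n_mlg == s.n_mlg
        for drop in range(toy_gm.n_loci):
            keep = [k for k in range(toy_gm.n_loci) if k != drop]
            sub = GenotypeMatrix(
                toy_gm.individuals, toy_gm.populations,
                [toy_gm.loci[k] for k in keep], toy_gm.calls[:, keep],
            )
            assert multilocus_genotypes(sub).n_mlg <= s.n_mlg
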