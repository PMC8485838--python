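"""Diversity, Tamura-Nei, AMOVA, G_ST/N_ST and Mantel statistics."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from cpphylo.alignment import Alignment
from cpphylo.popgen import (
    amova,
    great_circle_km,
    gst_nst,
    haplotype_diversity,
    mantel_test,
    nucleotide_diversity,
    pairwise_differences,
    pairwise_fst,
    tamura_nei_distance,
)
from cpphylo.synthetic import REFERENCE_LINEAGES, reference_haplotype_table

#: published per-population gene diversities (code -> (Hd, sd)) used as a
#: regression surface for Nei's closed form; singleton populations excluded
PRINTED_HD = {
    "FO": (1.0, 0.27), "SI": (0.83, 0.2), "CS": (1.0, 0.18), "JH": (1.0, 0.09),
    "TL": (0.9, 0.16), "MO": (0.9, 0.1), "HA": (0.8, 0.17), "TU": (0.6, 0.2),
    "MM": (1.0, 0.09), "GO": (0.93, 0.12), "CI": (0.87, 0.13), "AC": (1.0, 0.05),
    "MA": (1.0, 0.13), "MY": (1.0, 0.13), "CP": (1.0, 0.18), "FXC": (1.0, 0.5),
    "ZA": (0.9, 0.16), "SC": (0.7, 0.22),
}
PRINTED_LINEAGE_HD = {"north": 0.949, "central": 0.923, "south": 0.7}


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((4, 1, 1), 0.6), ((3, 1, 1), 0.7), ((3, 1, 1, 1), 0.8), ((2, 1, 1, 2, 1), 0.9048)],
    )
    def test_closed_form_examples(self, counts, expected):
        assert haplotype_diversity(counts).hd == pytest.approx(expected, abs=5e-5)

    def test_degenerate_cases(self):
        assert haplotype_diversity([7]).hd == 0.0
        assert haplotype_diversity([1] * 5).hd == pytest.approx(1.0)
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    def test_survey_regression_all_populations(self):
        """Hd and its SD match the published survey on every n >= 2 row."""
        table = reference_haplotype_table()
        for pop, (hd_printed, sd_printed) in PRINTED_HD.items():
            col = table.counts[pop]
            res = haplotype_diversity(col[col > 0].to_numpy())
            assert round(res.hd, 2) == pytest.approx(round(hd_printed, 2), abs=1e-9), pop
            # SDs are printed at mixed precision and sometimes truncated
            # rather than rounded; allow one unit in the last printed digit
            decimals = len(str(sd_printed).split(".")[1])
            assert abs(res.hd_sd - sd_printed) <= 10.0**-decimals + 1e-12, pop

    def test_survey_regression_lineages(self):
        table = reference_haplotype_table()
        lineage_counts = table.counts.T.groupby(
            table.counts.columns.map(REFERENCE_LINEAGES)
        ).sum().T
        for lineage, expected in PRINTED_LINEAGE_HD.items():
            col = lineage_counts[lineage]
            res = haplotype_diversity(col[col > 0].to_numpy())
            assert round(res.hd, 3) == pytest.approx(expected, abs=5e-4), lineage


class TestNucleotideDiversity:
    def test_examples(self):
        assert nucleotide_diversity(["A" * 50, "A" * 50]).pi == 0.0
        assert nucleotide_diversity(["A" * 100, "A" * 99 + "T"]).pi == pytest.approx(0.01)
        assert nucleotide_diversity(["AAAA", "AAAT", "AATT"]).pi == pytest.approx(1 / 3)

    def test_bounded_by_polymorphic_fraction(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
        poly = sum(len(set(col)) > 1 for col in zip(*seqs))
        assert nucleotide_diversity(seqs).pi <= poly / 30 + 1e-12


class TestTamuraNei:
    def test_identical_pair_is_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert tamura_nei_distance(aln).iloc[0, 1] == 0.0

    def test_symmetric_and_at_least_p_distance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        aln = Alignment([f"s{i}" for i in range(5)], seqs)
        d = tamura_nei_distance(aln).to_numpy()
        p = pairwise_differences(seqs) / 60
        assert np.allclose(d, d.T)
        assert (d + 1e-12 >= p).all()

    def test_matches_ape_reference_implementation(self, tmp_path):
        """Cross-check against ape::dist.dna(model='TN93') via Rscript."""
        seqs = {
            "s1": "ACGTACGTACGTACGTAAGGCCTTACGT",
            "s2": "ACGTACGTACGCACGTAAGGCCTTACGC",
            "s3": "ATGTACGAACGTACGTAAGGCCTAACGT",
        }
        aln = Alignment(list(seqs), list(seqs.values()))
        ours = tamura_nei_distance(aln)
        fasta = tmp_path / "tn.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            a <- read.dna("{fasta}", format="fasta")
            write.csv(as.matrix(dist.dna(a, model="TN93")), stdout())
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        import io
        theirs = pd.read_csv(io.StringIO(out.stdout), index_col=0)
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-6)

    def test_reduces_to_kimura_with_equal_frequencies(self):
        """With equal base composition TN93 equals the K80 closed form."""
        # equal ACGT composition; transitions split equally between the
        # A<->G and C<->T classes (the regime where TN93 collapses to K80)
        s1 = "AACCGGTTAACCGGTT" * 3
        s2 = "GACCAGTTAATCGGCT" * 3  # A<->G swap and C<->T swap per repeat
        aln = Alignment(["x", "y"], [s1, s2])
        d = tamura_nei_distance(aln).iloc[0, 1]
        P, Q = 4 / 16, 0.0
        k80 = -0.5 * np.log((1 - 2 * P - Q) * np.sqrt(1 - 2 * Q))
        assert d == pytest.approx(k80, rel=1e-9)


def _fixed_difference_matrix(n_a: int, n_b: int, steps: float = 1.0) -> np.ndarray:
    d = np.zeros((n_a + n_b, n_a + n_b))
    d[:n_a, n_a:] = steps
    d[n_a:, :n_a] = steps
    return d


class TestAmova:
    def test_fixed_difference_gives_fst_one(self):
        d = _fixed_difference_matrix(5, 5)
        res = amova(d, ["A"] * 5 + ["B"] * 5, n_perm=199, seed=1)
        assert res.fixation_indices["F_ST"] == pytest.approx(1.0)
        assert res.p_values["F_ST"] < 0.05
        assert res.table["percent"].iloc[-1] == pytest.approx(100.0)
        assert res.table["df"].iloc[-1] == 9  # N - 1

    def test_null_case_fst_near_zero(self, rng):
        n = 20
        seqs = rng.choice(8, size=n)  # 8 haplotype classes assigned at random
        d = (seqs[:, None] != seqs[None, :]).astype(float)
        pops = ["A"] * 10 + ["B"] * 10
        res = amova(d, pops, n_perm=199, seed=3)
        assert abs(res.fixation_indices["F_ST"]) < 0.3
        assert res.p_values["F_ST"] > 0.05

    def test_single_population_yields_only_within_variance(self):
        d = _fixed_difference_matrix(3, 3)
        res = amova(d, ["A"] * 6, n_perm=9, seed=0)
        assert res.fixation_indices["F_ST"] == 0.0
        assert res.table.loc[res.table["stratum"] == "among_populations", "variance"].iloc[0] == 0.0

    def test_two_level_equals_pairwise_fst(self):
        d = _fixed_difference_matrix(5, 3, steps=2.0)
        pops = ["A"] * 5 + ["B"] * 3
        res = amova(d, pops, n_perm=49, seed=2)
        fst, _ = pairwise_fst(d, pops, n_perm=49, seed=2)
        assert fst.loc["A", "B"] == pytest.approx(res.fixation_indices["F_ST"])

    def test_three_level_design(self):
        # two groups of two populations; groups fully differentiated
        d = np.zeros((12, 12))
        d[:6, 6:] = 4.0
        d[6:, :6] = 4.0
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        res = amova(d, pops, groups, n_perm=99, seed=4)
        assert res.fixation_indices["F_CT"] > 0.9
        assert res.fixation_indices["F_SC"] == pytest.approx(0.0, abs=1e-9)
        assert res.table["df"].tolist() == [1, 2, 8, 11]
        assert res.table["percent"].iloc[-1] == pytest.approx(100.0)

    def test_population_without_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="no group"):
            amova(d, ["A", "A", "B", "B"], groups={"A": "g1"}, n_perm=9)


class TestGstNst:
    def test_equidistant_haplotypes_collapse_nst_to_gst(self):
        counts = pd.DataFrame({"P1": [5, 2, 1], "P2": [1, 4, 3]}, index=["H1", "H2", "H3"])
        d = 3.0 * (1 - np.eye(3))
        res = gst_nst(counts, d, n_perm=50, seed=0)
        assert res.n_st == pytest.approx(res.g_st)

    def test_identical_frequencies_give_gst_near_zero(self):
        counts = pd.DataFrame({"P1": [4, 4, 2], "P2": [4, 4, 2]}, index=["H1", "H2", "H3"])
        res = gst_nst(counts, (1 - np.eye(3)), n_perm=0)
        assert abs(res.g_st) < 0.1

    def test_phylogeographic_structure_detected(self):
        # each population fixed for its own cluster of similar haplotypes;
        # 8 haplotypes so the identity-permutation null is informative
        counts = pd.DataFrame(
            {"P1": [3, 3, 2, 2, 0, 0, 0, 0], "P2": [0, 0, 0, 0, 3, 3, 2, 2]},
            index=[f"H{i}" for i in range(8)],
        )
        d = np.full((8, 8), 10.0)
        d[:4, :4] = 1.0
        d[4:, 4:] = 1.0
        np.fill_diagonal(d, 0.0)
        res = gst_nst(counts, d, n_perm=999, seed=5)
        assert res.n_st > res.g_st
        assert res.p_nst_gt_gst < 0.05

    def test_monomorphic_data_rejected(self):
        counts = pd.DataFrame({"P1": [5], "P2": [5]}, index=["H1"])
        with pytest.raises(ValueError, match="monomorphic"):
            gst_nst(counts, np.zeros((1, 1)), n_perm=0)

    def test_singleton_populations_excluded(self):
        counts = pd.DataFrame(
            {"P1": [3, 2], "P2": [2, 3], "tiny": [1, 0]}, index=["H1", "H2"]
        )
        res = gst_nst(counts, (1 - np.eye(2)), n_perm=0)
        assert np.isfinite(res.g_st)


class TestMantel:
    def test_identical_matrices_give_r_one(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        r, p = mantel_test(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_invariant_under_joint_permutation(self, rng):
        n = 6
        a = rng.random((n, n)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((n, n)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        r1, _ = mantel_test(a, b, n_perm=0 or 1, seed=1)
        perm = rng.permutation(n)
        r2, _ = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)], n_perm=1, seed=1)
        assert r1 == pytest.approx(r2)

    def test_observed_r_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        n = 7
        a = rng.random((n, n)); a = (a + a.T); np.fill_diagonal(a, 0)
        b = rng.random((n, n)); b = (b + b.T); np.fill_diagonal(b, 0)
        r_ours, _ = mantel_test(a, b, n_perm=1, seed=0)
        r_skbio = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b), permutations=0)[0]
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-12)

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))


def test_great_circle_one_degree_latitude():
    d = great_circle_km(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    assert d[0, 1] == pytest.approx(111.19, abs=0.1)
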