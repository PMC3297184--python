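import itertools
import math

import numpy as np
import pytest

from flaxnet.alignment import InputError, RegionAnnotation
from flaxnet.popgen import (
    fu_li_star_tests,
    group_summary,
    haplotype_count,
    hudson_kaplan_rm,
    mean_pairwise_differences,
    nucleotide_diversity,
    segregating_sites,
    tajima_d,
    tajima_d_band,
    watterson_theta,
)

from conftest import brute_force_pi, brute_force_rm, make_alignment


def random_alignment(rng, n, L, gap_prob=0.0):
    mat = rng.choice(list("ACGT"), size=(n, L))
    if gap_prob:
        mat[rng.random((n, L)) < gap_prob] = "-"
    return make_alignment(["".join(r) for r in mat])


class TestSegregatingSites:
    def test_planted_snps_and_gap_run(self):
        # 4 x 6: SNPs at columns 2 and 5, one 2-bp gap run at 3..4
        aln = make_alignment(
            ["AAAAAA", "ACAAAA", "AC--CA", "AA--CA"]
        )
        table = segregating_sites(aln)
        assert table.positions == [2, 5]
        assert len(table.indel_events) == 1
        ev = table.indel_events[0]
        assert (ev.start, ev.end, ev.length) == (3, 4, 2)
        assert ev.presence == (False, False, True, True)

    def test_identical_sequences(self):
        table = segregating_sites(make_alignment(["ACGT"] * 3))
        assert table.S == 0 and not table.indel_events

    def test_indel_columns_not_substitution_sites(self):
        aln = make_alignment(["AAAA", "A--A", "A--A"])
        table = segregating_sites(aln)
        assert table.S == 0
        assert [e.name for e in table.indel_events] == ["indel:2-3"]

    def test_adjacent_distinct_gap_patterns_split(self):
        aln = make_alignment(["A-AA", "AA-A", "AAAA"])
        table = segregating_sites(aln)
        assert [(e.start, e.end) for e in table.indel_events] == [(2, 2), (3, 3)]

    def test_parsimony_informative_needs_two_carriers(self):
        aln = make_alignment(["AAAA", "ACAA", "ACGA", "ACGA"])
        table = segregating_sites(aln)
        assert table.positions == [2, 3]
        assert table.parsimony_informative() == [3]

    def test_region_outside_alignment_rejected(self):
        with pytest.raises(InputError):
            segregating_sites(make_alignment(["ACGT"] * 2), region=(2, 9))


class TestDiversity:
    def test_single_pair_one_of_ten(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAC"])
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_identical_gives_zero(self):
        assert nucleotide_diversity(make_alignment(["ACGT"] * 4)) == 0.0

    def test_single_sample_undefined(self):
        assert math.isnan(nucleotide_diversity(make_alignment(["ACGT"])))

    @pytest.mark.parametrize("gap_mode", ["pairwise", "complete"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed, gap_mode):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=6, L=30, gap_prob=0.05)
        assert nucleotide_diversity(aln, gap_mode=gap_mode) == pytest.approx(
            brute_force_pi(aln, gap_mode), abs=1e-12
        )


class TestTajimaD:
    def test_intermediate_frequency_excess_positive(self):
        # two divergent haplotype classes at equal frequency
        aln = make_alignment(["AAAAAAAAAA"] * 4 + ["CCCCCAAAAA"] * 4)
        assert tajima_d(aln) > 0

    def test_singleton_excess_negative(self):
        base = "A" * 10
        seqs = [base] * 5 + [
            base[:i] + "C" + base[i + 1 :] for i in range(5)
        ]
        assert tajima_d(make_alignment(seqs)) < 0

    def test_monomorphic_undefined(self):
        assert math.isnan(tajima_d(make_alignment(["ACGT"] * 5)))

    def test_small_sample_undefined(self):
        assert math.isnan(tajima_d(make_alignment(["AAAA", "AACA", "ACAA"])))

    def test_band_for_modest_statistic_not_significant(self):
        aln = make_alignment(["AAAAAAAAAA"] * 3 + ["CAAAAAAAAA"] * 3)
        d = tajima_d(aln)
        assert tajima_d_band(d, 6) == "P > 0.10"

    def test_monomorphic_column_removal_invariant(self):
        seqs = ["ACGTAA", "ACGTCA", "AAGTCA", "ACGTAA"]
        trimmed = [s[:2] + s[3:] for s in seqs]  # drop monomorphic column 3
        a1, a2 = make_alignment(seqs), make_alignment(trimmed)
        assert segregating_sites(a1).S == segregating_sites(a2).S
        assert haplotype_count(a1) == haplotype_count(a2)
        assert tajima_d(a1) == pytest.approx(tajima_d(a2))


class TestAgainstTskit:
    """Coalescent simulations scored by an independent library."""

    @pytest.mark.parametrize("anc_seed,mut_seed", [(5, 7), (11, 13), (23, 2)])
    def test_tajima_and_pi_match(self, anc_seed, mut_seed):
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=8, ploidy=1, sequence_length=500, random_seed=anc_seed
        )
        mts = msprime.sim_mutations(
            ts, rate=2e-3, random_seed=mut_seed,
            model=msprime.BinaryMutationModel(),
        )
        base = np.full((mts.num_samples, 500), "A", dtype="<U1")
        for var in mts.variants():
            pos = int(var.site.position)
            for i, g in enumerate(var.genotypes):
                base[i, pos] = "C" if var.alleles[g] != var.alleles[0] else "A"
        aln = make_alignment(["".join(r) for r in base])
        assert tajima_d(aln) == pytest.approx(float(mts.Tajimas_D()), abs=1e-10)
        assert nucleotide_diversity(aln) == pytest.approx(
            float(mts.diversity(span_normalise=True)), abs=1e-10
        )


def _fu_li_oracle(n, eta, eta_s, k_bar):
    """Independent scalar transcription of the corrected D*/F* formulas."""
    a = sum(1 / i for i in range(1, n))
    b = sum(1 / i**2 for i in range(1, n))
    an1 = a + 1 / n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1 / n
    )
    vD = (
        (n / (n - 1)) ** 2 * b + a**2 * dn - 2 * n * a * (a + 1) / (n - 1) ** 2
    ) / (a**2 + b)
    uD = n / (n - 1) * (a - n / (n - 1)) - vD
    dstar = (n / (n - 1) * eta - a * eta_s) / math.sqrt(uD * eta + vD * eta**2)
    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))) / a - vF
    fstar = (k_bar - (n - 1) / n * eta_s) / math.sqrt(uF * eta + vF * eta**2)
    return dstar, fstar


class TestFuLiStar:
    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=8, L=60)
        table = segregating_sites(aln)
        k_bar, _ = mean_pairwise_differences(aln, gap_mode="complete")
        expect = _fu_li_oracle(aln.n, table.eta, table.singleton_count(), k_bar)
        got = fu_li_star_tests(aln)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_monomorphic_undefined(self):
        d, f = fu_li_star_tests(make_alignment(["ACGT"] * 6))
        assert math.isnan(d) and math.isnan(f)

    def test_singleton_excess_drives_dstar_negative(self):
        base = "A" * 12
        seqs = [base] * 6 + [base[:i] + "G" + base[i + 1 :] for i in range(6)]
        d, f = fu_li_star_tests(make_alignment(seqs))
        assert d < 0 and f < 0


def test_watterson_theta_small_case():
    # S=3, n=4: theta = 3 / (1 + 1/2 + 1/3)
    assert watterson_theta(3, 4) == pytest.approx(3 / (11 / 6))


class TestHudsonKaplanRm:
    def test_four_gamete_rectangle(self, rectangle_recombination):
        rm, intervals = hudson_kaplan_rm(rectangle_recombination)
        assert rm == 1
        (a, b) = intervals[0]
        assert a < b and 1 <= a and b <= 8

    def test_tree_data_gives_zero(self):
        # nested (compatible) variation only
        aln = make_alignment(["AAAA", "CAAA", "CCAA", "CCCA"])
        assert hudson_kaplan_rm(aln) == (0, [])

    def test_two_disjoint_crossovers(self):
        # four gametes at sites (1,2) among the first four samples and at
        # (5,6) among the rest; the two regions stay mutually compatible
        seqs = [
            "AAAAAAA",
            "CCAAAAA",
            "ACAAAAA",
            "CAAAAAA",
            "AAAACCA",
            "AAAAACA",
            "AAAACAA",
        ]
        rm, intervals = hudson_kaplan_rm(make_alignment(seqs))
        assert rm == 2
        assert intervals[0][1] <= intervals[1][0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_disjoint_set(self, seed):
        rng = np.random.default_rng(seed)
        # binary alignments keep every variable site biallelic
        mat = rng.choice(list("AC"), size=(8, 12))
        aln = make_alignment(["".join(r) for r in mat])
        rm, _ = hudson_kaplan_rm(aln)
        assert rm == brute_force_rm(aln)


class TestGroupSummary:
    @pytest.fixture
    def grouped(self):
        seqs = {
            "w1": "AAAAAAAAAA", "w2": "CAAAAAAACA", "w3": "CAAAAAAAAA",
            "c1": "AAAAAAAAAC", "c2": "AAAAAAAAAC", "c3": "AAAAAAAAAC",
        }
        groups = {k: ("wild" if k.startswith("w") else "cult") for k in seqs}
        return make_alignment(list(seqs.values()), groups=groups, ids=list(seqs))

    def test_monomorphic_group_row(self, grouped):
        df = group_summary(grouped)
        row = df.xs("cult (3)", level="group")
        assert row.loc["S", "Total"] == 0
        assert row.loc["H", "Total"] == 1
        assert row.loc["pi_per_bp", "Total"] == 0.0
        assert math.isnan(row.loc["D", "Total"])  # printed as nd

    def test_region_columns_present(self, grouped):
        ann = RegionAnnotation([("left", 1, 5), ("right", 6, 10)], L=10)
        df = group_summary(grouped, ann)
        assert list(df.columns) == ["left", "right", "Total"]
        wild = df.xs("wild (3)", level="group")
        assert wild.loc["S", "left"] == 1
        assert wild.loc["S", "right"] == 1
        assert wild.loc["S", "Total"] == 2

    def test_unknown_group_rejected(self, grouped):
        with pytest.raises(InputError):
            group_summary(grouped, groups=["nope"])
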