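"""SFS, F_ST, diversity, distances and the Mantel test."""

import itertools

import numpy as np
import pytest
from dataclasses import replace

from phylodem.coalsim import simulate_dataset
from phylodem.demography import SampleConfig
from phylodem.sumstats import (
    DistanceMatrix,
    diversity_stats,
    genetic_distance_matrix,
    harmonic_number,
    joint_sfs,
    mantel_test,
    moment_estimates,
    population_distance_matrix,
    slatkin_linearize,
    weighted_fst,
)

from conftest import make_dataset


def _relabel(dataset, assignment):
    """Copy a dataset with individuals reassigned to new populations."""
    individuals = [
        replace(ind, population=assignment[ind.id])
        for ind in dataset.individuals
    ]
    return replace(dataset, individuals=individuals)


class TestJointSfs:
    def test_monomorphic_only_mass_at_origin(self):
        ds = make_dataset(
            [np.zeros((8, 0))], ["A", "A", "B", "B"], lengths=[100]
        )
        sfs = joint_sfs(ds, "A", "B")
        assert sfs.counts[0, 0] == 100
        assert sfs.n_sites == 100

    def test_single_site_forced_cell(self):
        # derived count 2/4 in A, 0/4 in B
        h = np.zeros((8, 1), dtype=np.uint8)
        h[0, 0] = h[1, 0] = 1
        ds = make_dataset([h], ["A", "A", "B", "B"], lengths=[10])
        sfs = joint_sfs(ds, "A", "B", include_monomorphic=False)
        assert sfs.counts[2, 0] == 1
        assert sfs.n_sites == 1

    def test_folded_matches_brute_force(self, small_dataset):
        folded = joint_sfs(small_dataset, "A", "B", folded=True)
        unfolded = joint_sfs(small_dataset, "A", "B", folded=False)
        n1, n2 = folded.n1, folded.n2
        # brute-force per-site recount with explicit minor-allele orientation
        expected = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if 2 * (i + j) > n1 + n2:
                    expected[n1 - i, n2 - j] += unfolded.counts[i, j]
                else:
                    expected[i, j] += unfolded.counts[i, j]
        np.testing.assert_array_equal(folded.counts, expected)
        assert folded.n_sites == unfolded.n_sites

    def test_complete_case_drops_loci_with_missingness(self, two_tip_model):
        ds = simulate_dataset(
            two_tip_model, SampleConfig({"A": 2, "B": 2}), n_loci=30,
            locus_length=200, missingness_rate=0.3, seed=5,
        )
        sfs = joint_sfs(ds, "A", "B")
        complete = [
            l for l in range(ds.n_loci) if not ds.missing[:, l].any()
        ]
        assert sfs.n_sites == sum(ds.loci[l].length for l in complete)

    def test_unknown_population(self, small_dataset):
        with pytest.raises(ValueError, match="unknown population"):
            joint_sfs(small_dataset, "A", "Z")


class TestWeightedFst:
    def test_fixed_difference_is_one(self):
        h = np.zeros((8, 1), dtype=np.uint8)
        h[:4, 0] = 1  # p1 = 1, p2 = 0 with n1 = n2 = 4
        ds = make_dataset([h], ["A", "A", "B", "B"])
        sfs = joint_sfs(ds, "A", "B", include_monomorphic=False)
        assert weighted_fst(sfs, "hudson") == pytest.approx(1.0)

    def test_toy_sfs_against_per_site_recomputation(self):
        # sites (2,0), (1,1), (4,4) with n1 = n2 = 4; the (4,4) site is
        # monomorphic in the pooled pair and must be skipped
        n1 = n2 = 4
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[2, 0] = counts[1, 1] = counts[4, 4] = 1
        from phylodem.sumstats import SFS2D

        sfs = SFS2D(counts, n1, n2, "A", "B")
        num = den = 0.0
        for i, j in [(2, 0), (1, 1)]:
            p1, p2 = i / n1, j / n2
            num += (p1 - p2) ** 2 - p1 * (1 - p1) / 3 - p2 * (1 - p2) / 3
            den += p1 * (1 - p2) + p2 * (1 - p1)
        assert weighted_fst(sfs, "hudson") == pytest.approx(num / den)

    def test_ratio_of_sums_invariant_under_site_duplication(self, small_dataset):
        sfs = joint_sfs(small_dataset, "A", "B")
        doubled = replace(sfs, counts=sfs.counts * 2)
        for estimator in ("hudson", "reynolds"):
            assert weighted_fst(doubled, estimator) == pytest.approx(
                weighted_fst(sfs, estimator), abs=1e-15
            )

    def test_hudson_equals_reynolds_at_equal_sample_sizes(self, small_dataset):
        # the haploid coancestry algebra reduces exactly to Hudson's
        # numerator/denominator (up to the common factor 1/2) when n1 == n2
        sfs = joint_sfs(small_dataset, "A", "B")
        assert weighted_fst(sfs, "reynolds") == pytest.approx(
            weighted_fst(sfs, "hudson"), rel=1e-12
        )

    def test_no_polymorphism_is_an_error(self):
        ds = make_dataset([np.zeros((8, 0))], ["A", "A", "B", "B"], lengths=[50])
        sfs = joint_sfs(ds, "A", "B")
        with pytest.raises(ValueError, match="no polymorphic sites"):
            weighted_fst(sfs)

    def test_folding_does_not_change_fst(self, small_dataset):
        unfolded = joint_sfs(small_dataset, "A", "B", folded=False)
        folded = joint_sfs(small_dataset, "A", "B", folded=True)
        assert weighted_fst(folded) == pytest.approx(weighted_fst(unfolded))


class TestSlatkin:
    @pytest.mark.parametrize(
        "fst,expected", [(0.0, 0.0), (0.5, 1.0), (0.2, 0.25)]
    )
    def test_closed_form(self, fst, expected):
        assert slatkin_linearize(fst) == pytest.approx(expected)

    def test_rejects_fst_of_one(self):
        with pytest.raises(ValueError):
            slatkin_linearize(1.0)


class TestDiversity:
    def test_all_zero_without_segregating_sites(self):
        ds = make_dataset(
            [np.zeros((4, 0)), np.zeros((4, 0))], ["A", "A"], lengths=[100, 100]
        )
        stats = diversity_stats(ds, "A")
        assert stats["pi"] == 0.0
        assert stats["theta_w"] == 0.0

    def test_watterson_n2(self):
        h = np.zeros((2, 5), dtype=np.uint8)
        h[0, :] = 1  # 5 segregating sites between the two haplotypes
        ds = make_dataset([h], ["A"], lengths=[1000])
        assert diversity_stats(ds, "A")["theta_w"] == pytest.approx(0.005)

    def test_watterson_n4(self):
        h = np.zeros((4, 11), dtype=np.uint8)
        h[0, :] = 1
        ds = make_dataset([h], ["A", "A"], lengths=[1000])
        expected = 11 / (harmonic_number(3) * 1000)
        assert diversity_stats(ds, "A")["theta_w"] == pytest.approx(expected)

    def test_dxy_brute_force(self, small_dataset):
        stats = diversity_stats(small_dataset, "A", "B")
        rows_a = [0, 1, 2, 3]
        rows_b = [4, 5, 6, 7]
        total = 0.0
        length = 0
        for locus in small_dataset.loci:
            for a in rows_a:
                for b in rows_b:
                    total += (locus.haplotypes[a] != locus.haplotypes[b]).sum()
            length += locus.length
        assert stats["d_xy"] == pytest.approx(total / (16 * length))


class TestMomentEstimates:
    def test_population_against_itself_gives_zero_tau(self, two_tip_model):
        ds = simulate_dataset(
            two_tip_model, SampleConfig({"A": 4, "B": 1}), n_loci=400,
            locus_length=300, seed=21,
        )
        # split A's four individuals into two pseudo-populations: τ truth = 0
        assignment = {f"A_{k}": ("A1" if k < 2 else "A2") for k in range(4)}
        assignment.update({"B_0": "B"})
        relabeled = _relabel(ds, assignment)
        est = moment_estimates(relabeled, "A1", "A2")
        assert abs(est["tau"]) < 2e-4  # |τ̂| small for a panmictic split


class TestDistances:
    def test_self_distance_zero_and_symmetry(self, small_dataset):
        dm = genetic_distance_matrix(small_dataset)
        assert np.allclose(np.diag(dm.values), 0)
        assert np.allclose(dm.values, dm.values.T)

    def test_opposite_homozygotes_at_every_site(self):
        h = np.zeros((4, 10), dtype=np.uint8)
        h[2:, :] = 1  # individual 0 is 0/0, individual 1 is 1/1 everywhere
        ds = make_dataset([h], ["A", "B"])
        dm = genetic_distance_matrix(ds, metric="allele-sharing")
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_brute_force_recount(self, small_dataset):
        dm = genetic_distance_matrix(small_dataset, metric="allele-sharing")
        dosage = np.hstack(
            [small_dataset.genotype_matrix(l) for l in range(small_dataset.n_loci)]
        ).astype(float)
        n_sites = dosage.shape[1]
        for i in range(4):
            for j in range(4):
                expected = np.abs(dosage[i] - dosage[j]).sum() / (2 * n_sites)
                assert dm.values[i, j] == pytest.approx(expected)

    def test_euclidean_dosage_metric(self, small_dataset):
        dm = genetic_distance_matrix(small_dataset, metric="euclidean-dosage")
        dosage = np.hstack(
            [small_dataset.genotype_matrix(l) for l in range(small_dataset.n_loci)]
        ).astype(float)
        n_sites = dosage.shape[1]
        expected = np.linalg.norm(dosage[0] - dosage[1]) / np.sqrt(n_sites)
        assert dm.values[0, 1] == pytest.approx(expected)

    def test_population_level_mean_of_cross_pairs(self, small_dataset):
        ind = genetic_distance_matrix(small_dataset)
        pop = population_distance_matrix(small_dataset, ind)
        expected = np.mean([ind.values[i, j] for i in (0, 1) for j in (2, 3)])
        assert pop.values[0, 1] == pytest.approx(expected)

    def test_zero_overlap_pair_is_an_error(self):
        h = np.zeros((4, 3), dtype=np.uint8)
        ds = make_dataset([h], ["A", "B"], missing=[[True], [False]])
        with pytest.raises(ValueError, match="no genotyped sites"):
            genetic_distance_matrix(ds)

    def test_tsv_roundtrip(self, small_dataset, tmp_path):
        dm = genetic_distance_matrix(small_dataset)
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        dm2 = DistanceMatrix.from_tsv(path)
        assert dm2.labels == dm.labels
        assert dm2.metric == dm.metric
        np.testing.assert_allclose(dm2.values, dm.values, rtol=1e-9)


def _random_dm(n, rng, labels=None):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(0.5, 2.0, size=len(iu[0]))
    m = m + m.T
    return DistanceMatrix(m, labels or [f"x{i}" for i in range(n)])


class TestMantel:
    def test_perfect_linear_relation_gives_r_one(self):
        rng = np.random.default_rng(0)
        d1 = _random_dm(6, rng)
        d2 = DistanceMatrix(
            2 * d1.values + 1 - np.diag(np.full(6, 1.0)), d1.labels
        )
        result = mantel_test(d1, d2, n_permutations=99, seed=1)
        assert result["r"] == pytest.approx(1.0)

    def test_exhaustive_enumeration_n5(self):
        """Sampled-permutation p agrees with full enumeration over 5! = 120."""
        rng = np.random.default_rng(4)
        d1 = _random_dm(5, rng)
        d2 = DistanceMatrix(d1.values.copy(), d1.labels)
        iu = np.triu_indices(5, k=1)
        v1 = d1.values[iu]
        z1 = (v1 - v1.mean()) / v1.std()

        def r_of(perm):
            v = d2.values[np.ix_(perm, perm)][iu]
            return np.mean(z1 * (v - v.mean()) / v.std())

        r_obs = r_of(np.arange(5))
        assert r_obs == pytest.approx(1.0)
        rs = [r_of(np.array(p)) for p in itertools.permutations(range(5))]
        q = np.mean([r >= r_obs - 1e-12 for r in rs])  # exact tail fraction
        n_perm = 999
        result = mantel_test(d1, d2, n_permutations=n_perm, seed=7)
        # sampled count is Binomial(n_perm, q): compare at 4 sigma
        se = np.sqrt(q * (1 - q) / n_perm)
        assert abs(result["p"] - (1 + n_perm * q) / (1 + n_perm)) < 4 * se + 1 / n_perm

    def test_label_mismatch_and_zero_variance(self):
        rng = np.random.default_rng(2)
        d1 = _random_dm(5, rng)
        d2 = _random_dm(5, rng, labels=[f"y{i}" for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            mantel_test(d1, d2)
        flat = DistanceMatrix(
            np.ones((5, 5)) - np.eye(5), d1.labels
        )
        with pytest.raises(ValueError, match="variance"):
            mantel_test(d1, flat, n_permutations=9)

    def test_agrees_with_skbio(self):
        """Independent cross-check of r and the one-tailed p convention."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(9)
        d1 = _random_dm(8, rng)
        noise = _random_dm(8, rng)
        d2 = DistanceMatrix(0.7 * d1.values + 0.3 * noise.values, d1.labels)
        ours = mantel_test(d1, d2, n_permutations=999, seed=3)
        r_skbio, p_skbio, _ = skbio_mantel(
            SkbioDM(d1.values, ids=d1.labels),
            SkbioDM(d2.values, ids=d2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours["r"] == pytest.approx(float(r_skbio), abs=1e-9)
        assert abs(ours["p"] - float(p_skbio)) < 0.05


def test_plot_ibd_writes_figure(tmp_path):
    from phylodem.sumstats import plot_ibd

    rng = np.random.default_rng(5)
    geo = _random_dm(5, rng)
    lin = DistanceMatrix(geo.values * 0.1, geo.labels, metric="linearized-fst")
    out = tmp_path / "ibd.png"
    plot_ibd(lin, geo, out)
    assert out.stat().st_size > 0


class TestOrderingInvariance:
    def test_statistics_invariant_to_individual_and_locus_order(self, small_dataset):
        ds = small_dataset
        # permute individuals (with their haplotype row indices intact) and loci
        rng = np.random.default_rng(13)
        ind_perm = rng.permutation(len(ds.individuals))
        locus_perm = rng.permutation(ds.n_loci)
        shuffled = replace(
            ds,
            individuals=[ds.individuals[i] for i in ind_perm],
            loci=[ds.loci[l] for l in locus_perm],
            missing=ds.missing[np.ix_(ind_perm, locus_perm)],
        )
        f1 = weighted_fst(joint_sfs(ds, "A", "B"))
        f2 = weighted_fst(joint_sfs(shuffled, "A", "B"))
        assert f2 == pytest.approx(f1, abs=1e-15)
        s1 = diversity_stats(ds, "A", "B")
        s2 = diversity_stats(shuffled, "A", "B")
        for key in ("pi_A", "pi_B", "d_xy"):
            assert s2[key] == pytest.approx(s1[key], abs=1e-15)
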