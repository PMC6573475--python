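"""Phi-st, AMOVA, Mantel, NMDS, shared haplotypes and rank contrasts."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from oracles import (
    amova3_oracle,
    da_oracle,
    mantel_r_oracle,
    mwu_u_oracle,
    phist_2pop_oracle,
)

from msypop.diversity import population_summaries
from msypop.io import (
    DegenerateInputError,
    DistanceMatrix,
    HaplotypeAlignment,
    collapse_haplotypes,
)
from msypop.structure import (
    amova,
    corrected_pairwise_difference,
    geographic_distance_matrix,
    great_circle_distance,
    mantel,
    nmds,
    phist_pairwise,
    rank_contrast,
    residence_contrast_report,
    shared_haplotype_matrix,
)


def _aln(seqs, pops):
    return HaplotypeAlignment(
        sample_ids=[f"s{i}" for i in range(len(seqs))],
        populations=pops,
        sites=np.array([list(s) for s in seqs]),
        locus_length_bp=len(seqs[0]),
    )


class TestPhist:
    def test_fixed_difference_gives_one(self):
        aln = _aln(["AAAA"] * 3 + ["TTTT"] * 3, ["P1"] * 3 + ["P2"] * 3)
        phi, p = phist_pairwise(aln, n_perm=99, seed=0)
        assert phi.values[0, 1] == pytest.approx(1.0)
        assert p.values[0, 1] < 0.2

    def test_random_split_near_zero(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(16)]
        aln = _aln(seqs, ["P1"] * 8 + ["P2"] * 8)
        phi, _ = phist_pairwise(aln, n_perm=99, seed=0)
        assert abs(phi.values[0, 1]) < 0.15

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        for rep in range(5):
            seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(8)]
            aln = _aln(seqs, ["P1"] * 4 + ["P2"] * 4)
            phi, _ = phist_pairwise(aln, n_perm=9, seed=0)
            expected = phist_2pop_oracle(seqs[:4], seqs[4:], squared=True)
            assert phi.values[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_small_population_skipped_with_warning(self):
        aln = _aln(["AAAA", "AATT", "ATTT", "TTTT"], ["P1", "P1", "P1", "P2"])
        with pytest.warns(UserWarning, match="n < 2"):
            phi, _ = phist_pairwise(aln, n_perm=9, seed=0)
        assert math.isnan(phi.values[0, 1])


class TestCorrectedPairwiseDifference:
    def test_identical_monomorphic_populations_zero(self):
        aln = _aln(["AAAT"] * 4, ["P1", "P1", "P2", "P2"])
        assert corrected_pairwise_difference(aln, "P1", "P2") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_fixed_haplotypes_k_apart(self):
        aln = _aln(["AAAA"] * 3 + ["ATTT"] * 3, ["P1"] * 3 + ["P2"] * 3)
        assert corrected_pairwise_difference(aln, "P1", "P2") == pytest.approx(3.0)

    def test_matches_mean_term_oracle(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(6)]
        aln = _aln(seqs, ["P1"] * 3 + ["P2"] * 3)
        assert corrected_pairwise_difference(aln, "P1", "P2") == pytest.approx(
            da_oracle(seqs[:3], seqs[3:]), abs=1e-10
        )


class TestAmova:
    def test_panmictic_pool_mostly_within(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(24)]
        res = amova(_aln(seqs, ["P1"] * 8 + ["P2"] * 8 + ["P3"] * 8),
                    n_perm=99, seed=0)
        assert res.percentages["within_populations"] > 90
        assert abs(res.percentages["among_populations"]) < 10

    def test_each_population_its_own_group_kills_sigma_b(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(12)]
        aln = _aln(seqs, ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4)
        with pytest.warns(UserWarning, match="single population"):
            res = amova(aln, {"P1": "G1", "P2": "G2", "P3": "G3"},
                        n_perm=9, seed=0)
        assert res.variance_components[
            "among_populations_within_groups"
        ] == pytest.approx(0.0, abs=1e-9)

    def test_three_level_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("AT"), 10)) for _ in range(16)]
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
        aln = _aln(seqs, pops)
        res = amova(aln, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"},
                    n_perm=9, seed=0)
        oracle = amova3_oracle(
            [[seqs[:4], seqs[4:8]], [seqs[8:12], seqs[12:16]]], squared=True
        )
        assert res.variance_components["among_groups"] == pytest.approx(
            oracle["sigma_a"], abs=1e-10
        )
        assert res.variance_components[
            "among_populations_within_groups"
        ] == pytest.approx(oracle["sigma_b"], abs=1e-10)
        assert res.variance_components["within_populations"] == pytest.approx(
            oracle["sigma_c"], abs=1e-10
        )
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        for phi in ("phi_st", "phi_ct", "phi_sc"):
            assert res.phi_stats[phi] == pytest.approx(oracle[phi], abs=1e-10)

    def test_percentages_sum_to_100_with_negative_component(self):
        # near-identical populations in distinct groups produce negative
        # among-group components, mirroring the sign convention of reported
        # AMOVA tables
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), 15)
        seqs = []
        for _ in range(16):
            s = base.copy()
            k = rng.integers(0, 3)
            idx = rng.choice(15, size=k, replace=False)
            for i in idx:
                s[i] = rng.choice(list("ACGT"))
            seqs.append("".join(s))
        aln = _aln(seqs, ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4)
        res = amova(aln, {"P1": "G1", "P2": "G2", "P3": "G1", "P4": "G2"},
                    n_perm=9, seed=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_two_level_reproduces_phist_entry(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(10)]
        aln = _aln(seqs, ["P1"] * 5 + ["P2"] * 5)
        res = amova(aln, n_perm=9, seed=0)
        phi, _ = phist_pairwise(aln, n_perm=9, seed=0)
        assert res.phi_stats["phi_st"] == pytest.approx(
            phi.values[0, 1], abs=1e-12
        )


class TestSharedHaplotypes:
    def test_disjoint_sets_zero(self):
        aln = _aln(["AAAA", "AAAT", "TTTT", "TTTA"], ["P1", "P1", "P2", "P2"])
        m = shared_haplotype_matrix(collapse_haplotypes(aln))
        assert m.values[0, 1] == 0

    def test_identical_single_haplotype(self):
        aln = _aln(["AAAA"] * 4, ["P1", "P1", "P2", "P2"])
        raw = shared_haplotype_matrix(collapse_haplotypes(aln), "none")
        rel = shared_haplotype_matrix(collapse_haplotypes(aln), "per_pair")
        assert raw.values[0, 1] == 1
        assert rel.values[0, 1] == pytest.approx(1.0)

    def test_three_population_hand_count(self):
        seqs = ["AAAA", "AAAT", "AAAA", "ATTT", "AAAA", "AAAT"]
        pops = ["P1", "P1", "P2", "P2", "P3", "P3"]
        m = shared_haplotype_matrix(collapse_haplotypes(_aln(seqs, pops)))
        # AAAA shared by all three; AAAT shared by P1 and P3
        assert m.values[0, 1] == 1
        assert m.values[0, 2] == 2
        assert m.values[1, 2] == 1


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_distance(10, 20, 10, 20) == 0.0

    def test_antipodal_half_circumference(self):
        d = great_circle_distance(0, 0, 0, 180)
        assert d == pytest.approx(math.pi * 6371.0088, rel=1e-6)

    def test_one_degree_longitude_at_equator(self):
        d = great_circle_distance(0, 0, 0, 1)
        assert d == pytest.approx(math.pi * 6371.0088 / 180, rel=1e-6)


class TestMantel:
    def _random_dm(self, rng, n=6):
        m = rng.uniform(1, 10, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix([f"l{i}" for i in range(n)], m)

    def test_affine_relation_r_one(self):
        rng = np.random.default_rng(8)
        a = self._random_dm(rng)
        b = DistanceMatrix(a.labels, 2 * a.values + 3 - 3 * np.eye(6))
        res = mantel(a, b, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_negative_relation_r_minus_one(self):
        rng = np.random.default_rng(8)
        a = self._random_dm(rng)
        vals = a.values.max() + 1 - a.values
        np.fill_diagonal(vals, 0)
        b = DistanceMatrix(a.labels, vals)
        res = mantel(a, b, n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_r_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(10)
        a, b = self._random_dm(rng, 5), self._random_dm(rng, 5)
        b = DistanceMatrix(a.labels, b.values)
        res = mantel(a, b, n_perm=99, seed=1)
        assert res.r == pytest.approx(
            mantel_r_oracle(a.values, b.values), abs=1e-12
        )

    def test_p_stable_across_seeds(self):
        rng = np.random.default_rng(12)
        n = 8
        base = rng.uniform(size=(n, 2))
        geo = np.sqrt(((base[:, None] - base[None, :]) ** 2).sum(-1))
        gen = geo + rng.normal(0, 0.2, size=(n, n))
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        labels = [f"l{i}" for i in range(n)]
        a = DistanceMatrix(labels, geo)
        b = DistanceMatrix(labels, gen)
        p1 = mantel(a, b, n_perm=9999, seed=1).p
        p2 = mantel(a, b, n_perm=9999, seed=2).p
        assert abs(p1 - p2) < 0.01

    def test_permutation_null_mean_near_zero(self):
        rng = np.random.default_rng(13)
        a = self._random_dm(rng, 7)
        iu = np.triu_indices(7, 1)
        va = a.values[iu]
        rs = []
        for _ in range(2000):
            perm = rng.permutation(7)
            rs.append(np.corrcoef(va, a.values[np.ix_(perm, perm)][iu])[0, 1])
        assert abs(np.mean(rs)) < 0.02

    def test_constant_matrix_rejected(self):
        labels = list("abcd")
        a = DistanceMatrix(labels, 1 - np.eye(4))
        with pytest.raises(DegenerateInputError):
            mantel(a, a, n_perm=9, seed=0)

    def test_geographic_matrix_from_metadata(self, small_study):
        _, meta, _ = small_study
        geo = geographic_distance_matrix(meta)
        assert geo.values.max() > 0
        assert len(geo.labels) == len(meta)


class TestNMDS:
    def test_equilateral_three_points(self):
        m = DistanceMatrix(list("abc"), np.array(
            [[0, 1.0, 1], [1, 0, 1], [1, 1, 0]]))
        res = nmds(m, k=2, n_restarts=5, seed=0)
        assert res.stress < 1e-6

    def test_perfect_reconstruction_of_planar_points(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        m = DistanceMatrix([f"p{i}" for i in range(7)], d)
        res = nmds(m, k=2, n_restarts=10, seed=0)
        assert res.stress < 1e-6

    def test_stress_nonincreasing_in_k(self):
        rng = np.random.default_rng(15)
        m = rng.uniform(1, 5, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"p{i}" for i in range(10)], m)
        s2 = nmds(dm, k=2, n_restarts=10, seed=0).stress
        s3 = nmds(dm, k=3, n_restarts=10, seed=0).stress
        assert s3 <= s2 + 1e-9

    def test_stress_competitive_with_sklearn_smacof(self):
        from sklearn.manifold import MDS

        rng = np.random.default_rng(22)
        m = rng.uniform(1, 5, size=(9, 9))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"p{i}" for i in range(9)], m)
        ours = nmds(dm, k=2, n_restarts=10, seed=0).stress
        ref = MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=10, random_state=0, normalized_stress=True,
        ).fit(m)
        assert ours <= ref.stress_ + 0.02

    def test_negative_entries_clamped_with_warning(self):
        vals = np.array([[0, -0.02, 0.5], [-0.02, 0, 0.4], [0.5, 0.4, 0]])
        m = DistanceMatrix(list("abc"), vals, kind="phist")
        with pytest.warns(UserWarning, match="clamped"):
            res = nmds(m, k=2, n_restarts=3, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)


class TestRankContrast:
    def test_identical_groups_p_one(self):
        res = rank_contrast([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)
        assert res.Z == pytest.approx(0.0, abs=1e-12)

    def test_complete_separation(self):
        res = rank_contrast([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.U in (0.0, 16.0)

    def test_u_matches_pairwise_win_count(self):
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        res = rank_contrast(x, y)
        assert res.U == pytest.approx(mwu_u_oracle(x, y))

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=12)
        y = rng.normal(0.8, 1, size=15)
        res = rank_contrast(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.U == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_all_tied_returns_z_zero(self):
        res = rank_contrast([5, 5, 5], [5, 5])
        assert res.Z == 0.0 and res.p == 1.0

    def test_u_complement_identity(self):
        rng = np.random.default_rng(17)
        x = rng.integers(0, 50, 9).astype(float)
        y = rng.integers(0, 50, 7).astype(float)
        u1 = rank_contrast(x, y).U
        u2 = rank_contrast(y, x).U
        assert u1 + u2 == pytest.approx(len(x) * len(y))


class TestResidenceContrast:
    def test_direction_matches_construction(self, small_study):
        aln, meta, _ = small_study
        summaries = population_summaries(aln, meta, n_sims=100, seed=0)
        phist, _ = phist_pairwise(aln, n_perm=19, seed=0)
        rows = residence_contrast_report(summaries, phist, meta)
        by = {r["contrast"]: r for r in rows}
        # patrilocal AA-like block built with lower diversity
        assert by["h_patrilocal_vs_matrilocal"]["direction"] == "matrilocal_higher"
        assert by["phist_patrilocal_vs_matrilocal"]["direction"] == "patrilocal_higher"

    def test_single_class_rejected(self, small_study):
        aln, meta, _ = small_study
        summaries = population_summaries(aln, meta, n_sims=100, seed=0)
        phist, _ = phist_pairwise(aln, n_perm=19, seed=0)
        for m in meta:
            m.residence = "patrilocal"
        with pytest.raises(DegenerateInputError):
            residence_contrast_report(summaries, phist, meta)

    def test_identical_data_in_both_classes_p_one(self):
        seqs = ["AAAA", "AAAT", "AATT"] * 2
        pops = ["P1"] * 3 + ["P2"] * 3
        aln = _aln(seqs, pops)
        from msypop.io import PopulationMetadata

        meta = [
            PopulationMetadata("P1", "x", "AA", "r", 10, 100, "patrilocal", 3),
            PopulationMetadata("P2", "x", "ST", "r", 11, 101, "matrilocal", 3),
        ]
        summaries = population_summaries(aln, meta, n_sims=100, seed=0)
        phist, _ = phist_pairwise(aln, n_perm=19, seed=0)
        rows = residence_contrast_report(summaries, phist, meta)
        for r in rows:
            if r["contrast"].startswith(("h_", "mpd_")):
                assert r["p"] == pytest.approx(1.0)
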