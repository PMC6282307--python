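"""SNP filtering, IBS distances, classical MDS and group assignment."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

import polyphylo as pp
from polyphylo.diversity import (
    DistanceMatrix,
    GenotypeMatrix,
    assign_groups,
    classical_mds,
    filter_variants,
    ibs_distance,
    read_vcf,
)
from polyphylo.simulate import GenotypeSimConfig, simulate_genotypes, write_vcf


def toy_vcf(tmp_path, body, samples=("s1", "s2", "s3")):
    path = tmp_path / "toy.vcf"
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    path.write_text(header + body)
    return path


class TestReadVcf:
    def test_gt_dosages(self, tmp_path):
        path = toy_vcf(
            tmp_path,
            "1\t1\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t2\tv2\tA\tT\t.\t.\t.\tGT\t0/1\t./.\t0/0\n",
        )
        g = read_vcf(path)
        assert g.samples == ["s1", "s2", "s3"]
        assert g.calls[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert g.calls[0, 1] == 1.0 and np.isnan(g.calls[1, 1])

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        path = toy_vcf(
            tmp_path,
            "1\t1\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t2\tv2\tA\tT,G\t.\t.\t.\tGT\t0/1\t0/2\t0/0\n",
        )
        g = read_vcf(path)
        assert g.variant_ids == ["v1"]
        assert g.n_multiallelic_skipped == 1

    def test_simulated_vcf_roundtrip(self, tmp_path):
        matrix, _ = simulate_genotypes(
            GenotypeSimConfig(n_snps=40, samples_per_group=4, missing_rate=0.1,
                              seed=8)
        )
        write_vcf(matrix, tmp_path / "sim.vcf")
        back = read_vcf(tmp_path / "sim.vcf")
        np.testing.assert_array_equal(
            np.nan_to_num(back.calls, nan=-9), np.nan_to_num(matrix.calls, nan=-9)
        )


class TestFilterVariants:
    def make(self, calls):
        calls = np.asarray(calls, dtype=float)
        n, m = calls.shape
        return GenotypeMatrix([f"s{i}" for i in range(n)],
                              [f"v{j}" for j in range(m)], calls)

    def test_missingness_rule_boundary(self):
        # 100 samples: 10 missing (10%) kept, 11 missing (11%) removed
        base = np.tile([0.0, 1.0], 50)
        v_keep, v_drop = base.copy(), base.copy()
        v_keep[:10] = np.nan
        v_drop[:11] = np.nan
        g = self.make(np.column_stack([v_keep, v_drop]))
        kept = filter_variants(g)
        assert kept.variant_ids == ["v0"]

    def test_maf_rule_boundary(self):
        # single heterozygote among 100 samples: MAF 0.005 < 0.01 -> removed
        rare = np.zeros(100)
        rare[0] = 1.0
        common = np.zeros(100)
        common[:2] = 1.0                      # MAF 0.01 kept (inclusive)
        mono = np.zeros(100)                  # MAF 0 removed
        g = self.make(np.column_stack([rare, common, mono]))
        kept = filter_variants(g)
        assert kept.variant_ids == ["v1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(30, 50)).astype(float)
        calls[rng.random(calls.shape) < 0.2] = np.nan
        g = self.make(calls)
        once = filter_variants(g)
        twice = filter_variants(once)
        assert once.variant_ids == twice.variant_ids

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(40, 30)).astype(float)
        g = self.make(calls)
        kept = filter_variants(g)
        idx = [g.variant_ids.index(v) for v in kept.variant_ids]
        assert idx == sorted(idx)


class TestIbsDistance:
    def test_identical_samples_distance_zero(self):
        calls = np.tile([0.0, 1.0, 2.0, 1.0], (2, 1))
        d = ibs_distance(GenotypeMatrix(["a", "b"], [f"v{i}" for i in range(4)], calls))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        calls = np.array([[0.0] * 5, [2.0] * 5])
        d = ibs_distance(GenotypeMatrix(["a", "b"], [f"v{i}" for i in range(5)], calls))
        assert d.values[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        calls = np.array([[0.0], [1.0]])
        d = ibs_distance(GenotypeMatrix(["a", "b"], ["v0"], calls))
        assert d.values[0, 1] == 0.5

    def test_pairwise_complete_ignores_missing(self):
        calls = np.array([[0.0, np.nan, 2.0], [0.0, 1.0, np.nan]])
        d = ibs_distance(GenotypeMatrix(["a", "b"], ["v0", "v1", "v2"], calls))
        assert d.values[0, 1] == 0.0       # only v0 is shared

    def test_all_missing_pair_raises(self):
        calls = np.array([[0.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="share no"):
            ibs_distance(GenotypeMatrix(["a", "b"], ["v0", "v1"], calls))

    def test_sample_reordering_permutes_matrix(self, np_rng):
        calls = np_rng.integers(0, 3, size=(6, 30)).astype(float)
        g = GenotypeMatrix([f"s{i}" for i in range(6)],
                           [f"v{j}" for j in range(30)], calls)
        perm = np_rng.permutation(6)
        g2 = GenotypeMatrix([g.samples[i] for i in perm],
                            g.variant_ids, calls[perm])
        d1, d2 = ibs_distance(g).values, ibs_distance(g2).values
        np.testing.assert_allclose(d2, d1[np.ix_(perm, perm)])


class TestClassicalMds:
    def test_recovers_planar_configuration(self, np_rng):
        """Euclidean-embeddable distances reproduce the generating points."""
        X = np_rng.normal(size=(20, 2)) / 8.0
        D = DistanceMatrix([f"s{i}" for i in range(20)], squareform(pdist(X)))
        res = classical_mds(D, 2)
        Xc = X - X.mean(axis=0)
        R, _ = orthogonal_procrustes(res.coordinates, Xc)
        rms = np.sqrt(((res.coordinates @ R - Xc) ** 2).mean())
        assert rms < 1e-8
        np.testing.assert_allclose(
            squareform(pdist(res.coordinates)), D.values, atol=1e-8
        )

    def test_equilateral_triangle(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.ones((3, 3)) - np.eye(3))
        res = classical_mds(D, 2)
        np.testing.assert_allclose(pdist(res.coordinates), [1, 1, 1], atol=1e-10)

    def test_duplicate_samples_coincide(self):
        D = DistanceMatrix(
            ["a", "a2", "b"],
            np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float),
        )
        res = classical_mds(D, 2)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-12)

    def test_coordinates_centered_eigenvalues_sorted(self, np_rng):
        X = np_rng.normal(size=(10, 3)) / 10.0
        D = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(X)))
        res = classical_mds(D, 3)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)
        assert all(np.diff(res.eigenvalues) <= 1e-9)

    def test_k_too_large_rejected(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(ValueError):
            classical_mds(D, 2)


class TestAssignGroups:
    def test_recovers_separated_clusters(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        matrix, labels = simulate_genotypes(GenotypeSimConfig(seed=13))
        kept = filter_variants(matrix)
        res = classical_mds(ibs_distance(kept), 2)
        groups = assign_groups(res.coordinates, 3, seed=1)
        assert sklearn.adjusted_rand_score(labels, groups) == 1.0

    def test_single_group(self, np_rng):
        coords = np_rng.normal(size=(7, 2))
        assert set(assign_groups(coords, 1, seed=0)) == {0}

    def test_each_sample_own_group(self, np_rng):
        coords = np_rng.normal(size=(5, 2))
        assert sorted(assign_groups(coords, 5, seed=0)) == list(range(5))

    def test_deterministic_given_seed(self, np_rng):
        coords = np_rng.normal(size=(30, 2))
        a = assign_groups(coords, 3, seed=42)
        b = assign_groups(coords, 3, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_too_many_groups_rejected(self, np_rng):
        with pytest.raises(ValueError):
            assign_groups(np_rng.normal(size=(4, 2)), 5, seed=0)
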