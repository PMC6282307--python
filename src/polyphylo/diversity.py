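"""Post-VCF genetic-diversity analysis: filtering, IBS distances, MDS.

The genotyping-by-sequencing stage consumes a biallelic SNP matrix
(samples x variants, alt-allele dosages 0/1/2 with missing calls),
filters variants on missingness (> 10% removed) and minor allele
frequency (< 1% removed), computes pairwise identity-by-state (IBS)
distances ``1 - mean shared-allele fraction`` over pairwise-complete
variants, embeds them by classical (metric) multidimensional scaling,
and optionally partitions the leading coordinates into k groups by
k-medoids. This mirrors the standard PLINK-style IBS/MDS clustering of
reduced-representation genotype panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes: samples x variants, NaN marks a missing call."""

    samples: list[str]
    variant_ids: list[str]
    calls: np.ndarray                    # float array, values 0/1/2 or NaN
    chrom: Optional[list[str]] = None
    pos: Optional[list[int]] = None
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.variant_ids)):
            raise ValueError("call matrix shape does not match sample/variant ids")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must be dosages 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.calls).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.calls, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=self.samples,
            variant_ids=[v for v, k in zip(self.variant_ids, keep) if k],
            calls=self.calls[:, keep],
            chrom=[c for c, k in zip(self.chrom, keep) if k] if self.chrom else None,
            pos=[p for p, k in zip(self.pos, keep) if k] if self.pos else None,
            n_multiallelic_skipped=self.n_multiallelic_skipped,
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class MdsResult:
    """Classical-MDS coordinates (column-centered) plus Gram eigenvalues."""

    samples: list[str]
    coordinates: np.ndarray              # samples x k
    eigenvalues: np.ndarray              # all eigenvalues, non-increasing

    def to_dataframe(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"C{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample", self.samples)
        return df


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT dosages from a VCF; multiallelic records are skipped (counted)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
    vcf.close()
    if skipped:
        logger.info("skipped %d multiallelic record(s)", skipped)
    calls = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, ids, calls, chroms, poss,
                          n_multiallelic_skipped=skipped)


def filter_variants(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
) -> GenotypeMatrix:
    """Keep variants with missingness <= ``max_missing`` and MAF >= ``min_maf``.

    MAF is computed on non-missing calls; variant order is preserved and
    the operation is idempotent. Defaults match the usual GBS cleaning
    thresholds (remove > 10% missing, remove MAF < 1%).
    """
    miss = genotypes.missing_fraction()
    maf = genotypes.maf()
    keep = (miss <= max_missing) & (maf >= min_maf)
    kept = genotypes.subset_variants(keep)
    logger.info(
        "filter_variants: kept %d/%d (removed %d by missingness > %.3g, "
        "%d by MAF < %.3g)",
        kept.n_variants, genotypes.n_variants,
        int((miss > max_missing).sum()),
        max_missing,
        int(((miss <= max_missing) & (maf < min_maf)).sum()),
        min_maf,
    )
    if kept.n_variants == 0:
        logger.warning("filter_variants removed every variant")
    return kept


def ibs_distance(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise IBS distance: 1 - mean shared-allele fraction.

    Per variant the shared fraction is ``1 - |d_i - d_j| / 2`` for
    dosages d; the mean runs over variants non-missing in both samples
    (pairwise-complete, no imputation). A pair with no shared variant is
    an error.
    """
    n = genotypes.n_samples
    if n < 2:
        raise ValueError("at least two samples are required")
    X = genotypes.calls
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]) / 2.0            # (n-i-1) x variants
        shared = 1.0 - diff
        counts = np.sum(~np.isnan(shared), axis=1)
        if np.any(counts == 0):
            j = int(np.where(counts == 0)[0][0]) + i + 1
            raise ValueError(
                f"samples {genotypes.samples[i]!r} and {genotypes.samples[j]!r} "
                "share no genotyped variant"
            )
        d = 1.0 - np.nansum(shared, axis=1) / counts
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return DistanceMatrix(genotypes.samples, D)


def classical_mds(distances: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical (Torgerson) MDS: double-center -D^2/2, eigendecompose.

    Coordinates are the top-k eigenvectors scaled by the square root of
    their (positive) eigenvalues; negative eigenvalues — evidence of a
    non-Euclidean distance — are excluded from axis selection. Axis signs
    are fixed deterministically (largest-magnitude loading positive).
    """
    D = distances.values
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k must be < number of samples ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    axis = 0
    for i in range(n):
        if axis >= k:
            break
        if eigval[i] > 1e-12:
            v = eigvec[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, axis] = v * np.sqrt(eigval[i])
            axis += 1
    return MdsResult(distances.samples, coords, eigval)


def assign_groups(
    coordinates: np.ndarray,
    k_groups: int,
    seed: Optional[int] = None,
    n_restarts: int = 10,
) -> np.ndarray:
    """Partition MDS coordinates into ``k_groups`` by k-medoids (PAM).

    Deterministic given ``seed``; restarts keep the best total
    within-cluster distance. Written here because no installed library
    ships k-medoids.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k_groups <= n:
        raise ValueError(f"k_groups must be in [1, {n}]")
    if k_groups == n:
        return np.arange(n)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    rng = np.random.default_rng(seed)

    best_cost, best_labels = np.inf, None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k_groups, replace=False)
        for _ in range(100):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for g in range(k_groups):
                members = np.where(labels == g)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[g] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    # stable group numbering: order groups by first occurrence
    remap, out = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out
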