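"""Between-sample AE sharing and classical MDS embedding.

The distance between two samples is the fraction of their shared AE sites
called significant in exactly one of the two — 0 for samples that agree on
every shared site, 1 for samples that disagree on all of them. "Shared"
means the site passed the depth threshold and QC filters and was tested in
both samples. The resulting distance matrix is embedded with classical
(Torgerson) multidimensional scaling for batch-effect inspection: samples
that cluster by laboratory or sequencing depth rather than biology reveal
technical structure in the significance calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence, Set

import numpy as np

from .ae_stats import AEResult

__all__ = [
    "SampleDistanceMatrix",
    "pairwise_ae_distance",
    "ae_distance_matrix",
    "classical_mds",
]


@dataclass(frozen=True)
class SampleDistanceMatrix:
    """Pairwise AE distances with the shared-site totals behind them.

    ``d`` is symmetric with zero diagonal; cells with zero shared sites are
    NaN (undefined) and ``shared_counts`` exposes the denominators.
    """

    sample_ids: tuple[str, ...]
    d: np.ndarray
    shared_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.shared_counts.shape != (n, n):
            raise ValueError("matrix shapes must match number of samples")

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.d).any())


def pairwise_ae_distance(
    sig_a: Set[Hashable], sig_b: Set[Hashable], shared: Set[Hashable]
) -> float:
    """AE distance between two samples over their shared site universe.

    Number of shared sites significant in exactly one sample, divided by
    the number of shared sites. Significant-site sets are restricted to the
    shared universe before comparison.
    """
    if len(shared) == 0:
        raise ValueError("no shared sites: distance undefined")
    a = set(sig_a) & set(shared)
    b = set(sig_b) & set(shared)
    return len(a ^ b) / len(shared)


def ae_distance_matrix(
    results_by_sample: Mapping[str, Sequence[AEResult]]
) -> SampleDistanceMatrix:
    """Build the all-pairs distance matrix from per-sample AE results.

    Each sample's tested sites (every AEResult present) define its site
    universe; a pair's shared set is the intersection of the two universes.
    Pairs with no shared sites get NaN.
    """
    sample_ids = tuple(results_by_sample)
    universes = {
        s: {r.site.key for r in results_by_sample[s]} for s in sample_ids
    }
    sig_sets = {
        s: {r.site.key for r in results_by_sample[s] if r.significant}
        for s in sample_ids
    }
    n = len(sample_ids)
    d = np.zeros((n, n))
    shared_counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared_counts[i, i] = len(universes[sample_ids[i]])
        for j in range(i + 1, n):
            shared = universes[sample_ids[i]] & universes[sample_ids[j]]
            shared_counts[i, j] = shared_counts[j, i] = len(shared)
            if not shared:
                d[i, j] = d[j, i] = np.nan
            else:
                dist = pairwise_ae_distance(
                    sig_sets[sample_ids[i]], sig_sets[sample_ids[j]], shared
                )
                d[i, j] = d[j, i] = dist
    return SampleDistanceMatrix(sample_ids=sample_ids, d=d, shared_counts=shared_counts)


def classical_mds(
    dist: SampleDistanceMatrix | np.ndarray, k: int = 2
) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes it and
    returns the top-``k`` coordinate columns scaled by root-eigenvalues.
    For a Euclidean-embeddable matrix the embedding reproduces the input
    distances exactly (up to sign and rotation of the axes). Negative
    eigenvalues — possible because the AE distance is not guaranteed
    Euclidean — are truncated to zero with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.d if isinstance(dist, SampleDistanceMatrix) else np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError(
            "distance matrix has undefined cells; impute them or drop the "
            "samples with no shared sites before embedding"
        )
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9 * max(1.0, abs(eigval[0]))).any():
        warnings.warn(
            "distance matrix is not Euclidean-embeddable; negative "
            "eigenvalues truncated to zero",
            stacklevel=2,
        )
    eigval = np.clip(eigval, 0.0, None)
    k = min(k, n)
    return eigvec[:, :k] * np.sqrt(eigval[:k])
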