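"""Sample clustering of log-ratio profiles and group-separation testing.

Mirrors the classic expression-matrix workflow: log-transform the
ratios, compute city-block (Manhattan) distances between sample
profiles with pairwise-complete handling of missing cells, agglomerate,
cut into two groups, and test tumor/normal separation with Welch's
unequal-variance t-test on a per-sample summary score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .io_formats import CANCER, NORMAL, RatioMatrix

LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterResult:
    """Two-group agglomerative clustering of samples.

    ``merge_tree`` is the scipy linkage matrix (each row: the two merged
    node indices, merge height, member count).  ``assignment`` maps each
    sample to group "A" or "B", "A" being the group of the first sample
    in input order.  ``composition`` counts cancer/normal members per
    group.
    """

    merge_tree: np.ndarray
    assignment: dict[str, str]
    composition: dict[str, dict[str, int]]
    welch_p: float | None = None

    @property
    def tumor_only_group(self) -> str | None:
        """Label of a group with >=1 cancer and zero normal samples."""
        for g, comp in self.composition.items():
            if comp[NORMAL] == 0 and comp[CANCER] > 0:
                return g
        return None


def log_transform(matrix: RatioMatrix, base: float = 2.0) -> pd.DataFrame:
    """Replace each present ratio by its log; missing cells stay missing."""
    if base <= 0 or base == 1:
        raise ValueError(f"invalid logarithm base {base}")
    return np.log(matrix.values) / math.log(base)


def cityblock_distance(transformed: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete city-block distances between sample columns.

    For each sample pair the mean absolute difference over proteins
    present in both is rescaled by the total protein count, so sparser
    pairs are not systematically closer.  A pair sharing no present
    protein is an error.
    """
    samples = list(transformed.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    x = transformed.to_numpy(dtype=float)
    n_prot = x.shape[0]
    m = len(samples)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n_both = int(both.sum())
            if n_both == 0:
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no "
                    f"quantified protein")
            d[i, j] = d[j, i] = \
                np.abs(x[both, i] - x[both, j]).mean() * n_prot
    return pd.DataFrame(d, index=samples, columns=samples)


def hierarchical_cluster(distances: pd.DataFrame,
                         groups: Mapping[str, str],
                         linkage_method: str = "average") -> ClusterResult:
    """Agglomerate samples and cut the dendrogram into two groups.

    ``groups`` labels each sample cancer/normal for the composition
    report.  Merging is deterministic: scipy resolves equal-height
    candidates by the smallest node indices.
    """
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance table must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance table must have a zero diagonal")
    samples = list(distances.columns)
    z = linkage(squareform(d, checks=False), method=linkage_method)
    flat = fcluster(z, t=2, criterion="maxclust")
    first = flat[0]
    assignment = {s: ("A" if c == first else "B")
                  for s, c in zip(samples, flat)}
    composition = {
        g: {CANCER: sum(1 for s in samples
                        if assignment[s] == g and groups[s] == CANCER),
            NORMAL: sum(1 for s in samples
                        if assignment[s] == g and groups[s] == NORMAL)}
        for g in ("A", "B")
    }
    return ClusterResult(merge_tree=z, assignment=assignment,
                         composition=composition)


def sample_scores(matrix: RatioMatrix,
                  protein_set: Iterable[str] | None = None,
                  base: float = 2.0) -> pd.Series:
    """Per-sample mean |log ratio| over the (present) proteins of a set.

    This scalar summarizes how far a sample's profile sits from the
    reference pool; dysregulated proteins push tumor scores up in both
    directions of regulation.
    """
    sub = matrix if protein_set is None else matrix.subset(protein_set)
    logged = log_transform(sub, base=base)
    return logged.abs().mean(axis=0, skipna=True)


def welch_separation_test(matrix: RatioMatrix,
                          protein_set: Iterable[str] | None = None) -> float:
    """Welch's two-tailed t-test of cancer vs normal sample scores.

    Returns the two-sided p-value; identical group score distributions
    give p = 1.  Each group must contribute at least two samples.
    """
    scores = sample_scores(matrix, protein_set)
    cancer = scores[matrix.cancer_samples].dropna()
    normal = scores[matrix.normal_samples].dropna()
    if len(cancer) < 2 or len(normal) < 2:
        raise ValueError("both groups need >= 2 samples with scores")
    t, p = stats.ttest_ind(cancer, normal, equal_var=False)
    return float(p)


def cluster_matrix(matrix: RatioMatrix,
                   protein_set: Iterable[str] | None = None,
                   base: float = 2.0,
                   linkage_method: str = "average",
                   with_welch: bool = True) -> ClusterResult:
    """Convenience pipeline: log -> distances -> cluster (+ Welch p)."""
    sub = matrix if protein_set is None else matrix.subset(protein_set)
    logged = log_transform(sub, base=base)
    dist = cityblock_distance(logged)
    result = hierarchical_cluster(dist, sub.groups, linkage_method)
    if with_welch:
        try:
            result.welch_p = welch_separation_test(matrix, protein_set)
        except ValueError:
            result.welch_p = None
    return result
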