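"""Entropy-guided merging of overlapping mixture components.

Greedy insertion can overestimate the number of biologically distinct
clusters when components overlap heavily (a skewed population may be
covered by two symmetric-ish components, say). Merging repairs this after
the fit, operating purely on the posterior assignment matrix: at each
stage the pair of clusters whose combination most reduces the assignment
entropy

    Ent(k) = - sum_j sum_i z_ij log z_ij

is summed column-wise, down from k = g to k = 1. Component parameters and
weights are untouched, so the overall mixture density is exactly invariant
along the path; only the grouping of components into clusters changes.
The number of clusters is read off the entropy-versus-k curve, either at
its elbow (largest second difference) or at the largest single entropy
drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .mixture import FitResult, STNMixture

__all__ = ["ClusterPosteriors", "MergePath", "entropy", "select_merge_pair",
           "merge_pair", "merge_path", "select_num_clusters",
           "merged_cluster_density"]


@dataclass
class ClusterPosteriors:
    """Posterior cluster-membership probabilities plus bookkeeping.

    ``z`` is n x k, rows summing to one; ``members[c]`` lists the original
    mixture-component indices aggregated into cluster ``c`` (together the
    members partition the original components).
    """

    z: np.ndarray
    members: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "members",
                           tuple(tuple(m) for m in self.members))
        if z.ndim != 2 or z.shape[1] != len(self.members):
            raise ValueError("z must be n x k with one member set per column")
        if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
            raise ValueError("posterior entries must lie in [0, 1]")
        if np.any(np.abs(z.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("posterior rows must sum to 1")
        flat = sorted(i for m in self.members for i in m)
        if flat != list(range(len(flat))):
            raise ValueError("member sets must partition the original "
                             "component indices")

    @property
    def k(self) -> int:
        return self.z.shape[1]


@dataclass
class MergePath:
    """Sequence of posteriors and entropies from k = g down to k = 1."""

    stages: list[ClusterPosteriors]
    entropies: np.ndarray
    merged_pairs: list[tuple[int, int]]
    mixture: Optional[STNMixture] = None

    def stage_with_k(self, k: int) -> ClusterPosteriors:
        for cp in self.stages:
            if cp.k == k:
                return cp
        raise KeyError(f"no stage with k = {k} clusters")


def _xlogx(z: np.ndarray) -> np.ndarray:
    # 0 log 0 = 0 by continuity
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(z > 0, z * np.log(np.where(z > 0, z, 1.0)), 0.0)
    return out


def entropy(cp: ClusterPosteriors) -> float:
    """Assignment entropy -sum_ij z_ij log z_ij (natural log, >= 0)."""
    return float(-_xlogx(cp.z).sum() + 0.0)  # +0.0 normalizes IEEE -0.0


def _pair_criterion(z: np.ndarray, l: int, lp: int) -> float:
    zl, zlp = z[:, l], z[:, lp]
    return float(-(_xlogx(zl) + _xlogx(zlp)).sum() + _xlogx(zl + zlp).sum())


def select_merge_pair(cp: ClusterPosteriors) -> tuple[int, int]:
    """Pair (l, l') maximizing the entropy reduction of their merger.

    The criterion -sum[z_l log z_l + z_l' log z_l'] + sum (z_l + z_l')
    log(z_l + z_l') is non-negative by concavity of x log x; ties break
    lexicographically.
    """
    k = cp.k
    if k < 2:
        raise ValueError("need at least two clusters to merge")
    best, best_val = (0, 1), -np.inf
    for l in range(k):
        for lp in range(l + 1, k):
            v = _pair_criterion(cp.z, l, lp)
            if v > best_val + 1e-15:
                best, best_val = (l, lp), v
    return best


def merge_pair(cp: ClusterPosteriors, l: int, lp: int) -> ClusterPosteriors:
    """Sum columns l and l' into one cluster; rows keep summing to 1."""
    k = cp.k
    if not (0 <= l < k and 0 <= lp < k) or l == lp:
        raise ValueError(f"invalid column pair ({l}, {lp}) for k = {k}")
    l, lp = min(l, lp), max(l, lp)
    keep = [c for c in range(k) if c not in (l, lp)]
    z_new = np.column_stack([cp.z[:, keep], cp.z[:, l] + cp.z[:, lp]]) \
        if keep else (cp.z[:, l] + cp.z[:, lp])[:, None]
    members = tuple(cp.members[c] for c in keep) \
        + (tuple(sorted(cp.members[l] + cp.members[lp])),)
    return ClusterPosteriors(z=z_new, members=members)


def merge_path(fit: FitResult | ClusterPosteriors) -> MergePath:
    """Iterate pair selection and merging from k = g down to k = 1."""
    if isinstance(fit, ClusterPosteriors):
        cp, mixture = fit, None
    else:
        cp = ClusterPosteriors(
            z=fit.posterior,
            members=tuple((i,) for i in range(fit.model.g)))
        mixture = fit.model
    stages = [cp]
    ents = [entropy(cp)]
    pairs: list[tuple[int, int]] = []
    while cp.k > 1:
        pair = select_merge_pair(cp)
        pairs.append(pair)
        cp = merge_pair(cp, *pair)
        stages.append(cp)
        ents.append(entropy(cp))
    return MergePath(stages=stages, entropies=np.array(ents),
                     merged_pairs=pairs, mixture=mixture)


def select_num_clusters(path: MergePath,
                        mode: Literal["elbow", "difference-peak", "manual"]
                        = "elbow",
                        k: Optional[int] = None) -> int:
    """Read the cluster count off the entropy-versus-k curve.

    Elbow mode returns the k with the largest second difference of Ent(k);
    difference-peak mode the k above the largest single entropy drop (ties
    to larger k). Paths too short for second differences fall back to
    difference-peak; a path with a single stage returns 1.
    """
    ents = path.entropies  # index i corresponds to k = g - i
    g = path.stages[0].k
    ks = np.arange(g, 0, -1)
    if mode == "manual":
        if k is None:
            raise ValueError("manual mode needs an explicit k")
        return int(k)
    if g == 1:
        return 1
    drops = ents[:-1] - ents[1:]  # drop when going from ks[i] to ks[i]-1
    if mode == "elbow" and g >= 3:
        # second difference of Ent as a function of k, at interior k
        second = ents[:-2] - 2 * ents[1:-1] + ents[2:]
        i = int(np.argmax(second))
        return int(ks[i + 1])
    # difference-peak (also the fallback): keep the clusters just above the
    # largest drop; on ties prefer the larger k (i.e. merge less)
    i = int(np.argmax(drops))
    return int(ks[i])


def merged_cluster_density(path: MergePath, cp: ClusterPosteriors,
                           cluster: int):
    """Density callable and weight of one merged cluster.

    The cluster's density is the sub-mixture over its member components,
    renormalized by their total weight; the mixture as a whole is invariant
    under merging, this is only a view onto one cluster.
    """
    if path.mixture is None:
        raise ValueError("merge path carries no mixture parameters")
    m = path.mixture
    idx = cp.members[cluster]
    w = m.weights[list(idx)]
    total = w.sum()
    comps = [m.components[i] for i in idx]

    def pdf(y):
        y = np.asarray(y, dtype=float)
        from .stn import stn_pdf
        return sum(wi * stn_pdf(y, c) for wi, c in zip(w, comps)) / total

    return pdf, float(total)
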