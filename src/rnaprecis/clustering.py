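"""Unsupervised clustering of suites on the 7-torus (MINT-AGE style).

The training side groups high-detail suites — points on the 7-torus of
backbone dihedrals — into conformational clusters in three stages:

1. an average-linkage merge tree under the torus metric,
2. AGE: adaptive cutting of the tree into preclusters, detaching the
   loosest (lowest-density) branches first, with a minimal cluster size
   kappa and a relative branching parameter q,
3. MINT: each precluster is projected to one circular coordinate
   capturing its dominant variation and recursively split wherever a
   bootstrap-calibrated likelihood-ratio test prefers a bimodal over a
   unimodal Gaussian — sensitive enough to isolate subclusters of
   size 2.

The circular projection here is a principal-geodesic-style reduction
(unwrap about per-coordinate circular means, dominant eigenvector of the
unwrapped covariance), a deliberately lighter construction than
stratified-sphere torus PCA; it preserves the pipeline role of a 1D
circular reduction feeding mode hunting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

__all__ = [
    "AgeParams",
    "ClusterModel",
    "ModeHuntConfig",
    "DEFAULT_AGE_PARAMS",
    "SYNTHETIC_AGE_PARAMS",
    "torus_distance",
    "torus_pairwise",
    "average_linkage_tree",
    "age_cut",
    "principal_circle_scores",
    "mode_hunt_split",
    "mint_age",
]


@dataclass(frozen=True)
class AgeParams:
    """AGE tuning parameters: relative branching distance q, minimal
    cluster size kappa, and the tolerated outlier fraction d_max."""

    q: float
    kappa: int = 3
    d_max: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.kappa < 2:
            raise ValueError("kappa must be >= 2")
        if not 0.0 <= self.d_max <= 1.0:
            raise ValueError("d_max must lie in [0, 1]")


#: Defaults per curated pucker-pair data set (kappa = 3 throughout so
#: clusters with very few elements can still be identified).  q is a
#: per-data-set tuning parameter, chosen so that the clusters found
#: agree with known conformers.
DEFAULT_AGE_PARAMS: Dict[str, AgeParams] = {
    "P33": AgeParams(q=0.09, kappa=3, d_max=0.011),
    "P32": AgeParams(q=0.05, kappa=3, d_max=0.0034),
    "P23": AgeParams(q=0.07, kappa=3, d_max=0.014),
    "P22": AgeParams(q=0.05, kappa=3, d_max=0.007),
}

#: AGE parameters tuned (in the same spirit) for the synthetic
#: gold-standard mixtures of the `synthetic` module, whose clusters are
#: broader relative to their separations than curated suite data.
SYNTHETIC_AGE_PARAMS = AgeParams(q=0.15, kappa=3, d_max=0.02)


@dataclass(frozen=True)
class ModeHuntConfig:
    alpha_level: float = 0.05
    n_boot: int = 200
    n_restarts: int = 10
    max_em_iter: int = 200
    seed: int = 0


def _wrapped_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal wrapped angular differences, degrees in [0, 180]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


def torus_distance(t1, t2) -> float:
    """Flat torus metric: root sum of squared minimal wrapped
    per-coordinate differences (degrees)."""
    d = _wrapped_diff(t1, t2)
    return float(np.sqrt(d @ d))


def torus_pairwise(points: np.ndarray) -> np.ndarray:
    """Condensed pairwise torus distance vector for an (n, 7) array."""
    pts = np.asarray(points, dtype=float)
    diff = np.abs(pts[:, None, :] - pts[None, :, :]) % 360.0
    diff = np.minimum(diff, 360.0 - diff)
    dm = np.sqrt((diff ** 2).sum(axis=-1))
    return squareform(dm, checks=False)


def average_linkage_tree(points: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage matrix) under the torus
    metric."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("linkage needs at least 2 points")
    return linkage(torus_pairwise(pts), method="average")


def _subtree_leaves(Z: np.ndarray, n: int) -> List[np.ndarray]:
    """Leaf index sets for every node id (0..2n-2)."""
    leaves: List[Optional[np.ndarray]] = [np.array([i]) for i in range(n)]
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        leaves.append(np.concatenate([leaves[a], leaves[b]]))
    return leaves


def age_cut(Z: np.ndarray, params: AgeParams
            ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Adaptive cut of an average-linkage tree into preclusters.

    Walking the tree from the root, a merge node is split into its two
    children when the vertical gap between its merge height and its
    taller child exceeds q x (full tree height) — the two branches join
    only across a large stretch of empty merge heights, the dendrogram
    signature of separated groups, with the loosest (lowest-density)
    branches detaching first.  Groups smaller than kappa become
    outliers.  A warning reports the achieved outlier fraction when it
    exceeds d_max.

    q trades resolution against stability and is a per-data-set tuning
    parameter (see DEFAULT_AGE_PARAMS and SYNTHETIC_AGE_PARAMS).

    Returns (preclusters as arrays of point indices, outlier indices).
    """
    n = int(Z.shape[0]) + 1
    heights = np.zeros(2 * n - 1)
    heights[n:] = Z[:, 2]
    root = 2 * n - 2
    threshold = params.q * heights[root]
    leaves = _subtree_leaves(Z, n)

    groups: List[np.ndarray] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            groups.append(leaves[node])
            continue
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        gap = heights[node] - max(heights[a], heights[b])
        if gap > threshold:
            stack.extend([b, a])
        else:
            groups.append(leaves[node])

    preclusters = [np.sort(g) for g in groups if len(g) >= params.kappa]
    outliers = np.sort(np.concatenate(
        [g for g in groups if len(g) < params.kappa] or [np.array([], int)]
    )).astype(int)
    frac = len(outliers) / n
    if frac > params.d_max:
        log.warning("AGE outlier fraction %.3f exceeds d_max=%.3f",
                    frac, params.d_max)
    preclusters.sort(key=lambda g: (-len(g), int(g[0])))
    return preclusters, outliers


def _circular_mean_deg(a: np.ndarray) -> np.ndarray:
    """Per-column circular means, degrees in [0, 360)."""
    rad = np.radians(a)
    return np.degrees(np.arctan2(np.sin(rad).mean(axis=0),
                                 np.cos(rad).mean(axis=0))) % 360.0


def _unwrap_about(a: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Signed deviations from ``center``, degrees in (-180, 180]."""
    return (np.asarray(a, float) - center + 180.0) % 360.0 - 180.0


def principal_circle_scores(points: np.ndarray) -> np.ndarray:
    """Project a concentrated torus cluster to one circular coordinate.

    Each point is unwrapped about the per-coordinate circular means
    (safe for concentrated clusters), the dominant eigenvector of the
    unwrapped covariance is taken as the principal direction, and the
    centred projections are returned as angles wrapped to [0, 360).
    Deterministic: the eigenvector's largest-magnitude component is made
    positive (lowest index on ties).  A zero-variance cluster yields all
    zeros.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need an (n >= 2, d) array of torus points")
    dev = _unwrap_about(pts, _circular_mean_deg(pts))
    cov = dev.T @ dev / (len(pts) - 1)
    if np.allclose(cov, 0.0, atol=1e-12):
        return np.zeros(len(pts))
    vals, vecs = np.linalg.eigh(cov)
    u = vecs[:, -1]
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u = -u
    return (dev @ u) % 360.0


# ---------------------------------------------------------------------------
# parametric circular mode hunting

#: Component scale floor in degrees.  Suites whose scores differ by less
#: than about half a degree are geometrically indistinguishable, so no
#: mixture component may claim a smaller spread; this also prevents
#: near-coincident points from forming degenerate likelihood spikes.
_SIGMA_FLOOR = 0.5

#: Split margin: the observed likelihood-ratio statistic must exceed
#: this multiple of the bootstrap null's 95% quantile (in addition to
#: the p-value condition), demanding practical and not just statistical
#: significance before a cluster is divided.
_SPLIT_MARGIN = 1.5


def _normal_loglik(x: np.ndarray) -> np.ndarray:
    """Row-wise max log-likelihood of a single Gaussian; x is (B, n)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = np.maximum(x.std(axis=1, keepdims=True), _SIGMA_FLOOR)
    z = (x - mu) / sd
    return (-0.5 * (z ** 2) - np.log(sd) - 0.5 * np.log(2 * np.pi)).sum(axis=1)


def _em_two_component(x: np.ndarray, cfg: ModeHuntConfig
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Best 2-component Gaussian mixture log-likelihood per row of the
    (B, n) data array, with deterministic sorted-split restarts.

    Returns (loglik (B,), best-restart parameters (B, 5) as columns
    (w1, mu1, sd1, mu2, sd2))."""
    B, n = x.shape
    xs = np.sort(x, axis=1)
    floor = _SIGMA_FLOOR
    w_min = min(2.0 / n, 0.5)  # components must carry >= 2 points
    best_ll = np.full(B, -np.inf)
    best_par = np.zeros((B, 5))
    for r in range(1, cfg.n_restarts + 1):
        cut = max(1, min(n - 1, round(n * r / (cfg.n_restarts + 1))))
        # init from the sorted split at this cut
        mu1 = xs[:, :cut].mean(axis=1)
        mu2 = xs[:, cut:].mean(axis=1)
        sd1 = np.maximum(xs[:, :cut].std(axis=1), _SIGMA_FLOOR)
        sd2 = np.maximum(xs[:, cut:].std(axis=1), _SIGMA_FLOOR)
        w = np.full(B, cut / n)
        ll_prev = np.full(B, -np.inf)
        for _ in range(cfg.max_em_iter):
            z1 = (x - mu1[:, None]) / sd1[:, None]
            z2 = (x - mu2[:, None]) / sd2[:, None]
            log_p1 = (np.log(w)[:, None] - np.log(sd1)[:, None]
                      - 0.5 * z1 ** 2 - 0.5 * np.log(2 * np.pi))
            log_p2 = (np.log1p(-w)[:, None] - np.log(sd2)[:, None]
                      - 0.5 * z2 ** 2 - 0.5 * np.log(2 * np.pi))
            m = np.maximum(log_p1, log_p2)
            log_tot = m + np.log(np.exp(log_p1 - m) + np.exp(log_p2 - m))
            ll = log_tot.sum(axis=1)
            resp2 = np.exp(log_p2 - log_tot)
            w2 = resp2.mean(axis=1)
            w1 = 1.0 - w2
            mu1 = ((1 - resp2) * x).sum(axis=1) / np.maximum(w1 * n, 1e-12)
            mu2 = (resp2 * x).sum(axis=1) / np.maximum(w2 * n, 1e-12)
            var1 = ((1 - resp2) * (x - mu1[:, None]) ** 2).sum(axis=1) \
                / np.maximum(w1 * n, 1e-12)
            var2 = (resp2 * (x - mu2[:, None]) ** 2).sum(axis=1) \
                / np.maximum(w2 * n, 1e-12)
            sd1 = np.maximum(np.sqrt(var1), _SIGMA_FLOOR)
            sd2 = np.maximum(np.sqrt(var2), _SIGMA_FLOOR)
            w = np.clip(w1, w_min, 1.0 - w_min)
            if np.all(np.abs(ll - ll_prev) < 1e-8):
                break
            ll_prev = ll
        improve = ll > best_ll
        best_par[improve] = np.column_stack([w, mu1, sd1, mu2, sd2])[improve]
        best_ll = np.maximum(best_ll, ll)
    return best_ll, best_par


def _lrt_statistic(x: np.ndarray, cfg: ModeHuntConfig
                   ) -> Tuple[np.ndarray, np.ndarray]:
    ll1, par = _em_two_component(x, cfg)
    ll0 = _normal_loglik(x)
    return 2.0 * (ll1 - ll0), par


def _mixture_antimode(par: np.ndarray) -> Optional[float]:
    """Interior density minimum (antimode) of a fitted 2-component
    mixture, or None when the mixture density is unimodal.

    A mixture of two Gaussians is bimodal exactly when its density has a
    local minimum strictly between the component means that lies below
    the density at both means; located on a dense grid.
    """
    w1, mu1, sd1, mu2, sd2 = par
    lo, hi = sorted((mu1, mu2))
    if hi - lo < 1e-9:
        return None

    def dens(t):
        t = np.asarray(t, dtype=float)
        return (w1 / sd1 * np.exp(-0.5 * ((t - mu1) / sd1) ** 2)
                + (1 - w1) / sd2 * np.exp(-0.5 * ((t - mu2) / sd2) ** 2))

    grid = np.linspace(lo, hi, 512)
    f = dens(grid)
    k = int(np.argmin(f))
    if k == 0 or k == len(grid) - 1:
        return None
    if f[k] >= min(dens(mu1), dens(mu2)) * (1.0 - 1e-9):
        return None
    return float(grid[k])


def _gaussian_factor(dev: np.ndarray) -> np.ndarray:
    """Square root factor L (7, 7) of the sample covariance of unwrapped
    deviations, tolerating rank deficiency."""
    cov = dev.T @ dev / max(len(dev) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def mode_hunt_split(scores: np.ndarray,
                    config: ModeHuntConfig = ModeHuntConfig(),
                    rng: Optional[np.random.Generator] = None,
                    points: Optional[np.ndarray] = None
                    ) -> List[np.ndarray]:
    """Recursive unimodal-vs-bimodal splitting of circular scores.

    The scores are unwrapped about their circular mean; a likelihood
    ratio of the best 2-component Gaussian mixture against a single
    Gaussian is calibrated by a parametric bootstrap under a unimodal
    null.  The sample is split at the antimode of the fitted mixture
    when the test rejects at ``alpha_level`` *and* the fitted mixture
    density is genuinely bimodal (the alternative of the test is a
    bimodal Gaussian, not an arbitrary mixture).  Splitting recurses on
    parts with at least 4 points; returns the final index sets
    (ascending within each part).

    When the underlying (n, 7) torus ``points`` are supplied, the null
    replicates the whole projection pipeline: a matched multivariate
    Gaussian cluster is drawn and re-projected through
    :func:`principal_circle_scores` for every bootstrap replicate, so
    the calibration absorbs the extra spread that picking the dominant
    variance direction induces.  Scores are then also recomputed per
    subset during recursion.  Without ``points`` the null is a plain
    fitted 1D Gaussian on the unwrapped scores.
    """
    scores = np.asarray(scores, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = np.arange(len(scores))

    def rec(indices: np.ndarray) -> List[np.ndarray]:
        n = len(indices)
        if n < 4:
            return [indices]
        if points is None:
            sub_scores = scores[indices]
        else:
            sub_scores = principal_circle_scores(points[indices])
        x = _unwrap_about(sub_scores, _circular_mean_deg(sub_scores))
        stat, par = _lrt_statistic(x[None, :], config)
        stat = float(stat[0])
        antimode = _mixture_antimode(par[0])
        if antimode is None:  # best mixture is unimodal: nothing to split
            return [indices]
        if points is None:
            mu0, sd0 = x.mean(), max(x.std(), _SIGMA_FLOOR)
            boot = rng.normal(mu0, sd0, size=(config.n_boot, n))
        else:
            dev = _unwrap_about(points[indices],
                                _circular_mean_deg(points[indices]))
            L = _gaussian_factor(dev)
            boot = np.empty((config.n_boot, n))
            for b in range(config.n_boot):
                sim = rng.normal(size=(n, L.shape[1])) @ L.T
                sc = principal_circle_scores(sim % 360.0)
                boot[b] = _unwrap_about(sc, _circular_mean_deg(sc))
        boot_stat, _ = _lrt_statistic(boot, config)
        p = (1.0 + np.sum(boot_stat >= stat)) / (config.n_boot + 1.0)
        if p >= config.alpha_level:
            return [indices]
        if stat <= _SPLIT_MARGIN * float(np.quantile(boot_stat, 0.95)):
            return [indices]
        hard = x > antimode
        part1, part2 = indices[~hard], indices[hard]
        if len(part1) == 0 or len(part2) == 0:
            return [indices]
        return rec(part1) + rec(part2)

    return rec(idx)


# ---------------------------------------------------------------------------
# full MINT-AGE pass

@dataclass
class ClusterModel:
    """One trained cluster of one pucker-pair set."""

    cluster_id: Tuple[str, int]          # (pucker pair, 1-based index)
    members: List                         # suite ids (or plain indices)
    hd_points: np.ndarray                 # (n, 7) torus points
    conformer_labels: Counter = field(default_factory=Counter)
    ld_points: list = field(default_factory=list)   # MuccssPoint members
    ld_summary: object = None             # FrechetSummary, set at training

    @property
    def size(self) -> int:
        return len(self.members)


def mint_age(points: np.ndarray,
             params: AgeParams,
             pucker_pair: str = "P33",
             suite_ids: Optional[Sequence] = None,
             labels: Optional[Sequence[str]] = None,
             mode_hunt: ModeHuntConfig = ModeHuntConfig(),
             rng: Optional[np.random.Generator] = None
             ) -> Tuple[List[ClusterModel], np.ndarray]:
    """Cluster one pucker-pair set of high-detail torus points.

    AGE preclusters are each refined by circular mode hunting; singleton
    refinements fall to the outlier set, subclusters of size >= 2 are
    kept.  Clusters are numbered by decreasing size (ties by smallest
    member id).  Returns (clusters, outlier indices).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if suite_ids is None:
        suite_ids = list(range(n))
    if rng is None:
        rng = np.random.default_rng(mode_hunt.seed)
    if n < params.kappa:
        log.warning("%s: only %d points (< kappa=%d); all outliers",
                    pucker_pair, n, params.kappa)
        return [], np.arange(n)

    Z = average_linkage_tree(pts)
    preclusters, outliers = age_cut(Z, params)
    outlier_set = list(outliers)

    member_sets: List[np.ndarray] = []
    for pre in preclusters:
        scores = principal_circle_scores(pts[pre])
        for part in mode_hunt_split(scores, mode_hunt, rng=rng,
                                    points=pts[pre]):
            sub = pre[part]
            if len(sub) < 2:
                outlier_set.extend(sub.tolist())
            else:
                member_sets.append(np.sort(sub))

    member_sets.sort(key=lambda m: (-len(m), str(suite_ids[m[0]])))
    clusters = []
    for i, m in enumerate(member_sets, start=1):
        labs = Counter(labels[j] for j in m) if labels is not None else Counter()
        clusters.append(ClusterModel(
            cluster_id=(pucker_pair, i),
            members=[suite_ids[j] for j in m],
            hd_points=pts[m],
            conformer_labels=labs,
        ))
    return clusters, np.sort(np.array(outlier_set, dtype=int))
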