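"""Spatio-temporal significance testing of TRF coefficient maps.

One-sample tests on baseline-corrected per-participant coefficient maps
(channels x lags) use a regularized 'hat' variance estimate; multiplicity is
handled either by cluster-based sign-flip permutation (max cluster mass) or
by threshold-free cluster enhancement (TFCE) with a max-statistic null.
Channel adjacency is an explicit neighborhood graph (ring or grid for the
synthetic sensor arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ClusterTestConfig",
    "ClusterResult",
    "hat_t",
    "baseline_correct",
    "ring_adjacency",
    "grid_adjacency",
    "cluster_permutation",
    "tfce",
]


@dataclass
class ClusterTestConfig:
    """Settings for cluster permutation and TFCE testing.

    ``baseline_window`` (seconds, both <= 0) defines the per-participant
    baseline subtracted before testing; ``hat_sigma`` scales the variance
    offset by the maximum variance over the map; the cluster-forming
    threshold is a two-sided alpha on the hat-t map.  TFCE uses score
    sum_h e(h)^E h^H dh with at least ``tfce_min_levels`` integration steps.
    """

    baseline_window: tuple[float, float] = (-0.2, 0.0)
    n_permutations: int = 2000
    hat_sigma: float = 1e-3
    adjacency: Sequence[Sequence[int]] | None = None  # neighbor lists per channel
    cluster_alpha: float = 0.05
    tfce_start: float = 0.1
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_min_levels: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not self.baseline_window[0] < self.baseline_window[1] <= 0:
            raise ValueError("baseline window must precede time 0")


@dataclass
class ClusterResult:
    """Clusters with their permutation p-values and optional TFCE map."""

    cluster_masses: list[float] = field(default_factory=list)
    cluster_members: list[list[tuple[int, int]]] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    t_map: np.ndarray | None = None
    tfce_p_map: np.ndarray | None = None

    @property
    def min_p(self) -> float:
        return min(self.p_values) if self.p_values else 1.0


def hat_t(test_data: np.ndarray, sigma: float = 1e-3) -> np.ndarray:
    """One-sample t map with 'hat' variance adjustment.

    t = mean / sqrt((var + sigma * max_var) / n), where max_var is the
    maximum sample variance across the whole map; sigma = 0 recovers the
    classical one-sample t exactly.
    """
    x = np.asarray(test_data, dtype=float)
    if x.ndim < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 participants on the first axis")
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    max_var = var.max()
    denom = np.sqrt((var + sigma * max_var) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mean / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def baseline_correct(
    coef_maps: np.ndarray, lag_times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Subtract each participant/channel's mean over the baseline lags."""
    maps = np.asarray(coef_maps, dtype=float)
    in_base = (lag_times >= window[0] - 1e-9) & (lag_times <= window[1] + 1e-9)
    if not in_base.any():
        raise ValueError("baseline window contains no lags")
    return maps - maps[..., in_base].mean(axis=-1, keepdims=True)


def ring_adjacency(n_channels: int) -> list[list[int]]:
    """Ring neighborhood for synthetic sensor arrays."""
    return [
        [(c - 1) % n_channels, (c + 1) % n_channels] for c in range(n_channels)
    ]


def grid_adjacency(n_rows: int, n_cols: int) -> list[list[int]]:
    """4-neighborhood on an n_rows x n_cols sensor grid (row-major ids)."""
    adj: list[list[int]] = []
    for r in range(n_rows):
        for c in range(n_cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * n_cols + c)
            if r < n_rows - 1:
                nb.append((r + 1) * n_cols + c)
            if c > 0:
                nb.append(r * n_cols + c - 1)
            if c < n_cols - 1:
                nb.append(r * n_cols + c + 1)
            adj.append(nb)
    return adj


def _clusters(
    mask: np.ndarray, values: np.ndarray, adjacency: Sequence[Sequence[int]]
) -> list[tuple[float, list[tuple[int, int]]]]:
    """Connected components of suprathreshold cells.

    Cells (channel, lag) are connected through temporal contiguity within a
    channel and through channel adjacency at the same lag.  Returns
    (mass, member list) per cluster, mass = sum of ``values`` over members.
    """
    n_chan, n_lag = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    for c0 in range(n_chan):
        for l0 in range(n_lag):
            if not mask[c0, l0] or seen[c0, l0]:
                continue
            stack = [(c0, l0)]
            seen[c0, l0] = True
            members = []
            mass = 0.0
            while stack:
                c, l = stack.pop()
                members.append((c, l))
                mass += values[c, l]
                for ll in (l - 1, l + 1):
                    if 0 <= ll < n_lag and mask[c, ll] and not seen[c, ll]:
                        seen[c, ll] = True
                        stack.append((c, ll))
                for cc in adjacency[c]:
                    if mask[cc, l] and not seen[cc, l]:
                        seen[cc, l] = True
                        stack.append((cc, l))
            out.append((mass, members))
    return out


def _max_cluster_mass(
    t_map: np.ndarray, thresh: float, adjacency: Sequence[Sequence[int]]
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        for mass, _ in _clusters(sign * t_map > thresh, sign * t_map, adjacency):
            best = max(best, mass)
    return best


def cluster_permutation(
    test_data: np.ndarray, cfg: ClusterTestConfig
) -> ClusterResult:
    """Sign-flip cluster-based permutation test of a participants x channels
    x lags array (already baseline-corrected).

    Clusters of cells exceeding the two-sided cluster-forming threshold on
    the hat-t map are scored by their t mass; the null is the distribution of
    the maximum cluster mass over sign-flip permutations, and
    p = (1 + #(perm >= observed)) / (1 + n_permutations).
    """
    x = np.asarray(test_data, dtype=float)
    n, n_chan, _ = x.shape
    adjacency = cfg.adjacency if cfg.adjacency is not None else ring_adjacency(n_chan)
    if len(adjacency) != n_chan:
        raise ValueError("adjacency must cover all channels")
    thresh = stats.t.ppf(1 - cfg.cluster_alpha / 2, df=n - 1)
    t_obs = hat_t(x, cfg.hat_sigma)
    observed = []
    for sign in (1.0, -1.0):
        for mass, members in _clusters(sign * t_obs > thresh, sign * t_obs, adjacency):
            observed.append((mass, members, sign))
    rng = np.random.default_rng(cfg.seed)
    null_max = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = hat_t(x * signs[:, None, None], cfg.hat_sigma)
        null_max[i] = _max_cluster_mass(t_perm, thresh, adjacency)
    result = ClusterResult(t_map=t_obs)
    for mass, members, sign in sorted(observed, reverse=True, key=lambda o: o[0]):
        p = (1 + int((null_max >= mass).sum())) / (1 + cfg.n_permutations)
        result.cluster_masses.append(sign * mass)
        result.cluster_members.append(members)
        result.p_values.append(p)
    return result


def _tfce_map(
    t_map: np.ndarray, cfg: ClusterTestConfig, adjacency: Sequence[Sequence[int]]
) -> np.ndarray:
    """Signed TFCE transform: sum over heights of extent^E * height^H * dh."""
    out = np.zeros_like(t_map)
    for sign in (1.0, -1.0):
        v = sign * t_map
        vmax = v.max()
        if vmax <= cfg.tfce_start:
            continue
        n_levels = max(cfg.tfce_min_levels, 50)
        heights = np.linspace(cfg.tfce_start, vmax, n_levels + 1)[1:]
        dh = heights[1] - heights[0] if len(heights) > 1 else vmax - cfg.tfce_start
        acc = np.zeros_like(v)
        for h in heights:
            for _, members in _clusters(v >= h, v, adjacency):
                extent = len(members)
                inc = extent**cfg.tfce_e * h**cfg.tfce_h * dh
                for c, l in members:
                    acc[c, l] += inc
        out += sign * acc
    return out


def tfce(test_data: np.ndarray, cfg: ClusterTestConfig) -> ClusterResult:
    """TFCE significance map with a sign-flip max-statistic permutation null.

    Returns per-cell p-values (``tfce_p_map``); a cell is significant when
    its TFCE score exceeds the permutation distribution of the map maximum.
    """
    x = np.asarray(test_data, dtype=float)
    n, n_chan, _ = x.shape
    adjacency = cfg.adjacency if cfg.adjacency is not None else ring_adjacency(n_chan)
    if len(adjacency) != n_chan:
        raise ValueError("adjacency must cover all channels")
    t_obs = hat_t(x, cfg.hat_sigma)
    score_obs = _tfce_map(t_obs, cfg, adjacency)
    rng = np.random.default_rng(cfg.seed)
    null_max = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = hat_t(x * signs[:, None, None], cfg.hat_sigma)
        null_max[i] = np.abs(_tfce_map(t_perm, cfg, adjacency)).max()
    p_map = (
        1 + (null_max[None, None, :] >= np.abs(score_obs)[..., None]).sum(axis=-1)
    ) / (1 + cfg.n_permutations)
    return ClusterResult(t_map=t_obs, tfce_p_map=p_map)


def tfce_score_map(t_map: np.ndarray, cfg: ClusterTestConfig) -> np.ndarray:
    """The TFCE transform of a precomputed statistic map (no permutation)."""
    n_chan = t_map.shape[0]
    adjacency = cfg.adjacency if cfg.adjacency is not None else ring_adjacency(n_chan)
    return _tfce_map(np.asarray(t_map, dtype=float), cfg, adjacency)


__all__.append("tfce_score_map")
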