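"""Soft clustering of temporal expression trajectories by fuzzy c-means.

Replicates are collapsed to per-stage means of log2(CPM+1), each feature's
trajectory is z-scored, and the standardized trajectories are clustered with
the classical fuzzy c-means algorithm (Bezdek): memberships u_ik and centers
are updated alternately until the largest center shift falls below a
tolerance. The fuzzifier m controls softness (m -> 1 approaches hard
k-means); the defaults are c = 8 clusters and m = 1.15. Initialization
selects c distinct features as starting centers; several seeded restarts
keep the solution with the lowest objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SampleSheet

DEFAULT_C = 8
DEFAULT_M = 1.15


def standardize(
    cpm: pd.DataFrame,
    sheet: SampleSheet,
    features: Optional[Sequence[str]] = None,
    sd_floor: float = 1e-8,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-feature z-scored stage-mean trajectories of log2(CPM+1).

    Returns (trajectories, dropped): rows with standard deviation below
    ``sd_floor`` (flat trajectories) are dropped and listed. The sd uses the
    n-1 denominator.
    """
    sub = cpm.loc[list(features)] if features is not None else cpm
    stage_means = pd.DataFrame(
        {
            stage: np.log2(
                sub[[s.sample_id for s in sheet.samples_for_stage(stage)]] + 1
            ).mean(axis=1)
            for stage in sheet.stages
        }
    )
    sd = stage_means.std(axis=1, ddof=1)
    dropped = list(stage_means.index[sd < sd_floor])
    kept = stage_means.loc[sd >= sd_floor]
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=1), axis=0)
    return z, dropped


@dataclass
class MembershipMatrix:
    """Fuzzy memberships (rows sum to 1), cluster centers, and fit metadata."""

    memberships: pd.DataFrame   # features x clusters (1..c)
    centers: np.ndarray         # c x n_stages
    m: float
    objective: float
    objective_history: List[float]  # per-iteration, for the winning restart
    n_iter: int
    seed: int


def _spread_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: data points chosen with probability
    proportional to squared distance from the centers picked so far."""
    n = x.shape[0]
    chosen = [int(rng.integers(n))]
    for _ in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - x[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        chosen.append(int(rng.choice(n, p=probs)))
    return x[chosen].copy()


def _fcm_once(
    x: np.ndarray, c: int, m: float, rng: np.random.Generator,
    tol: float, max_iter: int,
    init_centers: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float, int, List[float]]:
    n = x.shape[0]
    centers = _spread_init(x, c, rng) if init_centers is None else init_centers.copy()
    exponent = 2.0 / (m - 1.0)
    u = np.empty((n, c))
    history: List[float] = []
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        # a feature sitting exactly on a center gets membership 1 there
        rows, cols = np.nonzero(zero)
        for r in np.unique(rows):
            u[r] = 0.0
            u[r, cols[rows == r][0]] = 1.0
        um = u**m
        history.append(float((um * d2).sum()))
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float((u**m * d2).sum())
    return u, centers, objective, it, history


def fuzzy_cmeans(
    trajectories: pd.DataFrame,
    c: int = DEFAULT_C,
    m: float = DEFAULT_M,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> MembershipMatrix:
    """Fuzzy c-means over standardized trajectories.

    Memberships follow u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)) and centers
    are the u^m-weighted means; iteration stops when the largest center
    shift is below ``tol``. ``n_restarts`` seeded restarts keep the best
    (lowest-objective) solution. Same seed, same input => identical result.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = trajectories.to_numpy(dtype=float)
    n = x.shape[0]
    if c > n:
        raise ValueError(f"cannot fit {c} clusters to {n} features")
    if c < 1:
        raise ValueError("c must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    # first candidate: polish a (nearly hard) k-means solution, which lands
    # in the right basin far more reliably than random center seeding when
    # m is close to 1; remaining restarts are random spread seedings
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=c, n_init=10, random_state=seed).fit(x)
    inits: List[Optional[np.ndarray]] = [km.cluster_centers_]
    inits.extend([None] * (n_restarts - 1))
    for init in inits:
        u, centers, obj, it, hist = _fcm_once(x, c, m, rng, tol, max_iter,
                                              init_centers=init)
        if best is None or obj < best[2]:
            best = (u, centers, obj, it, hist)
    u, centers, obj, it, hist = best
    memberships = pd.DataFrame(
        u, index=trajectories.index, columns=[f"cluster_{k+1}" for k in range(c)]
    )
    return MembershipMatrix(
        memberships=memberships, centers=centers, m=m,
        objective=obj, objective_history=hist, n_iter=it, seed=seed,
    )


def assign_clusters(
    result: MembershipMatrix, min_membership: float = 0.5
) -> pd.Series:
    """Hard labels: argmax membership when it reaches the threshold.

    Ties go to the smallest cluster index; below-threshold features are
    labelled 0 (unassigned).
    """
    u = result.memberships.to_numpy()
    best = u.argmax(axis=1)  # argmax returns the first (smallest) index on ties
    labels = np.where(u[np.arange(len(u)), best] >= min_membership, best + 1, 0)
    return pd.Series(labels, index=result.memberships.index, name="cluster")


def center_distance_diagnostic(
    trajectories: pd.DataFrame,
    c_values: Sequence[int] = tuple(range(2, 13)),
    m: float = DEFAULT_M,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimum pairwise center distance for a range of cluster counts.

    A sharp drop in the minimum centroid distance as c grows past the true
    number of patterns is the usual heuristic for choosing c.
    """
    rows = []
    for c in c_values:
        if c > len(trajectories):
            continue
        fit = fuzzy_cmeans(trajectories, c=c, m=m, seed=seed)
        d = np.sqrt(
            ((fit.centers[:, None, :] - fit.centers[None, :, :]) ** 2).sum(axis=2)
        )
        np.fill_diagonal(d, np.inf)
        rows.append({"c": c, "min_center_distance": float(d.min())})
    return pd.DataFrame(rows)
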