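"""Perturbation efficacy (on-score) and specificity (off-score).

The on-score is the 1-Wasserstein (Earth Mover's) distance between the
perturbed and target single-cell populations over the on-signature
features, divided by the reference distance — the same EMD between the
reference and target states.  A score of 1 means the perturbation is
indistinguishable from the reference state along the on-axis, 0 means full
convergence to the target, and values above 1 mean the perturbation pushed
cells past the reference, away from the target.

The off-score is the fraction of off-signature features whose distribution
is significantly altered by the perturbation (per-feature KS tests,
BH-corrected within the off-feature family); lower means fewer off-target
effects.

EMD is computed as one multivariate discrete optimal-transport problem over
the joint on-feature space: uniform point masses, Euclidean ground metric.
Equal-size supports reduce to a minimum-cost perfect matching (Hungarian
algorithm); unequal sizes are solved exactly as a sparse transportation LP
(HiGHS).  Cost grows quadratically with cell count, so populations can be
capped by uniform subsampling before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance

from .profiles import PopulationSelector, ProfileTable, SelectorLike, select_population
from .signatures import SignatureResult
from .stats import bh_adjust, ks_two_sample

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "emd",
    "reference_distance",
    "on_score",
    "off_score",
    "score_screen",
]


def _as_points(name: str, X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty 2-D point set")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def _transport_lp(cost: np.ndarray) -> float:
    """Exact uniform-weight optimal transport via a sparse transportation LP."""
    n, m = cost.shape
    a, b = 1.0 / n, 1.0 / m
    row_con = sp.kron(sp.eye(n, format="csr"), np.ones((1, m)), format="csr")
    col_con = sp.kron(np.ones((1, n)), sp.eye(m, format="csr"), format="csr")
    # one marginal constraint is redundant; dropping it keeps A_eq full rank
    A_eq = sp.vstack([row_con, col_con[:-1]], format="csr")
    b_eq = np.concatenate([np.full(n, a), np.full(m - 1, b)])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if res.status != 0:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd(X, Y, mode: str = "joint") -> float:
    """1-Wasserstein distance between two empirical point clouds.

    Uniform weight per point, Euclidean ground metric, exact solution.
    Symmetric, nonnegative, and zero iff the two point sets coincide as
    distributions.

    ``mode="joint"`` (default) solves a single multivariate transport
    problem in the full feature space.  ``mode="per_feature"`` is a labeled
    cheaper alternative: the mean of per-feature 1-D Wasserstein distances,
    which ignores cross-feature structure and is NOT the joint distance.
    """
    Xa = _as_points("X", X)
    Ya = _as_points("Y", Y)
    if Xa.shape[1] != Ya.shape[1]:
        raise ValueError(f"dimension mismatch: {Xa.shape[1]} vs {Ya.shape[1]}")
    if mode == "per_feature":
        return float(
            np.mean([wasserstein_distance(Xa[:, j], Ya[:, j]) for j in range(Xa.shape[1])])
        )
    if mode != "joint":
        raise ValueError("mode must be 'joint' or 'per_feature'")
    cost = cdist(Xa, Ya)
    n, m = cost.shape
    if n == m:
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].mean())
    return _transport_lp(cost)


def reference_distance(
    reference: ProfileTable,
    target: ProfileTable,
    signature: SignatureResult,
    mode: str = "joint",
) -> float:
    """EMD between the reference and target states over the on-signature.

    This is the normalization constant for all on-scores.  A zero distance
    (identical point sets) or an empty on-signature means the two states are
    statistically indistinguishable at alpha and scoring is impossible.
    """
    if not signature.on_features:
        raise ValueError(
            "empty on-signature: no feature separates the reference and target "
            f"states at alpha={signature.alpha}; the states are indistinguishable"
        )
    d = emd(reference.values(signature.on_features), target.values(signature.on_features), mode=mode)
    if d <= 0:
        raise ValueError(
            "reference distance is zero: reference and target coincide on the "
            "on-signature, so normalized scores are undefined"
        )
    return d


def on_score(
    perturbed: ProfileTable,
    target: ProfileTable,
    signature: SignatureResult,
    ref_dist: float,
    mode: str = "joint",
) -> float:
    """Normalized efficacy: EMD(perturbed, target | on-features) / ref_dist."""
    if ref_dist <= 0:
        raise ValueError(f"reference distance must be positive, got {ref_dist}")
    if not signature.on_features:
        raise ValueError("empty on-signature")
    d = emd(perturbed.values(signature.on_features), target.values(signature.on_features), mode=mode)
    return d / ref_dist


def off_score(
    perturbed: ProfileTable,
    comparison: ProfileTable,
    signature: SignatureResult,
    alpha: float | None = None,
) -> tuple[float, pd.Series]:
    """Specificity: fraction of off-signature features significantly altered.

    Per-feature KS tests between the perturbed population and the comparison
    population (target state by default in the pipeline; configurable to the
    reference state), BH-corrected within this perturbation's off-feature
    family.  Returns ``(score, flags)`` with one boolean flag per off-feature.
    """
    if not signature.off_features:
        raise ValueError("empty off-signature: off-score is undefined")
    if perturbed.n_cells < 2 or comparison.n_cells < 2:
        raise ValueError("both populations need at least 2 cells for the off-score")
    alpha = signature.alpha if alpha is None else alpha
    pvals = []
    for feat in signature.off_features:
        x = perturbed.data[feat].to_numpy(dtype=float)
        y = comparison.data[feat].to_numpy(dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            pvals.append(1.0)
        else:
            pvals.append(ks_two_sample(x, y).p_value)
    _, reject = bh_adjust(pvals, alpha=alpha)
    flags = pd.Series(reject, index=list(signature.off_features), name="off_significant")
    return float(flags.sum() / len(flags)), flags


@dataclass
class ScoreResult:
    """Scores for one perturbation group."""

    group_key: dict
    on_score: float
    raw_emd: float
    reference_distance: float
    off_score: float
    off_flags: pd.Series
    n_cells: int


def score_screen(
    profiles: ProfileTable,
    signature: SignatureResult,
    reference_sel: PopulationSelector | SelectorLike,
    target_sel: PopulationSelector | SelectorLike,
    group_by: Sequence[str],
    pool_wells: bool = True,
    well_column: str = "Metadata_well",
    off_comparison: str = "target",
    max_cells_per_population: int | None = 5000,
    seed: int = 0,
    mode: str = "joint",
) -> pd.DataFrame:
    """Score every perturbation group in a screen against one shared reference distance.

    Groups are formed by ``group_by`` (typically the treatment column);
    with ``pool_wells=False`` the well column is appended so each replicate
    well is scored independently.  The reference and target populations may
    themselves appear among the scored groups — scoring the reference
    recovers 1.0 and scoring the target 0.0 by construction.

    ``off_comparison`` selects the population the off-score tests against:
    ``"target"`` (default) or ``"reference"``.  Populations larger than
    ``max_cells_per_population`` are uniformly subsampled (seeded) before
    the EMD, since transport cost grows quadratically with cell count.

    Returns a tidy frame with one row per group: group keys, ``n_cells``,
    ``raw_emd``, ``reference_distance``, ``on_score``, ``off_score``,
    ``n_off_significant``, ``n_off_total``.
    """
    if off_comparison not in ("target", "reference"):
        raise ValueError("off_comparison must be 'target' or 'reference'")
    group_cols = list(group_by)
    if not pool_wells:
        if well_column not in profiles.data.columns:
            raise KeyError(f"well column {well_column!r} not in table")
        if well_column not in group_cols:
            group_cols.append(well_column)
    missing = [c for c in group_cols if c not in profiles.data.columns]
    if missing:
        raise KeyError(f"unknown grouping columns: {missing}")

    rng = np.random.default_rng(seed)
    cap = max_cells_per_population or profiles.n_cells

    reference = select_population(profiles, reference_sel).subsample(cap, rng)
    target = select_population(profiles, target_sel).subsample(cap, rng)
    if reference.n_cells == 0 or target.n_cells == 0:
        raise ValueError("reference or target population is empty after selection")
    ref_dist = reference_distance(reference, target, signature, mode=mode)
    comparison = target if off_comparison == "target" else reference

    rows = []
    for key, sub in profiles.data.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        group = ProfileTable(sub, validate=False).subsample(cap, rng)
        if group.n_cells < 2:
            logger.warning("skipping group %s: only %d cell(s)", dict(zip(group_cols, key)), group.n_cells)
            continue
        raw = emd(
            group.values(signature.on_features),
            target.values(signature.on_features),
            mode=mode,
        )
        off, flags = off_score(group, comparison, signature)
        rows.append(
            {
                **dict(zip(group_cols, key)),
                "n_cells": group.n_cells,
                "raw_emd": raw,
                "reference_distance": ref_dist,
                "on_score": raw / ref_dist,
                "off_score": off,
                "n_off_significant": int(flags.sum()),
                "n_off_total": int(len(flags)),
            }
        )
    return pd.DataFrame(rows)
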