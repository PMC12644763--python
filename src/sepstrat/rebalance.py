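"""Class rebalancing and cross-center adaptation.

Implements plain SMOTE (synthetic minority oversampling by convex
interpolation between nearest minority neighbors), the interval-
constrained moment-aligned variant MMID-SMOTE, a per-feature moment-
matching baseline, and the max-min interval discrepancy (MMID) metric
used to quantify covariate-range mismatch between centers.

The MMID metric is a scale-free reconstruction from its expanded name:
for feature j,

    d_j = (|min_src - min_tgt| + |max_src - max_tgt|) / range_tgt

with a range floor of 1e-9, aggregated as the mean over features.
MMID-SMOTE clips SMOTE candidates into the target per-feature
[min, max] interval, moves their per-feature mean and variance toward
the target's by ``moment_weight``, and re-clips — so the interval
constraint always holds for the final output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("sepstrat")

__all__ = [
    "RebalanceResult",
    "DiscrepancyReport",
    "smote",
    "mmid",
    "mmid_smote",
    "moment_match",
    "rebalance_cohort",
]


@dataclass
class RebalanceResult:
    """Synthetic samples plus full per-row provenance."""

    samples: np.ndarray          # (n_synthetic, d), original feature scale
    parent: np.ndarray           # index into the minority matrix
    neighbor: np.ndarray         # index into the minority matrix
    lam: np.ndarray              # interpolation coefficient in [0, 1]
    clipped: np.ndarray          # bool per row: any feature clipped
    adjusted: np.ndarray         # bool per row: moment alignment applied
    method: str = "smote"
    seed: int = 0


@dataclass
class DiscrepancyReport:
    feature_discrepancy: np.ndarray  # per-feature interval discrepancy
    aggregate: float                 # mean over features (the MMID score)
    mean_gap: np.ndarray             # |mean_src - mean_tgt| per feature
    var_gap: np.ndarray              # |var_src - var_tgt| per feature


def _as_matrix(X) -> np.ndarray:
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A


def smote(
    X_minority,
    k_neighbors: int = 5,
    n_synthetic: int = 0,
    seed: int = 0,
) -> RebalanceResult:
    """Plain SMOTE: each synthetic row is x_i + lam * (x_nn - x_i) with
    lam ~ U(0,1) and x_nn one of the k nearest minority neighbors of a
    uniformly drawn parent x_i (Euclidean distance on z-standardized
    features; ties broken by index order)."""
    X = _as_matrix(X_minority)
    n, d = X.shape
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if n <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} minority rows, got {n}"
        )
    empty = RebalanceResult(
        np.empty((0, d)), np.empty(0, int), np.empty(0, int),
        np.empty(0), np.zeros(0, bool), np.zeros(0, bool), "smote", seed,
    )
    if n_synthetic == 0:
        return empty

    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Z)
    _, idx = nn.kneighbors(Z)  # first column is the point itself
    neighbors = idx[:, 1:]

    rng = np.random.default_rng(seed)
    parent = rng.integers(0, n, size=n_synthetic)
    pick = rng.integers(0, k_neighbors, size=n_synthetic)
    neighbor = neighbors[parent, pick]
    lam = rng.random(n_synthetic)
    samples = X[parent] + lam[:, None] * (X[neighbor] - X[parent])
    return RebalanceResult(
        samples, parent, neighbor, lam,
        np.zeros(n_synthetic, bool), np.zeros(n_synthetic, bool), "smote", seed,
    )


def mmid(X_source, X_target) -> DiscrepancyReport:
    """Max-min interval discrepancy between two samples of the same
    features (normalized by the target range, floor 1e-9)."""
    S, T = _as_matrix(X_source), _as_matrix(X_target)
    if S.size == 0 or T.size == 0:
        raise ValueError("source and target must be nonempty")
    if S.shape[1] != T.shape[1]:
        raise ValueError("source and target must share feature columns")
    rng_t = np.maximum(T.max(axis=0) - T.min(axis=0), 1e-9)
    d = (np.abs(S.min(axis=0) - T.min(axis=0)) + np.abs(S.max(axis=0) - T.max(axis=0))) / rng_t
    return DiscrepancyReport(
        feature_discrepancy=d,
        aggregate=float(d.mean()),
        mean_gap=np.abs(S.mean(axis=0) - T.mean(axis=0)),
        var_gap=np.abs(S.var(axis=0) - T.var(axis=0)),
    )


def mmid_smote(
    X_source_minority,
    X_target,
    k_neighbors: int = 5,
    n_synthetic: int = 0,
    moment_weight: float = 0.5,
    seed: int = 0,
) -> RebalanceResult:
    """Interval-constrained, moment-aligned SMOTE.

    SMOTE candidates are (1) clipped per feature into the target
    [min, max] interval, (2) affinely moved so their per-feature mean
    and sd shift toward the target's by ``moment_weight`` (1 = full
    alignment), then (3) re-clipped.  Clip-then-adjust-then-reclip
    ordering guarantees the final rows always satisfy the interval
    constraint."""
    if not (0.0 <= moment_weight <= 1.0):
        raise ValueError("moment_weight must be in [0, 1]")
    T = _as_matrix(X_target)
    if T.size == 0:
        raise ValueError("target must be nonempty")
    base = smote(X_source_minority, k_neighbors, n_synthetic, seed)
    if n_synthetic == 0:
        base.method = "mmid_smote"
        return base
    lo, hi = T.min(axis=0), T.max(axis=0)
    raw = base.samples
    out = np.clip(raw, lo, hi)
    clipped = (out != raw).any(axis=1)
    adjusted = np.zeros(len(out), bool)
    if moment_weight > 0:
        cur_m, cur_s = out.mean(axis=0), out.std(axis=0, ddof=0)
        tgt_m, tgt_s = T.mean(axis=0), T.std(axis=0, ddof=0)
        new_m = (1 - moment_weight) * cur_m + moment_weight * tgt_m
        new_s = (1 - moment_weight) * cur_s + moment_weight * tgt_s
        safe = cur_s > 0
        scale = np.where(safe, new_s / np.where(safe, cur_s, 1.0), 1.0)
        moved = (out - cur_m) * scale + new_m
        reclipped = np.clip(moved, lo, hi)
        adjusted = (reclipped != out).any(axis=1)
        clipped |= (reclipped != moved).any(axis=1)
        out = reclipped
    return RebalanceResult(
        out, base.parent, base.neighbor, base.lam, clipped, adjusted,
        "mmid_smote", seed,
    )


def moment_match(X_source, X_target) -> np.ndarray:
    """Per-feature affine map aligning source mean/sd to target mean/sd
    (the second-order-statistics adaptation baseline)."""
    S, T = _as_matrix(X_source), _as_matrix(X_target)
    if S.shape[1] != T.shape[1]:
        raise ValueError("source and target must share feature columns")
    sm, ss = S.mean(axis=0), S.std(axis=0, ddof=0)
    tm, ts = T.mean(axis=0), T.std(axis=0, ddof=0)
    degenerate = ss == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance source feature(s); "
            "map degenerates to a constant shift"
        )
    scale = np.where(degenerate, 0.0, ts / np.where(degenerate, 1.0, ss))
    return (S - sm) * scale + tm


def rebalance_cohort(
    cohort: pd.DataFrame,
    method: str = "smote",
    target_cohort: pd.DataFrame | None = None,
    feature_columns: Sequence[str] | None = None,
    ratio: float = 1.0,
    k_neighbors: int = 5,
    moment_weight: float = 0.5,
    outcome: str = "died_28d",
    seed: int = 0,
) -> pd.DataFrame:
    """Oversample the minority outcome class of a cohort.

    ``ratio`` is the desired minority/majority count ratio after
    augmentation (1.0 = balanced).  Synthetic rows carry interpolated
    marker values, the minority outcome, their parent's remaining
    columns, and ``is_synthetic = 1``.
    """
    from sepstrat.io import MARKER_COLUMNS

    if method not in ("smote", "mmid_smote", "none"):
        raise ValueError(f"unknown method {method!r}; valid: smote, mmid_smote, none")
    out = cohort.copy()
    out["is_synthetic"] = 0
    if method == "none":
        return out
    if method == "mmid_smote" and target_cohort is None:
        raise ValueError("mmid_smote requires a target_cohort")

    cols = list(feature_columns) if feature_columns is not None else list(MARKER_COLUMNS)
    y = cohort[outcome].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    n_needed = max(int(round(ratio * n_maj)) - n_min, 0)
    if n_needed == 0:
        return out
    mask = y == minority
    X_min = cohort.loc[mask, cols].to_numpy(dtype=float)
    if method == "smote":
        result = smote(X_min, k_neighbors, n_needed, seed)
    else:
        result = mmid_smote(
            X_min, target_cohort[cols].to_numpy(dtype=float),
            k_neighbors, n_needed, moment_weight, seed,
        )
    parents = cohort.loc[mask].iloc[result.parent].copy()
    parents[cols] = result.samples
    parents["is_synthetic"] = 1
    parents["patient_id"] = np.arange(len(cohort), len(cohort) + n_needed)
    logger.info("rebalance_cohort: added %d synthetic minority rows (%s)",
                n_needed, method)
    return pd.concat([out, parents], ignore_index=True)
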