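"""Coagulation-inflammatory subphenotype identification.

Patients are clustered on the eight z-standardized routine markers with
a full-covariance Gaussian mixture fitted by EM (k-means start, several
random restarts, ridge-regularized covariances).  The mixture count is
selected by a majority vote of three internal-validity indices
(silhouette and Calinski-Harabasz maximized, Davies-Bouldin minimized).
Components are relabeled canonically by a marker-only severity
composite — mean standardized APTT + INR + WBC - PLT — so that CIS2 is
always the high-severity coagulation-inflammatory profile (prolonged
clotting, leukocytosis, thrombocytopenia) and labeling at inference
time needs no outcome data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.cluster import AgglomerativeClustering, Birch, KMeans, MiniBatchKMeans
from sklearn.decomposition import FastICA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from sepstrat.io import MARKER_COLUMNS

__all__ = [
    "SubphenotypeModel",
    "ClusterIndexReport",
    "select_cluster_count",
    "fit_subphenotypes",
    "compare_clusterers",
    "embed_2d",
    "siri",
    "subgroup_summary",
]

_SEVERITY_WEIGHTS = {"aptt": 1.0, "inr": 1.0, "wbc": 1.0, "plt": -1.0}


# ----------------------------------------------------------------------
# Gaussian mixture EM
# ----------------------------------------------------------------------

def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = linalg.cholesky(cov, lower=True)
    solved = linalg.solve_triangular(chol, (X - mean).T, lower=True)
    maha = np.sum(solved ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _em_once(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    reg: float,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, d = X.shape
    km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    hard = km.fit_predict(X)
    resp = np.full((n, k), 1e-6)
    resp[np.arange(n), hard] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)

    weights = np.empty(k)
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for c in range(k):
            diff = X - means[c]
            covs[c] = (resp[:, c, None] * diff).T @ diff / nk[c]
            covs[c].flat[:: d + 1] += reg
        # E step
        log_prob = np.column_stack([
            np.log(weights[c] + 1e-300) + _log_gaussian(X, means[c], covs[c])
            for c in range(k)
        ])
        log_norm = np.logaddexp.reduce(log_prob, axis=1)
        resp = np.exp(log_prob - log_norm[:, None])
        ll = float(log_norm.mean())
        trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return trace[-1], weights, means, covs, trace


@dataclass
class SubphenotypeModel:
    """Fitted mixture in standardized marker space, with the
    standardization parameters and the canonical component -> CIS map."""

    k: int
    weights: np.ndarray
    means: np.ndarray          # (k, d), standardized space
    covariances: np.ndarray    # (k, d, d)
    feature_names: list[str]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    label_map: Mapping[int, str]   # component index -> "CIS1"... ordered by severity
    seed: int
    loglik_trace: list[float] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.standardize_mean) / self.standardize_sd

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.asarray(X, dtype=float))
        log_prob = np.column_stack([
            np.log(self.weights[c] + 1e-300)
            + _log_gaussian(Z, self.means[c], self.covariances[c])
            for c in range(self.k)
        ])
        log_norm = np.logaddexp.reduce(log_prob, axis=1)
        return np.exp(log_prob - log_norm[:, None])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Canonical CIS labels ('CIS1'..'CISk') by argmax responsibility."""
        comp = np.argmax(self.responsibilities(X), axis=1)
        return np.array([self.label_map[int(c)] for c in comp])

    def severity_composite(self) -> np.ndarray:
        """Per-component severity score in standardized marker space."""
        w = np.array([_SEVERITY_WEIGHTS.get(f, 0.0) for f in self.feature_names])
        return self.means @ w

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "feature_names": self.feature_names,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "seed": self.seed,
            "loglik_trace": self.loglik_trace,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SubphenotypeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        p = json.loads(text)
        return cls(
            k=p["k"],
            weights=np.array(p["weights"]),
            means=np.array(p["means"]),
            covariances=np.array(p["covariances"]),
            feature_names=p["feature_names"],
            standardize_mean=np.array(p["standardize_mean"]),
            standardize_sd=np.array(p["standardize_sd"]),
            label_map={int(k): v for k, v in p["label_map"].items()},
            seed=p["seed"],
            loglik_trace=p["loglik_trace"],
        )


def _fit_gmm(
    Z: np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 10,
    reg: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-7,
):
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        try:
            fit = _em_once(Z, k, rng, reg, max_iter, tol)
        except linalg.LinAlgError:
            # singular covariance despite ridge: retry with stronger ridge
            fit = _em_once(Z, k, rng, reg * 1e3, max_iter, tol)
        if best is None or fit[0] > best[0]:
            best = fit
    return best


def fit_subphenotypes(
    cohort: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    markers: Sequence[str] = tuple(MARKER_COLUMNS),
    n_restarts: int = 10,
) -> tuple[SubphenotypeModel, pd.DataFrame]:
    """Fit a k-component Gaussian mixture on the standardized markers.

    Returns the model and a row-aligned assignment frame with the
    canonical label and per-component responsibilities.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = cohort[list(markers)].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    _, weights, means, covs, trace = _fit_gmm(Z, k, seed, n_restarts=n_restarts)

    model = SubphenotypeModel(
        k=k, weights=weights, means=means, covariances=covs,
        feature_names=list(markers), standardize_mean=mu, standardize_sd=sd,
        label_map={}, seed=seed, loglik_trace=trace,
    )
    order = np.argsort(model.severity_composite())  # ascending severity
    model.label_map = {int(c): f"CIS{rank + 1}" for rank, c in enumerate(order)}

    resp = model.responsibilities(X)
    assignment = pd.DataFrame(
        {"label": model.predict(X)},
        index=cohort.index,
    )
    for c in range(k):
        assignment[f"resp_{model.label_map[c]}"] = resp[:, c]
    return model, assignment


@dataclass
class ClusterIndexReport:
    candidates: list[int]
    silhouette: list[float]
    calinski_harabasz: list[float]
    davies_bouldin: list[float]
    selected_k: int
    rationale: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.candidates,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "davies_bouldin": self.davies_bouldin,
        })


def select_cluster_count(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    n_restarts: int = 3,
) -> ClusterIndexReport:
    """Choose the mixture count by majority vote of three indices.

    Silhouette and Calinski-Harabasz vote for their maximizing k,
    Davies-Bouldin for its minimizing k; ties break toward smaller k.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = k_range
    if not (2 <= lo <= hi <= len(X) - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
    candidates = list(range(lo, hi + 1))
    sil, ch, db = [], [], []
    for k in candidates:
        _, weights, means, covs, _ = _fit_gmm(X, k, seed, n_restarts=n_restarts)
        log_prob = np.column_stack([
            np.log(weights[c] + 1e-300) + _log_gaussian(X, means[c], covs[c])
            for c in range(k)
        ])
        labels = np.argmax(log_prob, axis=1)
        if np.unique(labels).size < 2:
            sil.append(-1.0), ch.append(0.0), db.append(np.inf)
            continue
        sil.append(float(silhouette_score(X, labels)))
        ch.append(float(calinski_harabasz_score(X, labels)))
        db.append(float(davies_bouldin_score(X, labels)))

    votes = [
        candidates[int(np.argmax(sil))],
        candidates[int(np.argmax(ch))],
        candidates[int(np.argmin(db))],
    ]
    counts = {k: votes.count(k) for k in set(votes)}
    top = max(counts.values())
    selected = min(k for k, c in counts.items() if c == top)
    return ClusterIndexReport(
        candidates, sil, ch, db, selected,
        rationale=f"votes silhouette/CH/DB = {votes}; majority (ties -> smaller k)",
    )


_CLUSTERERS = ("GMM", "KMeans", "MiniBatchKMeans", "HAC", "Birch")


def compare_clusterers(
    X: np.ndarray,
    k: int = 2,
    methods: Sequence[str] = _CLUSTERERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise adjusted-Rand agreement matrix across clustering methods."""
    from sklearn.metrics import adjusted_rand_score

    X = np.asarray(X, dtype=float)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    unknown = sorted(set(methods) - set(_CLUSTERERS))
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid methods: {list(_CLUSTERERS)}")
    labelings = {}
    for m in methods:
        if m == "GMM":
            _, weights, means, covs, _ = _fit_gmm(X, k, seed, n_restarts=5)
            log_prob = np.column_stack([
                np.log(weights[c] + 1e-300) + _log_gaussian(X, means[c], covs[c])
                for c in range(k)
            ])
            labelings[m] = np.argmax(log_prob, axis=1)
        elif m == "KMeans":
            labelings[m] = KMeans(k, n_init=10, random_state=seed).fit_predict(X)
        elif m == "MiniBatchKMeans":
            labelings[m] = MiniBatchKMeans(k, n_init=10, random_state=seed).fit_predict(X)
        elif m == "HAC":
            labelings[m] = AgglomerativeClustering(k).fit_predict(X)
        elif m == "Birch":
            labelings[m] = Birch(n_clusters=k).fit_predict(X)
    mat = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in list(methods)[i + 1:]:
            ari = adjusted_rand_score(labelings[a], labelings[b])
            mat.loc[a, b] = mat.loc[b, a] = ari
    return mat


def embed_2d(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two maximally independent components (FastICA), unit variance."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 columns")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise ValueError("input is rank-deficient; cannot extract 2 components")
    ica = FastICA(n_components=2, whiten="unit-variance", random_state=seed, max_iter=1000)
    return ica.fit_transform(X)


def siri(neut, mon, lym):
    """Systemic inflammatory response index: NEUT x MON / LYM."""
    neut = np.asarray(neut, dtype=float)
    mon = np.asarray(mon, dtype=float)
    lym = np.asarray(lym, dtype=float)
    out = np.full(np.broadcast(neut, mon, lym).shape, np.nan)
    ok = lym != 0
    out[ok] = neut[ok] * mon[ok] / lym[ok]
    return out if out.ndim else float(out)


def subgroup_summary(cohort: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-subphenotype clinical summary.

    One row per canonical label: n, 28-day mortality, median (IQR) of
    each marker, SIRI median (rows with LYM = 0 excluded and counted),
    and — when exactly two groups are present — two-sided rank-sum
    p-values for each marker contrast.
    """
    if len(assignment) != len(cohort):
        raise ValueError("assignment must be row-aligned with the cohort")
    labels = assignment["label"].to_numpy()
    groups = sorted(set(labels))
    siri_all = siri(cohort["neut"], cohort["mon"], cohort["lym"])
    rows = []
    for g in groups:
        mask = labels == g
        sub = cohort.loc[mask]
        row = {"label": g, "n": int(mask.sum())}
        if "died_28d" in cohort:
            row["mortality"] = float(sub["died_28d"].mean())
        for m in MARKER_COLUMNS:
            q1, q2, q3 = np.percentile(sub[m], [25, 50, 75])
            row[f"{m}_median"] = q2
            row[f"{m}_iqr"] = q3 - q1
        s = siri_all[mask]
        row["siri_median"] = float(np.nanmedian(s)) if np.isfinite(s).any() else np.nan
        row["siri_excluded"] = int(np.isnan(s).sum())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("label")
    if len(groups) == 2:
        a, b = (labels == groups[0]), (labels == groups[1])
        for m in MARKER_COLUMNS:
            stat = stats.mannwhitneyu(cohort.loc[a, m], cohort.loc[b, m],
                                      alternative="two-sided")
            table[f"{m}_p"] = stat.pvalue
    return table
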