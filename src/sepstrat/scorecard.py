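"""SMART risk scorecard: frozen evaluation engine and construction pipeline.

The frozen card assigns points to eight routine predictors (APTT, INR,
WBC, neutrophil, lymphocyte, monocyte and platelet counts, and patient
age) via ordered interval bins, sums them, and maps the total onto four
risk levels (mild, moderate, severe, dangerous).  Count-type markers,
APTT and age use lower-inclusive / upper-exclusive bins; INR bins are
lower-exclusive / upper-inclusive.

The construction pipeline mirrors standard credit-scorecard practice:
supervised bottom-up ChiMerge discretization, weight-of-evidence (WOE)
encoding with information value (IV) diagnostics, an L1-penalized
logistic fit on the WOE features, and points scaling via
(base_points, base_odds, pdo).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "Bin",
    "ScorecardSpec",
    "ScoreResult",
    "DEFAULT_RISK_THRESHOLDS",
    "RISK_LEVELS",
    "load_frozen_smart",
    "score_patient",
    "score_cohort",
    "chimerge_discretize",
    "woe_iv",
    "fit_scorecard",
]

RISK_LEVELS = ("mild", "moderate", "severe", "dangerous")

#: Repository-default total-score cutoffs (mild <= t1 < moderate <= t2 <
#: severe <= t3 < dangerous).  The source scorecard publishes no level
#: cutoffs; these defaults were calibrated once on synthetic cohorts to
#: reproduce the ~5 / 15 / 30 / 50 % mortality gradient and can be
#: overridden in the spec.
DEFAULT_RISK_THRESHOLDS = (7.0, 11.0, 15.0)


@dataclass(frozen=True)
class Bin:
    """One scoring interval: ``low <low_op> x <high_op> high -> points``
    with operators ``>=``/``>`` below and ``<``/``<=`` above."""

    low: float
    low_op: str  # ">=" or ">"
    high: float
    high_op: str  # "<" or "<="
    points: float

    def contains(self, x: float) -> bool:
        lo_ok = x >= self.low if self.low_op == ">=" else x > self.low
        hi_ok = x < self.high if self.high_op == "<" else x <= self.high
        return lo_ok and hi_ok

    def to_dict(self) -> dict:
        return {
            "low": self.low, "low_op": self.low_op,
            "high": self.high, "high_op": self.high_op,
            "points": self.points,
        }


@dataclass(frozen=True)
class ScorecardSpec:
    version: str
    variables: Mapping[str, Sequence[Bin]]
    thresholds: tuple[float, float, float] = DEFAULT_RISK_THRESHOLDS
    provenance: str = "fitted"  # "frozen" | "fitted"

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("risk thresholds must be ascending")
        for name, bins in self.variables.items():
            for a, b in zip(bins, bins[1:]):
                adjacent = a.high == b.low and {a.high_op, b.low_op} in (
                    {"<", ">="}, {"<=", ">"},
                )
                if not adjacent:
                    raise ValueError(f"bins of {name!r} are not contiguous at {a.high}")
            if not np.isinf(bins[-1].high):
                raise ValueError(f"bins of {name!r} do not cover +inf")

    def risk_level(self, total: float) -> str:
        t1, t2, t3 = self.thresholds
        if total <= t1:
            return "mild"
        if total <= t2:
            return "moderate"
        if total <= t3:
            return "severe"
        return "dangerous"

    def score_range(self) -> tuple[float, float]:
        """Minimum and maximum achievable totals."""
        lo = sum(min(b.points for b in bins) for bins in self.variables.values())
        hi = sum(max(b.points for b in bins) for bins in self.variables.values())
        return float(lo), float(hi)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "provenance": self.provenance,
            "thresholds": list(self.thresholds),
            "variables": {
                name: [b.to_dict() for b in bins]
                for name, bins in self.variables.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScorecardSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            version=payload["version"],
            variables={
                name: tuple(Bin(**b) for b in bins)
                for name, bins in payload["variables"].items()
            },
            thresholds=tuple(payload["thresholds"]),
            provenance=payload.get("provenance", "fitted"),
        )


@dataclass(frozen=True)
class ScoreResult:
    components: Mapping[str, float]
    matched_bins: Mapping[str, Bin]
    total: float
    risk_level: str


def _lo(points_and_edges, first_low=0.0, low_op=">="):
    """Build a contiguous lower-inclusive bin chain from
    [(upper_1, pts_1), ..., (inf, pts_k)]."""
    bins, low = [], first_low
    hi_op = "<" if low_op == ">=" else "<="
    for high, pts in points_and_edges:
        bins.append(Bin(low, low_op, high, hi_op, float(pts)))
        low = high
    return tuple(bins)


_INF = float("inf")

_FROZEN = ScorecardSpec(
    version="smart-frozen-v1",
    provenance="frozen",
    thresholds=DEFAULT_RISK_THRESHOLDS,
    variables={
        "aptt": _lo([(24.0, 0.0), (37.0, 1.0), (_INF, 2.0)]),
        "neut": _lo([(1.8, 2.0), (6.3, 1.0), (25.0, 2.0), (_INF, 3.0)]),
        "age": _lo([(46.0, -1.0), (58.0, 1.0), (83.0, 2.0), (_INF, 3.0)], first_low=18.0),
        "wbc": _lo([(4.0, 2.0), (10.0, 1.0), (28.0, 2.0), (_INF, 3.0)]),
        "plt": _lo([(125.0, 2.0), (_INF, 1.0)]),
        "inr": _lo([(1.2, 0.0), (1.4, 1.0), (1.6, 2.0), (_INF, 3.0)], low_op=">"),
        "lym": _lo([(1.1, 2.0), (_INF, 1.0)]),
        "mon": _lo([(0.1, 2.0), (0.6, 1.0), (_INF, 2.0)]),
    },
)


def load_frozen_smart() -> ScorecardSpec:
    """Return the shipped, immutable frozen scorecard."""
    return _FROZEN


def score_patient(record: Mapping[str, float], spec: ScorecardSpec | None = None) -> ScoreResult:
    """Score one patient record (any mapping with the eight marker keys)."""
    spec = spec or _FROZEN
    components: dict[str, float] = {}
    matched: dict[str, Bin] = {}
    for name, bins in spec.variables.items():
        if name not in record or record[name] is None:
            raise ValueError(f"missing marker {name!r}")
        x = float(record[name])
        if not np.isfinite(x):
            raise ValueError(f"non-finite value for marker {name!r}")
        if x < 0:
            raise ValueError(f"negative value {x} for marker {name!r}")
        if name == "age" and x < 18:
            raise ValueError("age must be >= 18")
        hit = next((b for b in bins if b.contains(x)), None)
        if hit is None:
            raise ValueError(f"value {x} for marker {name!r} matches no bin")
        components[name] = hit.points
        matched[name] = hit
    total = float(sum(components.values()))
    return ScoreResult(components, matched, total, spec.risk_level(total))


def score_cohort(cohort: pd.DataFrame, spec: ScorecardSpec | None = None) -> pd.DataFrame:
    """Score every row; returns a row-aligned frame with per-marker
    points, the total and the risk level.  Per-row validation errors are
    re-raised with the offending row index."""
    spec = spec or _FROZEN
    rows = []
    for idx, record in enumerate(cohort[list(spec.variables)].to_dict(orient="records")):
        try:
            res = score_patient(record, spec)
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        rows.append({
            **{f"pts_{k}": v for k, v in res.components.items()},
            "total": res.total,
            "risk_level": res.risk_level,
        })
    out = pd.DataFrame(rows, index=cohort.index)
    out.attrs["level_frequencies"] = (
        out["risk_level"].value_counts(normalize=True)
        .reindex(RISK_LEVELS, fill_value=0.0).to_dict()
    )
    return out


# ----------------------------------------------------------------------
# construction pipeline: ChiMerge -> WOE/IV -> L1 logistic -> points
# ----------------------------------------------------------------------

def _chi2_2x2(e1: float, n1: float, e2: float, n2: float) -> float:
    """Pearson chi-square of an adjacent interval pair (events /
    non-events); cells with zero expectation contribute nothing."""
    obs = np.array([[e1, n1], [e2, n2]], dtype=float)
    total = obs.sum()
    if total == 0:
        return 0.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    return float(terms.sum())


def chimerge_discretize(
    values: Sequence[float],
    labels: Sequence[int],
    max_bins: int = 5,
    chi2_threshold: float = 3.841,
    min_bin_frac: float = 0.05,
    prebins: int = 20,
) -> np.ndarray:
    """Supervised bottom-up ChiMerge binning.

    Values are quantile pre-binned (at most ``prebins`` intervals);
    then, while the smallest adjacent 2x2 chi-square class association
    stays below ``chi2_threshold`` and more than ``max_bins`` intervals
    remain, the least-associated adjacent pair is merged (so an
    infinite threshold merges exactly down to ``max_bins``).  Intervals
    holding fewer than ``min_bin_frac`` of the rows are always merged
    into their less-associated neighbor.  Returns strictly increasing
    edges covering the observed range (first edge = min value, last
    edge = max value).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.ndim != 1 or v.shape != y.shape:
        raise ValueError("values and labels must be 1-D and aligned")
    if np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct values")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        warnings.warn("all labels identical; returning a single bin")
        return np.array([v.min(), v.max()])

    uniq = np.unique(v)
    if uniq.size > prebins:
        cuts = np.unique(np.quantile(v, np.linspace(0, 1, prebins + 1)[1:-1]))
        cuts = cuts[(cuts > uniq[0]) & (cuts < uniq[-1])]
    else:
        cuts = (uniq[:-1] + uniq[1:]) / 2.0
    # interval i = (edge_i, edge_{i+1}]; first interval closed below
    edges = np.concatenate([[uniq[0]], cuts, [uniq[-1]]])
    idx = np.clip(np.searchsorted(edges[1:-1], v, side="left"), 0, len(edges) - 2)
    k = len(edges) - 1
    events = np.bincount(idx, weights=y, minlength=k)
    counts = np.bincount(idx, minlength=k)
    nonevents = counts - events

    ev, ne, ed = list(events), list(nonevents), list(edges)
    total = counts.sum()

    def merge(i: int) -> None:
        ev[i] += ev[i + 1]
        ne[i] += ne[i + 1]
        del ev[i + 1], ne[i + 1], ed[i + 1]

    while len(ev) > 1:
        chis = [_chi2_2x2(ev[i], ne[i], ev[i + 1], ne[i + 1]) for i in range(len(ev) - 1)]
        fracs = [(ev[i] + ne[i]) / total for i in range(len(ev))]
        if any(f < min_bin_frac for f in fracs):
            # merge the smallest offending bin with its lower-chi2 neighbor
            i = int(np.argmin(fracs))
            if i == 0:
                merge(0)
            elif i == len(ev) - 1:
                merge(i - 1)
            else:
                merge(i - 1 if chis[i - 1] <= chis[i] else i)
        elif len(ev) > max_bins and min(chis) < chi2_threshold:
            merge(int(np.argmin(chis)))
        else:
            break
    return np.asarray(ed, dtype=float)


def woe_iv(
    events: Sequence[float],
    nonevents: Sequence[float],
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Weight of evidence and information value per bin.

    WOE_b = ln((e_b/E)/(n_b/N)); zero cells receive a 0.5 continuity
    correction before the distributions are formed.  IV is the sum of
    (e_b/E - n_b/N) * WOE_b, stored per bin in ``iv_contribution``
    (total in ``frame.attrs["iv"]``).
    """
    e = np.asarray(events, dtype=float).copy()
    n = np.asarray(nonevents, dtype=float).copy()
    if e.size == 0 or e.shape != n.shape:
        raise ValueError("events and nonevents must be nonempty and aligned")
    if e.sum() <= 0 or n.sum() <= 0:
        raise ValueError("event and non-event totals must both be positive")
    e[e == 0] = 0.5
    n[n == 0] = 0.5
    de = e / e.sum()
    dn = n / n.sum()
    woe = np.log(de / dn)
    iv_contrib = (de - dn) * woe
    frame = pd.DataFrame({
        "events": e, "nonevents": n,
        "event_share": de, "nonevent_share": dn,
        "woe": woe, "iv_contribution": iv_contrib,
    })
    if labels is not None:
        frame.insert(0, "bin", list(labels))
    frame.attrs["iv"] = float(iv_contrib.sum())
    return frame


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def fit_scorecard(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    penalty: float = 0.01,
    base_points: float = 12.0,
    base_odds: float = 1.0 / 9.0,
    pdo: float = 4.0,
    outcome: str = "died_28d",
    thresholds: tuple[float, float, float] = DEFAULT_RISK_THRESHOLDS,
    max_bins: int = 5,
    orientation: str = "risk",
) -> ScorecardSpec:
    """Build a scorecard: ChiMerge bins, WOE encoding, L1-penalized
    logistic fit, and points scaling.

    Bin points are ``round(sign * coef_j * WOE_b * pdo/ln2 + offset/m)``
    where the offset spreads ``base_points - factor*ln(base_odds) -
    factor*intercept`` evenly over the ``m`` markers; ``orientation
    = "risk"`` (default) makes higher points mean higher mortality risk,
    ``"protective"`` keeps the credit-scoring direction.
    """
    if orientation not in ("risk", "protective"):
        raise ValueError("orientation must be 'risk' or 'protective'")
    y = cohort[outcome].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: only one class present")
    sign = 1.0 if orientation == "risk" else -1.0

    edges_per_marker: dict[str, np.ndarray] = {}
    woe_tables: dict[str, pd.DataFrame] = {}
    W = np.empty((len(cohort), len(markers)))
    bin_index = np.empty((len(cohort), len(markers)), dtype=int)
    for j, m in enumerate(markers):
        v = cohort[m].to_numpy(dtype=float)
        edges = chimerge_discretize(v, y, max_bins=max_bins)
        idx = np.clip(np.searchsorted(edges[1:-1], v, side="left"), 0, len(edges) - 2)
        k = len(edges) - 1
        ev = np.bincount(idx, weights=y, minlength=k)
        cnt = np.bincount(idx, minlength=k)
        table = woe_iv(ev, cnt - ev)
        edges_per_marker[m] = edges
        woe_tables[m] = table
        W[:, j] = table["woe"].to_numpy()[idx]
        bin_index[:, j] = idx

    clf = LogisticRegression(
        penalty="l1", C=1.0 / max(penalty, 1e-12), solver="liblinear", max_iter=2000
    )
    clf.fit(W, y)
    coefs = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])

    factor = pdo / np.log(2.0)
    offset = base_points - factor * np.log(base_odds) - sign * factor * intercept
    share = offset / len(markers)

    variables: dict[str, tuple[Bin, ...]] = {}
    for j, m in enumerate(markers):
        edges = edges_per_marker[m]
        woes = woe_tables[m]["woe"].to_numpy()
        bins = []
        for b in range(len(edges) - 1):
            pts = _round_half_away(sign * coefs[j] * woes[b] * factor + share)
            low = 0.0 if b == 0 else edges[b]
            high = np.inf if b == len(edges) - 2 else edges[b + 1]
            # interior intervals are (edge, edge]; outermost extended to cover all reals
            bins.append(Bin(low, ">=" if b == 0 else ">", high, "<=", pts))
        variables[m] = tuple(bins)

    spec = ScorecardSpec(
        version="fitted", variables=variables,
        thresholds=thresholds, provenance="fitted",
    )
    object.__setattr__(spec, "_fit_details", {
        "coefficients": dict(zip(markers, coefs)),
        "intercept": intercept,
        "iv": {m: woe_tables[m].attrs["iv"] for m in markers},
        "edges": {m: edges_per_marker[m].tolist() for m in markers},
    })
    return spec
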