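"""Frozen scorecard exactness and the construction pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepstrat import (
    GeneratorConfig,
    ScorecardSpec,
    chimerge_discretize,
    fit_scorecard,
    generate_cohort,
    load_frozen_smart,
    score_cohort,
    score_patient,
    woe_iv,
)

# ----------------------------------------------------------------------
# independent brute-force oracle for the frozen card: explicit interval
# lookups written directly from the published bin table, no shared code
# ----------------------------------------------------------------------

def _oracle_total(r):
    pts = 0.0
    pts += 0.0 if r["aptt"] < 24 else 1.0 if r["aptt"] < 37 else 2.0
    pts += 2.0 if r["neut"] < 1.8 else 1.0 if r["neut"] < 6.3 else 2.0 if r["neut"] < 25 else 3.0
    pts += -1.0 if r["age"] < 46 else 1.0 if r["age"] < 58 else 2.0 if r["age"] < 83 else 3.0
    pts += 2.0 if r["wbc"] < 4 else 1.0 if r["wbc"] < 10 else 2.0 if r["wbc"] < 28 else 3.0
    pts += 2.0 if r["plt"] < 125 else 1.0
    pts += 0.0 if r["inr"] <= 1.2 else 1.0 if r["inr"] <= 1.4 else 2.0 if r["inr"] <= 1.6 else 3.0
    pts += 2.0 if r["lym"] < 1.1 else 1.0
    pts += 2.0 if r["mon"] < 0.1 else 1.0 if r["mon"] < 0.6 else 2.0
    return pts


def _random_record(rng):
    return {
        "aptt": rng.uniform(0.1, 120), "neut": rng.uniform(0, 40),
        "age": rng.uniform(18, 100), "wbc": rng.uniform(0, 50),
        "plt": rng.uniform(0, 600), "inr": rng.uniform(0.3, 5),
        "lym": rng.uniform(0, 5), "mon": rng.uniform(0, 2),
    }


class TestFrozenCard:
    def test_bin_counts_match_published_table(self):
        spec = load_frozen_smart()
        counts = {name: len(bins) for name, bins in spec.variables.items()}
        assert counts == {
            "aptt": 3, "neut": 4, "age": 4, "wbc": 4,
            "plt": 2, "inr": 4, "lym": 2, "mon": 3,
        }

    def test_score_range_extremes(self):
        assert load_frozen_smart().score_range() == (4.0, 20.0)

    @pytest.mark.parametrize(
        "marker,value,points",
        [
            ("aptt", 40.0, 2.0),
            ("age", 40.0, -1.0),
            # lower-inclusive boundaries for count-type markers, APTT, age
            ("aptt", 37.0, 2.0),
            ("age", 46.0, 1.0),
            ("age", 58.0, 2.0),
            ("age", 83.0, 3.0),
            ("wbc", 4.0, 1.0),
            ("wbc", 10.0, 2.0),
            ("wbc", 28.0, 3.0),
            ("neut", 1.8, 1.0),
            ("neut", 6.3, 2.0),
            ("neut", 25.0, 3.0),
            ("plt", 125.0, 1.0),
            ("lym", 1.1, 1.0),
            ("mon", 0.1, 1.0),
            ("mon", 0.6, 2.0),
            # INR bins are upper-inclusive
            ("inr", 1.2, 0.0),
            ("inr", 1.4, 1.0),
            ("inr", 1.6, 2.0),
        ],
    )
    def test_boundary_semantics(self, marker, value, points):
        record = {"aptt": 30.0, "neut": 3.0, "age": 50.0, "wbc": 8.0,
                  "plt": 200.0, "inr": 1.1, "lym": 1.5, "mon": 0.3}
        record[marker] = value
        assert score_patient(record).components[marker] == points

    def test_worked_example_total(self):
        res = score_patient({"aptt": 20, "neut": 3.0, "age": 50, "wbc": 8,
                             "plt": 200, "inr": 1.1, "lym": 1.5, "mon": 0.3})
        assert res.total == 6.0
        assert res.risk_level == "mild"

    def test_engine_equals_oracle_on_10000_random_inputs(self):
        rng = np.random.default_rng(0)
        spec = load_frozen_smart()
        for _ in range(10000):
            rec = _random_record(rng)
            assert score_patient(rec, spec).total == _oracle_total(rec)

    def test_spec_round_trip(self, tmp_path):
        spec = load_frozen_smart()
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert ScorecardSpec.from_json(path) == spec

    @pytest.mark.parametrize("missing", ["aptt", "mon"])
    def test_missing_marker_named(self, missing):
        record = _random_record(np.random.default_rng(1))
        del record[missing]
        with pytest.raises(ValueError, match=missing):
            score_patient(record)

    def test_negative_value_rejected(self):
        record = _random_record(np.random.default_rng(1))
        record["wbc"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            score_patient(record)


class TestScoreCohort:
    def test_single_row_matches_score_patient(self, small_cohort):
        one = small_cohort.head(1)
        frame = score_cohort(one)
        res = score_patient(one.iloc[0].to_dict())
        assert frame["total"].iloc[0] == res.total
        assert frame["risk_level"].iloc[0] == res.risk_level

    def test_identical_patients_identical_totals(self, small_cohort):
        rep = small_cohort.head(1).loc[small_cohort.index[:1].repeat(10)]
        assert score_cohort(rep)["total"].nunique() == 1

    def test_row_error_reports_index(self, small_cohort):
        bad = small_cohort.head(5).copy()
        bad.loc[bad.index[3], "wbc"] = -2.0
        with pytest.raises(ValueError, match="row 3"):
            score_cohort(bad)


# ----------------------------------------------------------------------
# ChiMerge: exhaustive merge-simulation oracle on small inputs
# ----------------------------------------------------------------------

def _chimerge_oracle(values, labels, max_bins, chi2_threshold, min_bin_frac):
    """Independent step-by-step simulation with naive chi-square."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(values)
    intervals = [[u] for u in uniq]  # each holds its member values

    def counts(iv):
        mask = np.isin(values, iv)
        return labels[mask].sum(), (~labels.astype(bool))[mask].sum()

    def chi2(iv1, iv2):
        e1, n1 = counts(iv1)
        e2, n2 = counts(iv2)
        obs = np.array([[e1, n1], [e2, n2]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        return float(np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum())

    total = len(values)
    while len(intervals) > 1:
        chis = [chi2(intervals[i], intervals[i + 1]) for i in range(len(intervals) - 1)]
        fracs = [np.isin(values, iv).sum() / total for iv in intervals]
        if any(f < min_bin_frac for f in fracs):
            i = int(np.argmin(fracs))
            if i == 0:
                j = 0
            elif i == len(intervals) - 1:
                j = i - 1
            else:
                j = i - 1 if chis[i - 1] <= chis[i] else i
            intervals[j] = intervals[j] + intervals[j + 1]
            del intervals[j + 1]
        elif len(intervals) > max_bins and min(chis) < chi2_threshold:
            j = int(np.argmin(chis))
            intervals[j] = intervals[j] + intervals[j + 1]
            del intervals[j + 1]
        else:
            break
    edges = [uniq[0]]
    for a, b in zip(intervals, intervals[1:]):
        edges.append((max(a) + min(b)) / 2)
    edges.append(uniq[-1])
    return np.asarray(edges)


class TestChiMerge:
    def test_textbook_split(self):
        edges = chimerge_discretize([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1], max_bins=2)
        assert len(edges) == 3
        assert 3 < edges[1] < 4

    def test_matches_exhaustive_oracle_on_small_inputs(self, rng):
        for trial in range(50):
            n_distinct = rng.integers(3, 9)
            values = rng.choice(np.arange(n_distinct, dtype=float), size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            kwargs = dict(max_bins=int(rng.integers(2, 5)),
                          chi2_threshold=float(rng.choice([0.5, 3.841, np.inf])),
                          min_bin_frac=0.0)
            got = chimerge_discretize(values, labels, **kwargs)
            want = _chimerge_oracle(values, labels, **kwargs)
            np.testing.assert_allclose(got, want)

    def test_infinite_threshold_merges_to_max_bins(self, rng):
        values = rng.normal(size=500)
        labels = rng.integers(0, 2, size=500)  # independent of values
        edges = chimerge_discretize(values, labels, max_bins=4, chi2_threshold=np.inf,
                                    min_bin_frac=0.0)
        assert len(edges) - 1 == 4

    def test_edges_strictly_increasing_and_cover_range(self, rng):
        values = rng.lognormal(size=400)
        labels = (values + rng.normal(size=400) > 1).astype(int)
        edges = chimerge_discretize(values, labels)
        assert (np.diff(edges) > 0).all()
        assert edges[0] == values.min() and edges[-1] == values.max()

    def test_constant_labels_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="single bin"):
            edges = chimerge_discretize([1.0, 2.0, 3.0], [1, 1, 1])
        assert len(edges) == 2


class TestWoeIv:
    def test_equal_distributions_zero_woe(self):
        frame = woe_iv([10, 20], [100, 200])
        np.testing.assert_allclose(frame["woe"], 0.0, atol=1e-12)
        assert frame.attrs["iv"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_example(self):
        # bin with event share 0.2 vs non-event share 0.1
        frame = woe_iv([20, 80], [10, 90])
        assert frame["woe"].iloc[0] == pytest.approx(np.log(2), abs=1e-9)
        assert frame["iv_contribution"].iloc[0] == pytest.approx(0.1 * np.log(2), abs=1e-9)

    def test_swap_flips_woe_keeps_iv(self, rng):
        e = rng.integers(1, 50, size=6)
        n = rng.integers(1, 50, size=6)
        a, b = woe_iv(e, n), woe_iv(n, e)
        np.testing.assert_allclose(a["woe"], -b["woe"], atol=1e-12)
        assert a.attrs["iv"] == pytest.approx(b.attrs["iv"], abs=1e-12)

    @given(st.lists(st.integers(0, 200), min_size=2, max_size=10),
           st.lists(st.integers(0, 200), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_iv_nonnegative_and_reorder_invariant(self, e, n):
        k = min(len(e), len(n))
        e, n = np.array(e[:k]), np.array(n[:k])
        if e.sum() == 0 or n.sum() == 0:
            return
        frame = woe_iv(e, n)
        assert frame.attrs["iv"] >= -1e-12
        assert frame["event_share"].sum() == pytest.approx(1.0)
        assert frame["nonevent_share"].sum() == pytest.approx(1.0)
        perm = np.random.default_rng(0).permutation(k)
        assert woe_iv(e[perm], n[perm]).attrs["iv"] == pytest.approx(frame.attrs["iv"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            woe_iv([], [])


class TestFitScorecard:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(GeneratorConfig(n_per_center=4000, seed=21))

    def test_full_shrinkage_gives_flat_points(self, cohort):
        spec = fit_scorecard(cohort, ["aptt", "wbc"], penalty=1e6)
        for bins in spec.variables.values():
            assert len({b.points for b in bins}) == 1

    def test_single_marker_points_monotone_in_event_rate(self, cohort):
        spec = fit_scorecard(cohort, ["aptt"], penalty=1e-6)
        details = spec._fit_details
        edges = np.asarray(details["edges"]["aptt"])
        v = cohort["aptt"].to_numpy()
        idx = np.clip(np.searchsorted(edges[1:-1], v), 0, len(edges) - 2)
        rates = [cohort["died_28d"][idx == b].mean() for b in range(len(edges) - 1)]
        pts = [b.points for b in spec.variables["aptt"]]
        order = np.argsort(rates)
        ordered = np.asarray(pts)[order]
        assert (np.diff(ordered) >= 0).all() or (np.diff(ordered) <= 0).all()

    def test_risk_orientation_scores_deaths_higher(self, cohort):
        spec = fit_scorecard(cohort, ["aptt", "plt", "age"], penalty=0.001)
        scores = score_cohort(cohort, spec)["total"]
        died = cohort["died_28d"] == 1
        assert scores[died].mean() > scores[~died].mean()

    def test_fitted_spec_satisfies_invariants(self, cohort):
        spec = fit_scorecard(cohort, ["aptt", "wbc", "lym"], penalty=0.01)
        # construction through ScorecardSpec enforces contiguity/coverage;
        # every finite value must match exactly one bin
        rng = np.random.default_rng(3)
        for bins in spec.variables.values():
            for x in rng.uniform(0, 500, size=50):
                assert sum(b.contains(x) for b in bins) == 1

    def test_degenerate_outcome_rejected(self, cohort):
        flat = cohort.copy()
        flat["died_28d"] = 0
        with pytest.raises(ValueError, match="one class"):
            fit_scorecard(flat, ["aptt"])
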