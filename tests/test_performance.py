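import math

import numpy as np
import pandas as pd
import pytest

from nrf2modnet.io import EXPERIMENT_COLUMNS
from nrf2modnet.network import GeneModule, ModuleSet
from nrf2modnet.performance import (
    call_perturbations,
    calls_from_significance_flags,
    performance_indicators,
    roc_auc,
    select_negative_control_modules,
)


def _scores(rows: dict[tuple, list[float]], modules=("M1",)):
    index = pd.MultiIndex.from_tuples(rows.keys(), names=EXPERIMENT_COLUMNS)
    return pd.DataFrame(list(rows.values()), index=index, columns=list(modules))


def _annotations(mapping: dict[str, str], column: str = "reactivity"):
    other = "dili_concern" if column == "reactivity" else "reactivity"
    df = pd.DataFrame({"compound": list(mapping), column: list(mapping.values())})
    df["is_drug"] = 1
    df[other] = "unknown" if other == "reactivity" else "absent"
    return df


def _calls_from_bools(mapping: dict[str, bool]):
    return pd.DataFrame(
        {"positive_combined": list(mapping.values())}, index=pd.Index(list(mapping), name="compound")
    )


class TestCallPerturbations:
    def test_threshold_inclusive_at_exactly_two(self):
        calls = call_perturbations(_scores({("A", "high", 24): [2.0]}))
        assert bool(calls.loc["A", "positive_M1"])

    def test_max_over_experiments_rule(self):
        calls = call_perturbations(
            _scores(
                {
                    ("A", "low", 8): [1.9],
                    ("A", "middle", 8): [1.8],
                    ("A", "high", 24): [2.3],
                }
            )
        )
        assert calls.loc["A", "M1"] == pytest.approx(2.3)
        assert bool(calls.loc["A", "positive_M1"])

    def test_combined_flag_is_union_of_module_flags(self):
        scores = _scores(
            {("A", "high", 24): [2.5, 0.1], ("B", "high", 24): [0.3, 0.2]},
            modules=("M1", "M2"),
        )
        calls = call_perturbations(scores)
        assert bool(calls.loc["A", "positive_combined"])
        assert not bool(calls.loc["B", "positive_combined"])
        single = calls["positive_M1"] | calls["positive_M2"]
        assert (calls["positive_combined"] == single).all()

    def test_flags_from_stored_significance_marks(self):
        flags = pd.DataFrame(
            {"144": [True, False], "192": [False, False]},
            index=pd.Index(["A", "B"], name="compound"),
        )
        calls = calls_from_significance_flags(flags)
        assert bool(calls.loc["A", "positive_combined"])
        assert not bool(calls.loc["B", "positive_combined"])


class TestPerformanceIndicators:
    def test_worked_arithmetic_example(self):
        # 8/10 reactive called positive, 3/17 non-reactive called positive
        mapping = {}
        calls = {}
        for i in range(10):
            mapping[f"R{i}"] = "reactive"
            calls[f"R{i}"] = i < 8
        for i in range(17):
            mapping[f"N{i}"] = "not_bioactivated_or_reactive"
            calls[f"N{i}"] = i < 3
        rep = performance_indicators(_calls_from_bools(calls), _annotations(mapping), "reactivity")
        assert rep["sensitivity"] == pytest.approx(0.800, abs=1e-3)
        assert rep["specificity"] == pytest.approx(1 - 3 / 17)
        assert rep["ppv"] == pytest.approx(8 / 11)
        assert rep["npv"] == pytest.approx(14 / 16)
        assert rep["accuracy"] == pytest.approx(22 / 27)

    def test_degenerate_all_positive_caller(self):
        mapping = {"R0": "reactive", "N0": "not_bioactivated_or_reactive"}
        rep = performance_indicators(
            _calls_from_bools({"R0": True, "N0": True}), _annotations(mapping), "reactivity"
        )
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 0.0
        assert math.isnan(rep["npv"])  # undefined, never reported as 0

    def test_out_of_class_compounds_excluded(self):
        mapping = {
            "R0": "reactive",
            "N0": "not_bioactivated_or_reactive",
            "U0": "unknown",
            "B0": "bioactivated",
        }
        rep = performance_indicators(
            _calls_from_bools({c: True for c in mapping}), _annotations(mapping), "reactivity"
        )
        assert rep["tp"] + rep["fp"] + rep["tn"] + rep["fn"] == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        compounds = [f"C{i}" for i in range(30)]
        labels = rng.choice(["most", "less_none", "ambiguous", "absent"], size=30)
        called = rng.random(30) < 0.5
        mapping = dict(zip(compounds, labels))
        rep = performance_indicators(
            _calls_from_bools(dict(zip(compounds, called))),
            _annotations(mapping, column="dili_concern"),
            "dili_concern",
        )
        tp = fp = tn = fn = 0  # exhaustive recount
        for c, lab, pos in zip(compounds, labels, called):
            if lab == "most":
                tp, fn = tp + pos, fn + (not pos)
            elif lab == "less_none":
                fp, tn = fp + pos, tn + (not pos)
        assert (rep["tp"], rep["fp"], rep["tn"], rep["fn"]) == (tp, fp, tn, fn)
        assert rep["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_empty_class_errors(self):
        mapping = {"R0": "reactive"}
        with pytest.raises(ValueError, match="negative class"):
            performance_indicators(
                _calls_from_bools({"R0": True}), _annotations(mapping), "reactivity"
            )


class TestRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series([3.0, 2.5, 0.1, -0.5], index=list("abcd"))
        labels = pd.Series([True, True, False, False], index=list("abcd"))
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        scores = pd.Series([1.0] * 6, index=list("abcdef"))
        labels = pd.Series([True, False] * 3, index=list("abcdef"))
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        idx = [f"c{i}" for i in range(n)]
        scores = pd.Series(np.round(rng.normal(size=n), 1), index=idx)  # forces ties
        labels = pd.Series(rng.random(n) < 0.5, index=idx)
        if labels.all() or not labels.any():
            labels.iloc[0] = not labels.iloc[0]
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels].to_numpy()
        neg = scores[~labels].to_numpy()
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        idx = [f"c{i}" for i in range(20)]
        scores = pd.Series(rng.normal(size=20), index=idx)
        labels = pd.Series(rng.random(20) < 0.4, index=idx)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores * 3), labels)
        assert a1 == pytest.approx(a2)

    def test_one_class_empty_errors(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(scores, pd.Series([True, True], index=["a", "b"]))

    def test_threshold_monotonicity_of_indicators(self):
        # raising the threshold never increases sensitivity / decreases specificity
        rng = np.random.default_rng(8)
        from nrf2modnet.io import EXPERIMENT_COLUMNS

        rows = {(f"C{i}", "high", 24): [rng.normal(1.5, 1.5)] for i in range(40)}
        scores = _scores(rows)
        labels = {f"C{i}": ("reactive" if rng.random() < 0.5 else "not_bioactivated_or_reactive") for i in range(40)}
        ann = _annotations(labels)
        prev_sens, prev_spec = 1.1, -0.1
        for thr in (0.5, 1.5, 2.5, 3.5):
            calls = call_perturbations(scores, threshold=thr)
            rep = performance_indicators(calls, ann, "reactivity", scorer="combined")
            if not math.isnan(rep["sensitivity"]):
                assert rep["sensitivity"] <= prev_sens + 1e-12
                prev_sens = rep["sensitivity"]
            if not math.isnan(rep["specificity"]):
                assert rep["specificity"] >= prev_spec - 1e-12
                prev_spec = rep["specificity"]


class TestNegativeControlSelection:
    def _mset(self, sizes, offset=0):
        modules = []
        g = offset
        for i, s in enumerate(sizes):
            modules.append(GeneModule(f"M{i}", [f"g{j}" for j in range(g, g + s)]))
            g += s
        return ModuleSet(modules=modules, unassigned=[])

    def test_size_window_inclusive(self):
        mset = self._mset([5, 6, 8, 11, 12])
        picked = select_negative_control_modules(mset, size_range=(6, 11))
        assert picked == ["M1", "M2", "M3"]

    def test_exclusion_set_disjointness(self):
        mset = self._mset([8, 8])
        exclusion = {"g0", "g1"}  # inside M0 only
        picked = select_negative_control_modules(mset, exclusion_genes=exclusion)
        assert picked == ["M1"]

    def test_planted_signal_modules_never_selected(self, small_panel):
        from .conftest import moduleset_from_truth

        _, _, truth = small_panel
        mset = moduleset_from_truth(truth.gene_module_assignment)
        signal_genes = set(truth.nrf2_dependent_genes.index)
        picked = select_negative_control_modules(
            mset, size_range=(2, 50), exclusion_genes=signal_genes
        )
        assert picked  # background modules exist
        for mid in picked:
            assert not (set(mset.module(mid).genes) & signal_genes)
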