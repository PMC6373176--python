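"""Compound-level perturbation calls and DILI-feature performance indicators.

A compound positively perturbs a module when the maximum module score over
all of its experiments (concentration x time combinations) is at or above
the threshold (2.0 by default, applied to full-precision scores).  The
*combined* metric calls a compound positive when any of the selected modules
is positive.  Calls are then evaluated against compound features associated
with drug-induced liver injury — intrinsic biochemical reactivity, metabolic
bioactivation, clinical DILI concern — via confusion-matrix indicators and
ROC analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .network import ModuleSet

POSITIVE_THRESHOLD = 2.0

FEATURE_CLASSES = {
    # feature -> (positive labels, negative labels); everything else excluded
    "reactivity": (("reactive",), ("not_bioactivated_or_reactive",)),
    "bioactivation": (("bioactivated",), ("not_bioactivated_or_reactive",)),
    "dili_concern": (("most",), ("less_none",)),
}
FEATURE_COLUMN = {"reactivity": "reactivity", "bioactivation": "reactivity", "dili_concern": "dili_concern"}


def call_perturbations(
    z_scores: pd.DataFrame,
    module_ids: list[str] | None = None,
    threshold: float = POSITIVE_THRESHOLD,
) -> pd.DataFrame:
    """Per-compound maximum module score and positive-perturbation flags.

    ``z_scores`` is experiments x modules with a (compound, concentration,
    time_h) MultiIndex.  For each compound the experiment with the highest
    score is used per module; the flag is max >= threshold (inclusive) and
    the combined flag is "any module positive".
    """
    if module_ids is None:
        module_ids = list(z_scores.columns)
    missing = [m for m in module_ids if m not in z_scores.columns]
    if missing:
        raise ValueError(f"modules absent from score table: {missing}")
    sub = z_scores[module_ids]
    by_compound = sub.groupby(level="compound", sort=True).max()
    calls = by_compound.copy()
    flags = by_compound >= threshold
    flags.columns = [f"positive_{m}" for m in module_ids]
    out = pd.concat([calls, flags], axis=1)
    out["positive_combined"] = flags.any(axis=1)
    return out


def calls_from_significance_flags(flags: pd.DataFrame) -> pd.DataFrame:
    """Perturbation calls taken directly from stored significance marks.

    Used with published tables whose displayed values are rounded: the marks
    encode significance at full precision, so thresholding is not re-applied.
    """
    out = flags.copy().astype(bool)
    out.columns = [f"positive_{m}" for m in flags.columns]
    out["positive_combined"] = out.any(axis=1)
    return out


def _split_classes(
    annotations: pd.DataFrame,
    feature: str,
    positive_class: tuple[str, ...] | None = None,
    negative_class: tuple[str, ...] | None = None,
) -> tuple[set[str], set[str]]:
    if feature not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {sorted(FEATURE_CLASSES)}")
    pos_default, neg_default = FEATURE_CLASSES[feature]
    positive_class = tuple(positive_class) if positive_class else pos_default
    negative_class = tuple(negative_class) if negative_class else neg_default
    col = FEATURE_COLUMN[feature]
    ann = annotations.set_index("compound")[col]
    pos = set(ann.index[ann.isin(positive_class)])
    neg = set(ann.index[ann.isin(negative_class)])
    if not pos:
        raise ValueError(f"empty positive class for feature {feature}")
    if not neg:
        raise ValueError(f"empty negative class for feature {feature}")
    return pos, neg


def performance_indicators(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    feature: str,
    scorer: str = "combined",
    positive_class: tuple[str, ...] | None = None,
    negative_class: tuple[str, ...] | None = None,
) -> dict:
    """Confusion-matrix indicators of one scorer against one compound feature.

    sensitivity = TP / (TP + FN); specificity = 1 - FP / (FP + TN);
    accuracy = (TP + TN) / all; PPV = TP / (TP + FP); NPV = TN / (TN + FN).
    Compounds outside the positive and negative classes are excluded before
    counting.  Zero-denominator ratios are reported as NaN, never as 0.
    """
    flag_col = f"positive_{scorer}"
    if flag_col not in calls.columns:
        raise ValueError(f"no flag column {flag_col!r} in calls")
    pos, neg = _split_classes(annotations, feature, positive_class, negative_class)
    universe = pos | neg
    # compounds absent from the call table never reached threshold
    called = pd.Series(False, index=sorted(universe))
    present = calls.index.intersection(called.index)
    called[present] = calls.loc[present, flag_col].astype(bool)

    tp = int(sum(called[c] for c in universe & pos))
    fn = int(len(universe & pos) - tp)
    fp = int(sum(called[c] for c in universe & neg))
    tn = int(len(universe & neg) - fp)

    def ratio(a, b):
        return a / b if b > 0 else math.nan

    return {
        "feature": feature,
        "scorer": scorer,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": 1.0 - ratio(fp, fp + tn) if (fp + tn) > 0 else math.nan,
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def roc_auc(scores: pd.Series, labels: pd.Series) -> tuple[float, pd.DataFrame]:
    """ROC curve and trapezoidal AUC of a continuous score vs binary labels.

    Thresholds sweep the observed scores; the trapezoidal area equals the
    Mann-Whitney U statistic scaled by n+ * n-, with ties counted one half.
    """
    labels = labels.loc[scores.index].astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes nonempty")

    s = scores.to_numpy(dtype=float)
    y = labels.to_numpy()
    thresholds = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        called = s >= thr
        tpr.append(float(np.sum(called & y)) / n_pos)
        fpr.append(float(np.sum(called & ~y)) / n_neg)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return auc, points


def select_negative_control_modules(
    modules: ModuleSet,
    size_range: tuple[int, int] = (6, 11),
    exclusion_genes: set[str] | None = None,
) -> list[str]:
    """Similarly sized modules disjoint from a supplied exclusion gene set.

    Stands in for the published criteria "comparable size (6-11 genes) and
    no oxidative-stress GO enrichment": the ontology criterion is reduced to
    disjointness from a caller-supplied gene set (e.g. planted signal genes
    or known stress-response genes).
    """
    lo, hi = size_range
    if lo > hi:
        raise ValueError("empty size range")
    exclusion_genes = exclusion_genes or set()
    out = []
    for module in modules.modules:
        if lo <= len(module.genes) <= hi and not (set(module.genes) & exclusion_genes):
            out.append(module.module_id)
    return out
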