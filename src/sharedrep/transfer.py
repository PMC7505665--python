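"""Applying trained patterns to independent data.

Two questions are answered here.  Specificity: does a pain decoder also
discriminate non-painful high-arousal negative pictures from neutral
ones (it should not, if it encodes pain rather than arousal)?
Generalization: does the pattern's expression track graded thermal pain
— correlation with temperature level and subjective rating, and forced
choice between averaged high and low stimulation levels?

Pattern expression on transfer data is always the raw dot product of the
weight map with the image; the training scaler is never applied because
independent acquisitions are not on the training set's per-voxel scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .decode import (
    CVScheme,
    EvalResult,
    PatternModel,
    _paired_summary,
    fit_pattern,
    pattern_expression,
)
from .simulate import SyntheticDataset

__all__ = [
    "expression_series",
    "expression_correlation",
    "level_contrast_2afc",
    "specificity_eval",
]


def expression_series(
    model: PatternModel, dataset: SyntheticDataset
) -> pd.DataFrame:
    """One pattern-expression value per image, joined to the design table.

    Returns the design with an added ``expression`` column (raw dot
    product, offset excluded, no scaling).
    """
    if dataset.images.shape[1] != model.weights.size:
        raise ValueError(
            f"image length {dataset.images.shape[1]} != model voxel count "
            f"{model.weights.size}"
        )
    expr = pattern_expression(model, dataset.images, apply_scaling=False)
    out = dataset.design.copy()
    out["expression"] = np.asarray(expr, dtype=float)
    if not np.all(np.isfinite(out["expression"])):
        raise ValueError("non-finite expression values")
    return out


def expression_correlation(
    series: pd.DataFrame, covariate: str = "level"
) -> tuple[float, int, float]:
    """Pooled Pearson correlation of expression with a covariate.

    Rows are pooled across subjects and conditions (33 subjects x 6
    levels gives df = 196); returns (r, df, p) with df = n_rows - 2.
    """
    if covariate not in series.columns:
        raise ValueError(f"series has no column {covariate!r}")
    x = series[covariate].to_numpy(dtype=float)
    y = series["expression"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 rows")
    if np.all(x == x[0]):
        raise ValueError("constant covariate")
    r, p = stats.pearsonr(x, y)
    return float(r), int(x.size - 2), float(p)


def level_contrast_2afc(
    series: pd.DataFrame,
    low_levels: set[int],
    high_levels: set[int],
) -> EvalResult:
    """Forced choice between averaged high and low stimulation levels.

    Per subject, expressions are averaged within each level set; the
    high-set average should exceed the low-set average.  Subjects missing
    any required level are excluded with a warning.
    """
    low = set(low_levels)
    high = set(high_levels)
    if not low or not high:
        raise ValueError("both level sets must be nonempty")
    if low & high:
        raise ValueError("level sets must be disjoint")
    diffs = []
    excluded = []
    for subject, rows in series.groupby("subject"):
        levels = set(rows["level"].dropna().astype(int))
        if not (low <= levels and high <= levels):
            excluded.append(subject)
            continue
        lo = rows.loc[rows["level"].isin(low), "expression"].mean()
        hi = rows.loc[rows["level"].isin(high), "expression"].mean()
        diffs.append(hi - lo)
    if excluded:
        warnings.warn(f"excluded subjects missing levels: {excluded}")
    if not diffs:
        raise ValueError("no subject has all required levels")
    return _paired_summary(np.asarray(diffs), single_correct=np.array([]))


def specificity_eval(
    dataset: SyntheticDataset,
    train_modality: str,
    scheme: CVScheme,
    C: float = 1.0,
    test_modality: str = "IAPS",
    test_conditions: tuple[str, str] = ("negative", "neutral"),
    train_conditions: tuple[str, str] = ("pain", "control"),
) -> EvalResult:
    """Forced choice of a pain decoder on the negative-vs-neutral contrast.

    The fold structure mirrors the decoder's own cross-validation: within
    each repeat x fold, the decoder trained on the training-fold pain
    pairs is applied (raw dot products) to the held-out subjects'
    negative and neutral images.  Chance-level accuracy indicates the
    decoder does not encode the arousal/negative-affect axis.
    """
    subs_tr, pain, ctrl = dataset.paired(train_modality, *train_conditions)
    subs_te, neg, neu = dataset.paired(test_modality, *test_conditions)
    if not np.array_equal(subs_tr, subs_te):
        raise ValueError("train and test conditions must cover the same subjects")
    assignments = scheme.assignments(pain.shape[0])
    n_subjects = pain.shape[0]
    per_repeat = []
    for r in range(assignments.shape[0]):
        fold_of = assignments[r]
        diffs = np.empty(n_subjects)
        for f in range(fold_of.max() + 1):
            test_idx = np.flatnonzero(fold_of == f)
            train_idx = np.flatnonzero(fold_of != f)
            x = np.vstack([pain[train_idx], ctrl[train_idx]])
            y = np.concatenate([np.ones(train_idx.size), -np.ones(train_idx.size)])
            model = fit_pattern(x, y, C=C)
            expr_neg = pattern_expression(model, neg[test_idx], apply_scaling=False)
            expr_neu = pattern_expression(model, neu[test_idx], apply_scaling=False)
            diffs[test_idx] = np.atleast_1d(expr_neg - expr_neu)
        per_repeat.append(_paired_summary(diffs, single_correct=np.array([])))
    return EvalResult(
        accuracy_2afc=float(np.mean([r.accuracy_2afc for r in per_repeat])),
        accuracy_single=float("nan"),
        p_value=float(np.mean([r.p_value for r in per_repeat])),
        cohens_d=float(np.mean([r.cohens_d for r in per_repeat])),
        per_subject_correct=np.mean(
            [r.per_subject_correct for r in per_repeat], axis=0
        ),
        per_repeat=per_repeat,
    )
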