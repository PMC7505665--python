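"""Whole-brain linear decoders and their evaluation machinery.

The decoder is a linear support-vector machine (C = 1 by default) trained
on per-subject condition-average images.  Before training, every voxel of
the training set is affinely scaled to [-1, 1] (min -> -1, max -> +1);
test images are scaled with the *training* parameters, so test values may
fall outside [-1, 1].  Performance is summarized two ways:

* single-interval accuracy — sign of the decision value w.x + b against
  the label, per image;
* two-alternative forced choice (2AFC) — per subject, the member of the
  (pain, control) pair with the higher pattern expression w.x is called
  pain; ties score 0.5.

Significance is a one-tailed binomial test of the per-subject 2AFC
outcomes against chance 0.5, and the effect size is Cohen's d of the
paired expression differences.  Cross-validation assigns whole subjects
to folds (both members of a pair always travel together) and is repeated
over independent random partitions; accuracies and p values are averaged
across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .simulate import SyntheticDataset

__all__ = [
    "PatternModel",
    "CVScheme",
    "EvalResult",
    "fit_scaler",
    "apply_scaler",
    "train_decoder",
    "fit_pattern",
    "pattern_expression",
    "forced_choice",
    "repeated_cv",
    "cross_modality_eval",
    "train_final",
    "learning_curve",
]


# ---------------------------------------------------------------------------
# model container and primitives


@dataclass
class PatternModel:
    """A trained linear decoder in masked voxel space."""

    weights: np.ndarray
    offset: float
    scale_min: np.ndarray
    scale_max: np.ndarray
    margin_param: float = 1.0
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.scale_min = np.asarray(self.scale_min, dtype=float)
        self.scale_max = np.asarray(self.scale_max, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite decoder weights")
        if np.any(self.scale_max < self.scale_min):
            raise ValueError("scale_max must be >= scale_min elementwise")

    def scale(self, images: np.ndarray) -> np.ndarray:
        return apply_scaler(images, self.scale_min, self.scale_max)

    def decision_values(self, images: np.ndarray, apply_scaling: bool = True) -> np.ndarray:
        x = np.atleast_2d(np.asarray(images, dtype=float))
        if apply_scaling:
            x = self.scale(x)
        return x @ self.weights + self.offset


def fit_scaler(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel min/max of the training images (>= 2 rows required)."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need at least 2 training images")
    return train.min(axis=0), train.max(axis=0)


def apply_scaler(
    images: np.ndarray, scale_min: np.ndarray, scale_max: np.ndarray
) -> np.ndarray:
    """Affine map sending train min -> -1, train max -> +1 per voxel.

    Voxels constant in the training set map every value (train and test)
    to 0.  Test values outside the training range extrapolate beyond
    [-1, 1].
    """
    x = np.atleast_2d(np.asarray(images, dtype=float))
    rng = scale_max - scale_min
    ok = rng > 0
    out = np.zeros_like(x)
    out[:, ok] = -1.0 + 2.0 * (x[:, ok] - scale_min[ok]) / rng[ok]
    return out


def train_decoder(
    scaled_train: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    scale_min: np.ndarray | None = None,
    scale_max: np.ndarray | None = None,
    training_meta: dict | None = None,
    tol: float = 1e-6,
) -> PatternModel:
    """Fit the linear max-margin classifier (hinge loss, penalty C).

    ``scaled_train`` must already be in the scaled feature space; the
    scaler parameters are stored on the model so that test images can be
    mapped identically.
    """
    x = np.asarray(scaled_train, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded +1/-1")
    svm = SVC(kernel="linear", C=C, tol=tol)
    svm.fit(x, y)
    w = svm.coef_.ravel().astype(float)
    b = float(svm.intercept_[0])
    # sklearn orients the decision function by class order; enforce +1 side
    if svm.classes_[1] == -1:
        w, b = -w, -b
    if scale_min is None:
        scale_min = np.zeros(x.shape[1])
        scale_max = np.zeros(x.shape[1])
    return PatternModel(
        weights=w,
        offset=b,
        scale_min=scale_min,
        scale_max=scale_max,
        margin_param=C,
        training_meta=training_meta or {},
    )


def fit_pattern(
    images: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    training_meta: dict | None = None,
) -> PatternModel:
    """Convenience: fit the scaler on ``images`` then train the decoder."""
    mn, mx = fit_scaler(images)
    scaled = apply_scaler(images, mn, mx)
    return train_decoder(scaled, labels, C=C, scale_min=mn, scale_max=mx,
                         training_meta=training_meta)


def pattern_expression(
    model: PatternModel, image: np.ndarray, apply_scaling: bool = False
) -> float | np.ndarray:
    """Dot product of the weight map with an image (offset excluded).

    By default the raw image is used — the convention for applying a
    pattern to independent data whose units differ from the training
    set.  ``apply_scaling=True`` reproduces the within-paradigm feature
    space instead.
    """
    x = np.asarray(image, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.weights.size:
        raise ValueError(
            f"image length {x.shape[1]} != model voxel count {model.weights.size}"
        )
    if apply_scaling:
        x = model.scale(x)
    out = x @ model.weights
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    """Accuracy / significance / effect-size summary of one evaluation."""

    accuracy_2afc: float
    accuracy_single: float
    p_value: float
    cohens_d: float
    per_subject_correct: np.ndarray = field(default_factory=lambda: np.array([]))
    per_fold_accuracy: list = field(default_factory=list)
    per_repeat: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "accuracy_2afc": self.accuracy_2afc,
            "accuracy_single": self.accuracy_single,
            "p_value": self.p_value,
            "cohens_d": self.cohens_d,
        }


def _binom_p_greater(wins: int, n: int) -> float:
    """One-tailed (greater than chance) exact binomial p."""
    if n == 0:
        return 1.0
    return float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue)


def _paired_summary(
    diffs: np.ndarray, single_correct: np.ndarray, per_fold: list | None = None
) -> EvalResult:
    """Summarize per-subject expression differences (pain minus control)."""
    diffs = np.asarray(diffs, dtype=float)
    correct = np.where(diffs > 0, 1.0, np.where(diffs == 0, 0.5, 0.0))
    acc2 = float(correct.mean())
    wins = int((diffs > 0).sum())
    p = _binom_p_greater(wins, diffs.size)
    sd = diffs.std(ddof=1) if diffs.size > 1 else 0.0
    if sd > 0:
        d = float(diffs.mean() / sd)
    else:
        d = float(np.sign(diffs.mean()) * np.inf) if diffs.mean() != 0 else 0.0
    return EvalResult(
        accuracy_2afc=acc2,
        accuracy_single=float(np.mean(single_correct)) if len(single_correct) else np.nan,
        p_value=p,
        cohens_d=d,
        per_subject_correct=correct,
        per_fold_accuracy=per_fold or [],
    )


def forced_choice(
    model: PatternModel,
    pain_images: np.ndarray,
    control_images: np.ndarray,
    apply_scaling: bool = True,
) -> EvalResult:
    """Two-alternative forced choice over subject-aligned image pairs."""
    pain = np.atleast_2d(np.asarray(pain_images, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_images, dtype=float))
    if pain.shape != ctrl.shape:
        raise ValueError("pain and control image arrays must align")
    if pain.shape[0] < 1:
        raise ValueError("need at least one pair")
    expr_p = pattern_expression(model, pain, apply_scaling=apply_scaling)
    expr_c = pattern_expression(model, ctrl, apply_scaling=apply_scaling)
    diffs = np.atleast_1d(expr_p - expr_c)
    dv = model.decision_values(np.vstack([pain, ctrl]), apply_scaling=apply_scaling)
    labels = np.concatenate([np.ones(pain.shape[0]), -np.ones(ctrl.shape[0])])
    single = np.where(np.sign(dv) == labels, 1.0, np.where(dv == 0, 0.5, 0.0))
    return _paired_summary(diffs, single)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVScheme:
    """Subject-level fold assignment, repeated over random partitions.

    Folds partition subjects into ``n_folds`` groups whose sizes differ by
    at most one; both condition images of a subject always share a fold.
    """

    n_folds: int = 10
    n_repeats: int = 10
    seed: int | None = None

    def assignments(self, n_subjects: int) -> np.ndarray:
        """(n_repeats, n_subjects) array of fold ids."""
        if n_subjects < self.n_folds:
            raise ValueError(
                f"{n_subjects} subjects cannot fill {self.n_folds} folds"
            )
        rng = np.random.default_rng(self.seed)
        out = np.empty((self.n_repeats, n_subjects), dtype=int)
        for r in range(self.n_repeats):
            perm = rng.permutation(n_subjects)
            folds = np.array_split(perm, self.n_folds)
            for f, idx in enumerate(folds):
                out[r, idx] = f
        return out


def _cv_arrays(
    train_pain: np.ndarray,
    train_ctrl: np.ndarray,
    test_pain: np.ndarray,
    test_ctrl: np.ndarray,
    assignments: np.ndarray,
    C: float = 1.0,
    apply_scaling: bool = True,
) -> EvalResult:
    """Repeated CV over subject-aligned arrays.

    Within each repeat x fold, the decoder is trained on the training-
    modality pairs of the train-fold subjects and evaluated by forced
    choice on the test-modality pairs of the held-out subjects (same fold
    partition).  Per repeat, subject outcomes are pooled across folds;
    accuracies and p values are averaged across repeats.
    """
    n_subjects = train_pain.shape[0]
    n_repeats, n_folds = assignments.shape[0], assignments.max() + 1
    per_repeat: list[EvalResult] = []
    per_fold_acc: list[float] = []
    for r in range(n_repeats):
        fold_of = assignments[r]
        diffs = np.empty(n_subjects)
        single = np.empty(2 * n_subjects)
        for f in range(n_folds):
            test_idx = np.flatnonzero(fold_of == f)
            train_idx = np.flatnonzero(fold_of != f)
            x_train = np.vstack([train_pain[train_idx], train_ctrl[train_idx]])
            y_train = np.concatenate(
                [np.ones(train_idx.size), -np.ones(train_idx.size)]
            )
            model = fit_pattern(x_train, y_train, C=C)
            res = forced_choice(
                model,
                test_pain[test_idx],
                test_ctrl[test_idx],
                apply_scaling=apply_scaling,
            )
            expr_p = pattern_expression(
                model, test_pain[test_idx], apply_scaling=apply_scaling
            )
            expr_c = pattern_expression(
                model, test_ctrl[test_idx], apply_scaling=apply_scaling
            )
            diffs[test_idx] = np.atleast_1d(expr_p - expr_c)
            dv_p = model.decision_values(test_pain[test_idx], apply_scaling=apply_scaling)
            dv_c = model.decision_values(test_ctrl[test_idx], apply_scaling=apply_scaling)
            single[test_idx] = np.where(dv_p > 0, 1.0, np.where(dv_p == 0, 0.5, 0.0))
            single[n_subjects + test_idx] = np.where(
                dv_c < 0, 1.0, np.where(dv_c == 0, 0.5, 0.0)
            )
            per_fold_acc.append(res.accuracy_2afc)
        per_repeat.append(_paired_summary(diffs, single))
    agg = EvalResult(
        accuracy_2afc=float(np.mean([r.accuracy_2afc for r in per_repeat])),
        accuracy_single=float(np.mean([r.accuracy_single for r in per_repeat])),
        p_value=float(np.mean([r.p_value for r in per_repeat])),
        cohens_d=float(np.mean([r.cohens_d for r in per_repeat])),
        per_subject_correct=np.mean(
            [r.per_subject_correct for r in per_repeat], axis=0
        ),
        per_fold_accuracy=per_fold_acc,
        per_repeat=per_repeat,
    )
    return agg


def repeated_cv(
    dataset: SyntheticDataset,
    modality: str,
    scheme: CVScheme,
    C: float = 1.0,
    conditions: tuple[str, str] = ("pain", "control"),
) -> EvalResult:
    """Within-modality repeated k-fold cross-validated forced choice."""
    _, pain, ctrl = dataset.paired(modality, *conditions)
    assignments = scheme.assignments(pain.shape[0])
    return _cv_arrays(pain, ctrl, pain, ctrl, assignments, C=C)


def cross_modality_eval(
    dataset: SyntheticDataset,
    train_modality: str,
    test_modality: str,
    scheme: CVScheme,
    C: float = 1.0,
    conditions: tuple[str, str] = ("pain", "control"),
) -> EvalResult:
    """Between-modality cross-prediction under the shared fold partition.

    The decoder trained on ``train_modality`` pairs of the training-fold
    subjects is applied to the ``test_modality`` pairs of the held-out
    subjects.  With ``train_modality == test_modality`` this reduces
    exactly to :func:`repeated_cv`.
    """
    subjects_tr, pain_tr, ctrl_tr = dataset.paired(train_modality, *conditions)
    subjects_te, pain_te, ctrl_te = dataset.paired(test_modality, *conditions)
    if not np.array_equal(subjects_tr, subjects_te):
        raise ValueError("both modalities must be present for the same subjects")
    assignments = scheme.assignments(pain_tr.shape[0])
    return _cv_arrays(pain_tr, ctrl_tr, pain_te, ctrl_te, assignments, C=C)


def train_final(
    dataset: SyntheticDataset,
    modalities: tuple[str, ...] = ("NS", "FE"),
    conditions: tuple[str, str] = ("pain", "control"),
    C: float = 1.0,
) -> PatternModel:
    """Fit one decoder on the full sample (for transfer analyses only).

    Pooling both induction modalities trains the modality-general
    pattern; a single modality reproduces that modality's decoder.
    """
    imgs, labels = [], []
    for m in modalities:
        _, pain, ctrl = dataset.paired(m, *conditions)
        imgs.extend([pain, ctrl])
        labels.extend([np.ones(pain.shape[0]), -np.ones(ctrl.shape[0])])
    x = np.vstack(imgs)
    y = np.concatenate(labels)
    return fit_pattern(
        x, y, C=C, training_meta={"modalities": list(modalities), "final": True}
    )


def learning_curve(
    dataset: SyntheticDataset,
    train_sizes: list[int],
    eval_fn,
    n_draws: int = 5,
    seed: int | None = None,
    modalities: tuple[str, ...] = ("NS", "FE"),
    C: float = 1.0,
):
    """Score a final-style decoder as a function of training-set size.

    For each size, ``n_draws`` random subject subsets are drawn, a decoder
    is trained per subset and ``eval_fn(model) -> float`` is averaged.
    Returns a list of (size, mean score, scores).
    """
    subjects = dataset.subjects
    if max(train_sizes) > subjects.size:
        raise ValueError("train size exceeds available subjects")
    if min(train_sizes) < 2:
        raise ValueError("train sizes must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for size in train_sizes:
        scores = []
        for _ in range(n_draws):
            chosen = rng.choice(subjects, size=size, replace=False)
            sel = dataset.design["subject"].isin(chosen).to_numpy()
            sub = SyntheticDataset(
                grid=dataset.grid,
                images=dataset.images[sel],
                design=dataset.design.loc[sel].reset_index(drop=True),
                truth=dataset.truth,
            )
            model = train_final(sub, modalities=modalities, C=C)
            scores.append(float(eval_fn(model)))
        rows.append((int(size), float(np.mean(scores)), scores))
    return rows
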