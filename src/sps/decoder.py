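"""Linear-SVM pattern signatures and forced-choice evaluation.

A signature is the weight vector (plus intercept) of a soft-margin
linear SVM trained on raw contrast values, one condition set labelled
+1 against another labelled -1 (one-vs-all or pairwise). Its scalar
"pattern response" to an image is the dot product of the weights with
the voxel values. Classification performance is scored with the
forced-choice protocol: within each subject, the condition whose image
yields the larger response is predicted, and accuracy is the percent of
subjects called correctly. Repeated k-fold cross-validation partitions
*subjects* (never single images) into folds to avoid leakage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .stack import MaskedImageStack

__all__ = [
    "LinearPatternModel",
    "ForcedChoiceReport",
    "train_signature",
    "pattern_response",
    "forced_choice",
    "repeated_cv_evaluate",
    "apply_external_signature",
]


@dataclass
class LinearPatternModel:
    """Signature weight vector, intercept and label convention."""

    weights: np.ndarray
    intercept: float
    label_map: dict[str, int]
    C: float = 1.0
    training_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite signature weights")
        if len(self.label_map) < 2:
            raise ValueError("label_map must cover at least 2 conditions")

    @property
    def positive_conditions(self) -> list[str]:
        return [c for c, y in self.label_map.items() if y == +1]

    @property
    def negative_conditions(self) -> list[str]:
        return [c for c, y in self.label_map.items() if y == -1]


@dataclass
class ForcedChoiceReport:
    """Forced-choice performance summary.

    ``accuracy_mean``/``accuracy_sd`` are in percent across repetitions
    (a single-pass evaluation has one repetition and SD 0). ``p_value``
    is a two-sided exact binomial test against chance on the non-tied
    subjects; ``cohens_d`` is mean/SD of the paired response
    differences; ``auc`` pools the two conditions' responses.
    """

    accuracy_mean: float
    accuracy_sd: float
    per_repetition: np.ndarray
    p_value: float
    auc: float
    cohens_d: float
    n_subjects: int
    n_ties: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_mean <= 100.0:
            raise ValueError("accuracy must lie in [0, 100] percent")
        if self.accuracy_sd < 0:
            raise ValueError("accuracy SD must be non-negative")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def _training_rows(
    stack: MaskedImageStack, positive: list[str], negative: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    conds = stack.obs_meta["condition"].to_numpy()
    keep = np.isin(conds, positive + negative)
    y = np.where(np.isin(conds[keep], positive), 1, -1)
    return np.flatnonzero(keep), y


def train_signature(
    stack: MaskedImageStack,
    positive: list[str] | str,
    negative: list[str] | str,
    C: float = 1.0,
) -> LinearPatternModel:
    """Train a linear SVM signature on raw (unscaled) contrast values.

    ``positive`` conditions are labelled +1, ``negative`` -1. No
    feature standardization is applied: scaling would change the
    soft-margin solution, and the contract is training on raw contrast
    units with C as given. Deterministic given the data.
    """
    positive = [positive] if isinstance(positive, str) else list(positive)
    negative = [negative] if isinstance(negative, str) else list(negative)
    if not positive or not negative:
        raise ValueError("both condition sets must be non-empty")
    if set(positive) & set(negative):
        raise ValueError("positive and negative condition sets must be disjoint")
    required = positive + negative
    for subject in stack.subjects:
        have = set(stack.select(subject=subject).obs_meta["condition"])
        missing = [c for c in required if c not in have]
        if missing:
            raise ValueError(
                f"subject {subject!r} is missing condition(s) {missing}"
            )
    if len(stack.subjects) < 2:
        raise ValueError("need at least 2 subjects to train")
    rows, y = _training_rows(stack, positive, negative)
    svm = SVC(kernel="linear", C=C)
    svm.fit(stack.data[rows], y)
    return LinearPatternModel(
        weights=svm.coef_[0],
        intercept=float(svm.intercept_[0]),
        label_map={**{c: +1 for c in positive}, **{c: -1 for c in negative}},
        C=C,
        training_subjects=list(stack.subjects),
    )


def pattern_response(
    model: LinearPatternModel,
    stack: MaskedImageStack,
    use_intercept: bool = False,
) -> np.ndarray:
    """Per-observation scalar response w.x (+ b if ``use_intercept``)."""
    if model.weights.shape[0] != stack.n_voxels:
        raise ValueError(
            f"signature has {model.weights.shape[0]} voxels but the stack "
            f"has {stack.n_voxels}; resample the weight map first"
        )
    r = stack.data @ model.weights
    if use_intercept:
        r = r + model.intercept
    return r


def _paired_responses(
    model: LinearPatternModel,
    stack: MaskedImageStack,
    cond_a: str,
    cond_b: str,
    use_intercept: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject mean responses for the two conditions."""
    subjects = []
    ra, rb = [], []
    for subject in stack.subjects:
        sub = stack.select(subject=subject)
        a = sub.select(condition=cond_a)
        b = sub.select(condition=cond_b)
        if a.n_obs == 0 or b.n_obs == 0:
            missing = cond_a if a.n_obs == 0 else cond_b
            raise ValueError(f"subject {subject!r} lacks condition {missing!r}")
        ra.append(pattern_response(model, a, use_intercept).mean())
        rb.append(pattern_response(model, b, use_intercept).mean())
        subjects.append(subject)
    return np.asarray(subjects), np.array(ra), np.array(rb)


def _score_forced_choice(ra: np.ndarray, rb: np.ndarray) -> ForcedChoiceReport:
    diff = ra - rb
    ties = diff == 0
    correct = np.where(diff > 0, 1.0, 0.0)
    correct[ties] = 0.5
    acc = 100.0 * correct.mean()
    n_eff = int((~ties).sum())
    k = int((diff > 0).sum())
    p = binomtest(k, n_eff, 0.5).pvalue if n_eff > 0 else 1.0
    sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
    d = diff.mean() / sd if sd > 0 else (np.inf * np.sign(diff.mean()) if diff.mean() else 0.0)
    labels = np.r_[np.ones(len(ra)), np.zeros(len(rb))]
    scores = np.r_[ra, rb]
    auc = 0.5 if len(np.unique(scores)) == 1 else float(roc_auc_score(labels, scores))
    return ForcedChoiceReport(
        accuracy_mean=acc,
        accuracy_sd=0.0,
        per_repetition=np.array([acc]),
        p_value=float(p),
        auc=auc,
        cohens_d=float(d),
        n_subjects=len(ra),
        n_ties=int(ties.sum()),
    )


def forced_choice(
    model: LinearPatternModel,
    stack: MaskedImageStack,
    cond_a: str,
    cond_b: str,
    use_intercept: bool = False,
) -> ForcedChoiceReport:
    """Two-alternative forced choice: predict the image with the larger
    pattern response as ``cond_a``, score percent of subjects correct.

    Exact ties are credited 0.5 and excluded from the binomial test
    (unbiased under the null). The intercept cancels in the
    within-subject comparison and is off by default.
    """
    subjects, ra, rb = _paired_responses(model, stack, cond_a, cond_b, use_intercept)
    if len(subjects) < 5:
        warnings.warn(
            f"forced choice on only {len(subjects)} subjects; estimates are unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return _score_forced_choice(ra, rb)


def repeated_cv_evaluate(
    stack: MaskedImageStack,
    positive: list[str] | str,
    negative: list[str] | str,
    pairs: list[tuple[str, str]] | None = None,
    C: float = 1.0,
    k: int = 10,
    n_repeats: int = 50,
    seed: int = 0,
    use_intercept: bool = False,
) -> dict[tuple[str, str], ForcedChoiceReport]:
    """Repeated k-fold cross-validated forced choice, per contrast pair.

    Folds partition subjects; all of a subject's images share a fold.
    Per repetition the full k-fold round is run with a fresh random
    partition, the signature retrained on k-1 folds and forced choice
    scored on the held-out subjects; the report carries the mean and SD
    of accuracy across repetitions. The reference protocol is k=10 with
    1000 repetitions; the desk-scale default is 50.
    """
    positive = [positive] if isinstance(positive, str) else list(positive)
    negative = [negative] if isinstance(negative, str) else list(negative)
    if pairs is None:
        pairs = [(p, n) for p in positive for n in negative]
    subjects = np.asarray(stack.subjects)
    n_subj = len(subjects)
    if k > n_subj:
        raise ValueError(f"k={k} folds exceed the {n_subj} subjects")
    rng = np.random.default_rng(seed)
    # correct[pair][rep, subject], diffs[pair][rep, subject]
    correct = {pair: np.zeros((n_repeats, n_subj)) for pair in pairs}
    diffs = {pair: np.zeros((n_repeats, n_subj)) for pair in pairs}
    resp_a = {pair: np.zeros((n_repeats, n_subj)) for pair in pairs}
    resp_b = {pair: np.zeros((n_repeats, n_subj)) for pair in pairs}
    for rep in range(n_repeats):
        order = rng.permutation(n_subj)
        folds = np.array_split(order, k)
        for fold in folds:
            test_subjects = subjects[fold]
            train_subjects = subjects[~np.isin(subjects, test_subjects)]
            model = train_signature(
                stack.select(subject=list(train_subjects)), positive, negative, C=C
            )
            held = stack.select(subject=list(test_subjects))
            for pair in pairs:
                held_subj, ra, rb = _paired_responses(model, held, *pair, use_intercept)
                pos = np.array(
                    [int(np.flatnonzero(subjects == s)[0]) for s in held_subj]
                )
                d = ra - rb
                c = np.where(d > 0, 1.0, 0.0)
                c[d == 0] = 0.5
                correct[pair][rep, pos] = c
                diffs[pair][rep, pos] = d
                resp_a[pair][rep, pos] = ra
                resp_b[pair][rep, pos] = rb
    reports = {}
    for pair in pairs:
        per_rep = 100.0 * correct[pair].mean(axis=1)
        subj_mean_correct = correct[pair].mean(axis=0)
        non_tied = subj_mean_correct != 0.5
        kk = int((subj_mean_correct > 0.5).sum())
        p = binomtest(kk, int(non_tied.sum()), 0.5).pvalue if non_tied.any() else 1.0
        mean_diff = diffs[pair].mean(axis=0)
        sd = mean_diff.std(ddof=1)
        d = mean_diff.mean() / sd if sd > 0 else 0.0
        labels = np.r_[np.ones(n_subj), np.zeros(n_subj)]
        scores = np.r_[resp_a[pair].mean(axis=0), resp_b[pair].mean(axis=0)]
        auc = 0.5 if len(np.unique(scores)) == 1 else float(roc_auc_score(labels, scores))
        reports[pair] = ForcedChoiceReport(
            accuracy_mean=float(per_rep.mean()),
            accuracy_sd=float(per_rep.std(ddof=1)) if n_repeats > 1 else 0.0,
            per_repetition=per_rep,
            p_value=float(p),
            auc=auc,
            cohens_d=float(d),
            n_subjects=n_subj,
            n_ties=int((~non_tied).sum()),
        )
    return reports


def apply_external_signature(
    weights: np.ndarray,
    stack: MaskedImageStack,
    pairs: list[tuple[str, str]],
    intercept: float = 0.0,
) -> dict[tuple[str, str], ForcedChoiceReport]:
    """Forced choice with a fixed, externally supplied weight map.

    Identical contract to :func:`forced_choice`, with no retraining.
    The weight vector must already be aligned to the stack's voxel
    space (see ``cli_io.resample_weights``).
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape[0] != stack.n_voxels:
        raise ValueError(
            f"external weights have {weights.shape[0]} voxels, stack has {stack.n_voxels}"
        )
    if not np.any(weights != 0):
        raise ValueError("external weight map has no support inside the mask")
    conds = sorted({c for pair in pairs for c in pair})
    model = LinearPatternModel(
        weights=weights,
        intercept=intercept,
        label_map={conds[0]: +1, **{c: -1 for c in conds[1:]}},
    )
    return {pair: forced_choice(model, stack, *pair) for pair in pairs}
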