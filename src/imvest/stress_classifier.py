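"""Leave-one-out PLS1 discriminant stress scoring.

A partial-least-squares regression with a single 0/1 response (0 = control,
1 = stress) is fitted on per-block rows of the 50-column feature table.  For
every participant, a model is trained on the test blocks (T1, T3, T4 by
default) of all *other* participants; the model's inner leave-one-out
cross-validated predictions yield an ROC curve and a Youden-optimal decision
threshold; the held-out participant's four test blocks are then scored and
the number of blocks called "stress" (0-4) is that participant's
physiological stress count.  Significance of a cohort-level model is assessed
by a participant-level label-permutation test on cross-validated AUC.

PLS1 is implemented directly (NIPALS-style deflation; for a univariate
response each component is a closed-form power step, no iteration needed) and
is checked against ordinary least squares and scikit-learn in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StressModel",
    "StressScore",
    "fit_pls1",
    "select_components",
    "loo_cv_predictions",
    "loo_stress_scores",
    "roc_auc",
    "youden_threshold",
    "permutation_auc_test",
    "average_model_coefficients",
    "TRAIN_BLOCKS",
    "SCORE_BLOCKS",
]

TRAIN_BLOCKS = ("T1", "T3", "T4")  # T2 is excluded from training by default
SCORE_BLOCKS = ("T1", "T2", "T3", "T4")


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------


@dataclass
class StressModel:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # features x components
    loadings: np.ndarray  # features x components
    scores: np.ndarray  # samples x components (training)
    coef: np.ndarray  # standardized-space regression coefficients
    n_components: int
    feature_names: list[str] = field(default_factory=list)
    kept: np.ndarray | None = None  # mask of non-constant features
    threshold: float = float("nan")
    training_ids: list[str] = field(default_factory=list)
    cv_auc: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kept is not None:
            X = X[:, self.kept]
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coef + self.y_mean


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: list[str] | None = None,
) -> StressModel:
    """PLS regression with one response by NIPALS deflation.

    X columns are z-scored (training statistics); y is centered.  Each
    component's weight vector is the (normalized) covariance X'y of the
    deflated X with the residual response, the canonical direction of maximal
    covariance between a unit-norm X-projection and y.  Constant columns are
    dropped with a warning.  Predictions are a linear score in the original
    feature space plus intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y have mismatched sample counts")
    sd = X.std(axis=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"{int((~kept).sum())} zero-variance feature(s) dropped")
    Xk = X[:, kept]
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
    kept_names = [nm for nm, k in zip(names, kept) if k]
    pk = Xk.shape[1]
    n_components = int(n_components)
    if n_components < 1 or n_components > pk:
        raise ValueError("n_components must be in 1..n_features")
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")

    x_mean = Xk.mean(axis=0)
    x_scale = Xk.std(axis=0)
    Xs = (Xk - x_mean) / x_scale
    y_mean = float(y.mean())
    f = y - y_mean

    E = Xs.copy()
    W = np.zeros((pk, n_components))
    P = np.zeros((pk, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if not np.isfinite(nw) or nw == 0:
            raise RuntimeError(f"PLS component {a + 1} failed to converge (zero covariance)")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            raise RuntimeError(f"PLS component {a + 1} failed to converge (zero scores)")
        pvec = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa

    coef = W @ np.linalg.solve(P.T @ W, q)
    return StressModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        scores=T,
        coef=coef,
        n_components=n_components,
        feature_names=kept_names,
        kept=kept,
    )


def loo_cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out cross-validated predictions of a PLS1 model.

    With ``groups`` given, whole groups (all blocks of one participant) are
    left out together, so sibling rows of the held-out unit never inform its
    prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    preds = np.empty(n)
    for g in np.unique(groups):
        m = groups != g
        model = fit_pls1(X[m], y[m], n_components)
        preds[~m] = model.predict(X[~m])
    return preds


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[int] | None = None,
    groups: np.ndarray | None = None,
) -> tuple[int, dict[int, np.ndarray]]:
    """Component count minimizing LOO-CV squared error; ties to the smaller.

    Also returns the CV prediction vectors per grid value so callers can
    reuse them (e.g., for ROC thresholding) without refitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_c = min(10, int(np.linalg.matrix_rank(X - X.mean(axis=0))), X.shape[1])
    if grid is None:
        grid = list(range(1, max(2, max_c + 1)))
    grid = sorted(set(int(g) for g in grid))
    preds: dict[int, np.ndarray] = {}
    best_g, best_err = None, np.inf
    for g in grid:
        try:
            p = loo_cv_predictions(X, y, g, groups=groups)
        except (RuntimeError, ValueError):
            continue
        preds[g] = p
        err = float(np.sum((p - y) ** 2))
        if err < best_err - 1e-12:
            best_err, best_g = err, g
    if best_g is None:
        raise RuntimeError("no component count produced a valid CV fit")
    return best_g, preds


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep over unique scores, AUC by trapezoid.

    The trapezoidal AUC equals the Mann-Whitney rank statistic
    P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        call = scores >= thr
        tpr = float((call & (labels == 1)).sum()) / n_pos
        fpr = float((call & (labels == 0)).sum()) / n_neg
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    roc = np.array(sorted(set(pts)))
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold (among unique scores) maximizing J = TPR - FPR; ties -> lowest.

    The classification rule is ``score >= threshold``.  If every score is
    identical, J = 0 everywhere and that score is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden threshold requires both classes present")
    cands = np.unique(scores)
    if len(cands) == 1:
        warnings.warn("all scores identical; Youden J is 0 everywhere")
        return float(cands[0])
    best_thr, best_j = None, -np.inf
    for thr in cands:  # ascending: the lowest maximizer wins
        call = scores >= thr
        j = (call & (labels == 1)).sum() / n_pos - (call & (labels == 0)).sum() / n_neg
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return best_thr


# ---------------------------------------------------------------------------
# LOO stress scoring
# ---------------------------------------------------------------------------


@dataclass
class StressScore:
    participant_id: str
    block_scores: dict  # block -> float
    block_calls: dict  # block -> bool
    stress_count: int
    threshold: float
    cv_auc: float
    n_components: int


def _analysis_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    meta = {"participant_id", "group", "block"}
    variables = [c for c in features.columns if c not in meta]
    return features, variables


def loo_stress_scores(
    features: pd.DataFrame,
    train_blocks: tuple[str, ...] = TRAIN_BLOCKS,
    score_blocks: tuple[str, ...] = SCORE_BLOCKS,
    n_components: int | None = None,
    component_grid: list[int] | None = None,
    stress_label: str = "stress",
) -> tuple[list[StressScore], list[StressModel]]:
    """Per-participant LOO stress counts and the individual PLS models.

    For each participant i, a PLS1 model is trained on the ``train_blocks``
    rows of all other participants (one labeled sample per block).  The
    component count is chosen by inner participant-grouped LOO CV (unless
    fixed; sibling blocks of a held-out participant leave together, so the
    inner CV cannot memorize participant identity), the Youden
    threshold comes from the same inner-CV predictions, and i's
    ``score_blocks`` are then scored; blocks at or above the threshold count
    as stress responses.  Participant i's own rows never enter training.
    """
    features, variables = _analysis_matrix(features)
    ids = list(features["participant_id"].unique())
    groups = features.drop_duplicates("participant_id").set_index("participant_id")["group"]
    if (groups == stress_label).sum() < 2 or (groups != stress_label).sum() < 2:
        raise ValueError("need >= 2 participants per group")

    train_rows = features[features["block"].isin(train_blocks)]
    results: list[StressScore] = []
    models: list[StressModel] = []
    for pid in ids:
        tr = train_rows[train_rows["participant_id"] != pid]
        X = tr[variables].to_numpy(float)
        y = (tr["group"] == stress_label).to_numpy(float)
        # impute remaining NaNs with training-column means
        col_mean = np.nanmean(X, axis=0)
        nan_mask = ~np.isfinite(X)
        if nan_mask.any():
            X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        grp = tr["participant_id"].to_numpy()
        if n_components is None:
            g, cv_preds = select_components(X, y, component_grid, groups=grp)
            preds = cv_preds[g]
        else:
            g = int(n_components)
            preds = loo_cv_predictions(X, y, g, groups=grp)
        _, auc = roc_auc(preds, y.astype(int))
        thr = youden_threshold(preds, y.astype(int))
        model = fit_pls1(X, y, g, feature_names=variables)
        model.threshold = thr
        model.cv_auc = auc
        model.training_ids = [p for p in ids if p != pid]
        models.append(model)

        own = features[(features["participant_id"] == pid) & (features["block"].isin(score_blocks))]
        block_scores, block_calls = {}, {}
        for block in score_blocks:
            row = own[own["block"] == block]
            if len(row) == 0:
                continue
            xs = row[variables].to_numpy(float)
            miss = ~np.isfinite(xs)
            if miss.any():
                xs[miss] = np.take(col_mean, np.nonzero(miss)[1])
            s = float(model.predict(xs)[0])
            block_scores[block] = s
            block_calls[block] = bool(s >= thr)
        results.append(
            StressScore(
                participant_id=pid,
                block_scores=block_scores,
                block_calls=block_calls,
                stress_count=int(sum(block_calls.values())),
                threshold=thr,
                cv_auc=auc,
                n_components=g,
            )
        )
    return results, models


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


def _grouped_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_components: int,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Participant-grouped K-fold CV AUC of a PLS1 model."""
    rng = rng or np.random.default_rng(0)
    uids = np.unique(groups)
    perm = rng.permutation(len(uids))
    folds = np.array_split(perm, n_folds)
    preds = np.empty(len(y))
    for fold in folds:
        test_ids = set(uids[fold])
        test_m = np.array([g in test_ids for g in groups])
        if test_m.all() or not test_m.any():
            continue
        try:
            model = fit_pls1(X[~test_m], y[~test_m], n_components)
            preds[test_m] = model.predict(X[test_m])
        except RuntimeError:  # degenerate fold (e.g. one-class training labels)
            preds[test_m] = float(y[~test_m].mean())
    _, auc = roc_auc(preds, y.astype(int))
    return auc


def permutation_auc_test(
    features: pd.DataFrame,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    n_components: int = 3,
    train_blocks: tuple[str, ...] = TRAIN_BLOCKS,
    stress_label: str = "stress",
    n_folds: int = 5,
) -> tuple[float, float, np.ndarray]:
    """Participant-level label permutation test of the cohort model's CV AUC.

    Labels are shuffled at the participant level (every block of a participant
    keeps one label), the grouped-CV AUC is recomputed per shuffle, and
    p = (1 + #{null AUC >= observed}) / (n_perm + 1).

    Returns (p_value, observed AUC, null AUC distribution).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    features, variables = _analysis_matrix(features)
    tr = features[features["block"].isin(train_blocks)]
    X = tr[variables].to_numpy(float)
    col_mean = np.nanmean(X, axis=0)
    miss = ~np.isfinite(X)
    if miss.any():
        X[miss] = np.take(col_mean, np.nonzero(miss)[1])
    pid = tr["participant_id"].to_numpy()
    uids, inverse = np.unique(pid, return_inverse=True)
    labels_by_pid = (
        tr.drop_duplicates("participant_id").set_index("participant_id")["group"] == stress_label
    ).astype(float)
    base = labels_by_pid.loc[uids].to_numpy()

    fold_rng = np.random.default_rng(rng.integers(2**31))
    observed = _grouped_cv_auc(X, base[inverse], pid, n_components, n_folds,
                               np.random.default_rng(fold_rng.integers(2**31)))
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = base[rng.permutation(len(base))]
        null[k] = _grouped_cv_auc(X, shuffled[inverse], pid, n_components, n_folds,
                                  np.random.default_rng(fold_rng.integers(2**31)))
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return p, observed, null


def average_model_coefficients(models: list[StressModel]) -> pd.Series:
    """Element-wise mean of the standardized-space coefficients across models.

    Positive values push a block's score toward the stress label.
    """
    if not models:
        raise ValueError("no models supplied")
    names = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != names:
            raise ValueError("models have mismatched feature sets")
    coefs = np.vstack([m.coef for m in models])
    return pd.Series(coefs.mean(axis=0), index=names)
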