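"""Connectome-based predictive modeling (CPM) of a behavioral score.

Within each training set, every edge of the individualized SCN is
correlated with the score; edges significant at ``p < threshold_p`` are
split by correlation sign into a positive and a negative network. Each
subject's network strength is the sum of their edge values over a mask, and
an ordinary-least-squares model (intercept + strength, or intercept + both
strengths in combined mode) maps strength to score. Prediction uses
leave-one-out cross-validation; significance comes from permuting the score
and rerunning the whole procedure.

Selection inside :func:`run_cpm_loocv` happens independently in every fold,
on training subjects only, so the held-out subject never influences the
edges or coefficients used to predict it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from scn_cpm.scn_builder import EdgeIndex, IndividualSCN

logger = logging.getLogger(__name__)

MODES = ("positive", "negative", "combined")
COMBINED_FORMS = ("two_predictor", "difference")

#: relative rank-deficiency cutoff in the per-fold OLS fit
_RCOND = 1e-10


@dataclass(frozen=True)
class SignedEdgeMasks:
    """Boolean positive/negative edge selections at a p threshold."""

    positive: np.ndarray
    negative: np.ndarray
    threshold_p: float = np.nan

    def __post_init__(self) -> None:
        pos = np.asarray(self.positive, dtype=bool)
        neg = np.asarray(self.negative, dtype=bool)
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        if pos.shape != neg.shape:
            raise ValueError("positive and negative masks must have equal length")
        if (pos & neg).any():
            raise ValueError("an edge cannot be in both the positive and negative mask")
        if not np.isnan(self.threshold_p) and not 0.0 < self.threshold_p < 1.0:
            raise ValueError("threshold_p must lie in (0, 1)")

    @property
    def n_edges(self) -> int:
        return self.positive.size


@dataclass
class CPMResult:
    """Everything a CPM run produces.

    ``fold_positive``/``fold_negative`` are folds x edges boolean matrices
    of per-fold selections; ``consensus`` holds edges selected in every
    fold; ``full_sample`` the (secondary) selection on all subjects at once.
    ``performance_r`` is the Pearson correlation between LOOCV-predicted and
    true scores, ``null_r`` the permutation null distribution and ``p_perm``
    its p-value (``None`` until a permutation test is attached).
    """

    predicted: np.ndarray
    fold_positive: np.ndarray
    fold_negative: np.ndarray
    consensus: SignedEdgeMasks
    full_sample: SignedEdgeMasks
    performance_r: float
    mode: str
    threshold_p: float
    edge_index: "EdgeIndex"
    null_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_perm: float | None = None
    seed: int | None = None

    @property
    def fold_masks(self) -> list[SignedEdgeMasks]:
        return [
            SignedEdgeMasks(p, n, self.threshold_p)
            for p, n in zip(self.fold_positive, self.fold_negative)
        ]


# ---------------------------------------------------------------------------
# elementary operations


def edge_score_correlation(edges: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson r with the score, and two-tailed t-based p-values.

    p is computed from ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2
    degrees of freedom. Edges with zero variance get r = 0, p = 1 (with a
    logged warning); a constant score is an error.
    """
    edges = np.asarray(edges, dtype=float)
    score = np.asarray(score, dtype=float)
    n = score.size
    if n < 4:
        raise ValueError("at least 4 subjects are required")
    if edges.shape[0] != n:
        raise ValueError("edges and score disagree on subject count")
    sc = score - score.mean()
    var_s = sc @ sc
    if var_s == 0.0:
        raise ValueError("score is constant; correlations are undefined")

    xc = edges - edges.mean(axis=0)
    cov = xc.T @ sc
    var_e = np.einsum("ij,ij->j", xc, xc)
    zero = var_e == 0.0
    if zero.any():
        logger.warning("%d edge(s) have zero variance; reporting r=0, p=1", int(zero.sum()))
    denom = np.sqrt(var_e * var_s)
    r = np.zeros_like(cov)
    np.divide(cov, denom, out=r, where=~zero)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    p = np.where(zero, 1.0, p)
    return r, p


def select_edges(r: np.ndarray, p: np.ndarray, threshold_p: float = 0.01) -> SignedEdgeMasks:
    """Split significant edges (strict ``p < threshold_p``) by sign of r."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p must have equal length")
    if not 0.0 < threshold_p < 1.0:
        raise ValueError("threshold_p must lie in (0, 1)")
    sig = p < threshold_p
    return SignedEdgeMasks(positive=sig & (r > 0), negative=sig & (r < 0), threshold_p=threshold_p)


def network_strength(edge_row: np.ndarray, mask: np.ndarray) -> float:
    """Sum of a subject's edge values over a mask (0 for an empty mask)."""
    edge_row = np.asarray(edge_row, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if edge_row.shape != mask.shape:
        raise ValueError("edge_row and mask must have equal length")
    return float(edge_row[mask].sum())


# ---------------------------------------------------------------------------
# model fitting


def _ols_predict(preds_train: list[np.ndarray], y_train: np.ndarray, preds_test: list[float]) -> float:
    """OLS fit on training strengths, applied to the test strengths.

    Falls back to the training-score mean when no predictors remain or the
    design is (numerically) rank deficient, e.g. a constant strength.
    """
    if not preds_train:
        return float(y_train.mean())
    X = np.column_stack([np.ones_like(y_train), *preds_train])
    coef, _, rank, _ = np.linalg.lstsq(X, y_train, rcond=_RCOND)
    if rank < X.shape[1] or not np.all(np.isfinite(coef)):
        logger.warning("singular design in fold fit; falling back to training mean")
        return float(y_train.mean())
    return float(coef[0] + np.dot(coef[1:], preds_test))


def _assemble_predictors(
    mode: str,
    combined_form: str,
    pos_train: np.ndarray,
    neg_train: np.ndarray,
    pos_test: float,
    neg_test: float,
    pos_any: bool,
    neg_any: bool,
) -> tuple[list[np.ndarray], list[float]]:
    """Predictor columns for a fold, dropping strengths of empty masks."""
    train: list[np.ndarray] = []
    test: list[float] = []
    if mode == "positive":
        if pos_any:
            train, test = [pos_train], [pos_test]
    elif mode == "negative":
        if neg_any:
            train, test = [neg_train], [neg_test]
    elif mode == "combined":
        if combined_form == "two_predictor":
            if pos_any:
                train.append(pos_train)
                test.append(pos_test)
            if neg_any:
                train.append(neg_train)
                test.append(neg_test)
        else:  # difference score
            if pos_any or neg_any:
                train, test = [pos_train - neg_train], [pos_test - neg_test]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return train, test


def fit_predict_fold(
    train_edges: np.ndarray,
    train_score: np.ndarray,
    test_edge_row: np.ndarray,
    threshold_p: float = 0.01,
    mode: str = "combined",
    combined_form: str = "two_predictor",
) -> float:
    """Train on one fold's training set and predict the held-out subject.

    Edge selection, strength computation and the OLS fit use the training
    subjects only. When no edges pass the threshold (or the design is
    singular) the prediction is the training-score mean.
    """
    _check_mode(mode, combined_form)
    train_edges = np.asarray(train_edges, dtype=float)
    train_score = np.asarray(train_score, dtype=float)
    test_edge_row = np.asarray(test_edge_row, dtype=float)
    if train_edges.shape[0] < 4:
        raise ValueError("at least 4 training subjects are required")

    r, p = edge_score_correlation(train_edges, train_score)
    masks = select_edges(r, p, threshold_p)
    posf = masks.positive.astype(float)
    negf = masks.negative.astype(float)
    preds_train, preds_test = _assemble_predictors(
        mode,
        combined_form,
        train_edges @ posf,
        train_edges @ negf,
        network_strength(test_edge_row, masks.positive),
        network_strength(test_edge_row, masks.negative),
        bool(masks.positive.any()),
        bool(masks.negative.any()),
    )
    if not preds_train:
        logger.warning("no edges selected in fold; predicting the training mean")
    return _ols_predict(preds_train, train_score, preds_test)


def _check_mode(mode: str, combined_form: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if combined_form not in COMBINED_FORMS:
        raise ValueError(f"combined_form must be one of {COMBINED_FORMS}, got {combined_form!r}")


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


def _fold_edge_correlations(theta: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Training-set edge-score correlations for every LOOCV fold at once.

    Row i holds Pearson correlations over the n-1 subjects excluding i,
    obtained by downdating full-sample sums (inputs are centered first for
    numerical accuracy). Edges with a degenerate training variance get 0.
    """
    theta = theta - theta.mean(axis=0)
    score = score - score.mean()
    n = score.size
    m = n - 1

    Se = theta.sum(axis=0)
    See = np.einsum("ij,ij->j", theta, theta)
    Ses = theta.T @ score
    ss = score.sum()
    sss = score @ score

    Se_i = Se[None, :] - theta
    See_i = See[None, :] - theta * theta
    Ses_i = Ses[None, :] - theta * score[:, None]
    ss_i = ss - score
    sss_i = sss - score * score

    cov = m * Ses_i - Se_i * ss_i[:, None]
    var_e = np.maximum(m * See_i - Se_i * Se_i, 0.0)
    var_s = np.maximum(m * sss_i - ss_i * ss_i, 0.0)[:, None]
    denom = np.sqrt(var_e * var_s)
    r = np.zeros_like(cov)
    np.divide(cov, denom, out=r, where=denom > 0.0)
    return np.clip(r, -1.0, 1.0)


def _critical_r(n_train: int, threshold_p: float) -> float:
    """|r| above which the two-tailed t-based p falls strictly below threshold."""
    df = n_train - 2
    if df < 1:
        raise ValueError("training sets must have at least 3 subjects")
    t_crit = stats.t.isf(threshold_p / 2.0, df)
    return t_crit / np.sqrt(df + t_crit * t_crit)


def _loocv(
    theta: np.ndarray,
    score: np.ndarray,
    threshold_p: float,
    mode: str,
    combined_form: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized LOOCV; returns (predicted, fold_positive, fold_negative)."""
    n, _ = theta.shape
    r_fold = _fold_edge_correlations(theta, score)
    r_crit = _critical_r(n - 1, threshold_p)
    fold_pos = r_fold > r_crit
    fold_neg = r_fold < -r_crit

    need_pos = mode in ("positive", "combined")
    need_neg = mode in ("negative", "combined")
    # strengths of every subject under every fold's mask: (subjects x folds)
    Sp = theta @ fold_pos.T.astype(float) if need_pos else None
    Sn = theta @ fold_neg.T.astype(float) if need_neg else None
    pos_any = fold_pos.any(axis=1)
    neg_any = fold_neg.any(axis=1)

    predicted = np.empty(n, dtype=float)
    tr = np.ones(n, dtype=bool)
    zeros = np.zeros(n - 1)
    for f in range(n):
        tr[f] = False
        y_train = score[tr]
        p_col = Sp[:, f] if need_pos else None
        n_col = Sn[:, f] if need_neg else None
        preds_train, preds_test = _assemble_predictors(
            mode,
            combined_form,
            p_col[tr] if p_col is not None else zeros,
            n_col[tr] if n_col is not None else zeros,
            float(p_col[f]) if p_col is not None else 0.0,
            float(n_col[f]) if n_col is not None else 0.0,
            bool(pos_any[f]),
            bool(neg_any[f]),
        )
        predicted[f] = _ols_predict(preds_train, y_train, preds_test)
        tr[f] = True
    return predicted, fold_pos, fold_neg


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))


def run_cpm_loocv(
    iscn: "IndividualSCN",
    score: np.ndarray,
    threshold_p: float = 0.01,
    mode: str = "combined",
    combined_form: str = "two_predictor",
) -> CPMResult:
    """Leave-one-out CPM on an individualized SCN.

    Each subject is predicted by a model whose edge selection and
    coefficients come from the remaining n-1 subjects. ``performance_r`` is
    the Pearson correlation between predicted and true scores (NaN, with a
    warning, if the predictions are constant). ``consensus`` holds the edges
    selected in every fold; ``full_sample`` the selection computed once on
    all subjects, reported as a secondary output.
    """
    _check_mode(mode, combined_form)
    if not 0.0 < threshold_p < 1.0:
        raise ValueError("threshold_p must lie in (0, 1)")
    theta = np.asarray(iscn.pseudovalues, dtype=float)
    score = np.asarray(score, dtype=float)
    n = score.size
    if theta.shape[0] != n:
        raise ValueError("iscn and score disagree on subject count")
    if n < 5:
        raise ValueError("at least 5 subjects are required for LOOCV")

    predicted, fold_pos, fold_neg = _loocv(theta, score, threshold_p, mode, combined_form)
    performance_r = _pearson_or_nan(predicted, score)
    if np.isnan(performance_r):
        logger.warning("LOOCV predictions are constant; performance r is undefined (NaN)")

    consensus = SignedEdgeMasks(
        positive=fold_pos.all(axis=0), negative=fold_neg.all(axis=0), threshold_p=threshold_p
    )
    r_all, p_all = edge_score_correlation(theta, score)
    full_sample = select_edges(r_all, p_all, threshold_p)
    return CPMResult(
        predicted=predicted,
        fold_positive=fold_pos,
        fold_negative=fold_neg,
        consensus=consensus,
        full_sample=full_sample,
        performance_r=performance_r,
        mode=mode,
        threshold_p=threshold_p,
        edge_index=iscn.edge_index,
    )


def permutation_test(
    iscn: "IndividualSCN",
    score: np.ndarray,
    threshold_p: float = 0.01,
    mode: str = "combined",
    n_perm: int = 5000,
    seed: int = 0,
    combined_form: str = "two_predictor",
    add_one: bool = True,
    true_r: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation null for the LOOCV performance correlation.

    Each permutation shuffles the score relative to subjects and reruns the
    full LOOCV (selection inside every fold); the run's performance r enters
    the null distribution (NaN runs are recorded as ``-inf``). With
    ``add_one`` (default) the p-value is ``(1 + #{null >= true}) /
    (1 + n_perm)``, which is bounded away from 0; ``add_one=False`` gives
    the raw proportion.
    """
    _check_mode(mode, combined_form)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    theta = np.asarray(iscn.pseudovalues, dtype=float)
    score = np.asarray(score, dtype=float)
    if true_r is None:
        predicted, _, _ = _loocv(theta, score, threshold_p, mode, combined_form)
        true_r = _pearson_or_nan(predicted, score)

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm, dtype=float)
    for k in range(n_perm):
        s_perm = rng.permutation(score)
        pred, _, _ = _loocv(theta, s_perm, threshold_p, mode, combined_form)
        r = _pearson_or_nan(pred, s_perm)
        null_r[k] = -np.inf if np.isnan(r) else r

    if np.isnan(true_r):
        return 1.0, null_r
    k_ge = int((null_r >= true_r).sum())
    p = (1.0 + k_ge) / (1.0 + n_perm) if add_one else k_ge / n_perm
    return float(p), null_r


def run_cpm(
    iscn: "IndividualSCN",
    score: np.ndarray,
    threshold_p: float = 0.01,
    mode: str = "combined",
    combined_form: str = "two_predictor",
    n_perm: int = 5000,
    seed: int = 0,
    add_one: bool = True,
) -> CPMResult:
    """LOOCV CPM plus permutation test, returning a complete result."""
    result = run_cpm_loocv(iscn, score, threshold_p, mode, combined_form)
    if n_perm > 0:
        p, null_r = permutation_test(
            iscn,
            score,
            threshold_p,
            mode,
            n_perm,
            seed,
            combined_form,
            add_one,
            true_r=result.performance_r,
        )
        result.p_perm = p
        result.null_r = null_r
    result.seed = seed
    return result


def confound_sensitivity(
    result: CPMResult, covariates: Mapping[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Correlate predicted scores with each nuisance covariate.

    Returns ``{name: (r, p)}`` with two-tailed t-based p-values. A constant
    covariate (or constant predictions) yields ``(nan, nan)`` with a
    warning. Non-significant correlations indicate the prediction is not
    driven by that confound.
    """
    predicted = np.asarray(result.predicted, dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for name, vec in covariates.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != predicted.shape:
            raise ValueError(f"covariate {name!r} length must equal the subject count")
        r = _pearson_or_nan(predicted, vec)
        if np.isnan(r):
            logger.warning("covariate %r or predictions constant; r undefined", name)
            out[name] = (float("nan"), float("nan"))
            continue
        df = predicted.size - 2
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), df))
        out[name] = (r, p)
    return out
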