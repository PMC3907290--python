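"""Exon regulation model: PSI-based labelling, three-class multinomial logistic
regression, LOOCV/ROC, threshold calls and binned-response validation.

The baseline class is always ``non_regulated``: each regulated class c has a
logit g_c(x) = beta0 + sum_i beta_i x_i = log(p_c / p_non_regulated), and

    p_repressed     = exp(g_R) / (1 + exp(g_R) + exp(g_E))
    p_enhanced      = exp(g_E) / (1 + exp(g_R) + exp(g_E))
    p_non_regulated = 1       / (1 + exp(g_R) + exp(g_E))

Enhanced-class predictions are reported but are known to be less reliable than
repression calls and should be treated with caution.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from splicebind.errors import DegenerateInputError

logger = logging.getLogger(__name__)

CLASS_ORDER = ("non_regulated", "repressed", "enhanced")  # baseline first
REPRESS_THRESHOLD = 0.65
NEGATIVE_THRESHOLD = 0.20


@dataclass(frozen=True)
class PsiMeasurement:
    exon_id: str
    psi_control: float
    psi_knockdown: float

    def __post_init__(self):
        for name, v in (("psi_control", self.psi_control), ("psi_knockdown", self.psi_knockdown)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.exon_id}: {name}={v} outside [0, 100]")

    @property
    def delta_psi(self) -> float:
        return self.psi_knockdown - self.psi_control


def classify_exons_from_psi(
    psi: Sequence[PsiMeasurement],
    min_minor: float = 5.0,
    min_delta: float = 30.0,
    nonreg_max_delta: float = 5.0,
) -> list[tuple[str, str]]:
    """Assign regulation labels from control/knockdown PSI.

    An exon is ``repressed`` (``enhanced``) when its minor-isoform inclusion
    min(PSI, 100-PSI) exceeds ``min_minor`` percent in BOTH samples and its
    inclusion rises (falls) by at least ``min_delta`` percent on knockdown;
    ``non_regulated`` when |delta PSI| <= ``nonreg_max_delta``; anything else
    is ``excluded``. Returns (exon_id, label) pairs in input order.
    """
    out = []
    for m in psi:
        minor_ok = (
            min(m.psi_control, 100.0 - m.psi_control) > min_minor
            and min(m.psi_knockdown, 100.0 - m.psi_knockdown) > min_minor
        )
        d = m.delta_psi
        if minor_ok and d >= min_delta:
            label = "repressed"
        elif minor_ok and d <= -min_delta:
            label = "enhanced"
        elif abs(d) <= nonreg_max_delta:
            label = "non_regulated"
        else:
            label = "excluded"
        out.append((m.exon_id, label))
    return out


# ---------------------------------------------------------------------------
# feature screening and outliers
# ---------------------------------------------------------------------------

def screen_features_ttest(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    alpha: float = 0.25,
) -> list[str]:
    """Keep features whose two-sample t-test p-value (a regulated class vs the
    non-regulated class) is strictly below ``alpha`` for at least one class."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    base = X[labels == "non_regulated"]
    if base.shape[0] < 2:
        raise DegenerateInputError("need >= 2 non_regulated exons to screen against")
    retained = []
    for j, name in enumerate(feature_names):
        best_p = 1.0
        degenerate = True
        for cls in ("repressed", "enhanced"):
            grp = X[labels == cls, j]
            if grp.size < 2:
                continue
            if np.ptp(grp) == 0 and np.ptp(base[:, j]) == 0:
                if grp.mean() != base[:, j].mean():
                    # constant but perfectly separated: maximally informative
                    degenerate = False
                    best_p = 0.0
                continue
            degenerate = False
            p = stats.ttest_ind(grp, base[:, j], equal_var=False).pvalue
            best_p = min(best_p, float(p))
        if degenerate:
            logger.warning("feature %s has zero variance in all comparisons; dropped", name)
            continue
        if best_p < alpha:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultinomialLogitModel:
    """Fitted three-class model; beta vectors are intercept-first."""

    feature_names: tuple[str, ...]
    beta_repressed: np.ndarray
    beta_enhanced: np.ndarray
    se_repressed: np.ndarray
    se_enhanced: np.ndarray
    converged: bool = True
    separation: bool = False
    n_per_class: dict = field(default_factory=dict)
    aic: float = float("nan")

    def coefficients_table(self) -> list[dict]:
        """Per-coefficient estimate, SE, Wald z and two-sided p, per logit."""
        rows = []
        names = ("intercept",) + tuple(self.feature_names)
        for cls, beta, se in (
            ("repressed", self.beta_repressed, self.se_repressed),
            ("enhanced", self.beta_enhanced, self.se_enhanced),
        ):
            for name, b, s in zip(names, beta, se):
                z = b / s if s > 0 else float("nan")
                p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
                rows.append({"logit": cls, "term": name, "beta": float(b),
                             "se": float(s), "wald_z": float(z), "p": float(p)})
        return rows

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "beta_repressed": self.beta_repressed.tolist(),
            "beta_enhanced": self.beta_enhanced.tolist(),
            "se_repressed": self.se_repressed.tolist(),
            "se_enhanced": self.se_enhanced.tolist(),
            "converged": self.converged,
            "separation": self.separation,
            "n_per_class": self.n_per_class,
            "aic": self.aic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultinomialLogitModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            beta_repressed=np.array(d["beta_repressed"], dtype=float),
            beta_enhanced=np.array(d["beta_enhanced"], dtype=float),
            se_repressed=np.array(d["se_repressed"], dtype=float),
            se_enhanced=np.array(d["se_enhanced"], dtype=float),
            converged=bool(d.get("converged", True)),
            separation=bool(d.get("separation", False)),
            n_per_class=dict(d.get("n_per_class", {})),
            aic=float(d.get("aic", float("nan"))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MultinomialLogitModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    codes = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    try:
        return np.array([codes[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


def fit_multinomial(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    ridge_alpha: float = 1.0,
) -> MultinomialLogitModel:
    """Maximum-likelihood multinomial logit with non_regulated as baseline.

    Complete separation (or non-convergence) is detected and reported, with a
    ridge-stabilised fallback fit; fallback standard errors are NaN.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    for cls in CLASS_ORDER:
        if not np.any(labels == cls):
            raise ValueError(f"class {cls!r} absent from the training table")
    y = _encode_labels(labels)
    design = np.column_stack([np.ones(X.shape[0]), X])
    n_per_class = {cls: int(np.sum(labels == cls)) for cls in CLASS_ORDER}

    separation = False
    converged = True
    aic = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, design).fit(method="newton", maxiter=200, disp=False)
            params = np.asarray(res.params)  # (k+1, 2): cols repressed, enhanced
            bse = np.asarray(res.bse)
            converged = bool(res.mle_retvals.get("converged", True))
            aic = float(res.aic)
            if not converged or np.abs(params).max() > 15 or not np.isfinite(bse).all():
                separation = True
        except Exception:
            separation = True
    if separation:
        logger.warning("possible complete separation; refitting with ridge penalty")
        params = _ridge_multinomial(design, y, ridge_alpha)
        bse = np.full_like(params, np.nan)
        converged = True
    return MultinomialLogitModel(
        feature_names=tuple(feature_names),
        beta_repressed=params[:, 0].copy(),
        beta_enhanced=params[:, 1].copy(),
        se_repressed=bse[:, 0].copy(),
        se_enhanced=bse[:, 1].copy(),
        converged=converged,
        separation=separation,
        n_per_class=n_per_class,
        aic=aic,
    )


def _ridge_multinomial(design: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """L2-penalised multinomial logit (penalty excludes intercepts)."""
    n, p = design.shape
    Y = np.zeros((n, 3))
    Y[np.arange(n), y] = 1.0

    def negloglik(flat: np.ndarray) -> float:
        B = flat.reshape(p, 2)
        G = np.column_stack([np.zeros(n), design @ B])  # baseline logit 0
        lse = np.log(np.exp(G - G.max(axis=1, keepdims=True)).sum(axis=1)) + G.max(axis=1)
        ll = float((Y * G).sum() - lse.sum())
        pen = alpha * float((B[1:] ** 2).sum())
        return -ll + pen

    res = optimize.minimize(negloglik, np.zeros(p * 2), method="L-BFGS-B")
    return res.x.reshape(p, 2)


def detect_outlier_exons(
    model: MultinomialLogitModel,
    X: np.ndarray,
    labels: Sequence[str],
    cutoff: float = 3.0,
) -> np.ndarray:
    """Flag exons whose observed class has |standardized Pearson residual| >
    ``cutoff`` under the interim fit. Returns a boolean mask, never silent."""
    if not np.isfinite(cutoff):
        return np.zeros(len(labels), dtype=bool)
    probs = predict_probabilities_batch(model, np.asarray(X, dtype=float))
    y = _encode_labels(labels)
    col = {0: 2, 1: 0, 2: 1}  # class code -> probability column
    p_obs = probs[np.arange(len(y)), [col[c] for c in y]]
    resid = (1.0 - p_obs) / np.sqrt(p_obs * (1.0 - p_obs) + 1e-300)
    flags = np.abs(resid) > cutoff
    if flags.any():
        logger.info("flagged %d outlier exon(s) at |residual| > %g", int(flags.sum()), cutoff)
    return flags


def stepwise_select(
    X: np.ndarray,
    labels: Sequence[str],
    candidate_features: Sequence[str],
    feature_names: Sequence[str],
) -> tuple[list[str], MultinomialLogitModel]:
    """Backward elimination by AIC over the screened candidates.

    Deterministic given the table: at each step the drop yielding the lowest
    AIC is taken if it improves on the current model. An empty candidate set
    yields the intercept-only model.
    """
    X = np.asarray(X, dtype=float)
    name_to_col = {f: i for i, f in enumerate(feature_names)}
    current = list(candidate_features)

    def fit_subset(subset: list[str]) -> MultinomialLogitModel:
        if subset:
            sub_X = X[:, [name_to_col[f] for f in subset]]
        else:
            sub_X = np.empty((X.shape[0], 0))
        return fit_multinomial(sub_X, labels, subset)

    best_model = fit_subset(current)
    improved = True
    while improved and current:
        improved = False
        trial_results = []
        for f in current:
            subset = [g for g in current if g != f]
            m = fit_subset(subset)
            trial_results.append((m.aic, f, subset, m))
        trial_results.sort(key=lambda t: (t[0], t[1]))
        best_aic, _, best_subset, best_trial = trial_results[0]
        if np.isfinite(best_aic) and (not np.isfinite(best_model.aic) or best_aic < best_model.aic):
            current, best_model = best_subset, best_trial
            improved = True
    return current, best_model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def g_values(model: MultinomialLogitModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    return X1 @ model.beta_repressed, X1 @ model.beta_enhanced


def predict_probabilities_batch(model: MultinomialLogitModel, X: np.ndarray) -> np.ndarray:
    """(n, 3) class probabilities, columns (repressed, enhanced, non_regulated)."""
    g_r, g_e = g_values(model, X)
    m = np.maximum(np.maximum(g_r, g_e), 0.0)
    er, ee, eb = np.exp(g_r - m), np.exp(g_e - m), np.exp(-m)
    denom = er + ee + eb
    return np.column_stack([er / denom, ee / denom, eb / denom])


def predict_probabilities(
    model: MultinomialLogitModel, x: Sequence[float]
) -> tuple[float, float, float]:
    """Class probabilities (p_repressed, p_enhanced, p_non_regulated) for one exon."""
    p = predict_probabilities_batch(model, np.asarray(x, dtype=float)[None, :])[0]
    return float(p[0]), float(p[1]), float(p[2])


def rank_and_threshold(
    exon_ids: Sequence[str],
    p_repressed: Sequence[float],
    repress_threshold: float = REPRESS_THRESHOLD,
    negative_threshold: float = NEGATIVE_THRESHOLD,
) -> list[dict]:
    """Sort exons by p_repressed (descending; ties by exon id) and call them.

    ``predicted_repressed`` strictly above the upper threshold;
    ``predicted_unregulated`` at or below the lower; ``intermediate`` between.
    """
    ps = np.asarray(p_repressed, dtype=float)
    if not np.isfinite(ps).all():
        raise ValueError("probabilities must be finite")
    order = sorted(range(len(ps)), key=lambda i: (-ps[i], exon_ids[i]))
    out = []
    for rank, i in enumerate(order, start=1):
        if ps[i] > repress_threshold:
            call = "predicted_repressed"
        elif ps[i] <= negative_threshold:
            call = "predicted_unregulated"
        else:
            call = "intermediate"
        out.append({"rank": rank, "exon_id": exon_ids[i],
                    "p_repressed": float(ps[i]), "call": call})
    n_above = int((ps > repress_threshold).sum())
    logger.info(
        "%d/%d exons (%.1f%%) above p_repressed threshold %g",
        n_above, len(ps), 100.0 * n_above / max(len(ps), 1), repress_threshold,
    )
    return out


# ---------------------------------------------------------------------------
# cross validation and ROC
# ---------------------------------------------------------------------------

def roc_points(scores: Sequence[float], positive: Sequence[bool]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC (fpr, tpr, thresholds) over unique score thresholds, descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positive, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both positives and negatives")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class CrossValidationResult:
    exon_ids: tuple[str, ...]
    held_out_probs: np.ndarray  # (n, 3) columns (repressed, enhanced, non_regulated)
    labels: tuple[str, ...]
    auc_repressed: float
    auc_enhanced: float
    roc_repressed: tuple[np.ndarray, np.ndarray, np.ndarray]
    roc_enhanced: tuple[np.ndarray, np.ndarray, np.ndarray]

    def sensitivity_specificity(self, threshold: float, target: str = "repressed") -> tuple[float, float]:
        """Sensitivity/specificity of calling ``target`` at p > threshold."""
        col = 0 if target == "repressed" else 1
        calls = self.held_out_probs[:, col] > threshold
        truth = np.asarray(self.labels) == target
        sens = float((calls & truth).sum() / max(truth.sum(), 1))
        spec = float((~calls & ~truth).sum() / max((~truth).sum(), 1))
        return sens, spec


def loocv_roc(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    exon_ids: Sequence[str] | None = None,
    screen_alpha: float = 0.25,
    stepwise: bool = True,
    reselect: bool = True,
) -> CrossValidationResult:
    """Leave-one-out cross-validation with per-fold feature screening/selection.

    Screening and stepwise selection are re-run inside every fold (the
    leakage-free protocol); set ``reselect=False`` to select once on the full
    table (faster, slightly optimistic).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    for cls in CLASS_ORDER:
        if np.sum(labels == cls) < 2:
            raise DegenerateInputError(f"LOOCV needs >= 2 exons of class {cls!r}")
    if exon_ids is None:
        exon_ids = [f"exon{i}" for i in range(n)]

    if not reselect:
        fixed = screen_features_ttest(X, labels, feature_names, screen_alpha)
        if stepwise:
            fixed, _ = stepwise_select(X, labels, fixed, feature_names)

    name_to_col = {f: i for i, f in enumerate(feature_names)}
    probs = np.empty((n, 3))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], labels[mask]
        if reselect:
            retained = screen_features_ttest(X_tr, y_tr, feature_names, screen_alpha)
            if stepwise:
                retained, model = stepwise_select(X_tr, y_tr, retained, feature_names)
            else:
                cols = [name_to_col[f] for f in retained]
                model = fit_multinomial(X_tr[:, cols], y_tr, retained)
        else:
            retained = fixed
            cols = [name_to_col[f] for f in retained]
            model = fit_multinomial(X_tr[:, cols], y_tr, retained)
        cols = [name_to_col[f] for f in retained]
        probs[i] = predict_probabilities_batch(model, X[i, cols][None, :])[0]

    fpr_r, tpr_r, th_r = roc_points(probs[:, 0], labels == "repressed")
    fpr_e, tpr_e, th_e = roc_points(probs[:, 1], labels == "enhanced")
    return CrossValidationResult(
        exon_ids=tuple(exon_ids),
        held_out_probs=probs,
        labels=tuple(labels),
        auc_repressed=auc_trapezoid(fpr_r, tpr_r),
        auc_enhanced=auc_trapezoid(fpr_e, tpr_e),
        roc_repressed=(fpr_r, tpr_r, th_r),
        roc_enhanced=(fpr_e, tpr_e, th_e),
    )


# ---------------------------------------------------------------------------
# binned response
# ---------------------------------------------------------------------------

def binned_response(
    x: Sequence[float],
    y: Sequence[float],
    bin_edges: Sequence[float],
) -> list[dict]:
    """Mean response per x-bin plus one-tailed t-tests between adjacent bins.

    Bins are [e_i, e_{i+1}) with the final bin right-closed. Empty bins are
    reported with n=0 and excluded from the adjacent-bin tests, which assess
    whether the higher bin's mean response exceeds the lower bin's (one-tailed
    Student's t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need >= 2 bin edges")
    idx = np.digitize(x, edges[1:-1], right=False)
    in_range = (x >= edges[0]) & (x <= edges[-1])
    bins: list[dict] = []
    for b in range(edges.size - 1):
        members = y[in_range & (idx == b)]
        bins.append({
            "bin": b,
            "lo": float(edges[b]),
            "hi": float(edges[b + 1]),
            "n": int(members.size),
            "mean": float(members.mean()) if members.size else None,
            "values": members,
            "p_vs_previous": None,
        })
    non_empty = [b for b in bins if b["n"] > 0]
    if not non_empty:
        raise DegenerateInputError("no non-empty bins")
    for prev, cur in zip(non_empty, non_empty[1:]):
        if prev["n"] >= 2 and cur["n"] >= 2:
            t = stats.ttest_ind(cur["values"], prev["values"],
                                equal_var=True, alternative="greater")
            cur["p_vs_previous"] = float(t.pvalue)
    for b in bins:
        del b["values"]
    return bins
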