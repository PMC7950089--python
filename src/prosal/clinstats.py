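"""Clinical-feature association and ROC classification of pN0 vs pN+.

The association cascade mirrors a conservative discovery filter: ordinary
least-squares regression of peptide abundance on a numerically coded
clinical covariate (p ≤ 0.05), Pearson |R| > 0.7 and R² > 0.5, at least six
valid peptide values per patient group, and — for the stringent tier — at
least three paired observations per clinical level.  ROC analysis scores
single features by univariate logistic regression (whose AUC coincides with
the Mann–Whitney rank statistic) or by random-forest out-of-bag
probabilities, and feature panels by multivariate binary logistic
regression with in-sample (resubstitution) AUC as the primary readout and
an optional seeded k-fold AUC alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .formats import ClinicalTable, PeptideQuantTable

logger = logging.getLogger("prosal")

#: default association filter thresholds
R_THRESHOLD = 0.7
R2_THRESHOLD = 0.5
MIN_VALID_PER_GROUP = 6
MIN_VALID_PER_LEVEL = 3


# ---------------------------------------------------------------------------
# Clinical association cascade
# ---------------------------------------------------------------------------

def correlate_clinical(
    quant: PeptideQuantTable,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> pd.DataFrame:
    """OLS + Pearson association of every (feature, clinical pair).

    Values are paired per sample with pairwise deletion of missing cells.
    Returns one row per (peptide, clinical feature) with slope, regression
    p-value, Pearson R, R², validity counts and the two filter flags.
    Pairs whose clinical covariate has zero variance after pairing are
    reported with ``testable=False``.
    """
    samples = [s for s in quant.samples if s in clinical.data.index]
    if not samples:
        raise ValueError("no overlap between quant samples and clinical table")
    groups = {s: quant.group_map[s] for s in samples}
    records = []
    inten = quant.intensities[samples]
    if log_transform:
        inten = np.log2(inten + 1.0)
    for feature in clinical.features:
        x_all = clinical.data.loc[samples, feature].astype(float)
        for pid, row in inten.iterrows():
            pair = pd.DataFrame({"x": x_all, "y": row}).dropna()
            n_group = {g: int(pair.index.map(groups).to_series().eq(g).sum()
                              if len(pair) else 0)
                       for g in quant.groups}
            level_counts = pair["x"].value_counts()
            rec = {
                "feature_id": pid, "clinical_feature": feature,
                "n_pairs": len(pair),
                **{f"n_{g}": n_group[g] for g in quant.groups},
                "min_per_level": int(level_counts.min()) if len(level_counts) else 0,
                "n_levels": int(len(level_counts)),
            }
            if len(pair) < 3 or pair["x"].nunique() < 2 or pair["y"].nunique() < 2:
                rec.update(slope=np.nan, p_value=np.nan, pearson_r=np.nan,
                           r_squared=np.nan, testable=False,
                           passes_default=False, passes_stringent=False)
                records.append(rec)
                continue
            fit = stats.linregress(pair["x"], pair["y"])
            r = float(fit.rvalue)
            passes_default = (
                fit.pvalue <= alpha
                and r * r > R2_THRESHOLD
                and abs(r) > R_THRESHOLD
                and all(n >= MIN_VALID_PER_GROUP for n in n_group.values())
            )
            passes_stringent = (
                passes_default
                and rec["min_per_level"] >= MIN_VALID_PER_LEVEL
            )
            rec.update(slope=float(fit.slope), p_value=float(fit.pvalue),
                       pearson_r=r, r_squared=r * r, testable=True,
                       passes_default=bool(passes_default),
                       passes_stringent=bool(passes_stringent))
            records.append(rec)
    out = pd.DataFrame(records)
    logger.info("clinical association: %d pairs, %d default, %d stringent",
                len(out), int(out["passes_default"].sum()),
                int(out["passes_stringent"].sum()))
    return out


def detection_rate_filter(
    quant: PeptideQuantTable,
    min_rate: float = 0.85,
) -> list[str]:
    """Features detected in at least ``min_rate`` of samples in each group."""
    keep = []
    for pid, row in quant.intensities.iterrows():
        ok = True
        for group in quant.groups:
            cols = quant.samples_in(group)
            if row[cols].notna().mean() < min_rate:
                ok = False
                break
        if ok:
            keep.append(pid)
    return keep


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocRecord:
    feature_ids: tuple[str, ...]
    method: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    detection_rate: dict[str, float]
    n_used: int
    degenerate: bool = False
    separation: bool = False
    coefficients: dict[str, float] = field(default_factory=dict)
    cv_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_ids), "method": self.method,
            "auc": self.auc, "ci_95": [self.ci_low, self.ci_high],
            "cutoff": self.cutoff, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "detection_rate": self.detection_rate, "n_used": self.n_used,
            "degenerate": self.degenerate, "separation": self.separation,
            "cv_auc": self.cv_auc,
        }


def delong_ci(scores: np.ndarray, labels: np.ndarray,
              level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong confidence interval for a single score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be represented")
    # placement values via midranks
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[:m]
    r_neg = ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - zq * se), min(1.0, auc + zq * se)
    return float(auc), float(lo), float(hi)


def _optimal_cutoff(scores: np.ndarray, labels: np.ndarray,
                    min_specificity: float = 0.70) -> tuple[float, float, float]:
    """Max sensitivity subject to specificity ≥ the decision threshold.

    Positive calls are scores ≥ cutoff.  If no cutoff attains the required
    specificity the most specific one is returned.
    """
    thresholds = np.unique(scores)
    best = None
    fallback = None
    pos = labels == 1
    neg = ~pos
    for t in thresholds[::-1]:
        pred = scores >= t
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & neg).sum() / neg.sum())
        if fallback is None or spec > fallback[2]:
            fallback = (float(t), sens, spec)
        if spec >= min_specificity and (best is None or sens > best[1]):
            best = (float(t), sens, spec)
    return best if best is not None else fallback


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Binary logistic fit; ridge fallback under (quasi-)separation.

    Returns (fitted probabilities, coefficients incl. intercept, separation
    flag).
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4:
            raise np.linalg.LinAlgError("diverged coefficients")
        return np.asarray(fit.predict(Xc), float), params, False
    except Exception:
        ridge = LogisticRegression(C=1.0, max_iter=1000)
        ridge.fit(X, y)
        prob = ridge.predict_proba(X)[:, 1]
        params = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
        return prob, params, True


def roc_single(
    values: pd.Series | np.ndarray,
    labels: np.ndarray,
    method: str = "logistic",
    seed: int = 0,
    min_specificity: float = 0.70,
    n_bootstrap: int = 2000,
    feature_id: str = "feature",
) -> RocRecord:
    """Single-feature ROC of pN0 (0) vs pN+ (1), complete-case.

    Logistic: AUC of the fitted probabilities (a monotone transform of the
    feature, hence the rank AUC) with a DeLong 95% CI.  Random forest: AUC
    of seeded out-of-bag class probabilities (500 trees) with a seeded
    percentile bootstrap CI over (score, label) pairs.
    """
    x = np.asarray(pd.Series(values), float)
    y = np.asarray(labels, int)
    present = ~np.isnan(x)
    detection = {
        "0": float(present[y == 0].mean()) if (y == 0).any() else np.nan,
        "1": float(present[y == 1].mean()) if (y == 1).any() else np.nan,
    }
    x, y = x[present], y[present]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be represented")
    if np.all(x == x[0]):
        return RocRecord(
            feature_ids=(feature_id,), method=method, auc=0.5,
            ci_low=0.5, ci_high=0.5, cutoff=float(x[0]), sensitivity=1.0,
            specificity=0.0, detection_rate=detection, n_used=len(x),
            degenerate=True)

    if method == "logistic":
        prob, params, separation = _fit_logistic(x.reshape(-1, 1), y)
        auc, lo, hi = delong_ci(prob, y)
        coefs = {"intercept": float(params[0]), feature_id: float(params[1])}
    elif method == "random_forest":
        rf = RandomForestClassifier(n_estimators=500, oob_score=True,
                                    random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(x.reshape(-1, 1), y)
        prob = rf.oob_decision_function_[:, 1]
        prob = np.nan_to_num(prob, nan=0.5)
        auc = float(roc_auc_score(y, prob))
        rng = np.random.default_rng(seed)
        boot = []
        idx_all = np.arange(len(y))
        for _ in range(n_bootstrap):
            idx = rng.choice(idx_all, size=len(y), replace=True)
            if len(np.unique(y[idx])) < 2:
                continue
            boot.append(roc_auc_score(y[idx], prob[idx]))
        lo, hi = (np.percentile(boot, [2.5, 97.5]) if boot else (auc, auc))
        separation = False
        coefs = {}
    else:
        raise ValueError(f"unknown ROC method {method!r}")

    cutoff, sens, spec = _optimal_cutoff(prob, y, min_specificity)
    return RocRecord(
        feature_ids=(feature_id,), method=method, auc=float(auc),
        ci_low=float(min(lo, auc)), ci_high=float(max(hi, auc)),
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        detection_rate=detection, n_used=len(x), separation=separation,
        coefficients=coefs)


def roc_panel(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    min_specificity: float = 0.70,
    cv_folds: int | None = None,
) -> RocRecord:
    """Multivariate binary logistic panel ROC, complete-case.

    Rows with any missing value among the panel features are dropped.  The
    primary AUC is in-sample (resubstitution) on the fitted linear
    predictor; when ``cv_folds`` is given a seeded stratified k-fold AUC is
    reported alongside as ``cv_auc``.
    """
    y_all = np.asarray(labels, int)
    X_all = features.to_numpy(float)
    complete = ~np.isnan(X_all).any(axis=1)
    detection = {
        "0": float(complete[y_all == 0].mean()),
        "1": float(complete[y_all == 1].mean()),
    }
    X, y = X_all[complete], y_all[complete]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be represented")
    prob, params, separation = _fit_logistic(X, y)
    auc, lo, hi = delong_ci(prob, y)
    cutoff, sens, spec = _optimal_cutoff(prob, y, min_specificity)

    cv_auc = None
    if cv_folds:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        for train, test in skf.split(X, y):
            _, coef, _ = _fit_logistic(X[train], y[train])
            Xc = sm.add_constant(X[test], has_constant="add")
            lin = Xc @ coef
            oof[test] = 1.0 / (1.0 + np.exp(-lin))
        cv_auc = float(roc_auc_score(y, oof))

    names = list(features.columns)
    coefs = {"intercept": float(params[0])}
    coefs.update({name: float(c) for name, c in zip(names, params[1:])})
    return RocRecord(
        feature_ids=tuple(names), method="logistic", auc=float(auc),
        ci_low=float(min(lo, auc)), ci_high=float(max(hi, auc)),
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        detection_rate=detection, n_used=len(y), separation=separation,
        coefficients=coefs, cv_auc=cv_auc)


def permutation_auc(
    values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Rank AUCs of seeded label permutations (null reference for AUC)."""
    x = np.asarray(values, float)
    y = np.asarray(labels, int)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = roc_auc_score(rng.permutation(y), x)
    return out
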