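"""Cohort-level statistics on marker tables.

Group comparisons use the two-sample t-test with unequal variances
(Welch) and Welch–Satterthwaite degrees of freedom; two-feature
composites use the Fisher linear discriminant with pooled within-class
covariance, normalized so the first feature's weight is +1 (composite
= f1 + w2*f2); classification at the discriminant midpoint boundary is
reported as resubstitution sensitivity / specificity / accuracy (no
cross-validation — by design, mirroring small-cohort practice, and
flagged in the report); cognitive-score association is ordinary
least-squares regression with the Pearson-r t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateStatisticError,
    InsufficientDataError,
    SchemaError,
)

__all__ = [
    "GroupComparison",
    "DiscriminantModel",
    "ClassificationReport",
    "RegressionResult",
    "welch_from_summary",
    "welch_from_samples",
    "fisher_lda2",
    "classify_and_report",
    "composite_index",
    "regress_score",
]


@dataclass(frozen=True)
class GroupComparison:
    """Welch test of a group-mean difference (group1 minus group2)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float

    def as_dict(self) -> dict:
        return {"mean1": self.mean1, "sd1": self.sd1, "n1": self.n1,
                "mean2": self.mean2, "sd2": self.sd2, "n2": self.n2,
                "t": self.t, "df": self.df, "p": self.p}


@dataclass(frozen=True)
class DiscriminantModel:
    """Two-feature Fisher discriminant, first weight normalized to 1."""

    feature_names: tuple[str, str]
    weights: np.ndarray          # (1, w2)
    threshold: float             # midpoint of projected class means
    class_a: str                 # class whose mean difference defines w
    class_b: str
    projected_mean_a: float
    projected_mean_b: float

    def project(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights

    def as_dict(self) -> dict:
        return {"features": list(self.feature_names),
                "weights": self.weights.tolist(),
                "threshold": self.threshold,
                "classes": [self.class_a, self.class_b],
                "projected_means": [self.projected_mean_a, self.projected_mean_b],
                "covariance": "pooled within-class (LDA)"}


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived percentages (exact, unrounded)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def as_dict(self) -> dict:
        # percentages rounded half-even to 1 decimal for display;
        # exact values kept alongside
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity_pct": round(self.sensitivity_pct, 1),
                "specificity_pct": round(self.specificity_pct, 1),
                "accuracy_pct": round(self.accuracy_pct, 1),
                "sensitivity_pct_exact": self.sensitivity_pct,
                "specificity_pct_exact": self.specificity_pct,
                "accuracy_pct_exact": self.accuracy_pct}


@dataclass(frozen=True)
class RegressionResult:
    """OLS line of score on index, with Pearson r and its p-value."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r": self.r, "p": self.p, "n": self.n}


def welch_from_summary(m1: float, s1: float, n1: int,
                       m2: float, s2: float, n2: int) -> GroupComparison:
    """Welch t-test from group means, sample SDs and sizes.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with the
    Welch–Satterthwaite degrees of freedom and a two-sided p-value
    from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise DegenerateStatisticError("SDs must be >= 0")
    if s1 == 0 and s2 == 0:
        raise DegenerateStatisticError("both group variances are zero")
    v1 = s1 * s1 / n1
    v2 = s2 * s2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(mean1=m1, sd1=s1, n1=n1, mean2=m2, sd2=s2, n2=n2,
                           t=float(t), df=float(df), p=min(p, 1.0))


def welch_from_samples(values1, values2) -> GroupComparison:
    """Welch t-test from raw per-subject values (sample-SD convention)."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DegenerateStatisticError("non-finite values")
    return welch_from_summary(float(a.mean()), float(a.std(ddof=1)), a.size,
                              float(b.mean()), float(b.std(ddof=1)), b.size)


def fisher_lda2(features, labels, class_a: str = "control",
                class_b: str = "patient",
                feature_names: tuple[str, str] = ("f1", "f2")) -> DiscriminantModel:
    """Fisher linear discriminant for two features and two classes.

    w is proportional to Sw^-1 (mu_a - mu_b) with Sw the pooled
    within-class covariance, then rescaled so the first weight equals
    +1 — the composite index is therefore f1 + w2*f2.  The decision
    threshold is the midpoint of the projected class means.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != 2:
        raise SchemaError("features must be an (n, 2) array")
    mask_a = labels == class_a
    mask_b = labels == class_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InsufficientDataError("each class needs >= 2 subjects")
    if not np.all(mask_a | mask_b):
        unknown = sorted(set(labels[~(mask_a | mask_b)]))
        raise SchemaError(f"unknown labels {unknown}")
    Xa, Xb = X[mask_a], X[mask_b]
    mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
    Sa = np.cov(Xa, rowvar=False)
    Sb = np.cov(Xb, rowvar=False)
    na, nb = Xa.shape[0], Xb.shape[0]
    Sw = ((na - 1) * Sa + (nb - 1) * Sb) / (na + nb - 2)
    try:
        w = np.linalg.solve(Sw, mu_a - mu_b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateStatisticError(f"singular within-class covariance: {exc}")
    if w[0] == 0.0:
        raise DegenerateStatisticError(
            "first-feature weight is zero; cannot normalize to w1 = 1")
    w = w / w[0]
    pa, pb = float(mu_a @ w), float(mu_b @ w)
    return DiscriminantModel(feature_names=tuple(feature_names),
                             weights=w, threshold=0.5 * (pa + pb),
                             class_a=class_a, class_b=class_b,
                             projected_mean_a=pa, projected_mean_b=pb)


def classify_and_report(model: DiscriminantModel, features, labels,
                        positive_class: str = "patient") -> ClassificationReport:
    """Classify by composite-vs-threshold and tally the confusion matrix.

    A subject is called ``positive_class`` when its composite lies on
    the same side of the threshold as that class's projected mean;
    points exactly on the boundary are assigned to the negative class.
    """
    labels = np.asarray(labels)
    known = {model.class_a, model.class_b}
    if positive_class not in known:
        raise SchemaError(f"positive class {positive_class!r} not in {sorted(known)}")
    unknown = sorted(set(labels) - known)
    if unknown:
        raise SchemaError(f"unknown labels {unknown}")
    composite = model.project(features)
    pos_mean = (model.projected_mean_a if positive_class == model.class_a
                else model.projected_mean_b)
    side = np.sign(pos_mean - model.threshold)
    predicted_pos = side * (composite - model.threshold) > 0
    actual_pos = labels == positive_class
    tp = int(np.sum(predicted_pos & actual_pos))
    fn = int(np.sum(~predicted_pos & actual_pos))
    fp = int(np.sum(predicted_pos & ~actual_pos))
    tn = int(np.sum(~predicted_pos & ~actual_pos))
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp)


def composite_index(features, feature_names, weights) -> float | np.ndarray:
    """Weighted combination of named marker features.

    ``features`` is a MarkerSet, a mapping, or an (n, k) array whose
    columns follow ``feature_names``.  Linear in every feature.
    """
    weights = np.asarray(weights, dtype=float)
    if len(feature_names) != weights.size:
        raise SchemaError("one weight per feature required")
    if isinstance(features, np.ndarray):
        if features.shape[-1] != weights.size:
            raise SchemaError("feature-array width must match weights")
        return features @ weights
    if hasattr(features, "feature"):
        values = [features.feature(name) for name in feature_names]
    else:
        try:
            values = [features[name] for name in feature_names]
        except KeyError as exc:
            raise SchemaError(f"missing feature {exc}") from None
    return float(np.dot(values, weights))


def regress_score(scores, index) -> RegressionResult:
    """OLS regression of cognitive scores on a model-based index."""
    y = np.asarray(scores, dtype=float)
    x = np.asarray(index, dtype=float)
    if y.size != x.size:
        raise SchemaError("scores and index must pair up")
    if y.size < 3:
        raise InsufficientDataError("need >= 3 paired values")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise DegenerateStatisticError("non-finite values")
    if np.ptp(x) == 0.0:
        raise DegenerateStatisticError("index has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), p=float(res.pvalue), n=y.size)
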