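"""Training contract, ROC-AUC, bootstrap confidence intervals and feature tests.

Classifier fitting and the rank statistics are delegated to scikit-learn and
scipy behind this module's surface; the test suite cross-checks them against
independent brute-force oracles (pair counting for AUC, exact enumeration for
the Mann–Whitney U test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitSpec",
    "AUCDistribution",
    "Scorer",
    "split_train_test",
    "class_weights",
    "train_classifier",
    "roc_auc",
    "bootstrap_auc",
    "feature_mannwhitney",
    "importance_percentiles",
    "top_features_by_type",
    "compare_auc_distributions",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class AUCDistribution:
    """Bootstrap AUC replicates with summary statistics."""

    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0
        self.ci95 = (float(np.percentile(self.values, 2.5)),
                     float(np.percentile(self.values, 97.5)))


@dataclass
class Scorer:
    """Fitted classifier exposing scores in [0, 1] and per-feature importances."""

    model: object
    model_name: str

    def scores(self, X: np.ndarray) -> np.ndarray:
        if np.isnan(np.asarray(X, dtype=float)).any():
            raise ValueError("feature matrix contains NaN")
        return self.model.predict_proba(X)[:, 1]

    @property
    def importances(self) -> np.ndarray:
        """Feature importances (forest) or |standardized coefficients| (logistic)."""
        if hasattr(self.model, "feature_importances_"):
            return np.asarray(self.model.feature_importances_)
        coef = np.abs(np.ravel(self.model.coef_))
        scale = getattr(self.model, "_feature_scale_", None)
        return coef * scale if scale is not None else coef


def split_train_test(n_samples: int, labels: np.ndarray,
                     spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified index split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    if labels.shape[0] != n_samples:
        raise ValueError("labels length must equal n_samples")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 members, got {dict(zip(classes, counts))}")
    idx = np.arange(n_samples)
    train, test = train_test_split(
        idx, train_size=spec.train_fraction, random_state=spec.seed,
        stratify=labels if spec.stratified else None, shuffle=True)
    return np.sort(train), np.sort(test)


def class_weights(labels: np.ndarray) -> dict:
    """Balanced inverse-frequency weights: w(c) = n_total / (2 · n_c)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = len(labels)
    return {c: n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def train_classifier(X: np.ndarray, labels: np.ndarray, weights: dict | None = None,
                     model: str = "forest", seed: int = 0,
                     n_estimators: int = 200) -> Scorer:
    """Fit a class-weighted random forest or logistic regression scorer."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if weights is None:
        weights = class_weights(labels)
    if model == "forest":
        clf = RandomForestClassifier(
            n_estimators=n_estimators, class_weight=weights, random_state=seed, n_jobs=1)
        clf.fit(X, labels)
    elif model == "logistic":
        clf = LogisticRegression(class_weight=weights, max_iter=2000, random_state=seed)
        clf.fit(X, labels)
        clf._feature_scale_ = X.std(axis=0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return Scorer(model=clf, model_name=model)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties ½."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, scores))


def bootstrap_auc(scores: np.ndarray, labels: np.ndarray, n_boot: int = 100,
                  sample_size: int = 50, seed: int = 0) -> AUCDistribution:
    """Bootstrap the AUC on resampled patient sets.

    Each replicate draws ``sample_size`` patients with replacement, redrawing
    until both classes are present, and records the replicate AUC; the 95% CI
    is the (2.5, 97.5) percentile pair of the replicate distribution.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = len(scores)
    values = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=sample_size)
            if len(np.unique(labels[idx])) > 1:
                break
        values[b] = roc_auc(scores[idx], labels[idx])
    return AUCDistribution(values=values)


def feature_mannwhitney(values: np.ndarray, labels: np.ndarray,
                        feature_ids: list[str],
                        feature_types: dict[str, str] | None = None) -> pd.DataFrame:
    """Two-sided Mann–Whitney U test per feature column, case vs control.

    Uses exact enumeration when n1·n2 ≤ 200 and the column is tie-free,
    otherwise the tie-corrected normal approximation.  Constant columns get
    U = n1·n2/2 and p = 1 by convention (flagged).  Features are ranked by
    ascending p within each feature type; Benjamini–Hochberg q-values are
    reported alongside raw p.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    case = values[labels == 1]
    ctrl = values[labels == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes must be present")
    n1, n2 = len(case), len(ctrl)
    rows = []
    for j, fid in enumerate(feature_ids):
        x, y = case[:, j], ctrl[:, j]
        constant = np.ptp(values[:, j]) == 0
        if constant:
            u, p = n1 * n2 / 2.0, 1.0
        else:
            has_ties = len(np.unique(values[:, j])) < n1 + n2
            method = "exact" if (n1 * n2 <= 200 and not has_ties) else "asymptotic"
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        direction = float(np.sign(np.median(x) - np.median(y)))
        ftype = feature_types.get(fid, "feature") if feature_types else "feature"
        rows.append((fid, ftype, u, p, direction, constant))
    df = pd.DataFrame(rows, columns=["node_id", "node_type", "u_statistic", "p_value",
                                     "direction", "constant"])
    m = len(df)
    order = np.argsort(df.p_value.to_numpy(), kind="stable")
    q = np.empty(m)
    cummin = 1.0
    for rank_from_last, i in enumerate(order[::-1]):
        k = m - rank_from_last
        cummin = min(cummin, df.p_value.iloc[i] * m / k)
        q[i] = cummin
    df["q_value"] = q
    df["rank"] = df.groupby("node_type")["p_value"].rank(method="first").astype(int)
    return df


def importance_percentiles(importances: np.ndarray, feature_ids: list[str],
                           feature_types: dict[str, str] | None = None) -> pd.DataFrame:
    """Midrank percentile of each feature within the full importance distribution.

    percentile = 100 · (midrank − 0.5) / N, so an all-equal distribution sits
    at 50 and a unique maximum at 100·(N − 0.5)/N.
    """
    importances = np.asarray(importances, dtype=float)
    n = len(importances)
    midranks = sps.rankdata(importances, method="average")
    pct = 100.0 * (midranks - 0.5) / n
    types = [feature_types.get(f, "feature") if feature_types else "feature"
             for f in feature_ids]
    return pd.DataFrame({"node_id": feature_ids, "node_type": types,
                         "importance": importances, "percentile": pct})


def top_features_by_type(report: pd.DataFrame, node_type: str, k: int = 15) -> pd.DataFrame:
    """Top-k features of one type, sorted by descending importance."""
    sub = report[report.node_type == node_type]
    return sub.sort_values(["importance", "node_id"], ascending=[False, True]).head(k)


def compare_auc_distributions(a: AUCDistribution, b: AUCDistribution,
                              test: str = "t") -> tuple[float, float]:
    """Two-sided comparison of two bootstrap AUC distributions.

    test="t" is Welch's unequal-variance t-test; test="ks" the two-sample
    Kolmogorov–Smirnov test.  Returns (statistic, p_value).
    """
    if len(a.values) != len(b.values):
        raise ValueError("replicate counts differ")
    if test == "t":
        res = sps.ttest_ind(a.values, b.values, equal_var=False)
    elif test == "ks":
        res = sps.ks_2samp(a.values, b.values)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
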