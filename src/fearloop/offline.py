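"""Post-hoc analyses: epoch QC, low-vs-high fear classification with nested
cross-validation, feature importance, band topographies, level statistics and
multiplicity-corrected correlation matrices.

The offline route works on 30-s epochs aligned to exposure iterations. Levels
1-2 form the "low" class and 4-5 the "high" class; level-3 epochs are
excluded (too few for a reliable third class). Classification is leak-free:
standardization and the hyperparameter grid search (inner 3-fold) are fitted
strictly inside each outer training fold of a stratified 5-fold scheme.

All multiple-comparison control uses the Benjamini-Hochberg step-up
procedure at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_validate
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests
from xgboost import XGBClassifier

from .features import STANDARD_BANDS, EpochSet, bandpower, welch_psd

__all__ = [
    "LabeledEpochSet",
    "ClassificationReport",
    "reject_epochs",
    "make_binary_labels",
    "nested_cv_classify",
    "rank_feature_importance",
    "grand_average_topomap",
    "hr_window_means",
    "level_stats",
    "correlation_matrix",
    "benjamini_hochberg",
]

N_PSD_FEATURES = 160  # 32 channels x 5 bands
N_FAA_FEATURES = 4


@dataclass
class LabeledEpochSet:
    """Epochs with stimulus levels and the derived binary fear labels
    (0 = low: levels 1-2, 1 = high: levels 4-5, -1 = excluded: level 3)."""

    levels: np.ndarray
    binary_label: np.ndarray
    epochs: EpochSet | None = None

    @property
    def included(self) -> np.ndarray:
        return self.binary_label >= 0


@dataclass
class ClassificationReport:
    algorithm: str
    feature_set: str
    accuracy_mean: float  # percent
    accuracy_sd: float
    f1_mean: float
    f1_sd: float
    fold_accuracy: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)
    importance: list[tuple[str, float]] = field(default_factory=list)


def reject_epochs(
    epochs: EpochSet, peak_to_peak_threshold_uv: float = 200.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose maximum per-channel peak-to-peak amplitude exceeds
    the threshold. Returns the surviving epochs and the boolean keep mask."""
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to screen")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    keep = ptp.max(axis=1) <= peak_to_peak_threshold_uv
    if not keep.any():
        raise ValueError("no epochs survive rejection")
    kept = EpochSet(
        epochs.data[keep],
        list(epochs.channel_labels),
        epochs.fs_hz,
        epochs.starts_s[keep],
        None if epochs.levels is None else epochs.levels[keep],
    )
    return kept, keep


def make_binary_labels(levels, epochs: EpochSet | None = None) -> LabeledEpochSet:
    """Levels 1-2 -> low (0), 4-5 -> high (1), 3 -> excluded (-1)."""
    levels = np.asarray(levels, dtype=int)
    if levels.size and (levels.min() < 1 or levels.max() > 5):
        raise ValueError("levels must be in 1..5")
    binary = np.where(levels <= 2, 0, np.where(levels >= 4, 1, -1))
    if levels.size and not (binary >= 0).any():
        warnings.warn("all epochs excluded (level 3 only); empty labeled set")
    return LabeledEpochSet(levels, binary, epochs)


_FEATURE_SLICES = {
    "PSD": slice(0, N_PSD_FEATURES),
    "FAA": slice(N_PSD_FEATURES, N_PSD_FEATURES + N_FAA_FEATURES),
    "PSD+FAA": slice(0, N_PSD_FEATURES + N_FAA_FEATURES),
}

_DEFAULT_GRIDS = {
    "svm": {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["linear", "rbf"]},
    "rf": {"clf__n_estimators": [100], "clf__max_depth": [None, 5]},
    "xgb": {"clf__n_estimators": [50, 100], "clf__max_depth": [2, 4]},
}


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "svm":
        return SVC(random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "xgb":
        return XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0,
            learning_rate=0.1,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def nested_cv_classify(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "svm",
    feature_set: str = "PSD+FAA",
    feature_names: list[str] | None = None,
    seed: int = 0,
    outer_folds: int = 5,
    inner_folds: int = 3,
    grid: dict | None = None,
    min_per_class: int = 10,
) -> ClassificationReport:
    """Leak-free nested cross-validation of one algorithm / feature set.

    The pipeline (z-scoring + classifier) and the grid search are fitted
    inside each outer training fold; reported accuracy/F1 are the outer-fold
    mean +/- sd in percent. The importance ranking comes from a final grid
    search refit on the full data (it does not enter the reported metrics).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < min_per_class:
        raise ValueError(f"need >= {min_per_class} samples per class, got {counts}")
    if feature_set not in _FEATURE_SLICES:
        raise ValueError(f"feature_set must be one of {sorted(_FEATURE_SLICES)}")
    if X.shape[1] == N_PSD_FEATURES + N_FAA_FEATURES:
        sel = _FEATURE_SLICES[feature_set]
    elif feature_set == "PSD+FAA":
        sel = slice(None)
    else:
        raise ValueError("feature subsets require the 164-feature layout")
    Xs = X[:, sel]
    if feature_names is not None:
        feature_names = list(feature_names[sel])
    pipe = Pipeline(
        [("scale", StandardScaler()), ("clf", _make_estimator(algorithm, seed))]
    )
    inner = GridSearchCV(
        pipe,
        grid or _DEFAULT_GRIDS[algorithm],
        cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )
    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=seed)
    scores = cross_validate(
        inner, Xs, y, cv=outer, scoring=("accuracy", "f1"), n_jobs=1
    )
    acc = 100.0 * scores["test_accuracy"]
    f1 = 100.0 * scores["test_f1"]
    final = clone(inner).fit(Xs, y)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(Xs.shape[1])]
    try:
        importance = rank_feature_importance(final.best_estimator_, feature_names)
    except ValueError:
        importance = []
    return ClassificationReport(
        algorithm=algorithm,
        feature_set=feature_set,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)),
        f1_mean=float(f1.mean()),
        f1_sd=float(f1.std(ddof=1)),
        fold_accuracy=acc.tolist(),
        fold_f1=f1.tolist(),
        importance=importance,
    )


def rank_feature_importance(
    model, feature_names: list[str]
) -> list[tuple[str, float]]:
    """Features sorted by importance, descending.

    Tree ensembles expose ``feature_importances_``; linear margin models use
    the absolute hyperplane weight on standardized features.
    """
    est = model.steps[-1][1] if isinstance(model, Pipeline) else model
    if hasattr(est, "feature_importances_"):
        imp = np.asarray(est.feature_importances_, dtype=float)
    elif hasattr(est, "coef_") and getattr(est, "kernel", "linear") == "linear":
        imp = np.abs(np.asarray(est.coef_, dtype=float)).ravel()
    else:
        raise ValueError("model exposes neither importances nor linear weights")
    if len(feature_names) != imp.size:
        raise ValueError("feature name count does not match model")
    order = np.argsort(imp)[::-1]
    return [(feature_names[i], float(imp[i])) for i in order]


def grand_average_topomap(
    epochs: EpochSet,
    bands=STANDARD_BANDS,
    levels=(1, 2, 3, 4, 5),
) -> tuple[np.ndarray, list[int], list[str]]:
    """Mean bandpower per channel for each (level, band).

    Returns ``(matrix, levels, band_names)`` where ``matrix`` has shape
    (n_levels, n_bands, n_channels); levels with no epochs yield NaN rows
    with a warning.
    """
    if epochs.levels is None:
        raise ValueError("epochs carry no level labels")
    freqs, psd = welch_psd(epochs.data, epochs.fs_hz)
    bp = np.stack([bandpower(freqs, psd, b) for b in bands], axis=1)  # (ep, band, ch)
    out = np.full((len(levels), len(bands), len(epochs.channel_labels)), np.nan)
    for i, lev in enumerate(levels):
        mask = epochs.levels == lev
        if not mask.any():
            warnings.warn(f"no epochs at level {lev}; NaN row")
            continue
        out[i] = bp[mask].mean(axis=0)
    return out, list(levels), [b.name for b in bands]


def hr_window_means(
    hr_times: np.ndarray,
    hr_values: np.ndarray,
    n_windows: int = 10,
    window_s: float = 30.0,
    t_start: float = 0.0,
) -> np.ndarray:
    """Iteratively average HR over consecutive 30-s windows (10 per run)."""
    hr_times = np.asarray(hr_times, dtype=float)
    hr_values = np.asarray(hr_values, dtype=float)
    out = np.full(n_windows, np.nan)
    for k in range(n_windows):
        lo = t_start + k * window_s
        sel = (hr_times >= lo) & (hr_times < lo + window_s)
        if sel.any():
            out[k] = hr_values[sel].mean()
    return out


def level_stats(
    values_by_level: dict[int, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Welch t-tests between levels with BH adjustment.

    Welch (unequal-variance) tests are used because level groups have
    unequal sizes. Pairs with degenerate variance in both groups are flagged
    with NaN statistics and excluded from the BH family.
    """
    groups = {
        k: np.asarray(v, dtype=float)
        for k, v in values_by_level.items()
        if np.asarray(v).size >= 2
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 levels with at least 2 values each")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        va, vb = groups[a], groups[b]
        if va.std() == 0 and vb.std() == 0:
            rows.append((a, b, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append((a, b, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    valid = df["p_raw"].notna().to_numpy()
    adj = np.full(len(df), np.nan)
    rej = np.zeros(len(df), dtype=bool)
    if valid.any():
        adj_v, rej_v = benjamini_hochberg(df.loc[valid, "p_raw"].to_numpy(), alpha)
        adj[valid], rej[valid] = adj_v, rej_v
    df["p_adj"] = adj
    df["significant"] = rej
    return df


def correlation_matrix(
    data: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with a BH-corrected significance mask.

    Returns ``(r, p_raw, p_adj, significant)`` DataFrames. Zero-variance
    variables yield NaN rows/columns and are excluded from the BH family.
    The diagonal is r = 1 and never enters the family.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 observations per variable")
    cols = list(data.columns)
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    x = data.to_numpy(dtype=float)
    degenerate = x.std(axis=0) == 0
    pairs = []
    for i, j in combinations(range(n), 2):
        if degenerate[i] or degenerate[j]:
            continue
        rij, pij = stats.pearsonr(x[:, i], x[:, j])
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
        pairs.append((i, j, pij))
    sig = np.zeros((n, n), dtype=bool)
    padj = np.full((n, n), np.nan)
    if pairs:
        adj, rej = benjamini_hochberg([pij for _, _, pij in pairs], alpha)
        for (i, j, _), a, rj in zip(pairs, adj, rej):
            padj[i, j] = padj[j, i] = a
            sig[i, j] = sig[j, i] = rj
    wrap = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return wrap(r), wrap(p), wrap(padj), wrap(sig)


def benjamini_hochberg(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up false-discovery-rate control; returns (adjusted p, reject)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject
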