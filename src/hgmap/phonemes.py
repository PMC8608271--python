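"""Phoneme-aligned decoding: evoked windows, RLS classification, speaker
invariance, F-ratio discriminability and MDS layouts.

Windows are half-open intervals [start, end) in ms relative to phone onset;
frame indices are ``floor(onset*fr) + floor(start*fr/1000) ..
floor(onset*fr) + floor(end*fr/1000) - 1`` (0-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import spatial, stats
from sklearn.linear_model import RidgeClassifier
from sklearn.manifold import smacof
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .arpabet import ATTRIBUTE_COLUMNS, NA
from .containers import HighGammaResponse

NEURAL_WINDOW_MS = (90.0, 150.0)       # onset-aligned neural MDS window
ACOUSTIC_WINDOW_MS = (10.0, 70.0)      # onset-aligned acoustic MDS window
CLASSIFIER_WINDOW_MS = (70.0, 180.0)   # decoding window
DEFAULT_ALPHAS = tuple(np.logspace(-1.0, 3.0, 5))


# ---------------------------------------------------------------------------
# evoked segmentation
# ---------------------------------------------------------------------------

@dataclass
class EvokedMatrix:
    """Instances x features matrix of onset-aligned windowed responses."""

    X: np.ndarray                  # (n_instances, n_frames_per_win * n_sites)
    labels: pd.DataFrame           # aligned rows of the phoneme table
    window_ms: tuple[float, float]
    n_sites: int
    n_frames: int                  # frames per window per site
    n_dropped: int = 0

    def site_features(self, site: int) -> np.ndarray:
        """Feature block of a single site."""
        j0 = site * self.n_frames
        return self.X[:, j0:j0 + self.n_frames]


def validate_phoneme_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"phoneme", "onset_s", "offset_s", "speaker", *ATTRIBUTE_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phoneme table missing columns {sorted(missing)}")
    if np.any(np.diff(table["onset_s"].to_numpy()) < 0):
        raise ValueError("phoneme onsets must be non-decreasing")
    return table


def segment_evoked(responses: HighGammaResponse, table: pd.DataFrame,
                   window_ms: tuple[float, float] = CLASSIFIER_WINDOW_MS
                   ) -> EvokedMatrix:
    """Cut one onset-aligned window per phoneme instance.

    Instances whose window extends past the recording are dropped; the count
    is reported on the returned matrix.
    """
    validate_phoneme_table(table)
    if len(table) == 0:
        raise ValueError("empty phoneme table")
    start_ms, end_ms = window_ms
    if not start_ms < end_ms:
        raise ValueError("window start must precede end")
    fr = responses.frame_rate
    off0 = int(np.floor(start_ms * fr / 1000.0))
    off1 = int(np.floor(end_ms * fr / 1000.0))
    w = off1 - off0
    T = responses.n_frames
    onset_frames = np.floor(table["onset_s"].to_numpy() * fr).astype(int)
    keep = (onset_frames + off0 >= 0) & (onset_frames + off1 <= T)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("no phoneme instance fits inside the recording")
    n_sites = responses.n_sites
    X = np.empty((kept.size, w * n_sites))
    for row, idx in enumerate(kept):
        sl = responses.values[:, onset_frames[idx] + off0:onset_frames[idx] + off1]
        X[row] = sl.reshape(-1)           # site-major blocks of w frames
    labels = table.iloc[kept].reset_index(drop=True)
    return EvokedMatrix(X=X, labels=labels, window_ms=window_ms,
                        n_sites=n_sites, n_frames=w,
                        n_dropped=int(len(table) - kept.size))


# ---------------------------------------------------------------------------
# F-statistic window selection and discriminability
# ---------------------------------------------------------------------------

def _f_per_feature(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes, inv = np.unique(y, return_inverse=True)
    k, n = classes.size, y.size
    if k < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("need at least 2 instances per class")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in range(k):
        Xi = X[inv == c]
        mu = Xi.mean(axis=0)
        ssb += counts[c] * (mu - grand) ** 2
        ssw += ((Xi - mu) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(msw > 0, msb / msw, np.inf)


def f_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled between/within variance ratio across all features.

    Zero pooled within-class variance yields +inf (flagged by a warning).
    A class with a single instance is an error: its within-variance is
    undefined.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    classes, inv = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("classes with a single instance have undefined "
                         "within-class variance")
    k, n = classes.size, y.size
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for c in range(k):
        Xi = X[inv == c]
        mu = Xi.mean(axis=0)
        ssb += counts[c] * np.sum((mu - grand) ** 2)
        ssw += np.sum((Xi - mu) ** 2)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0:
        warnings.warn("zero within-class variance; F-ratio is infinite",
                      stacklevel=2)
        return float("inf")
    return float(msb / msw)


def f_ratio_permutation_p(X: np.ndarray, labels: np.ndarray,
                          n_perm: int = 199, seed: int = 0) -> tuple[float, float]:
    """Permutation p-value for the pooled F-ratio (labels shuffled)."""
    rng = np.random.default_rng(seed)
    obs = f_ratio(X, labels)
    y = np.asarray(labels).copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(y)
        if f_ratio(X, y) >= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


@dataclass
class WindowSelection:
    window_ms: tuple[float, float]
    f_by_window: dict[tuple[float, float], float]
    informative: bool


def select_window_by_fstat(responses: HighGammaResponse, table: pd.DataFrame,
                           candidate_windows: list[tuple[float, float]],
                           label_column: str = "phoneme") -> WindowSelection:
    """Pick the onset-aligned window maximizing mean per-feature F-statistic.

    Ties break toward the earlier window.  The selection is flagged
    non-informative when the best mean F is below the 95th percentile of
    its F distribution under equal class means.
    """
    if not candidate_windows:
        raise ValueError("no candidate windows")
    f_by_window: dict[tuple[float, float], float] = {}
    best = None
    dfs = None
    for win in sorted(candidate_windows):
        ev = segment_evoked(responses, table, win)
        y = ev.labels[label_column].to_numpy()
        fvals = _f_per_feature(ev.X, y)
        fmean = float(np.mean(fvals[np.isfinite(fvals)]))
        f_by_window[win] = fmean
        if best is None or fmean > f_by_window[best]:
            best = win
            k = np.unique(y).size
            dfs = (k - 1, y.size - k)
    crit = stats.f.ppf(0.95, *dfs)
    return WindowSelection(window_ms=best, f_by_window=f_by_window,
                           informative=f_by_window[best] > crit)


# ---------------------------------------------------------------------------
# RLS classification
# ---------------------------------------------------------------------------

@dataclass
class RLSResult:
    accuracy: float
    confusion: np.ndarray          # rows = true class
    classes: np.ndarray
    ridge_param: float
    per_class_recall: np.ndarray
    predictions: np.ndarray


def _make_rls(alpha: float) -> RidgeClassifier:
    return RidgeClassifier(alpha=alpha, fit_intercept=True)


def rls_classify(train_X: np.ndarray, train_y: np.ndarray,
                 test_X: np.ndarray, test_y: np.ndarray,
                 alphas: tuple[float, ...] = DEFAULT_ALPHAS,
                 val_fraction: float = 0.1, seed: int = 0) -> RLSResult:
    """One-vs-rest regularized least-squares classifier.

    Ridge regression on +/-1 targets with argmax decision; the ridge
    parameter is chosen on a 10% validation split of the training data,
    then the model is refit on all of it.  Features are standardized on
    the training set.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    train_classes = np.unique(train_y)
    missing = np.setdiff1d(np.unique(test_y), train_classes)
    if missing.size:
        raise ValueError(f"test classes absent from training set: {missing.tolist()}")

    scaler = StandardScaler().fit(train_X)
    Ztr = scaler.transform(train_X)
    Zte = scaler.transform(test_X)

    best_alpha = alphas[0]
    if len(alphas) > 1 and train_y.size >= 20:
        try:
            splitter = StratifiedShuffleSplit(n_splits=1, test_size=val_fraction,
                                              random_state=seed)
            fit_idx, val_idx = next(splitter.split(Ztr, train_y))
        except ValueError:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(train_y.size)
            n_val = max(1, int(round(val_fraction * train_y.size)))
            val_idx, fit_idx = perm[:n_val], perm[n_val:]
        if np.unique(train_y[fit_idx]).size == train_classes.size:
            best_score = -np.inf
            for a in alphas:
                clf = _make_rls(a).fit(Ztr[fit_idx], train_y[fit_idx])
                score = clf.score(Ztr[val_idx], train_y[val_idx])
                if score > best_score:
                    best_score, best_alpha = score, a

    clf = _make_rls(best_alpha).fit(Ztr, train_y)
    pred = clf.predict(Zte)
    acc = float(np.mean(pred == test_y))
    cm = confusion_matrix(test_y, pred, labels=train_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(cm.sum(axis=1) > 0,
                          np.diag(cm) / cm.sum(axis=1), np.nan)
    return RLSResult(accuracy=acc, confusion=cm, classes=train_classes,
                     ridge_param=float(best_alpha), per_class_recall=recall,
                     predictions=pred)


def chance_level(labels: np.ndarray) -> float:
    """Analytic chance accuracy 1/k for the label set."""
    return 1.0 / np.unique(np.asarray(labels)).size


# ---------------------------------------------------------------------------
# speaker invariance index
# ---------------------------------------------------------------------------

@dataclass
class InvarianceResult:
    si: float
    cross_acc: float
    within_acc: float
    per_attribute: dict[str, float]
    chance: float
    unreliable: bool = False


def _attribute_subsets(labels: pd.DataFrame, attribute: str,
                       min_class_count: int) -> np.ndarray:
    y = labels[attribute].to_numpy()
    ok = y != NA
    vals, counts = np.unique(y[ok], return_counts=True)
    keep_vals = set(vals[counts >= min_class_count])
    if len(keep_vals) < 2:
        return np.zeros(y.size, dtype=bool)
    return ok & np.isin(y, list(keep_vals))


def _cv_accuracy(X: np.ndarray, y: np.ndarray, n_splits: int = 3,
                 val_fraction: float = 0.1, seed: int = 0,
                 alphas: tuple[float, ...] = DEFAULT_ALPHAS) -> float:
    """Repeated stratified 90/10 split accuracy ('10% cross-validation')."""
    accs = []
    try:
        splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                          test_size=val_fraction,
                                          random_state=seed)
        splits = list(splitter.split(X, y))
    except ValueError:
        return np.nan
    for tr, te in splits:
        if np.unique(y[tr]).size < 2:
            continue
        te = te[np.isin(y[te], y[tr])]
        if te.size == 0:
            continue
        res = rls_classify(X[tr], y[tr], X[te], y[te], alphas=alphas, seed=seed)
        accs.append(res.accuracy)
    return float(np.mean(accs)) if accs else np.nan


def speaker_invariance(evoked: EvokedMatrix, site: int | None = None,
                       attributes: tuple[str, ...] = ATTRIBUTE_COLUMNS,
                       min_class_count: int = 6, seed: int = 0,
                       alphas: tuple[float, ...] = DEFAULT_ALPHAS
                       ) -> InvarianceResult:
    """Speaker invariance index from onset-aligned evoked responses.

    For every held-out speaker, a phonetic-attribute classifier is trained
    on the remaining speakers (pooled) and tested on the unseen one; the
    cross-speaker accuracy (averaged over speakers and the five attributes)
    is divided by the within-speaker 10%-cross-validated accuracy.  ``site``
    restricts the features to one electrode; ``None`` uses the population.
    """
    X = evoked.site_features(site) if site is not None else evoked.X
    labels = evoked.labels
    speakers = np.unique(labels["speaker"])
    if speakers.size < 2:
        raise ValueError("need at least 2 speakers")
    spk = labels["speaker"].to_numpy()

    per_attr: dict[str, float] = {}
    cross_all, within_all, chance_all = [], [], []
    for attr in attributes:
        mask = _attribute_subsets(labels, attr, min_class_count)
        if not mask.any():
            continue
        y = labels[attr].to_numpy()
        cross_accs, within_accs = [], []
        for held in speakers:
            tr = mask & (spk != held)
            te = mask & (spk == held)
            tr_classes = np.unique(y[tr])
            te_keep = te & np.isin(y, tr_classes)
            if tr_classes.size < 2 or te_keep.sum() < 2:
                continue
            res = rls_classify(X[tr], y[tr], X[te_keep], y[te_keep],
                               alphas=alphas, seed=seed)
            cross_accs.append(res.accuracy)
            win = _cv_accuracy(X[te], y[te], seed=seed, alphas=alphas)
            if np.isfinite(win):
                within_accs.append(win)
        if cross_accs and within_accs:
            c, w = float(np.mean(cross_accs)), float(np.mean(within_accs))
            cross_all.append(c)
            within_all.append(w)
            chance_all.append(1.0 / np.unique(y[mask]).size)
            per_attr[attr] = c / w if w > 0 else np.nan
    if not cross_all:
        raise ValueError("no attribute had enough classes per speaker")
    cross = float(np.mean(cross_all))
    within = float(np.mean(within_all))
    chance = float(np.mean(chance_all))
    si = cross / within if within > 0 else np.nan
    return InvarianceResult(si=si, cross_acc=cross, within_acc=within,
                            per_attribute=per_attr, chance=chance,
                            unreliable=bool(within <= chance))


def speaker_invariance_per_site(evoked: EvokedMatrix, **kwargs
                                ) -> list[InvarianceResult]:
    return [speaker_invariance(evoked, site=i, **kwargs)
            for i in range(evoked.n_sites)]


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

def mds_embed(dissimilarity: np.ndarray, dims: int = 2, seed: int = 0
              ) -> tuple[np.ndarray, float]:
    """Embed a dissimilarity matrix minimizing Kruskal's normalized stress.

    Classical-scaling initialisation followed by SMACOF refinement; the
    returned stress is Kruskal stress-1, sqrt(sum (d - delta)^2 / sum d^2).
    The embedding is defined up to rotation and reflection.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be non-negative")
    n = D.shape[0]
    # classical MDS initialisation
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1][:dims]
    init = evecs[:, order] * np.sqrt(np.clip(evals[order], 0, None))
    coords, _ = smacof(D, n_components=dims, init=init, n_init=1,
                       random_state=seed, normalized_stress=False,
                       eps=1e-9, max_iter=1000)
    d_fit = spatial.distance.squareform(spatial.distance.pdist(coords))
    num = np.sum((d_fit - D) ** 2)
    den = np.sum(d_fit ** 2)
    stress1 = float(np.sqrt(num / den)) if den > 0 else 0.0
    return coords, stress1


def phoneme_dissimilarity(evoked: EvokedMatrix, by: tuple[str, ...] =
                          ("phoneme", "speaker")) -> tuple[np.ndarray, list]:
    """Pairwise Euclidean distances between mean evoked patterns per group."""
    groups = evoked.labels.groupby(list(by), sort=True).indices
    keys = list(groups)
    means = np.stack([evoked.X[idx].mean(axis=0) for idx in groups.values()])
    D = spatial.distance.squareform(spatial.distance.pdist(means))
    return D, keys
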