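"""Spatial analysis of electrode tuning maps.

Distances and axes (along-HG projection), display smoothing and
interpolation, feature-versus-distance correlations, hemisphere
comparisons, and the joint PCA + CCA gradient analysis.  Statistics are
always computed on raw per-site values; smoothing, interpolation and
imputation exist for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import interpolate, spatial, stats
from sklearn.cross_decomposition import CCA


@dataclass
class SiteGeometry:
    site_id: str
    hemisphere: str
    ml_mm: float       # |distance to midsagittal plane| minus cohort minimum
    pa_mm: float       # posterior -> anterior
    along_hg_mm: float


@dataclass
class FeatureMapSet:
    """N sites x M tuning features plus 2-D coordinates."""

    X: np.ndarray                 # (N, M) raw feature values
    coords: np.ndarray            # (N, 2) = (ML, PA) mm
    feature_names: list[str]
    site_ids: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.X.shape[0] != self.coords.shape[0]:
            raise ValueError("X and coords row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not self.site_ids:
            self.site_ids = [f"s{i:03d}" for i in range(self.X.shape[0])]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]


def ml_distance(x_mm: np.ndarray) -> np.ndarray:
    """Medial-lateral distance: |distance to midsagittal| minus cohort minimum."""
    d = np.abs(np.asarray(x_mm, dtype=float))
    return d - d.min()


def along_hg_distance(coords: np.ndarray,
                      eig_ratio_warn: float = 1.2) -> np.ndarray:
    """Signed projection of sites onto the first principal axis of the array.

    Origin is at the most medial site (minimum ML coordinate) and the sign
    is chosen so that the distance increases medial to lateral.  A warning
    is emitted when the electrode cloud is nearly isotropic (leading
    eigenvalue ratio below ``eig_ratio_warn``), in which case the axis
    direction is unstable.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 sites with (ML, PA) coordinates")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / (coords.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0 and evals[1] / evals[0] < eig_ratio_warn:
        warnings.warn(
            f"electrode cloud nearly isotropic (eigenvalue ratio "
            f"{evals[1] / evals[0]:.2f}); along-axis direction is unstable",
            stacklevel=2)
    axis = evecs[:, -1]
    proj = centred @ axis
    # increase medial -> lateral: positive correlation with ML coordinate
    if np.polyfit(proj, coords[:, 0], 1)[0] < 0:
        proj = -proj
    most_medial = int(np.argmin(coords[:, 0]))
    return proj - proj[most_medial]


def knn_smooth(values: np.ndarray, coords: np.ndarray, k: int = 4,
               site_ids: list[str] | None = None) -> np.ndarray:
    """Display smoothing: each site takes the mean of its k nearest neighbours.

    The site itself is excluded.  Equidistant neighbours are broken
    deterministically by site id order.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = values.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} sites")
    ids = site_ids if site_ids is not None else [f"s{i:03d}" for i in range(n)]
    order_key = np.argsort(np.argsort(ids))   # rank of each site id
    d = spatial.distance.squareform(spatial.distance.pdist(coords))
    np.fill_diagonal(d, np.inf)
    out = np.empty(n)
    for i in range(n):
        neigh = np.lexsort((order_key, d[i]))[:k]
        out[i] = values[neigh].mean()
    return out


def interpolate_surface(values: np.ndarray, coords: np.ndarray,
                        grid_x: np.ndarray, grid_y: np.ndarray) -> np.ma.MaskedArray:
    """Piecewise-linear (barycentric) interpolation on a triangulation.

    Grid points outside the convex hull of the sites are masked.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 sites to interpolate")
    interp = interpolate.LinearNDInterpolator(coords, np.asarray(values, float))
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="xy")
    z = interp(gx, gy)
    return np.ma.masked_invalid(z)


def impute_missing(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Fill NaN values with the nearest observed site's value (k = 1)."""
    values = np.asarray(values, dtype=float).copy()
    coords = np.asarray(coords, dtype=float)
    missing = np.isnan(values)
    if missing.all():
        raise ValueError("all values missing; cannot impute")
    if not missing.any():
        return values
    tree = spatial.cKDTree(coords[~missing])
    _, idx = tree.query(coords[missing], k=1)
    values[missing] = values[~missing][idx]
    return values


def feature_axis_correlation(values: np.ndarray, along_hg: np.ndarray,
                             log_transform: bool = False
                             ) -> tuple[float, float]:
    """Pearson correlation of raw tuning values with along-HG distance.

    ``log_transform`` applies log2 first (used for best frequency, which is
    analysed on a logarithmic axis).  Returns (r, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 sites")
    if log_transform:
        values = np.log2(values)
    if np.std(values) <= 1e-14 or np.std(along_hg) <= 1e-14:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(values, along_hg)
    return float(r), float(p)


def compare_hemispheres(values: np.ndarray, hemisphere: np.ndarray
                        ) -> tuple[float, float, int, int]:
    """Wilcoxon rank-sum test of a tuning value between hemispheres.

    Returns (statistic, p, n_left, n_right).  Very small groups fall back
    to the exact Mann-Whitney test with a warning.
    """
    values = np.asarray(values, dtype=float)
    hemisphere = np.asarray(hemisphere)
    left = values[hemisphere == "L"]
    right = values[hemisphere == "R"]
    if left.size == 0 or right.size == 0:
        raise ValueError("both hemispheres must have sites")
    if min(left.size, right.size) < 3:
        warnings.warn("hemisphere group smaller than 3; using exact test",
                      stacklevel=2)
        res = stats.mannwhitneyu(left, right, alternative="two-sided",
                                 method="exact")
        return float(res.statistic), float(res.pvalue), left.size, right.size
    stat, p = stats.ranksums(left, right)
    return float(stat), float(p), left.size, right.size


# ---------------------------------------------------------------------------
# joint analysis
# ---------------------------------------------------------------------------

@dataclass
class JointPCA:
    weights: np.ndarray            # (M, M), rows = components
    variance_fractions: np.ndarray
    projections: np.ndarray        # (N, M)
    feature_names: list[str]


def joint_pca(features: FeatureMapSet,
              log_features: tuple[str, ...] = ("bf",)) -> JointPCA:
    """PCA across the five standardized tuning maps.

    Features named in ``log_features`` enter as log2 values.  Each column
    is z-scored before the decomposition; the sign of each component is
    fixed so its largest-magnitude weight is positive.
    """
    X = features.X.astype(float).copy()
    for name in log_features:
        if name in features.feature_names:
            j = features.feature_names.index(name)
            X[:, j] = np.log2(X[:, j])
    n, m = X.shape
    if m < 2 or n <= m:
        raise ValueError("need at least 2 features and more sites than features")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 1e-14):
        bad = [features.feature_names[j] for j in np.flatnonzero(sd <= 1e-14)]
        raise ValueError(f"constant feature column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    cov = Z.T @ Z / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    weights = evecs.T
    for i in range(m):
        j = np.argmax(np.abs(weights[i]))
        if weights[i, j] < 0:
            weights[i] = -weights[i]
    return JointPCA(weights=weights,
                    variance_fractions=evals / evals.sum(),
                    projections=Z @ weights.T,
                    feature_names=list(features.feature_names))


def cca_best_direction(projection: np.ndarray, coords: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """Best spatial direction of a tuning projection by canonical correlation.

    Finds the unit vector a over (ML, PA) maximizing corr(coords @ a, Y).
    Returns (a_hat, canonical r).  The vector sign is fixed so the
    correlation is positive; directions are therefore axial (defined
    modulo 180 degrees).
    """
    Y = np.asarray(projection, dtype=float).reshape(-1, 1)
    X = np.asarray(coords, dtype=float)
    if X.shape[0] <= 3:
        raise ValueError("need more than 3 sites")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise ValueError("degenerate coordinates")
    cca = CCA(n_components=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xs, ys = cca.fit_transform(X, Y)
    a = cca.x_weights_[:, 0].copy()
    r = float(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
    if r < 0:
        a, r = -a, -r
    return a / np.linalg.norm(a), r


def direction_angle_deg(a: np.ndarray) -> float:
    """Axial angle of a 2-vector in degrees, in [0, 180)."""
    ang = np.degrees(np.arctan2(a[1], a[0])) % 180.0
    return float(ang)


def random_direction_control(coords: np.ndarray, n_draws: int = 200,
                             seed: int = 0) -> tuple[np.ndarray, float]:
    """CCA directions for random tuning values: the null of the best-direction test.

    Returns the axial angles (degrees) of ``n_draws`` random-Y fits and the
    Rayleigh-test p-value on the doubled angles; a non-significant p means
    the directions are uniform, i.e. the geometry alone does not prefer an
    axis.
    """
    rng = np.random.default_rng(seed)
    angles = np.empty(n_draws)
    for i in range(n_draws):
        y = rng.normal(size=coords.shape[0])
        a, _ = cca_best_direction(y, coords)
        angles[i] = direction_angle_deg(a)
    _, p = pg.circ_rayleigh(np.deg2rad(2.0 * angles))
    return angles, float(p)


def gradient_report(features: FeatureMapSet) -> pd.DataFrame:
    """Per-feature along-axis correlation and hemisphere comparison table."""
    along = along_hg_distance(features.coords)
    rows = []
    hemi = np.asarray(features.hemisphere) if features.hemisphere else None
    for j, name in enumerate(features.feature_names):
        r, p = feature_axis_correlation(features.X[:, j], along,
                                        log_transform=(name == "bf"))
        row = {"feature": name, "r": r, "p": p}
        if hemi is not None and len(hemi):
            stat, hp, nl, nr = compare_hemispheres(features.X[:, j], hemi)
            row.update({"hemi_stat": stat, "hemi_p": hp,
                        "n_left": nl, "n_right": nr})
        rows.append(row)
    return pd.DataFrame(rows)
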