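"""SPAD chemometrics: masked spectra, SPXY splitting, PLS, UVE, metrics.

The detection model is a PLS1 regression from per-plant mean reflectance
(25 bands) to the SPAD greenness index, built in four steps:

1. mean reflectance over the plant mask per band (:func:`extract_mean_reflectance`);
2. deterministic calibration/validation partition by joint X-Y distance
   (SPXY, default 2:1);
3. wavelength selection by uninformative variable elimination (UVE): the
   stability of each band's PLS coefficient under leave-one-out jackknife,
   summarized as a reliability index RI_j = mean_i(b_j^(i)) / std_i(b_j^(i)),
   keeping bands with |RI| >= threshold (default 1.0);
4. PLS with the component count chosen by leave-one-out cross validation.

Model quality is reported as R^2 = 1 - SSE/SST, RMSE = sqrt(SSE/n), and
RPD = std(reference) / RMSE graded good (> 2), middle (1.4-2), poor (< 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression

from .cube import BinaryMask, SpectralCube
from .errors import (
    BadComponents,
    DegenerateMetric,
    DegenerateTarget,
    EmptyMask,
    ShapeMismatch,
    TooFewSamples,
)

__all__ = [
    "SpectraTable",
    "PlsModel",
    "UveResult",
    "ModelMetrics",
    "extract_mean_reflectance",
    "spxy_split",
    "pls_fit",
    "pls_select_components",
    "uve_select",
    "evaluate",
]


@dataclass
class SpectraTable:
    """Per-sample mean reflectance vectors with SPAD reference values.

    CSV form: columns ``sample_id, spad, stage`` followed by one column per
    wavelength (header = nm).
    """

    ids: list[str]
    X: np.ndarray  # n x B reflectance
    y: np.ndarray  # n SPAD values
    wavelengths: tuple[float, ...]
    stage: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be n x B with one row per sample id")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("X columns must match wavelengths")
        if len(self.y) != len(self.ids):
            raise ValueError("y must have one entry per sample")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("SPAD values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "SpectraTable":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return SpectraTable(
            ids=list(ids),
            X=self.X[rows],
            y=self.y[rows],
            wavelengths=self.wavelengths,
            stage=[self.stage[i] for i in rows] if self.stage else None,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.ids)
        df.insert(1, "spad", self.y)
        df.insert(2, "stage", self.stage if self.stage else "")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = [c for c in ("sample_id", "spad", "stage") if c in df.columns]
        wl_cols = [c for c in df.columns if c not in meta]
        stage = df["stage"].astype(str).tolist() if "stage" in df.columns else None
        return cls(
            ids=df["sample_id"].astype(str).tolist(),
            X=df[wl_cols].to_numpy(dtype=float),
            y=df["spad"].to_numpy(dtype=float),
            wavelengths=tuple(float(c) for c in wl_cols),
            stage=stage,
        )


@dataclass
class PlsModel:
    """Collapsed PLS1 model: prediction = y_mean + (x - x_mean) . coefficients."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    training_wavelengths: tuple[float, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.coefficients


@dataclass
class UveResult:
    """Reliability indices per wavelength and the retained subset."""

    reliability_index: np.ndarray
    threshold: float
    selected_indices: np.ndarray
    selected_wavelengths: tuple[float, ...] = field(default_factory=tuple)


@dataclass
class ModelMetrics:
    """Eq.-style model quality: R^2, RMSE (SPAD units), RPD, and grade."""

    r2: float
    rmse: float
    rpd: float
    n: int
    grade: str


def extract_mean_reflectance(cube: SpectralCube, mask: BinaryMask) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over mask==1 pixels."""
    if mask.shape != cube.shape:
        raise ShapeMismatch(f"mask {mask.shape} vs cube {cube.shape}")
    sel = mask.data.astype(bool)
    if not sel.any():
        raise EmptyMask("mask has no foreground pixels")
    return cube.data[sel].astype(float).mean(axis=0)


def _spxy_distances(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    d = np.zeros_like(dx)
    if dx_max > 0:
        d += dx / dx_max
    if dy_max > 0:
        d += dy / dy_max
    return d


def spxy_split(
    table: SpectraTable, ratio: tuple[int, int] = (2, 1)
) -> tuple[list[str], list[str]]:
    """Deterministic calibration/validation split by joint X-Y distance.

    Seeds the calibration set with the pair of maximal joint distance
    (normalized Euclidean X-distance + normalized |dy|), then greedily adds
    the sample farthest (max-min) from the chosen set until the calibration
    size reaches ``ceil(n * cal / (cal + val))``. Ties resolve to the lowest
    sample index, so the split is permutation-stable up to exact ties.
    """
    cal_w, val_w = ratio
    if cal_w <= 0 or val_w <= 0:
        raise ValueError("ratio parts must be positive")
    n = table.n_samples
    if n < 3:
        raise TooFewSamples(f"need at least 3 samples, got {n}")
    n_cal = int(np.ceil(n * cal_w / (cal_w + val_w)))
    n_cal = min(max(n_cal, 2), n - 1)  # keep both sets non-empty

    d = _spxy_distances(table.X, table.y)
    i, j = np.unravel_index(np.argmax(d), d.shape)  # first maximizer in raster order
    chosen = [int(min(i, j)), int(max(i, j))]
    remaining = [k for k in range(n) if k not in chosen]
    min_d = d[remaining][:, chosen].min(axis=1)
    while len(chosen) < n_cal:
        pick_pos = int(np.argmax(min_d))
        pick = remaining.pop(pick_pos)
        chosen.append(pick)
        min_d = np.delete(min_d, pick_pos)
        if remaining:
            min_d = np.minimum(min_d, d[remaining, pick])
    cal_ids = [table.ids[k] for k in sorted(chosen)]
    val_ids = [table.ids[k] for k in sorted(remaining)]
    return cal_ids, val_ids


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be n x p with len(y) == n")
    return X, y


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    wavelengths: tuple[float, ...] | None = None,
    scale: bool = False,
) -> PlsModel:
    """Mean-centered PLS1 (NIPALS); ``scale=True`` adds unit-variance scaling.

    Reflectance bands share a common scale, so centering without
    autoscaling is the default.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 2:
        raise TooFewSamples(f"need at least 2 samples, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateTarget("y has zero variance")
    if not (1 <= n_components <= min(n - 1, p)):
        raise BadComponents(
            f"n_components={n_components} outside [1, {min(n - 1, p)}]"
        )
    pls = PLSRegression(n_components=n_components, scale=scale)
    pls.fit(X, y)
    coef = np.asarray(pls.coef_).reshape(-1)
    if wavelengths is None:
        wavelengths = tuple(float(i) for i in range(p))
    return PlsModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        coefficients=coef,
        training_wavelengths=tuple(wavelengths),
    )


def pls_select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int | None = None,
    scale: bool = False,
) -> tuple[int, np.ndarray]:
    """Leave-one-out RMSECV per component count; best k = argmin (ties: smaller k)."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise TooFewSamples(f"need at least 3 samples for LOO, got {n}")
    k_cap = min(n - 2, p, 15)  # n-2: every LOO fold must support k <= n_fold - 1
    if max_components is not None:
        k_cap = min(k_cap, max_components)
    if k_cap < 1:
        raise BadComponents("no admissible component count")
    sse = np.zeros(k_cap)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        for k in range(1, k_cap + 1):
            model = pls_fit(Xi, yi, k, scale=scale)
            pred = model.predict(X[i : i + 1])[0]
            sse[k - 1] += (pred - y[i]) ** 2
    rmsecv = np.sqrt(sse / n)
    best_k = int(np.argmin(rmsecv)) + 1  # argmin picks the smallest k on ties
    return best_k, rmsecv


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    wavelengths: tuple[float, ...] | None = None,
    threshold: float = 1.0,
    noise_augment: bool = False,
    random_state: int | None = None,
) -> UveResult:
    """Uninformative variable elimination by coefficient stability.

    Jackknife: refit the PLS coefficient vector with each sample left out;
    the reliability index of band j is mean over folds divided by the
    (sample) standard deviation over folds. Bands with ``|RI| >= threshold``
    are retained. A coefficient with zero spread but nonzero mean yields
    RI = +/-inf and is always retained.

    With ``noise_augment=True`` the classic construction is used instead:
    p artificial noise columns of negligible magnitude are appended and the
    cutoff becomes ``max |RI|`` over the noise columns, overriding
    ``threshold``.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise TooFewSamples(f"need at least 3 samples, got {n}")
    X_work = X
    if noise_augment:
        rng = np.random.default_rng(random_state)
        # tiny scale: noise columns probe coefficient stability without
        # perturbing the latent structure
        noise = rng.uniform(0.0, 1.0, size=(n, p)) * 1e-10
        X_work = np.hstack([X, noise])
    p_work = X_work.shape[1]
    k = min(n_components, n - 2, p_work)
    coefs = np.empty((n, p_work))
    for i in range(n):
        keep = np.arange(n) != i
        coefs[i] = pls_fit(X_work[keep], y[keep], k).coefficients
    mean = coefs.mean(axis=0)
    std = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = np.where(std > 0, mean / np.where(std > 0, std, 1.0),
                      np.where(mean != 0, np.inf * np.sign(mean), 0.0))
    ri_real = ri[:p]
    cutoff = float(np.max(np.abs(ri[p:]))) if noise_augment else float(threshold)
    selected = np.flatnonzero(np.abs(ri_real) >= cutoff)
    wl = tuple(wavelengths[int(i)] for i in selected) if wavelengths else ()
    return UveResult(
        reliability_index=ri_real,
        threshold=cutoff,
        selected_indices=selected,
        selected_wavelengths=wl,
    )


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    reference_std: float | None = None,
) -> ModelMetrics:
    """R^2, RMSE, RPD, and grade for a prediction set.

    R^2 = 1 - SSE/SST; RMSE = sqrt(SSE/n); RPD = std(y_true, ddof=1)/RMSE
    (or ``reference_std``/RMSE when a reference deviation is supplied).
    Grade: RPD > 2 good; 1.4 <= RPD <= 2 middle; RPD < 1.4 poor.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ShapeMismatch(f"{len(y_true)} true vs {len(y_pred)} predicted")
    n = len(y_true)
    if n < 2:
        raise TooFewSamples("need at least 2 samples")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise DegenerateTarget("y_true is constant; R^2 undefined")
    sse = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / n))
    if rmse == 0:
        raise DegenerateMetric("RMSE = 0; RPD undefined")
    std = float(reference_std) if reference_std is not None else float(np.std(y_true, ddof=1))
    rpd = std / rmse
    grade = "good" if rpd > 2 else ("middle" if rpd >= 1.4 else "poor")
    return ModelMetrics(r2=r2, rmse=rmse, rpd=rpd, n=n, grade=grade)
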