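"""Reflectance preprocessing chain for hyperspectral cotton scenes.

The chain runs, in order: black/white reflectance correction, spatial
cropping, standardization, multiplicative scatter correction (MSC), and
PCA band reduction. Each stage is exposed both as a cube-level function
and (where it learns state) as a scikit-learn style transformer over the
``(pixels, bands)`` spectral matrix, so stages compose with sklearn
pipelines and can be refit/reused on held-out cubes.

Notes on conventions
--------------------
* Standard deviations are population (``ddof=0``) throughout.
* Divide guards use ``eps = 1e-8``; guarded pixels/bands pass through or
  map to zero with a logged warning rather than producing non-finite output.
* Standardization supports two scopes. ``"band"`` standardizes each band
  across pixels. ``"global"`` uses one scalar mean/sd for the whole cube;
  this is the scope the full chain uses, because band-wise standardization
  makes the cube's mean spectrum identically zero and thereby degenerates
  a subsequent MSC fit against that mean reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import HsiCube, LabelMap

__all__ = [
    "EPS",
    "MscModel",
    "PcaModel",
    "PreprocessConfig",
    "PreprocessResult",
    "BandStandardizer",
    "MultiplicativeScatterCorrection",
    "SpectralPCA",
    "black_white_correct",
    "crop",
    "band_discrimination",
    "standardize",
    "msc",
    "pca_fit",
    "pca_apply",
    "absorbance",
    "preprocess_chain",
]

logger = logging.getLogger(__name__)

EPS = 1e-8


# ---------------------------------------------------------------------------
# fitted-state containers


@dataclass
class MscModel:
    """Fitted multiplicative-scatter-correction state.

    ``mean_spectrum`` is the reference the per-pixel regressions run
    against; ``slopes``/``intercepts`` hold the per-sample affine fit from
    the most recent application.
    """

    mean_spectrum: np.ndarray
    slopes: np.ndarray | None = None
    intercepts: np.ndarray | None = None


@dataclass
class PcaModel:
    """Fitted spectral PCA: orthonormal loadings, full eigenvalue spectrum, center."""

    components: np.ndarray  # (bands, p), orthonormal columns
    eigenvalues: np.ndarray  # length = bands, descending, population covariance
    center: np.ndarray  # per-band mean
    retained: int
    threshold: float | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


# ---------------------------------------------------------------------------
# stage 1: black/white correction


def black_white_correct(raw: HsiCube, dark: HsiCube, white: HsiCube) -> HsiCube:
    """Reflectance calibration ``R = (L - B) / (W - B)`` elementwise.

    ``L`` is the raw cube, ``B`` the dark (shutter-closed) reference and
    ``W`` the white-board reference. Cells where ``|W - B| < eps`` map to 0
    with a logged warning. No clipping is applied; mildly >1 reflectance
    is allowed.
    """
    if raw.shape != dark.shape or raw.shape != white.shape:
        raise ValueError(
            f"raw {raw.shape}, dark {dark.shape} and white {white.shape} cubes must share a shape"
        )
    denom = white.data - dark.data
    bad = np.abs(denom) < EPS
    if bad.any():
        logger.warning("black_white_correct: %d cells with |white - dark| < eps set to 0", int(bad.sum()))
    out = np.where(bad, 0.0, (raw.data - dark.data) / np.where(bad, 1.0, denom))
    return raw.with_data(out)


# ---------------------------------------------------------------------------
# stage 2: cropping and the band-separation analysis used for label making


def crop(
    cube: HsiCube,
    labels: LabelMap | None,
    row_range: tuple,
    col_range: tuple,
) -> tuple:
    """Spatial crop with half-open ``[start, stop)`` ranges; all bands kept.

    The label map, when given, is cropped identically.
    """
    r0, r1 = row_range
    c0, c1 = col_range
    if not (0 <= r0 < r1 <= cube.rows) or not (0 <= c0 < c1 <= cube.cols):
        raise ValueError(
            f"crop ranges rows [{r0},{r1}) cols [{c0},{c1}) invalid for a {cube.rows}x{cube.cols} cube"
        )
    out = cube.with_data(cube.data[r0:r1, c0:c1, :].copy())
    out_labels = None
    if labels is not None:
        labels.check_matches(cube)
        out_labels = LabelMap(labels.labels[r0:r1, c0:c1].copy(), list(labels.class_names))
    return out, out_labels


def band_discrimination(cube: HsiCube, labels: LabelMap) -> tuple:
    """Per-band worst-case class separation, for choosing a labeling band.

    For each band the score is the minimum over class pairs of the absolute
    difference of class-mean reflectance (means over labeled pixels only).
    Returns ``(scores, best_band)`` with ``best_band`` the first maximal band.
    """
    labels.check_matches(cube)
    lab = labels.labels
    classes = np.unique(lab[lab > 0])
    if classes.size < 2:
        raise ValueError("band discrimination needs at least 2 labeled classes")
    X = cube.pixels()
    flat = lab.ravel()
    means = np.stack([X[flat == c].mean(axis=0) for c in classes])  # (C, bands)
    diffs = np.abs(means[:, None, :] - means[None, :, :])  # (C, C, bands)
    iu = np.triu_indices(classes.size, k=1)
    scores = diffs[iu].min(axis=0)
    return scores, int(np.argmax(scores))


# ---------------------------------------------------------------------------
# stage 3: standardization


class BandStandardizer(TransformerMixin, BaseEstimator):
    """Zero-mean unit-sd scaling of spectra (population sd).

    ``scope="band"`` standardizes each band over samples; ``scope="global"``
    uses one scalar mean/sd over the whole matrix. Constant bands (sd < eps)
    map to 0 with a logged warning.
    """

    def __init__(self, scope: str = "band"):
        self.scope = scope

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.scope == "band":
            if X.shape[0] < 2:
                raise ValueError("need at least 2 samples to standardize per band")
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
        elif self.scope == "global":
            self.mean_ = np.asarray(X.mean())
            self.scale_ = np.asarray(X.std())
        else:
            raise ValueError(f"unknown scope '{self.scope}'")
        n_const = int(np.sum(np.atleast_1d(self.scale_) < EPS))
        if n_const:
            logger.warning("standardize: %d constant band(s) map to 0", n_const)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scale = np.where(np.atleast_1d(self.scale_) < EPS, 1.0, np.atleast_1d(self.scale_))
        out = (X - self.mean_) / scale
        mask = np.atleast_1d(self.scale_) < EPS
        if mask.any():
            if self.scope == "band":
                out[:, mask] = 0.0
            else:
                out[:] = 0.0
        return out


def standardize(cube: HsiCube, scope: str = "band") -> tuple:
    """Standardize a cube; returns ``(cube_out, mean, sd)`` (population sd)."""
    sc = BandStandardizer(scope=scope).fit(cube.pixels())
    out = sc.transform(cube.pixels()).reshape(cube.shape)
    return cube.with_data(out), sc.mean_, sc.scale_


# ---------------------------------------------------------------------------
# stage 4: multiplicative scatter correction


def _msc_fit_apply(X: np.ndarray, reference: np.ndarray) -> tuple:
    """Per-row OLS of each spectrum on the reference, then affine inversion."""
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError(f"reference length {ref.shape} does not match band count {X.shape[1]}")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom < EPS:
        logger.warning("msc: reference spectrum has (near-)zero variance; passing input through")
        return X.copy(), np.ones(X.shape[0]), np.zeros(X.shape[0])
    row_mean = X.mean(axis=1)
    slopes = (X - row_mean[:, None]) @ rc / denom
    intercepts = row_mean - slopes * ref.mean()
    degenerate = np.abs(slopes) < EPS
    if degenerate.any():
        logger.warning("msc: %d pixel(s) with |slope| < eps passed through", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, slopes)
    out = (X - np.where(degenerate, 0.0, intercepts)[:, None]) / safe[:, None]
    return out, slopes, intercepts


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC over a ``(samples, bands)`` matrix.

    Each sample spectrum ``Z_i`` is regressed on the reference spectrum
    (ordinary least squares over bands), yielding a multiplicative slope
    ``m_i`` and additive intercept ``b_i``; the corrected spectrum is
    ``(Z_i - b_i) / m_i``, which exactly inverts a noiseless affine
    distortion. The default reference is the fit data's mean spectrum.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("MSC needs at least 2 bands")
        self.reference_ = (
            X.mean(axis=0) if self.reference is None else np.asarray(self.reference, dtype=float)
        )
        if self.reference_.shape != (X.shape[1],):
            raise ValueError("reference length does not match band count")
        return self

    def transform(self, X):
        out, self.slopes_, self.intercepts_ = _msc_fit_apply(np.asarray(X, dtype=float), self.reference_)
        return out


def msc(cube: HsiCube, reference: np.ndarray | None = None) -> tuple:
    """Apply MSC to every pixel spectrum; returns ``(cube_out, MscModel)``."""
    tf = MultiplicativeScatterCorrection(reference=reference).fit(cube.pixels())
    out = tf.transform(cube.pixels())
    model = MscModel(mean_spectrum=tf.reference_, slopes=tf.slopes_, intercepts=tf.intercepts_)
    return cube.with_data(out.reshape(cube.shape)), model


# ---------------------------------------------------------------------------
# stage 5: PCA band reduction


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA over the spectral axis via eigendecomposition of the band covariance.

    Exactly one of ``n_components`` (fixed p) and ``var_threshold`` (smallest
    p whose cumulative explained-variance ratio reaches the threshold) must
    be given. Eigenvalues are those of the population covariance, sorted
    descending; loadings are orthonormal with a deterministic sign convention.
    """

    def __init__(self, n_components: int | None = None, var_threshold: float | None = None):
        self.n_components = n_components
        self.var_threshold = var_threshold

    def fit(self, X, y=None):
        if (self.n_components is None) == (self.var_threshold is None):
            raise ValueError("give exactly one of n_components and var_threshold")
        X = np.asarray(X, dtype=float)
        m, n = X.shape
        self.mean_ = X.mean(axis=0)
        Z = X - self.mean_
        cov = (Z.T @ Z) / m
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        flips = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(n)])
        flips[flips == 0] = 1.0
        evecs = evecs * flips
        if self.n_components is not None:
            p = int(self.n_components)
            if not 1 <= p <= n:
                raise ValueError(f"n_components={p} out of range for {n} bands")
        else:
            b = float(self.var_threshold)
            if not 0 < b <= 1:
                raise ValueError("var_threshold must lie in (0, 1]")
            ratio = np.cumsum(evals) / evals.sum()
            p = int(np.searchsorted(ratio, b - 1e-12) + 1)
            p = min(p, n)
        self.eigenvalues_ = evals
        self.components_ = evecs[:, :p]
        self.n_components_ = p
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"band count {X.shape[1]} does not match the fitted model ({self.mean_.shape[0]})"
            )
        return (X - self.mean_) @ self.components_

    def inverse_transform(self, T):
        return np.asarray(T) @ self.components_.T + self.mean_

    def to_model(self) -> PcaModel:
        return PcaModel(
            components=self.components_,
            eigenvalues=self.eigenvalues_,
            center=self.mean_,
            retained=self.n_components_,
            threshold=self.var_threshold,
        )


def pca_fit(
    cube: HsiCube,
    var_threshold: float | None = None,
    n_components: int | None = None,
) -> PcaModel:
    """Fit spectral PCA on a cube's pooled pixels; returns a :class:`PcaModel`."""
    tf = SpectralPCA(n_components=n_components, var_threshold=var_threshold).fit(cube.pixels())
    return tf.to_model()


def pca_apply(cube: HsiCube, model: PcaModel) -> HsiCube:
    """Project a cube onto the retained principal components (p output bands)."""
    if cube.bands != model.center.shape[0]:
        raise ValueError(f"cube has {cube.bands} bands but model expects {model.center.shape[0]}")
    T = (cube.pixels() - model.center) @ model.components
    out = T.reshape(cube.rows, cube.cols, model.retained)
    return HsiCube(out, np.arange(model.retained, dtype=float), dict(cube.meta))


# ---------------------------------------------------------------------------
# absorbance view


def absorbance(cube: HsiCube, reference: np.ndarray) -> HsiCube:
    """Absorbance ``A = -log10(I / I0)`` against a per-band reference intensity.

    Non-positive intensities are clipped to ``eps`` with a logged warning.
    """
    I0 = np.asarray(reference, dtype=float)
    if I0.shape != (cube.bands,):
        raise ValueError("reference length must equal the band count")
    I = cube.data
    n_bad = int(np.sum(I <= 0)) + int(np.sum(I0 <= 0))
    if n_bad:
        logger.warning("absorbance: %d non-positive intensities clipped to eps", n_bad)
    out = -np.log10(np.clip(I, EPS, None) / np.clip(I0, EPS, None))
    return cube.with_data(out)


# ---------------------------------------------------------------------------
# the full chain


@dataclass
class PreprocessConfig:
    """Which chain stages run, and their parameters. Every stage is skippable."""

    bw_correct: bool = True
    crop_rows: tuple | None = None
    crop_cols: tuple | None = None
    standardize: bool = True
    standardize_scope: str = "global"
    msc: bool = True
    msc_reference: np.ndarray | None = None
    pca: bool = True
    pca_components: int | None = 16
    pca_var_threshold: float | None = None


@dataclass
class PreprocessResult:
    cube: HsiCube
    labels: LabelMap | None
    pca_model: PcaModel | None
    msc_model: MscModel | None
    standardize_stats: tuple | None = None


def preprocess_chain(
    raw: HsiCube,
    dark: HsiCube | None,
    white: HsiCube | None,
    config: PreprocessConfig | None = None,
    labels: LabelMap | None = None,
) -> PreprocessResult:
    """Run the chain: correction -> crop -> standardize -> MSC -> PCA.

    Fitted MSC/PCA state is returned for reuse on held-out cubes.
    """
    cfg = config or PreprocessConfig()
    cube = raw
    out_labels = labels
    stats = None
    msc_model = None
    pca_model = None

    if cfg.bw_correct:
        if dark is None or white is None:
            raise ValueError("black/white correction requires dark and white reference cubes")
        cube = black_white_correct(cube, dark, white)
    if cfg.crop_rows is not None or cfg.crop_cols is not None:
        rr = cfg.crop_rows or (0, cube.rows)
        cc = cfg.crop_cols or (0, cube.cols)
        cube, out_labels = crop(cube, out_labels, rr, cc)
    if cfg.standardize:
        cube, mu, sd = standardize(cube, scope=cfg.standardize_scope)
        stats = (mu, sd)
    if cfg.msc:
        cube, msc_model = msc(cube, reference=cfg.msc_reference)
    if cfg.pca:
        pca_model = pca_fit(
            cube, var_threshold=cfg.pca_var_threshold, n_components=cfg.pca_components
        )
        cube = pca_apply(cube, pca_model)
    return PreprocessResult(cube, out_labels, pca_model, msc_model, stats)
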