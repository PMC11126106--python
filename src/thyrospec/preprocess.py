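"""Radiometric and spectral preprocessing.

Steps, in the default pipeline order: flat-field (whiteboard) correction to
reflectance, Savitzky-Golay smoothing along the spectral axis (window 21,
polynomial order 5), 0-1 min-max normalization, trimming of noisy edge bands,
and PCA spectral reduction.  Per-class spectral envelope statistics (mean /
min / max / smoothed-derivative curves) are computed for exploratory plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from thyrospec.errors import DegenerateReferenceError, EmptyClassError, ShapeError
from thyrospec.hsi_io import CaseRecord, HyperCube

#: reflectance of the calibration whiteboard used at acquisition time
DEFAULT_BOARD_REFLECTANCE = 0.5


def whiteboard_correct(raw: HyperCube, white_ref: HyperCube,
                       dark_ref: HyperCube,
                       rw: float = DEFAULT_BOARD_REFLECTANCE) -> HyperCube:
    """Flat-field correction: ``SC = (S - SD) / (SW - SD) * RW``.

    ``S`` is the raw tissue signal, ``SW`` the whiteboard signal, ``SD`` the
    dark signal and ``RW`` the known whiteboard reflectance.  The references
    must share the cube's band count and broadcast against its shape.

    Raises
    ------
    DegenerateReferenceError
        If ``SW <= SD`` anywhere (location reported).
    """
    if white_ref.n_bands != raw.n_bands or dark_ref.n_bands != raw.n_bands:
        raise ShapeError("reference band counts must match the raw cube")
    s = raw.data.astype(np.float64)
    sw = white_ref.data.astype(np.float64)
    sd = dark_ref.data.astype(np.float64)
    denom = sw - sd
    bad = denom <= 0
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateReferenceError(
            f"white <= dark at {int(bad.sum())} element(s), first at index {idx}"
        )
    sc = (s - sd) / denom * rw
    return HyperCube(sc, raw.wavelengths, bit_depth=raw.bit_depth,
                     units="reflectance")


def savgol_smooth(spectrum: np.ndarray, window: int = 21,
                  polyorder: int = 5, axis: int = -1) -> np.ndarray:
    """Savitzky-Golay smoothing along ``axis``.

    Each output sample is the centre value of the least-squares polynomial of
    degree ``polyorder`` fitted to the surrounding ``window`` samples; at the
    boundaries the polynomial fitted to the terminal window is evaluated
    (interpolation mode), which avoids reflection artefacts on band edges.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if spectrum.shape[axis] < window:
        raise ValueError(
            f"need >= {window} samples along axis, got {spectrum.shape[axis]}"
        )
    return savgol_filter(spectrum, window, polyorder, axis=axis, mode="interp")


def minmax_normalize(values: np.ndarray, scope: str = "per_block") -> np.ndarray:
    """0-1 normalization ``(v - min) / (max - min)`` over the chosen scope.

    Scopes: ``per_block`` (one min/max over the whole array), ``per_spectrum``
    (per pixel, over the last axis), ``per_band`` (per band, over the leading
    axes).  A scope with ``max == min`` maps to all zeros by convention.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("input must be finite")
    if scope == "per_block":
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    if scope == "per_spectrum":
        lo = v.min(axis=-1, keepdims=True)
        hi = v.max(axis=-1, keepdims=True)
    elif scope == "per_band":
        axes = tuple(range(v.ndim - 1))
        lo = v.min(axis=axes, keepdims=True)
        hi = v.max(axis=axes, keepdims=True)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    span = hi - lo
    out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


def trim_bands(cube: HyperCube, n_edge: int = 49) -> HyperCube:
    """Drop the first and last ``n_edge`` noisy edge bands.

    With the acquisition default of 294 bands and ``n_edge=49`` this keeps the
    central 196 bands.
    """
    if n_edge < 0:
        raise ValueError("n_edge must be >= 0")
    if n_edge == 0:
        return cube
    if cube.n_bands <= 2 * n_edge:
        raise ValueError(
            f"trimming {n_edge} bands per edge empties a {cube.n_bands}-band cube"
        )
    sl = slice(n_edge, cube.n_bands - n_edge)
    return HyperCube(cube.data[:, :, sl], cube.wavelengths[sl],
                     bit_depth=cube.bit_depth, units=cube.units)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAProjection:
    """Fitted PCA: column mean plus orthonormal loading rows.

    ``components`` has shape (k, F) with variance-sorted rows; the sign of
    each row is fixed so its largest-magnitude coefficient is positive,
    making fits run-to-run reproducible.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    k: int

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, components=self.components,
                 explained_variance=self.explained_variance, k=self.k)

    @classmethod
    def load(cls, path) -> "PCAProjection":
        z = np.load(path)
        return cls(z["mean"], z["components"], z["explained_variance"],
                   int(z["k"]))


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|coefficient| entry is positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def pca_fit(samples: np.ndarray, k: int) -> PCAProjection:
    """Fit a k-component PCA on an N x F sample matrix.

    Components are the top-k eigenvectors of the sample covariance (ddof=1),
    sorted by decreasing explained variance, with the deterministic sign
    convention of :class:`PCAProjection`.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 2:
        raise ShapeError("samples must be 2-D (N, F)")
    n, f = x.shape
    if not 1 <= k <= min(n, f):
        raise ValueError(f"need N >= k >= 1 and F >= k, got N={n}, F={f}, k={k}")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1][:k]
    comps = _fix_signs(evecs[:, order].T)
    ev = np.clip(evals[order], 0.0, None)
    return PCAProjection(mean=mean, components=comps, explained_variance=ev, k=k)


def pca_apply(proj: PCAProjection, block: np.ndarray) -> np.ndarray:
    """Project every pixel spectrum: ``components @ (spectrum - mean)``.

    Accepts any (..., F) array; spatial layout is unchanged and the last axis
    becomes length k.
    """
    block = np.asarray(block, dtype=float)
    f = proj.components.shape[1]
    if block.shape[-1] != f:
        raise ShapeError(
            f"last axis {block.shape[-1]} != projection feature count {f}"
        )
    return (block - proj.mean) @ proj.components.T


# ---------------------------------------------------------------------------
# Per-class spectral statistics
# ---------------------------------------------------------------------------

@dataclass
class SpectralProfile:
    """Bandwise envelope statistics of sampled pixel spectra for one class."""

    class_label: int
    mean_curve: np.ndarray
    min_curve: np.ndarray
    max_curve: np.ndarray
    derivative_curve: np.ndarray
    wavelengths: np.ndarray
    n_sampled: int

    def to_tsv(self, path) -> None:
        header = "band\twavelength\tmean\tmin\tmax\tderivative"
        rows = np.column_stack([
            np.arange(self.mean_curve.size), self.wavelengths,
            self.mean_curve, self.min_curve, self.max_curve,
            self.derivative_curve,
        ])
        np.savetxt(path, rows, delimiter="\t", header=header, comments="")


def spectral_profile(cases: list[CaseRecord], class_label: int,
                     n_samples: int = 150, seed: int = 0,
                     corrected: bool = True,
                     smooth_window: int = 21,
                     smooth_polyorder: int = 5) -> SpectralProfile:
    """Envelope statistics of randomly sampled pixel spectra of one class.

    Spectra are pooled across cases (flat-field corrected by default),
    sampled without replacement when possible, and summarized bandwise.  The
    derivative curve is the first forward difference of the Savitzky-Golay
    smoothed mean, with the last value repeated to preserve length.
    """
    pools = []
    for case in cases:
        sel = case.mask.labels == class_label
        if not sel.any():
            continue
        if corrected:
            cube = whiteboard_correct(case.cube, case.white_ref, case.dark_ref)
        else:
            cube = case.cube
        pools.append(cube.data[sel].astype(float))
    if not pools:
        raise EmptyClassError(f"no pixels of class {class_label} in any case")
    pool = np.concatenate(pools, axis=0)
    rng = np.random.default_rng(seed)
    if len(pool) >= n_samples:
        idx = rng.choice(len(pool), size=n_samples, replace=False)
    else:
        idx = rng.choice(len(pool), size=n_samples, replace=True)
    sample = pool[idx]
    mean_curve = sample.mean(axis=0)
    if mean_curve.size >= smooth_window:
        smoothed = savgol_smooth(mean_curve, smooth_window, smooth_polyorder)
    else:
        smoothed = mean_curve
    deriv = np.diff(smoothed)
    deriv = np.append(deriv, deriv[-1])
    wl = cases[0].cube.wavelengths
    return SpectralProfile(class_label=class_label, mean_curve=mean_curve,
                           min_curve=sample.min(axis=0),
                           max_curve=sample.max(axis=0),
                           derivative_curve=deriv, wavelengths=wl,
                           n_sampled=n_samples)
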