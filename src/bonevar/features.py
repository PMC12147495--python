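"""Featurization: spectral band intensities, LBP texture, GMM imputation.

Spectra (FT-IR intensity vs wavenumber, XRD intensity vs 2-theta) are
reduced to intensities at characteristic band positions — for
calcium-phosphate ceramics these are the phosphate bands of
hydroxyapatite and beta-TCP, supplied as configuration since they depend
on the instrument and phases at hand. Images are reduced to the 256-bin
histogram of local binary pattern (LBP) codes: each interior pixel is
coded by thresholding its 8 neighbour-minus-centre luminance differences
and reading the bits as one byte, so the code depends only on relative
luminance, not absolute brightness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

__all__ = [
    "BandList",
    "select_band_intensities",
    "compute_lbp_codes",
    "lbp_histogram",
    "impute_missing",
]


class BandOutOfRangeError(ValueError):
    """A requested band position has no axis point within its window."""


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. an all-missing column)."""


@dataclass(frozen=True)
class BandList:
    """Band positions (wavenumber cm^-1 or 2-theta degrees) + half-width.

    ``window`` is the half-width of the averaging interval in axis units;
    0 means "intensity at the nearest axis point".
    """

    positions: tuple[float, ...]
    window: float = 0.0

    def __init__(self, positions: Sequence[float], window: float = 0.0) -> None:
        object.__setattr__(self, "positions", tuple(float(p) for p in positions))
        object.__setattr__(self, "window", float(window))
        if not all(np.isfinite(self.positions)):
            raise ValueError("band positions must be finite")
        if self.window < 0:
            raise ValueError("window must be >= 0")


def select_band_intensities(
    axis: np.ndarray, intensity: np.ndarray, bands: BandList
) -> np.ndarray:
    """Extract one feature per band from a (axis, intensity) trace.

    For ``window > 0`` the feature is the mean intensity over axis points
    within +/- window of the band position; for ``window == 0`` it is the
    intensity at the nearest axis point. A band with no axis point in
    range raises :class:`BandOutOfRangeError`.
    """
    axis = np.asarray(axis, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if axis.ndim != 1 or axis.shape != intensity.shape:
        raise ValueError("axis and intensity must be 1-D and the same length")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")

    out = np.empty(len(bands.positions))
    for i, pos in enumerate(bands.positions):
        if bands.window == 0:
            if pos < axis[0] or pos > axis[-1]:
                raise BandOutOfRangeError(f"band {pos} outside axis range [{axis[0]}, {axis[-1]}]")
            out[i] = intensity[int(np.argmin(np.abs(axis - pos)))]
        else:
            mask = np.abs(axis - pos) <= bands.window
            if not mask.any():
                raise BandOutOfRangeError(f"no axis point within {bands.window} of band {pos}")
            out[i] = float(intensity[mask].mean())
    return out


# Clockwise neighbour order starting at the top-left pixel; the first
# neighbour contributes the most significant bit of the 8-bit code.
_LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def compute_lbp_codes(image: np.ndarray) -> np.ndarray:
    """LBP code matrix for a grayscale image, interior pixels only.

    Each neighbour-minus-centre difference is binarised with a >= 0 tie
    rule (so a constant image codes to 255 everywhere), read clockwise
    from the top-left neighbour as the most significant bit, and packed
    into a decimal code in [0, 255]. Output shape is (H-2, W-2).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be a 2-D array of at least 3x3 pixels")
    centre = image[1:-1, 1:-1]
    codes = np.zeros(centre.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        neigh = image[1 + dr : image.shape[0] - 1 + dr, 1 + dc : image.shape[1] - 1 + dc]
        codes |= ((neigh - centre) >= 0).astype(np.int64) << (7 - bit)
    return codes


def lbp_histogram(codes: np.ndarray, normalize: bool = True) -> np.ndarray:
    """256-bin histogram of LBP codes; sums to 1 when normalized."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty code matrix")
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    if normalize:
        hist /= codes.size
    return hist


def _conditional_mean(gmm: GaussianMixture, x: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """E[x_miss | x_obs] under a fitted full-covariance Gaussian mixture."""
    obs = ~miss
    log_resp = np.empty(gmm.n_components)
    cond_means = np.empty((gmm.n_components, int(miss.sum())))
    for k in range(gmm.n_components):
        mu = gmm.means_[k]
        cov = gmm.covariances_[k]
        c_oo = cov[np.ix_(obs, obs)]
        c_mo = cov[np.ix_(miss, obs)]
        diff = x[obs] - mu[obs]
        sol = np.linalg.solve(c_oo, diff)
        cond_means[k] = mu[miss] + c_mo @ sol
        log_resp[k] = np.log(gmm.weights_[k] + 1e-300) + multivariate_normal.logpdf(
            x[obs], mean=mu[obs], cov=c_oo, allow_singular=True
        )
    log_resp -= log_resp.max()
    resp = np.exp(log_resp)
    resp /= resp.sum()
    return resp @ cond_means


def impute_missing(
    table,
    n_components: int = 1,
    max_iter: int = 20,
    seed: int = 0,
    tol: float = 1e-3,
):
    """Fill missing feature values by iterative GMM conditional means.

    Missing cells are initialised with column means; a full-covariance
    Gaussian mixture is then fitted to the completed matrix and each
    missing cell replaced by its conditional mean given the row's
    observed cells, iterating until the largest per-cell change falls
    below ``tol`` or ``max_iter`` rounds. Observed cells are never
    touched. Returns a new table of the same type.
    """
    from .data import FeatureTable  # local import to avoid a cycle

    X = np.array(table.matrix, dtype=float)
    miss_mask = np.isnan(X)
    if not miss_mask.any():
        return FeatureTable(list(table.material_ids), X, list(table.column_names))
    if miss_mask.all(axis=0).any():
        bad = [table.column_names[j] for j in np.where(miss_mask.all(axis=0))[0]]
        raise ImputationError(f"columns entirely missing: {bad}")
    complete_rows = int((~miss_mask.any(axis=1)).sum())
    if complete_rows == 0:
        raise ImputationError("no complete row to anchor the imputation")
    if n_components > complete_rows:
        raise ImputationError(
            f"n_components={n_components} exceeds the {complete_rows} complete rows"
        )

    col_means = np.nanmean(X, axis=0)
    X_filled = np.where(miss_mask, col_means, X)

    for _ in range(max_iter):
        gmm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            reg_covar=1e-6,
            random_state=seed,
            max_iter=200,
        ).fit(X_filled)
        X_new = X_filled.copy()
        for i in np.where(miss_mask.any(axis=1))[0]:
            X_new[i, miss_mask[i]] = _conditional_mean(gmm, X_filled[i], miss_mask[i])
        delta = np.max(np.abs(X_new[miss_mask] - X_filled[miss_mask]))
        X_filled = X_new
        if delta < tol:
            break

    return FeatureTable(list(table.material_ids), X_filled, list(table.column_names))
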