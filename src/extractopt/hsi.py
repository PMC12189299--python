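"""SWIR hyperspectral processing chain for bread shelf-life monitoring.

The chain mirrors the standard push-broom workflow: (1) reflectance
calibration against white and dark references, I = (I_raw - I_dark) /
(I_white - I_dark); (2) background removal by thresholding the first
principal-component score image of the pixel spectra; (3) Savitzky-Golay
first-derivative smoothing (second-degree polynomial, seven-point window);
(4) per-sample mean spectra; (5) PCA of the mean spectra across storage
times, in which mold growth shows up as a separation of the late-storage
spectra from the fresh ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu

from .exceptions import DegenerateReferenceError, NoContrastError, ValidationError

__all__ = [
    "HyperCube",
    "SpectrumSet",
    "PcaResult",
    "correct_reflectance",
    "segment_foreground",
    "sg_first_derivative",
    "mean_spectrum",
    "pca_spectra",
]


@dataclass
class HyperCube:
    """A wavelength-indexed reflectance (or raw-intensity) image cube.

    ``data`` is (rows, cols, bands); ``wavelengths`` is the strictly
    increasing per-band axis in nm.  ``white_ref``/``dark_ref`` may be
    per-band vectors or full frames broadcastable against ``data``.
    Corrected reflectance typically lies in [0, ~1.2]; values outside are
    logged (warning), never clipped.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    white_ref: np.ndarray | None = None
    dark_ref: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"cube must be (rows, cols, bands), got {self.data.shape}")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValidationError(
                f"band count {self.data.shape[2]} != wavelength count {len(self.wavelengths)}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixel_spectra(self) -> np.ndarray:
        """(n_pixels, bands) view of the cube."""
        return self.data.reshape(-1, self.data.shape[2])


@dataclass(frozen=True)
class SpectrumSet:
    """Labeled spectra on one shared wavelength axis.

    ``provenance`` records preprocessing: ``"raw"`` or ``"sg_derivative"``.
    """

    wavelengths: np.ndarray
    spectra: dict[str, np.ndarray]
    provenance: str = "raw"
    labels: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        clean = {}
        for key, spec in self.spectra.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != wl.shape:
                raise ValidationError(
                    f"spectrum {key!r} has {spec.shape[0]} bands, axis has {len(wl)}"
                )
            clean[key] = spec
        object.__setattr__(self, "spectra", clean)

    def matrix(self) -> tuple[list[str], np.ndarray]:
        keys = list(self.spectra)
        return keys, np.vstack([self.spectra[k] for k in keys])


@dataclass(frozen=True)
class PcaResult:
    """Mean-centered PCA via singular value decomposition.

    Component signs are fixed so the largest-magnitude loading in each
    component is positive, making results deterministic.
    """

    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_bands, n_components), orthonormal columns
    explained_variance_pct: np.ndarray
    mean: np.ndarray


def correct_reflectance(raw: HyperCube, white=None, dark=None) -> HyperCube:
    """Calibrate raw intensities to reflectance: (raw - dark) / (white - dark).

    ``white``/``dark`` default to the references carried by the cube.  Any
    band where the white and dark references coincide is reported in a
    :class:`DegenerateReferenceError`.
    """
    white = raw.white_ref if white is None else np.asarray(white, dtype=float)
    dark = raw.dark_ref if dark is None else np.asarray(dark, dtype=float)
    if white is None or dark is None:
        raise ValidationError("white and dark references are required")
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    denom = white - dark
    zero = np.asarray(denom == 0).reshape(-1, raw.data.shape[2])
    degenerate = np.where(zero.any(axis=0))[0]
    if degenerate.size:
        raise DegenerateReferenceError(degenerate.tolist())
    corrected = (raw.data - dark) / denom
    out_of_range = np.mean((corrected < 0) | (corrected > 1.2))
    if out_of_range > 0.01:
        warnings.warn(
            f"{100 * out_of_range:.1f}% of corrected reflectances outside [0, 1.2]",
            stacklevel=2,
        )
    return HyperCube(
        data=corrected,
        wavelengths=raw.wavelengths,
        white_ref=white,
        dark_ref=dark,
        corrected=True,
    )


def segment_foreground(cube: HyperCube, foreground: str = "minority") -> np.ndarray:
    """Boolean foreground mask from PCA of the pixel spectra.

    The first principal-component score image is thresholded with Otsu's
    criterion.  Both polarities of the split are considered; ``foreground``
    selects which side is kept: ``"minority"`` (default; the sample usually
    covers fewer pixels than the background), ``"majority"``, ``"high"``
    (scores above threshold), or ``"low"``.
    """
    spectra = cube.pixel_spectra()
    centered = spectra - spectra.mean(axis=0)
    total_var = float(np.sum(centered**2))
    if total_var < 1e-12 * max(1.0, float(np.sum(spectra**2))):
        raise NoContrastError("all pixel spectra are identical; nothing to segment")
    # PC1 scores via SVD of the centered pixel matrix.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    if np.abs(pc1).max() > 0 and pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    scores = centered @ pc1
    thresh = threshold_otsu(scores)
    high = scores > thresh
    shape = cube.data.shape[:2]
    if foreground == "high":
        mask = high
    elif foreground == "low":
        mask = ~high
    elif foreground == "minority":
        mask = high if high.sum() <= (~high).sum() else ~high
    elif foreground == "majority":
        mask = high if high.sum() > (~high).sum() else ~high
    else:
        raise ValidationError(f"unknown foreground rule {foreground!r}")
    return mask.reshape(shape)


def savgol_derivative(
    values: np.ndarray, window: int = 7, polyorder: int = 2, delta: float = 1.0
) -> np.ndarray:
    """Savitzky-Golay first derivative along the last axis, valid interior only.

    Output drops ``window // 2`` bands at each edge, avoiding fabricated
    edge values.  ``delta`` is the abscissa step (1.0 = per band index).
    """
    if window % 2 == 0:
        raise ValidationError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValidationError(f"polyorder ({polyorder}) must be < window ({window})")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < window:
        raise ValidationError(
            f"need >= {window} bands for a {window}-point window, got {values.shape[-1]}"
        )
    full = savgol_filter(values, window, polyorder, deriv=1, delta=delta, axis=-1)
    half = window // 2
    return full[..., half:-half]


def sg_first_derivative(
    spectra: SpectrumSet, window: int = 7, polyorder: int = 2, scale_wavelength: bool = False
) -> SpectrumSet:
    """Savitzky-Golay first derivative of every spectrum in the set.

    Default parameters are the study's: second-degree polynomial, seven-
    point window.  The derivative is per band index unless
    ``scale_wavelength`` is set, in which case the (uniform) wavelength step
    is used as the abscissa unit.
    """
    wl = spectra.wavelengths
    delta = 1.0
    if scale_wavelength:
        steps = np.diff(wl)
        if not np.allclose(steps, steps[0]):
            raise ValidationError("wavelength scaling requires a uniform axis")
        delta = float(steps[0])
    half = window // 2
    out = {
        key: savgol_derivative(spec, window, polyorder, delta)
        for key, spec in spectra.spectra.items()
    }
    return SpectrumSet(
        wavelengths=wl[half:-half],
        spectra=out,
        provenance="sg_derivative",
        labels=dict(spectra.labels),
    )


def mean_spectrum(cube: HyperCube, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    if mask is None:
        mask = np.ones(cube.data.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValidationError(
            f"mask shape {mask.shape} != spatial shape {cube.data.shape[:2]}"
        )
    if not mask.any():
        raise ValidationError("mask selects no pixels")
    return cube.data[mask].mean(axis=0)


def pca_spectra(spectra, n_components: int = 2) -> PcaResult:
    """Mean-centered PCA of a set of spectra (rows = samples).

    Accepts a :class:`SpectrumSet` or a (samples, bands) array.  If fewer
    informative dimensions than requested are available the result is
    truncated with a warning.  Deterministic: component signs are fixed so
    each component's largest-magnitude loading is positive.
    """
    if isinstance(spectra, SpectrumSet):
        _, X = spectra.matrix()
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 spectra")
    max_rank = min(n_samples - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but rank is at most {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    mean = X.mean(axis=0)
    centered = X - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    # Deterministic sign convention.
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    var = s**2
    total = var.sum()
    explained = 100.0 * var / total if total > 0 else np.zeros_like(var)
    k = n_components
    return PcaResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_pct=explained[:k],
        mean=mean,
    )
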