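"""Synthetic study generators with known ground truth.

Two families of inputs are generated:

* Box-Behnken response datasets: replicate-level responses drawn as
  y = truth(X) + Normal(0, noise_sd), emulating the triplicated 15-run
  extraction experiments.
* SWIR shelf-life hypercube series (default 935-1719 nm at 8 nm, matching
  the imaging range of the study camera): scenes composed of background,
  bread-crumb, and mold endmember spectra, delivered as *raw* intensity
  cubes with matching white/dark reference frames so the reflectance-
  calibration step is exercised.  Mold endmembers carry Gaussian absorption
  features centered near 1150 and 1350 nm, the bands where spoilage shows
  up in derivative spectra.

All randomness flows through a single seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import Design
from .exceptions import ValidationError
from .hsi import HyperCube
from .rsm import QuadraticModel, ResponseTable

__all__ = [
    "SimulationSpec",
    "CubeSpec",
    "ShelfFrame",
    "simulate_bbd_study",
    "simulate_shelf_cubes",
    "default_wavelengths",
    "default_endmembers",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and noise model for a simulated extraction study."""

    truth: QuadraticModel
    noise_sd: float = 0.0
    n_rep: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_rep < 1:
            raise ValidationError("n_rep must be >= 1")


def simulate_bbd_study(spec: SimulationSpec, design: Design) -> ResponseTable:
    """Replicate-level responses from the truth model plus i.i.d. Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    truth_vals = spec.truth.predict(design.uncoded, warn_extrapolation=False)
    replicates = {}
    for rid, mu in zip(design.run_ids, truth_vals):
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_rep) if spec.noise_sd > 0 else np.zeros(spec.n_rep)
        replicates[int(rid)] = mu + noise
    return ResponseTable.from_replicates(replicates, response_name=spec.truth.response_name or "simulated")


def default_wavelengths() -> np.ndarray:
    """SWIR axis: 935-1719 nm at 8 nm resolution (99 bands)."""
    return np.arange(935.0, 1720.0, 8.0)


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_endmembers(wavelengths: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Smooth synthetic reflectance endmembers for background, crumb, and mold.

    These are geometric stand-ins, not measured bread spectra: what matters
    for the pipeline tests is that they are smooth, mutually distinct, and
    that the mold spectrum differs from crumb chiefly through absorption
    features centered near 1150 and 1350 nm.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    background = 0.12 + 0.05 * t  # dark, nearly flat tray/plate
    crumb = (
        0.62
        - 0.10 * t
        - 0.18 * _gaussian(wl, 1450.0, 60.0)  # water/starch absorption
        - 0.06 * _gaussian(wl, 1200.0, 80.0)
    )
    mold = crumb - 0.16 * _gaussian(wl, 1150.0, 30.0) - 0.14 * _gaussian(wl, 1350.0, 30.0)
    return {"background": background, "crumb": crumb, "mold": mold}


@dataclass(frozen=True)
class CubeSpec:
    """Scene layout and noise model for simulated shelf-life cubes.

    ``mold_fraction`` maps time label -> fraction of *bread* pixels bearing
    mold at that acquisition.  ``noise_sd`` is i.i.d. Gaussian noise on the
    reflectance scale; at typical crumb reflectance ~0.5 the default 0.025
    corresponds to a signal-to-noise ratio of about 20.
    """

    shape: tuple[int, int] = (64, 64)
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    endmembers: dict[str, np.ndarray] | None = None
    mold_fraction: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.0, "T2": 0.0, "T3": 0.0, "T4": 0.10}
    )
    noise_sd: float = 0.025
    seed: int = 0

    def __post_init__(self):
        for t, f in self.mold_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"mold_fraction[{t!r}] = {f} outside [0, 1]")
        em = self.endmembers or default_endmembers(self.wavelengths)
        names = list(em)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = np.corrcoef(em[names[i]], em[names[j]])[0, 1]
                if r > 0.999:
                    raise ValidationError(
                        f"endmembers {names[i]!r} and {names[j]!r} are not distinct "
                        f"(correlation {r:.5f})"
                    )
        object.__setattr__(self, "endmembers", em)


@dataclass(frozen=True)
class ShelfFrame:
    """One simulated acquisition: raw cube plus ground truth."""

    time: str
    cube: HyperCube  # raw intensities, with white/dark references attached
    truth_foreground: np.ndarray  # bread pixels
    truth_mold: np.ndarray  # mold pixels (subset of foreground)
    mold_fraction: float


def _bread_mask(shape: tuple[int, int]) -> np.ndarray:
    """Elliptical 'bread slice' occupying the center ~30% of the frame."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - h / 2) / (0.38 * h)) ** 2 + ((xx - w / 2) / (0.38 * w)) ** 2 <= 1.0


def simulate_shelf_cubes(spec: CubeSpec, times=("T1", "T2", "T3", "T4")) -> list[ShelfFrame]:
    """Simulate a storage series of raw SWIR cubes with ground-truth masks.

    Mold pixels are drawn (per time, reproducibly from the seed) only where
    ``mold_fraction`` is positive, and only inside the bread region.  The
    returned cubes are raw intensities I_raw = I_dark + R * (I_white -
    I_dark) with noise added on the reflectance scale, so running the
    calibration step recovers R + noise.
    """
    wl = np.asarray(spec.wavelengths, dtype=float)
    b = len(wl)
    em = spec.endmembers
    for needed in ("background", "crumb", "mold"):
        if needed not in em:
            raise ValidationError(f"endmembers must define {needed!r}")

    # Smooth, slightly sloped references typical of halogen illumination.
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    white = 0.90 + 0.05 * np.sin(np.pi * t)
    dark = np.full(b, 0.04)

    foreground = _bread_mask(spec.shape)
    fg_idx = np.flatnonzero(foreground.ravel())

    frames = []
    rng = np.random.default_rng(spec.seed)
    for time in times:
        frac = float(spec.mold_fraction.get(time, 0.0))
        scene = np.empty((spec.shape[0] * spec.shape[1], b))
        scene[:] = em["background"]
        scene[fg_idx] = em["crumb"]
        mold_mask = np.zeros(spec.shape[0] * spec.shape[1], dtype=bool)
        if frac > 0:
            n_mold = int(round(frac * len(fg_idx)))
            chosen = rng.choice(fg_idx, size=n_mold, replace=False)
            scene[chosen] = em["mold"]
            mold_mask[chosen] = True
        if spec.noise_sd > 0:
            scene = scene + rng.normal(0.0, spec.noise_sd, size=scene.shape)
        reflectance = scene.reshape(spec.shape[0], spec.shape[1], b)
        raw = dark + reflectance * (white - dark)
        cube = HyperCube(
            data=raw, wavelengths=wl, white_ref=white, dark_ref=dark, corrected=False
        )
        frames.append(
            ShelfFrame(
                time=time,
                cube=cube,
                truth_foreground=foreground.copy(),
                truth_mold=mold_mask.reshape(spec.shape),
                mold_fraction=frac,
            )
        )
    return frames
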