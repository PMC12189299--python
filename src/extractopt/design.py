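"""Three-factor Box-Behnken design generation and factor coding.

A Box-Behnken design (BBD) for three factors places runs at the midpoints of
the edges of the factor cube (all +/-1, +/-1, 0 permutations, 12 runs) plus
replicated center points.  Factors are coded affinely so that the low,
center, and high physical levels map to -1, 0, +1.

The default factors are those of the ultrasound-assisted extraction study
this package reproduces: ethanol fraction of the solvent (50-80 % v/v),
extraction time (40-60 min), and extraction temperature (70-80 degC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UnsupportedDesignError, ValidationError

__all__ = [
    "FactorSpec",
    "Run",
    "Design",
    "default_factors",
    "build_box_behnken",
    "code_level",
    "decode_level",
    "model_matrix",
    "TERM_NAMES",
]

#: Column order of the full second-order model matrix.
TERM_NAMES = (
    "Intercept",
    "X1",
    "X2",
    "X3",
    "X1^2",
    "X2^2",
    "X3^2",
    "X1X2",
    "X1X3",
    "X2X3",
)

# Edge-midpoint runs in the canonical block order: (X1,X2) block, (X1,X3)
# block, (X2,X3) block.  Center runs are appended last.
_EDGE_RUNS = (
    (-1, -1, 0),
    (1, -1, 0),
    (-1, 1, 0),
    (1, 1, 0),
    (-1, 0, -1),
    (1, 0, -1),
    (-1, 0, 1),
    (1, 0, 1),
    (0, -1, -1),
    (0, 1, -1),
    (0, -1, 1),
    (0, 1, 1),
)


@dataclass(frozen=True)
class FactorSpec:
    """A three-level factor with physical low/high anchors.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"ethanol"``.
    low, high : float
        Physical values at coded -1 and +1.  ``low < high`` is required.
    units : str
        Unit text for display, e.g. ``"% v/v"``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValidationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def default_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The ultrasound-assisted extraction study factors."""
    return (
        FactorSpec("ethanol", 50.0, 80.0, "% v/v"),
        FactorSpec("time", 40.0, 60.0, "min"),
        FactorSpec("temperature", 70.0, 80.0, "degC"),
    )


def code_level(factor: FactorSpec, physical) -> np.ndarray | float:
    """Map physical values to coded units: ``(x - center) / half_range``.

    Values outside [low, high] are allowed (extrapolation) and simply code
    beyond +/-1.
    """
    if factor.half_range == 0:
        raise ValidationError(f"factor {factor.name!r} has zero half-range")
    x = np.asarray(physical, dtype=float)
    coded = (x - factor.center) / factor.half_range
    return coded if coded.ndim else float(coded)


def decode_level(factor: FactorSpec, coded) -> np.ndarray | float:
    """Inverse of :func:`code_level`: ``center + code * half_range``."""
    if factor.half_range == 0:
        raise ValidationError(f"factor {factor.name!r} has zero half-range")
    z = np.asarray(coded, dtype=float)
    x = factor.center + z * factor.half_range
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class Run:
    run_id: int
    coded: tuple[float, float, float]
    uncoded: tuple[float, float, float]
    is_center: bool


@dataclass(frozen=True)
class Design:
    """An ordered Box-Behnken design: 12 edge runs then center replicates."""

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    runs: tuple[Run, ...]
    n_center: int = field(default=3)

    @property
    def run_ids(self) -> np.ndarray:
        return np.array([r.run_id for r in self.runs], dtype=int)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, 3) array of coded levels."""
        return np.array([r.coded for r in self.runs], dtype=float)

    @property
    def uncoded(self) -> np.ndarray:
        """(n_runs, 3) array of physical levels."""
        return np.array([r.uncoded for r in self.runs], dtype=float)

    def __len__(self) -> int:
        return len(self.runs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with coded and physical columns."""
        coded = self.coded
        uncoded = self.uncoded
        return pd.DataFrame(
            {
                "run": self.run_ids,
                "x1_coded": coded[:, 0],
                "x2_coded": coded[:, 1],
                "x3_coded": coded[:, 2],
                "X1": uncoded[:, 0],
                "X2": uncoded[:, 1],
                "X3": uncoded[:, 2],
                "is_center": [r.is_center for r in self.runs],
            }
        )


def build_box_behnken(factors, n_center: int = 3) -> Design:
    """Build the 3-factor Box-Behnken design: 12 edge runs + ``n_center`` centers.

    Run ordering is the canonical block order (X1X2 block, X1X3 block, X2X3
    block, then centers), matching the layout this study reports; run order
    randomization is not modeled.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only 3-factor Box-Behnken designs are supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise ValidationError(f"n_center must be >= 1, got {n_center}")

    runs = []
    for i, coded in enumerate(_EDGE_RUNS, start=1):
        uncoded = tuple(decode_level(f, c) for f, c in zip(factors, coded))
        runs.append(Run(i, tuple(float(c) for c in coded), uncoded, False))
    center_uncoded = tuple(f.center for f in factors)
    for j in range(n_center):
        runs.append(Run(13 + j, (0.0, 0.0, 0.0), center_uncoded, True))
    return Design(factors=factors, runs=tuple(runs), n_center=n_center)


def model_matrix(points: np.ndarray) -> np.ndarray:
    """Full second-order model matrix for 3 factors.

    Columns follow :data:`TERM_NAMES`: intercept, linear, pure quadratic,
    pairwise interactions.

    Parameters
    ----------
    points : (n, 3) array
        Factor settings (coded or physical; the matrix is built verbatim).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) points, got shape {pts.shape}")
    x1, x2, x3 = pts[:, 0], pts[:, 1], pts[:, 2]
    return np.column_stack(
        [
            np.ones(len(pts)),
            x1,
            x2,
            x3,
            x1**2,
            x2**2,
            x3**2,
            x1 * x2,
            x1 * x3,
            x2 * x3,
        ]
    )
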