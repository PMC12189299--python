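"""Second-order response-surface model fitting.

The response (total phenolic compounds, TPC, in mg GAE 100 g-1 FW, or
antioxidant activity, AA, in mg TE 100 g-1 FW) is modeled as a full
ten-term quadratic polynomial in the three process factors:

    Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj + e

Fitting is ordinary least squares on *coded* regressors (levels -1/0/+1),
which keeps the model matrix well conditioned; coefficients are converted
exactly to the uncoded (physical-unit) parameterization for reporting.
When replicate-level data are available, fitting on run means is exact for
balanced replication, so the published mean +/- SD tables suffice to
recover the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .design import TERM_NAMES, Design, FactorSpec, code_level, model_matrix
from .exceptions import AlignmentError, SingularFitError, ValidationError

__all__ = [
    "ResponseTable",
    "QuadraticModel",
    "FitResult",
    "fit_quadratic",
    "predict",
    "uncoded_equation",
]

_INTERACTION_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class ResponseTable:
    """Per-run response summaries, optionally with raw replicates.

    ``means``/``sds``/``n_reps`` are aligned to ``run_ids``.  ``replicates``
    maps run_id -> raw replicate values; when present, their means must agree
    with ``means`` within rounding.
    """

    run_ids: tuple[int, ...]
    means: np.ndarray
    sds: np.ndarray | None = None
    n_reps: np.ndarray | None = None
    replicates: dict[int, np.ndarray] | None = None
    response_name: str = ""

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        if len(self.run_ids) != len(means):
            raise ValidationError("run_ids and means length mismatch")
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValidationError("duplicate run_ids in response table")
        if self.sds is not None:
            sds = np.asarray(self.sds, dtype=float)
            if np.any(sds < 0):
                raise ValidationError("replicate SDs must be >= 0")
            object.__setattr__(self, "sds", sds)
        if self.n_reps is not None:
            n_reps = np.asarray(self.n_reps, dtype=int)
            if np.any(n_reps < 1):
                raise ValidationError("replicate counts must be >= 1")
            object.__setattr__(self, "n_reps", n_reps)
        if self.replicates is not None:
            for rid, vals in self.replicates.items():
                vals = np.asarray(vals, dtype=float)
                i = self.run_ids.index(rid)
                if abs(vals.mean() - means[i]) > 0.5 + 1e-9:
                    raise ValidationError(
                        f"run {rid}: replicate mean {vals.mean():.3f} disagrees "
                        f"with stored mean {means[i]:.3f}"
                    )

    @classmethod
    def from_means(cls, run_ids, means, sds=None, n_reps=None, response_name=""):
        return cls(
            run_ids=tuple(int(r) for r in run_ids),
            means=np.asarray(means, dtype=float),
            sds=None if sds is None else np.asarray(sds, dtype=float),
            n_reps=None if n_reps is None else np.asarray(n_reps, dtype=int),
            response_name=response_name,
        )

    @classmethod
    def from_replicates(cls, replicates: dict[int, np.ndarray], response_name=""):
        run_ids = tuple(sorted(replicates.keys()))
        reps = {int(r): np.asarray(replicates[r], dtype=float) for r in run_ids}
        means = np.array([reps[r].mean() for r in run_ids])
        sds = np.array([reps[r].std(ddof=1) if len(reps[r]) > 1 else 0.0 for r in run_ids])
        n_reps = np.array([len(reps[r]) for r in run_ids])
        return cls(run_ids, means, sds, n_reps, reps, response_name)

    @property
    def has_replicate_info(self) -> bool:
        if self.replicates is not None:
            return True
        return (
            self.sds is not None
            and self.n_reps is not None
            and bool(np.any(self.n_reps >= 2))
        )

    def aligned_to(self, design: Design) -> "ResponseTable":
        """Reorder rows to the design's run order, erroring on mismatch."""
        index = {rid: i for i, rid in enumerate(self.run_ids)}
        missing = [int(r) for r in design.run_ids if r not in index]
        if missing:
            raise AlignmentError(f"responses missing for design runs {missing}")
        order = [index[int(r)] for r in design.run_ids]
        return ResponseTable(
            run_ids=tuple(int(r) for r in design.run_ids),
            means=self.means[order],
            sds=None if self.sds is None else self.sds[order],
            n_reps=None if self.n_reps is None else self.n_reps[order],
            replicates=self.replicates,
            response_name=self.response_name,
        )


@dataclass(frozen=True)
class QuadraticModel:
    """A fitted (or specified) full second-order polynomial in three factors.

    ``coef`` holds the ten coefficients in :data:`~extractopt.design.TERM_NAMES`
    order, in either the coded or the uncoded parameterization.  The two
    parameterizations are related by the exact affine change of variables
    ``x_coded = (X - center) / half_range`` and are interconvertible without
    loss.
    """

    coef: np.ndarray
    parameterization: str  # "coded" | "uncoded"
    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    response_name: str = ""

    def __post_init__(self):
        coef = np.asarray(self.coef, dtype=float)
        if coef.shape != (10,):
            raise ValidationError(f"expected 10 coefficients, got shape {coef.shape}")
        if self.parameterization not in ("coded", "uncoded"):
            raise ValidationError(f"unknown parameterization {self.parameterization!r}")
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "factors", tuple(self.factors))

    # Convenience views of the coefficient blocks.
    @property
    def beta0(self) -> float:
        return float(self.coef[0])

    @property
    def beta_i(self) -> np.ndarray:
        return self.coef[1:4]

    @property
    def beta_ii(self) -> np.ndarray:
        return self.coef[4:7]

    @property
    def beta_ij(self) -> np.ndarray:
        """Interaction coefficients in (X1X2, X1X3, X2X3) order."""
        return self.coef[7:10]

    def predict(self, settings, warn_extrapolation: bool = True):
        """Evaluate the polynomial at physical factor settings.

        ``settings`` is a length-3 sequence or an (n, 3) array of physical
        values.  Settings coding beyond +/-1 trigger an extrapolation warning
        (prediction proceeds).
        """
        pts = np.atleast_2d(np.asarray(settings, dtype=float))
        if pts.shape[1] != 3:
            raise ValidationError(f"expected 3 factor settings, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("factor settings must be finite")
        coded = np.column_stack(
            [code_level(f, pts[:, k]) for k, f in enumerate(self.factors)]
        )
        if warn_extrapolation and np.any(np.abs(coded) > 1 + 1e-9):
            warnings.warn(
                "prediction outside the design region (|coded level| > 1)",
                stacklevel=2,
            )
        X = model_matrix(coded if self.parameterization == "coded" else pts)
        y = X @ self.coef
        return y if np.asarray(settings).ndim == 2 else float(y[0])

    def to_uncoded(self) -> "QuadraticModel":
        if self.parameterization == "uncoded":
            return self
        return replace(
            self, coef=_coded_to_uncoded(self.coef, self.factors), parameterization="uncoded"
        )

    def to_coded(self) -> "QuadraticModel":
        if self.parameterization == "coded":
            return self
        return replace(
            self, coef=_uncoded_to_coded(self.coef, self.factors), parameterization="coded"
        )


def _coded_to_uncoded(b: np.ndarray, factors) -> np.ndarray:
    """Exact change of variables x_coded = (X - c) / h applied to the
    coefficient vector (TERM_NAMES order)."""
    c = np.array([f.center for f in factors])
    h = np.array([f.half_range for f in factors])
    b0, bi, bii = b[0], b[1:4], b[4:7]
    bij = {pair: b[7 + k] for k, pair in enumerate(_INTERACTION_PAIRS)}

    a = np.zeros(10)
    a0 = b0 - np.sum(bi * c / h) + np.sum(bii * c**2 / h**2)
    for (i, j), bv in bij.items():
        a0 += bv * c[i] * c[j] / (h[i] * h[j])
    a[0] = a0
    for i in range(3):
        ai = bi[i] / h[i] - 2.0 * bii[i] * c[i] / h[i] ** 2
        for (p, q), bv in bij.items():
            if p == i:
                ai -= bv * c[q] / (h[p] * h[q])
            elif q == i:
                ai -= bv * c[p] / (h[p] * h[q])
        a[1 + i] = ai
        a[4 + i] = bii[i] / h[i] ** 2
    for k, (i, j) in enumerate(_INTERACTION_PAIRS):
        a[7 + k] = bij[(i, j)] / (h[i] * h[j])
    return a


def _uncoded_to_coded(a: np.ndarray, factors) -> np.ndarray:
    """Inverse change of variables X = c + h * x_coded."""
    c = np.array([f.center for f in factors])
    h = np.array([f.half_range for f in factors])
    a0, ai, aii = a[0], a[1:4], a[4:7]
    aij = {pair: a[7 + k] for k, pair in enumerate(_INTERACTION_PAIRS)}

    b = np.zeros(10)
    b0 = a0 + np.sum(ai * c) + np.sum(aii * c**2)
    for (i, j), av in aij.items():
        b0 += av * c[i] * c[j]
    b[0] = b0
    for i in range(3):
        bi = ai[i] * h[i] + 2.0 * aii[i] * c[i] * h[i]
        for (p, q), av in aij.items():
            if p == i:
                bi += av * c[q] * h[i]
            elif q == i:
                bi += av * c[p] * h[i]
        b[1 + i] = bi
        b[4 + i] = aii[i] * h[i] ** 2
    for k, (i, j) in enumerate(_INTERACTION_PAIRS):
        b[7 + k] = aij[(i, j)] * h[i] * h[j]
    return b


@dataclass(frozen=True)
class FitResult:
    """OLS fit of the quadratic, with per-run diagnostics.

    ``ss_total`` is computed about the grand mean of the data actually
    fitted.  The design and (aligned) response table are retained so the
    ANOVA stage can re-derive sums of squares without re-supplying inputs.
    """

    model: QuadraticModel
    fitted: np.ndarray
    residuals: np.ndarray
    ss_residual: float
    ss_total: float
    design: Design = field(repr=False)
    responses: ResponseTable = field(repr=False)


def fit_quadratic(design: Design, responses: ResponseTable) -> FitResult:
    """Fit the full ten-term quadratic by OLS on coded regressors.

    Fitting is on run means; for balanced replication this yields the same
    coefficient vector as fitting every replicate (the coded model matrix
    rows are simply repeated).  Requires at least 10 distinct runs.
    """
    responses = responses.aligned_to(design)
    if len(design) < 10:
        raise ValidationError(
            f"need >= 10 runs to fit 10 parameters, got {len(design)}"
        )
    X = model_matrix(design.coded)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify collinear columns via the QR diagonal.
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [TERM_NAMES[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SingularFitError(bad or list(TERM_NAMES))
    y = responses.means
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    residuals = y - fitted
    model = QuadraticModel(
        coef=coef,
        parameterization="coded",
        factors=design.factors,
        response_name=responses.response_name,
    )
    return FitResult(
        model=model,
        fitted=fitted,
        residuals=residuals,
        ss_residual=float(residuals @ residuals),
        ss_total=float(np.sum((y - y.mean()) ** 2)),
        design=design,
        responses=responses,
    )


def predict(model: QuadraticModel, settings, **kwargs):
    """Functional alias for :meth:`QuadraticModel.predict`."""
    return model.predict(settings, **kwargs)


def uncoded_equation(model: QuadraticModel, ndigits: int = 2) -> tuple[pd.Series, str]:
    """Uncoded coefficients rounded for display, plus a text rendering.

    All ten terms are always reported; near-zero coefficients stay visible
    rather than being dropped from the rendering.  Rounding is half away
    from zero, the convention of the published equations.
    """
    uncoded = model.to_uncoded()
    rounded = pd.Series(
        [round_half_away(v, ndigits) for v in uncoded.coef], index=list(TERM_NAMES)
    )
    parts = [f"{rounded['Intercept']:+.{ndigits}f}"]
    for name in TERM_NAMES[1:]:
        parts.append(f"{rounded[name]:+.{ndigits}f}*{name}")
    lhs = model.response_name or "Y"
    text = f"{lhs} = " + " ".join(parts)
    return rounded, text
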