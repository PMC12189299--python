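"""Variance decomposition for the fitted second-order model.

Per-term sums of squares are partial (drop-one-term): each term's SS is the
increase in residual SS when that term alone is removed from the full
ten-term model, computed on coded regressors.  The residual is split into
lack of fit (run means vs. model) and pure error (within-run replication)
whenever replicate information is available -- either raw replicate values
or the published mean +/- SD summaries, for which the within-run sum of
squares is recovered exactly as sum (n_i - 1) * sd_i^2.

The table can be computed at two granularities, following the data actually
supplied: 15 run means (residual df = 5, no pure-error split unless
summaries carry SDs) or the full replicate-level layout (n = sum n_i
observations).  For balanced replication the replicate-level term SS are
the mean-level SS scaled by the replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TERM_NAMES, model_matrix
from .exceptions import ValidationError
from .rsm import FitResult, ResponseTable

__all__ = ["AnovaTable", "anova_decomposition", "lack_of_fit"]

_EFFECT_TERMS = TERM_NAMES[1:]  # the nine non-intercept terms


@dataclass(frozen=True)
class AnovaTable:
    """Sums of squares, F tests, and goodness-of-fit summaries."""

    terms: pd.DataFrame  # index: term name; columns: ss, df, F, p_value
    residual_ss: float
    residual_df: int
    total_ss: float
    total_df: int
    r2: float
    r2_adj: float
    granularity: str  # "means" | "replicates"
    lof_ss: float | None = None
    lof_df: int | None = None
    pure_error_ss: float | None = None
    pure_error_df: int | None = None
    lof_F: float | None = None
    lof_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Render in the conventional row order: the nine effect terms,
        Residual, Lack of fit, Pure error, Total."""
        rows = [
            {
                "term": t,
                "ss": self.terms.loc[t, "ss"],
                "df": self.terms.loc[t, "df"],
                "F": self.terms.loc[t, "F"],
                "p_value": self.terms.loc[t, "p_value"],
            }
            for t in _EFFECT_TERMS
        ]
        rows.append(
            {"term": "Residual", "ss": self.residual_ss, "df": self.residual_df,
             "F": np.nan, "p_value": np.nan}
        )
        if self.lof_ss is not None:
            rows.append(
                {"term": "Lack of fit", "ss": self.lof_ss, "df": self.lof_df,
                 "F": self.lof_F, "p_value": self.lof_p}
            )
            rows.append(
                {"term": "Pure error", "ss": self.pure_error_ss,
                 "df": self.pure_error_df, "F": np.nan, "p_value": np.nan}
            )
        rows.append(
            {"term": "Total", "ss": self.total_ss, "df": self.total_df,
             "F": np.nan, "p_value": np.nan}
        )
        return pd.DataFrame(rows).set_index("term")


def _pure_error(responses: ResponseTable):
    """Within-run SS and df, from raw replicates when present else from
    the mean +/- SD summaries."""
    if responses.replicates is not None:
        ss = 0.0
        df = 0
        for rid in responses.run_ids:
            vals = np.asarray(responses.replicates[rid], dtype=float)
            ss += float(np.sum((vals - vals.mean()) ** 2))
            df += len(vals) - 1
        return ss, df
    if responses.sds is None or responses.n_reps is None:
        return None, None
    n = responses.n_reps
    ss = float(np.sum((n - 1) * responses.sds**2))
    df = int(np.sum(n - 1))
    return ss, df


def anova_decomposition(fit: FitResult) -> AnovaTable:
    """Full ANOVA for a fitted quadratic.

    Granularity follows the response table: replicate information present
    (raw values, or SDs with n_rep >= 2) gives the replicate-level table
    with the lack-of-fit / pure-error split; otherwise the table is at run-
    mean granularity.
    """
    design, responses = fit.design, fit.responses
    X = model_matrix(design.coded)
    y = responses.means
    n_runs = len(y)
    sse_full_means = fit.ss_residual

    # Drop-one-term residual SS, by explicit reduced refits.
    drop_ss = {}
    for k, term in enumerate(_EFFECT_TERMS, start=1):
        keep = [j for j in range(X.shape[1]) if j != k]
        coef_r, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
        sse_r = float(np.sum((y - X[:, keep] @ coef_r) ** 2))
        drop_ss[term] = max(sse_r - sse_full_means, 0.0)

    replicate_level = responses.has_replicate_info
    if replicate_level:
        pe_ss, pe_df = _pure_error(responses)
        n_reps = (
            responses.n_reps
            if responses.n_reps is not None
            else np.array([len(responses.replicates[r]) for r in responses.run_ids])
        )
        if len(set(int(m) for m in n_reps)) != 1:
            raise ValidationError(
                "replicate-level ANOVA requires balanced replication"
            )
        m = int(n_reps[0])
        n_obs = int(np.sum(n_reps))
        # Balanced replication: replicate-level model/term SS are the
        # mean-level SS scaled by m; the residual gains the within-run SS.
        term_ss = {t: m * v for t, v in drop_ss.items()}
        lof_ss = m * sse_full_means
        lof_df = n_runs - 10
        residual_ss = lof_ss + pe_ss
        residual_df = n_obs - 10
        total_ss = m * fit.ss_total + pe_ss
        total_df = n_obs - 1
    else:
        term_ss = dict(drop_ss)
        residual_ss = sse_full_means
        residual_df = n_runs - 10
        total_ss = fit.ss_total
        total_df = n_runs - 1
        pe_ss = pe_df = lof_ss = lof_df = None
        n_obs = n_runs

    if residual_df <= 0:
        raise ValidationError(
            "no residual degrees of freedom; supply replicate information "
            "so tests can use the pure-error denominator"
        )

    ms_res = residual_ss / residual_df
    rows = {}
    for term, ss in term_ss.items():
        if ms_res > 0:
            F = (ss / 1.0) / ms_res
            p = float(stats.f.sf(F, 1, residual_df))
        else:
            F, p = np.inf if ss > 0 else 0.0, 0.0 if ss > 0 else 1.0
        rows[term] = {"ss": ss, "df": 1, "F": F, "p_value": p}
    terms = pd.DataFrame.from_dict(rows, orient="index").loc[list(_EFFECT_TERMS)]

    r2 = 1.0 - residual_ss / total_ss if total_ss > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - 10)

    lof_F = lof_p = None
    if replicate_level and pe_df and pe_df > 0 and lof_df > 0:
        ms_lof = lof_ss / lof_df
        ms_pe = pe_ss / pe_df
        if ms_pe > 0:
            lof_F = float(ms_lof / ms_pe)
            lof_p = float(stats.f.sf(lof_F, lof_df, pe_df))

    return AnovaTable(
        terms=terms,
        residual_ss=float(residual_ss),
        residual_df=int(residual_df),
        total_ss=float(total_ss),
        total_df=int(total_df),
        r2=float(r2),
        r2_adj=float(r2_adj),
        granularity="replicates" if replicate_level else "means",
        lof_ss=None if lof_ss is None else float(lof_ss),
        lof_df=None if lof_df is None else int(lof_df),
        pure_error_ss=None if pe_ss is None else float(pe_ss),
        pure_error_df=None if pe_df is None else int(pe_df),
        lof_F=lof_F,
        lof_p=lof_p,
    )


def lack_of_fit(fit: FitResult):
    """Lack-of-fit vs. pure-error F test.

    Returns ``(lof_ss, pure_error_ss, F, p)``.  Pure error comes from raw
    replicates when available, else from the mean +/- SD summaries as
    sum (n_i - 1) sd_i^2; lack of fit is the replicate-weighted SS of
    (run mean - fitted).  Requires replication in at least one run.
    """
    responses = fit.responses
    pe_ss, pe_df = _pure_error(responses)
    if pe_ss is None or pe_df == 0:
        raise ValidationError(
            "lack of fit is undefined without replication (no run has n_rep >= 2)"
        )
    n_reps = (
        responses.n_reps
        if responses.n_reps is not None
        else np.array([len(responses.replicates[r]) for r in responses.run_ids])
    )
    lof_ss = float(np.sum(n_reps * fit.residuals**2))
    lof_df = len(responses.means) - 10
    if lof_df <= 0:
        raise ValidationError("no lack-of-fit degrees of freedom")
    if pe_ss == 0.0:
        # Degenerate replication (all replicates identical within runs).
        F = np.inf if lof_ss > 0 else 0.0
        return lof_ss, pe_ss, float(F), 0.0 if lof_ss > 0 else 1.0
    F = (lof_ss / lof_df) / (pe_ss / pe_df)
    p = float(stats.f.sf(F, lof_df, pe_df))
    return lof_ss, pe_ss, float(F), p
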