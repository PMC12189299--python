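"""Nonparametric group comparisons: Kruskal-Wallis, Dunn's post hoc test,
compact letter displays, and percent-change arithmetic.

The published tables report n = 3 replicates per group with superscript
letters at alpha = 0.05.  At such tiny sample sizes the chi-square
approximation to the Kruskal-Wallis H distribution is unreliable, so an
exact permutation p-value is computed whenever the enumeration is feasible
(``method="auto"``); the asymptotic value remains available behind a flag.
Dunn's pairwise z tests on pooled ranks use Bonferroni adjustment by
default (the most conservative common choice; configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_away
from .exceptions import ValidationError

__all__ = [
    "GroupTable",
    "ComparisonResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letters",
    "percent_change",
    "compare_groups",
]

# Enumeration cap for the exact Kruskal-Wallis permutation null
# (multinomial arrangement count).
_EXACT_LIMIT = 200_000


@dataclass(frozen=True)
class GroupTable:
    """Labeled replicate measurements for one variable."""

    groups: dict[str, np.ndarray]
    variable: str = ""
    units: str = ""

    def __post_init__(self):
        clean = {}
        for name, vals in self.groups.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size < 1:
                raise ValidationError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"group {name!r} contains non-finite values")
            clean[str(name)] = vals
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col="group", value_col="value",
                   variable="", units=""):
        """Build from a long-format table (one row per replicate)."""
        groups = {
            str(g): sub[value_col].to_numpy(dtype=float)
            for g, sub in frame.groupby(group_col, sort=False)
        }
        return cls(groups=groups, variable=variable, units=units)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def pooled(self) -> tuple[np.ndarray, list[int]]:
        """All values concatenated, plus per-group sizes (in name order)."""
        values = np.concatenate([self.groups[g] for g in self.names])
        sizes = [len(self.groups[g]) for g in self.names]
        return values, sizes


@dataclass(frozen=True)
class ComparisonResult:
    H: float
    p_value: float
    method: str
    pairwise: pd.DataFrame  # columns: group1, group2, z, p, p_adj
    letters: dict[str, str]
    alpha: float


def _h_from_rank_sums(rank_sums, sizes, N, tie_correction):
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / np.asarray(sizes)) - 3.0 * (N + 1)
    return h / tie_correction if tie_correction > 0 else 0.0


def _tie_correction(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    N = len(values)
    return 1.0 - np.sum(counts**3 - counts) / (N**3 - N)


def _exact_count(sizes) -> int:
    from math import comb

    total = sum(sizes)
    count = 1
    remaining = total
    for n in sizes:
        count *= comb(remaining, n)
        remaining -= n
    return count


def kruskal_wallis(table: GroupTable, method: str = "auto") -> tuple[float, float, str]:
    """Kruskal-Wallis rank test with tie correction.

    Returns ``(H, p, method_used)``.  ``method`` is ``"auto"`` (exact
    enumeration when the arrangement count is small enough, else the
    chi-square approximation), ``"exact"``, or ``"asymptotic"``.  All-equal
    data yield H = 0, p = 1.
    """
    names = table.names
    if len(names) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    values, sizes = table.pooled()
    if np.unique(values).size < 2:
        return 0.0, 1.0, "degenerate"

    H, p_asymp = stats.kruskal(*[table.groups[g] for g in names])
    H = float(H)

    use_exact = method == "exact" or (
        method == "auto" and _exact_count(sizes) <= _EXACT_LIMIT
    )
    if not use_exact:
        return H, float(p_asymp), "asymptotic"

    # Exact permutation null: enumerate all distinct assignments of the
    # pooled ranks to groups and count H* >= H.
    ranks = stats.rankdata(values)
    N = len(ranks)
    tc = _tie_correction(values)
    indices = list(range(N))
    count_ge = 0
    total = 0

    def recurse(avail: list[int], k: int, rank_sums: list[float]):
        nonlocal count_ge, total
        if k == len(sizes) - 1:
            rs = np.array(rank_sums + [ranks[avail].sum()])
            h = _h_from_rank_sums(rs, sizes, N, tc)
            total += 1
            if h >= H - 1e-12:
                count_ge += 1
            return
        for combo in itertools.combinations(avail, sizes[k]):
            rest = [i for i in avail if i not in set(combo)]
            recurse(rest, k + 1, rank_sums + [float(ranks[list(combo)].sum())])

    recurse(indices, 0, [])
    return H, count_ge / total, "exact"


def dunn_posthoc(table: GroupTable, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, with tie correction.

    Returns one row per pair with the z statistic, two-sided p, and the
    adjusted p (``"bonferroni"``, ``"holm"``, or ``"none"``).
    """
    names = table.names
    if len(names) < 2:
        raise ValidationError("Dunn's test needs >= 2 groups")
    values, sizes = table.pooled()
    N = len(values)
    ranks = stats.rankdata(values)
    offsets = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    variance_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = len(table.groups[g1]), len(table.groups[g2])
        se = np.sqrt(variance_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)

    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return out


def compact_letters(significant: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from a pairwise significance matrix.

    ``significant`` is a symmetric boolean DataFrame (True = the pair
    differs); the diagonal must be False.  Uses the insert-and-absorb
    algorithm: groups share a letter exactly when their difference is not
    significant, and letters are assigned from the start of the alphabet in
    first-group order.
    """
    groups = list(significant.index)
    if list(significant.columns) != groups:
        raise ValidationError("significance matrix must be square with matching labels")
    sig = significant.to_numpy(dtype=bool)
    if not np.array_equal(sig, sig.T):
        raise ValidationError("significance matrix must be symmetric")
    if np.any(np.diag(sig)):
        raise ValidationError("significance matrix diagonal must be False")

    n = len(groups)
    columns: list[set[int]] = [set(range(n))]
    for i, j in itertools.combinations(range(n), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            col_i = col - {j}
            col_j = col - {i}
            for new in (col_i, col_j):
                # absorb: keep only columns not contained in another
                if not any(new <= other for other in columns):
                    columns = [c for c in columns if not c <= new] + [new]

    # Order columns by their earliest group so letters read alphabetically.
    columns.sort(key=lambda c: min(c))
    letters = {g: "" for g in groups}
    for k, col in enumerate(columns):
        letter = chr(ord("a") + k)
        for i in sorted(col):
            letters[groups[i]] += letter
    return letters


def percent_change(reference: float, treated: float) -> float:
    """Relative change in percent: 100 * (treated - reference) / reference."""
    if reference == 0:
        raise ValidationError("reference value must be nonzero")
    return 100.0 * (treated - reference) / reference


def percent_change_rendered(reference: float, treated: float) -> float:
    """Percent change rounded half-away-from-zero to one decimal (display
    convention of the study tables)."""
    return round_half_away(percent_change(reference, treated), 1)


def compare_groups(
    table: GroupTable,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    method: str = "auto",
) -> ComparisonResult:
    """Full comparison: Kruskal-Wallis, Dunn post hoc, and letter display."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    H, p, used = kruskal_wallis(table, method=method)
    pairwise = dunn_posthoc(table, adjust=adjust)
    names = table.names
    sig = pd.DataFrame(False, index=names, columns=names)
    for _, row in pairwise.iterrows():
        flag = bool(row["p_adj"] <= alpha)
        sig.loc[row["group1"], row["group2"]] = flag
        sig.loc[row["group2"], row["group1"]] = flag
    letters = compact_letters(sig)
    return ComparisonResult(
        H=H, p_value=p, method=used, pairwise=pairwise, letters=letters, alpha=alpha
    )
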