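"""Kruskal-Wallis / Dunn / compact-letter statistics and the enrichment
percent-change arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from extractopt.exceptions import ValidationError
from extractopt.groupstats import (
    GroupTable,
    compact_letters,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    percent_change,
    percent_change_rendered,
)


def _rank_formula_h(groups):
    """Independent oracle: textbook rank-sum H with tie correction."""
    from scipy.stats import rankdata

    values = np.concatenate(list(groups.values()))
    n = len(values)
    ranks = rankdata(values)
    start = 0
    h = 0.0
    for vals in groups.values():
        r = ranks[start:start + len(vals)]
        h += r.sum() ** 2 / len(vals)
        start += len(vals)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_identical_group_multisets_give_zero_h(self):
        table = GroupTable({"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0]})
        H, p, _ = kruskal_wallis(table)
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_data_return_p_one(self):
        table = GroupTable({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert kruskal_wallis(table) == (0.0, 1.0, "degenerate")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_h_matches_rank_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = {g: rng.normal(loc=i, size=4) for i, g in enumerate("abc")}
        if seed == 2:  # force ties through rounding
            groups = {g: np.round(v) for g, v in groups.items()}
        table = GroupTable(groups)
        H, _, _ = kruskal_wallis(table, method="asymptotic")
        assert H == pytest.approx(_rank_formula_h(groups), abs=1e-10)

    def test_exact_enumeration_used_for_tiny_tables(self):
        table = GroupTable({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
                            "c": [7.0, 8.0, 9.0]})
        H, p, method = kruskal_wallis(table)
        assert method == "exact"
        # Fully separated ranks: H is maximal, attained by the 3! orderings
        # of the three blocks among 1680 arrangements.
        assert p == pytest.approx(6 / 1680)

    def test_asymptotic_flag_respected(self):
        table = GroupTable({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        _, _, method = kruskal_wallis(table, method="asymptotic")
        assert method == "asymptotic"

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis(GroupTable({"a": [1.0, 2.0]}))


class TestDunnPosthoc:
    def test_two_groups_adjustment_factor_is_one(self):
        table = GroupTable({"a": [1.0, 3.0, 2.0], "b": [6.0, 4.0, 5.0]})
        result = dunn_posthoc(table)
        assert len(result) == 1
        assert result.loc[0, "p_adj"] == pytest.approx(result.loc[0, "p"])

    def test_two_separated_groups_reach_small_p(self):
        # Fully separated ranks at n=10/group: z = 10/sqrt(35/5) ~ 3.78.
        rng = np.random.default_rng(42)
        table = GroupTable(
            {g: rng.normal(10.0 * i, 1.0, size=10) for i, g in enumerate("ab")}
        )
        result = dunn_posthoc(table)
        assert (result["p_adj"] < 1e-3).all()

    def test_three_separated_groups_all_significant(self):
        # Adjacent pairs saturate at z ~ 2.54 (rank statistics cap); every
        # pair must still clear alpha = 0.05 after Bonferroni.
        rng = np.random.default_rng(42)
        table = GroupTable(
            {g: rng.normal(10.0 * i, 1.0, size=10) for i, g in enumerate("abc")}
        )
        result = dunn_posthoc(table)
        assert (result["p_adj"] < 0.05).all()

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(17)
        table = GroupTable({g: rng.normal(size=5) for g in "abcd"})
        for method in ("bonferroni", "holm"):
            result = dunn_posthoc(table, adjust=method)
            assert (result["p_adj"] >= result["p"] - 1e-15).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            dunn_posthoc(GroupTable({"a": [1.0, 2.0]}))


def _brute_force_min_letters(sig: np.ndarray) -> int:
    """Smallest number of letters (cliques of the non-significance graph)
    covering every group and every non-significant pair."""
    n = sig.shape[0]
    cliques = [
        set(c)
        for r in range(1, n + 1)
        for c in itertools.combinations(range(n), r)
        if all(not sig[i, j] for i, j in itertools.combinations(c, 2))
    ]
    need_pairs = {(i, j) for i, j in itertools.combinations(range(n), 2) if not sig[i, j]}
    for k in range(1, len(cliques) + 1):
        for cover in itertools.combinations(cliques, k):
            covered = set().union(*cover)
            if covered != set(range(n)):
                continue
            pairs = {
                (i, j)
                for c in cover
                for i, j in itertools.combinations(sorted(c), 2)
            }
            if need_pairs <= pairs:
                return k
    raise AssertionError("no cover found")


def _sig_frame(matrix, names):
    return pd.DataFrame(matrix, index=names, columns=names)


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        names = list("wxyz")
        letters = compact_letters(_sig_frame(np.zeros((4, 4), bool), names))
        assert all(v == "a" for v in letters.values())

    def test_all_pairs_significant_distinct_letters(self):
        names = list("wxyz")
        sig = ~np.eye(4, dtype=bool)
        letters = compact_letters(_sig_frame(sig, names))
        assert sorted(letters.values()) == ["a", "b", "c", "d"]

    @pytest.mark.parametrize("n_groups", [3, 4])
    def test_consistent_and_minimal_on_all_patterns(self, n_groups):
        """Exhaustive check on every symmetric significance pattern: groups
        share a letter exactly when not significantly different, and the
        letter count matches the brute-force minimal clique cover."""
        names = [chr(ord("A") + i) for i in range(n_groups)]
        pairs = list(itertools.combinations(range(n_groups), 2))
        for bits in range(2 ** len(pairs)):
            sig = np.zeros((n_groups, n_groups), dtype=bool)
            for b, (i, j) in enumerate(pairs):
                if bits >> b & 1:
                    sig[i, j] = sig[j, i] = True
            letters = compact_letters(_sig_frame(sig, names))
            for i, j in pairs:
                shares = bool(set(letters[names[i]]) & set(letters[names[j]]))
                assert shares != sig[i, j], (bits, i, j)
            n_letters = len(set("".join(letters.values())))
            assert n_letters == _brute_force_min_letters(sig), bits

    def test_minimality_on_sampled_five_group_patterns(self):
        rng = np.random.default_rng(23)
        names = list("ABCDE")
        pairs = list(itertools.combinations(range(5), 2))
        for _ in range(25):
            sig = np.zeros((5, 5), dtype=bool)
            for (i, j) in pairs:
                if rng.random() < 0.4:
                    sig[i, j] = sig[j, i] = True
            letters = compact_letters(_sig_frame(sig, names))
            n_letters = len(set("".join(letters.values())))
            assert n_letters == _brute_force_min_letters(sig)

    def test_relabeling_permutes_sharing_structure(self):
        rng = np.random.default_rng(5)
        sig = np.zeros((4, 4), dtype=bool)
        sig[0, 2] = sig[2, 0] = sig[1, 3] = sig[3, 1] = True
        base = compact_letters(_sig_frame(sig, list("wxyz")))
        perm = [2, 0, 3, 1]
        permuted_sig = sig[np.ix_(perm, perm)]
        names_p = [list("wxyz")[i] for i in perm]
        permuted = compact_letters(_sig_frame(permuted_sig, names_p))
        for a, b in itertools.combinations("wxyz", 2):
            assert (bool(set(base[a]) & set(base[b]))
                    == bool(set(permuted[a]) & set(permuted[b])))

    def test_nonsymmetric_matrix_rejected(self):
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 1] = True
        with pytest.raises(ValidationError):
            compact_letters(_sig_frame(sig, list("abc")))

    def test_true_diagonal_rejected(self):
        sig = np.eye(3, dtype=bool)
        with pytest.raises(ValidationError):
            compact_letters(_sig_frame(sig, list("abc")))


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, treated, expected",
        [(23.6, 27.2, 15.3), (3.90, 7.00, 79.5), (4.5, 4.5, 0.0)],
    )
    def test_enrichment_percentages(self, ref, treated, expected):
        assert percent_change_rendered(ref, treated) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 5.0)


class TestCompareGroups:
    def test_full_pipeline_on_separated_groups(self):
        rng = np.random.default_rng(31)
        table = GroupTable(
            {g: rng.normal(8.0 * i, 1.0, size=6) for i, g in enumerate("abc")}
        )
        result = compare_groups(table)
        assert result.p_value < 0.05
        assert len(set(result.letters.values())) >= 2
        # Sharing must mirror the adjusted pairwise decisions.
        for _, row in result.pairwise.iterrows():
            shares = bool(
                set(result.letters[row["group1"]]) & set(result.letters[row["group2"]])
            )
            assert shares == (row["p_adj"] > result.alpha)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(GroupTable({"a": [1.0], "b": [2.0]}), alpha=1.5)
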