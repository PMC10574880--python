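"""Theme ranking, eligibility filtering, truncation and bookkeeping."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from oracles import mean_rank_composite

from germcore.select import (
    EligibilityFilter,
    ThemeSpec,
    apply_eligibility,
    rank_candidates,
    selection_summary,
    truncate,
)


def _blups(table):
    """dict trait -> object with a g_hat Series (and predicted alias)."""
    out = {}
    for trait, vals in table.items():
        s = pd.Series(vals, name=trait)
        s.index.name = "accession"
        out[trait] = SimpleNamespace(g_hat=s, predicted=s)
    return out


class TestRankCandidates:
    def test_single_trait_lower_better(self):
        blups = _blups({"severity": {"A": -1.0, "B": 0.0, "C": 2.0}})
        theme = ThemeSpec(name="t", traits={"severity": "lower"}, n_target=3)
        ranked = rank_candidates(blups, theme)
        assert ranked["accession"].tolist() == ["A", "B", "C"]

    def test_single_trait_higher_better(self):
        blups = _blups({"yield": {"A": -1.0, "B": 0.0, "C": 2.0}})
        theme = ThemeSpec(name="t", traits={"yield": "higher"}, n_target=3)
        assert rank_candidates(blups, theme)["accession"].tolist() == ["C", "B", "A"]

    def test_opposed_traits_tie_broken_by_accession_id(self):
        blups = _blups(
            {
                "up": {"A": 1.0, "B": 2.0, "C": 3.0},
                "down": {"A": 1.0, "B": 2.0, "C": 3.0},
            }
        )
        theme = ThemeSpec(
            name="t", traits={"up": "higher", "down": "lower"}, n_target=3
        )
        ranked = rank_candidates(blups, theme)
        assert ranked["composite_score"].nunique() == 1
        assert ranked["accession"].tolist() == ["A", "B", "C"]

    def test_composite_matches_independent_rank_sum(self, rng):
        table = {
            f"trait{k}": {f"A{i:02d}": float(rng.normal()) for i in range(20)}
            for k in range(3)
        }
        directions = {"trait0": "higher", "trait1": "lower", "trait2": "higher"}
        blups = _blups(table)
        theme = ThemeSpec(name="t", traits=directions, n_target=20)
        ranked = rank_candidates(blups, theme).set_index("accession")
        expected = mean_rank_composite(table, directions)
        for acc, score in expected.items():
            assert ranked.loc[acc, "composite_score"] == pytest.approx(score)

    def test_invariant_under_monotone_transform_of_one_trait(self, rng):
        base = {f"A{i}": float(rng.normal()) for i in range(15)}
        other = {f"A{i}": float(rng.normal()) for i in range(15)}
        theme = ThemeSpec(
            name="t", traits={"x": "higher", "y": "lower"}, n_target=15
        )
        r1 = rank_candidates(_blups({"x": base, "y": other}), theme)
        transformed = {a: float(np.exp(v)) for a, v in base.items()}  # monotone
        r2 = rank_candidates(_blups({"x": transformed, "y": other}), theme)
        assert r1["accession"].tolist() == r2["accession"].tolist()

    def test_low_trait_coverage_excluded(self):
        blups = _blups(
            {
                "x": {"A": 1.0, "B": 2.0, "C": 3.0},
                "y": {"A": 1.0, "B": 2.0, "C": 3.0},
                "z": {"A": 1.0},  # B and C missing 1 of 3 -> still covered
            }
        )
        # accession D exists only for one trait of three -> excluded
        blups["x"].g_hat.loc["D"] = 0.0
        theme = ThemeSpec(
            name="t", traits={"x": "higher", "y": "higher", "z": "higher"},
            n_target=4,
        )
        ranked = rank_candidates(blups, theme)
        status = ranked.set_index("accession")["status"]
        assert status["D"] == "excluded_low_coverage"
        assert (status.drop("D") == "ranked").all()

    def test_theme_without_usable_traits_errors(self):
        with pytest.raises(ValueError, match="none of its traits"):
            rank_candidates(
                _blups({"x": {"A": 1.0}}),
                ThemeSpec(name="t", traits={"missing": "higher"}, n_target=1),
            )


class TestEligibility:
    def _ranked(self, blups, theme):
        return rank_candidates(blups, theme)

    def test_threshold_filter_on_scores(self):
        qual = pd.DataFrame(
            {
                "accession": ["A", "B", "C"],
                "trait": "hcn",
                "value": [3, 5, 7],
            }
        )
        blups = _blups({"yield": {"A": 1.0, "B": 2.0, "C": 3.0}})
        theme = ThemeSpec(
            name="t",
            traits={"yield": "higher"},
            n_target=3,
            filters=(EligibilityFilter(trait="hcn", op="<", value=5),),
        )
        kept, removed = apply_eligibility(self._ranked(blups, theme), theme, qual)
        assert kept["accession"].tolist() == ["A"]
        assert sorted(removed["accession"]) == ["B", "C"]

    def test_no_filters_is_identity(self):
        blups = _blups({"yield": {"A": 1.0, "B": 2.0}})
        theme = ThemeSpec(name="t", traits={"yield": "higher"}, n_target=2)
        ranked = self._ranked(blups, theme)
        kept, removed = apply_eligibility(ranked, theme, None)
        assert kept["accession"].tolist() == ranked["accession"].tolist()
        assert removed.empty

    def test_four_filters_match_set_intersection_oracle(self, rng):
        n = 30
        accs = [f"A{i:02d}" for i in range(n)]
        hcn = {a: int(rng.integers(1, 10)) for a in accs}
        cook = {a: float(rng.uniform(10, 40)) for a in accs}
        color = {a: int(rng.integers(1, 6)) for a in accs}
        frias = {a: int(rng.integers(1, 5)) for a in accs}
        qual = pd.concat(
            [
                pd.DataFrame(
                    {"accession": accs, "trait": t, "value": [v[a] for a in accs]}
                )
                for t, v in [
                    ("hcn", hcn), ("cook", cook), ("color", color), ("fria", frias)
                ]
            ]
        )
        blups = _blups({"yield": {a: float(rng.normal()) for a in accs}})
        theme = ThemeSpec(
            name="t",
            traits={"yield": "higher"},
            n_target=n,
            filters=(
                EligibilityFilter(trait="hcn", op="<", value=5),
                EligibilityFilter(trait="cook", op="<", value=25.0),
                EligibilityFilter(trait="color", allowed=frozenset({2, 3})),
                EligibilityFilter(trait="fria", allowed=frozenset({3, 4})),
            ),
        )
        kept, _ = apply_eligibility(self._ranked(blups, theme), theme, qual)
        expected = {
            a
            for a in accs
            if hcn[a] < 5 and cook[a] < 25.0 and color[a] in (2, 3)
            and frias[a] in (3, 4)
        }
        assert set(kept["accession"]) == expected

    def test_filter_on_absent_trait_names_it(self):
        blups = _blups({"yield": {"A": 1.0}})
        theme = ThemeSpec(
            name="t",
            traits={"yield": "higher"},
            n_target=1,
            filters=(EligibilityFilter(trait="ghost", op="<", value=1),),
        )
        with pytest.raises(ValueError, match="ghost"):
            apply_eligibility(self._ranked(blups, theme), theme, None)


class TestTruncate:
    def _ranked_abc(self):
        blups = _blups({"x": {"A": 3.0, "B": 2.0, "C": 1.0}})
        theme = ThemeSpec(name="t", traits={"x": "higher"}, n_target=3)
        return rank_candidates(blups, theme)

    def test_top_n(self):
        coll = truncate(self._ranked_abc(), "t", 2)
        assert coll.members == ["A", "B"]

    def test_target_beyond_length_takes_all_with_warning(self):
        with pytest.warns(UserWarning, match="taking all"):
            coll = truncate(self._ranked_abc(), "t", 10)
        assert coll.members == ["A", "B", "C"]

    def test_truncation_is_monotone_in_k(self):
        ranked = self._ranked_abc()
        for k in (1, 2):
            small = set(truncate(ranked, "t", k).members)
            big = set(truncate(ranked, "t", k + 1).members)
            assert small <= big


class TestSelectionSummary:
    def test_bookkeeping_identity(self):
        s = selection_summary([(30, 2), (25, 1)])
        assert s["total_final"] == 52
        for c in s["collections"]:
            assert c["initial"] - c["removed"] == c["final"]

    def test_shares_round_to_half_percent(self):
        s = selection_summary([(72, 0), (63, 0), (64, 0)], universe_size=1810)
        assert [c["share_pct"] for c in s["collections"]] == [4.0, 3.5, 3.5]
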