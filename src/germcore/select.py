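"""Trait-directed ranking and truncated selection of thematic collections.

A theme names its traits with a direction each (higher-better or
lower-better), optional hard eligibility filters, and a target size. The
procedure is: rank accessions per trait on their BLUPs in the stated
direction, combine ranks, drop accessions violating hard filters, and
truncate to the target size. Ranks are combined by an equal-weight
rank mean (scale-free and robust to traits with very different BLUP
variances); an accession must carry BLUPs for at least half of a theme's
traits to be ranked at all. All ties break on accession id so runs are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_TRAIT_COVERAGE = 0.5

_COMPARATORS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": np.equal,
}


@dataclass(frozen=True)
class EligibilityFilter:
    """Hard filter: comparator on a numeric trait, or an allowed class set."""

    trait: str
    op: str | None = None
    value: float | None = None
    allowed: frozenset | None = None

    def __post_init__(self):
        if (self.op is None) == (self.allowed is None):
            raise ValueError("filter needs exactly one of (op, value) or allowed")
        if self.op is not None and self.op not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.op!r}")


@dataclass(frozen=True)
class ThemeSpec:
    name: str
    traits: dict  # trait -> "higher" | "lower"
    n_target: int
    filters: tuple = ()

    def __post_init__(self):
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        for trait, direction in self.traits.items():
            if direction not in ("higher", "lower"):
                raise ValueError(
                    f"direction for {trait} must be 'higher' or 'lower', "
                    f"got {direction!r}"
                )


@dataclass
class ThematicCollection:
    """Ordered members of one theme, with removal provenance."""

    name: str
    members: list  # best first
    scores: pd.Series  # composite rank score per member (lower = better)
    stage: str = "initial"  # "initial" | "post_dedup"
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["accession", "reason", "detail"])
    )

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("collection members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)


def rank_candidates(blups: dict, theme: ThemeSpec) -> pd.DataFrame:
    """Composite rank table for a theme.

    ``blups`` maps trait -> TraitBlup (anything with a ``g_hat`` Series
    works). Per trait, accessions are ranked best-first in the theme's
    direction; the composite score is the mean rank over the traits where
    the accession has a BLUP. Accessions with BLUP coverage below 50% of
    the theme's traits are excluded with a reason.

    Returns a DataFrame sorted best-first with columns accession,
    composite_score, n_traits, status.
    """
    usable = [t for t in theme.traits if t in blups and len(blups[t].g_hat)]
    if not usable:
        raise ValueError(f"theme {theme.name!r}: none of its traits have BLUPs")
    missing = sorted(set(theme.traits) - set(usable))
    if missing:
        warnings.warn(
            f"theme {theme.name!r}: traits without BLUPs ignored: {missing}",
            stacklevel=2,
        )
    rank_cols = {}
    for trait in usable:
        g = blups[trait].g_hat
        ascending = theme.traits[trait] == "lower"
        rank_cols[trait] = g.rank(ascending=ascending, method="average")
    ranks = pd.DataFrame(rank_cols)
    n_traits = ranks.notna().sum(axis=1)
    composite = ranks.mean(axis=1, skipna=True)
    out = pd.DataFrame(
        {
            "accession": ranks.index,
            "composite_score": composite.to_numpy(),
            "n_traits": n_traits.to_numpy(),
        }
    )
    covered = out["n_traits"] >= MIN_TRAIT_COVERAGE * len(usable)
    out["status"] = np.where(covered, "ranked", "excluded_low_coverage")
    out.loc[~covered, "composite_score"] = np.nan
    # best-first; accession id breaks composite ties deterministically
    out = out.sort_values(
        ["status", "composite_score", "accession"],
        ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)
    return out


def apply_eligibility(
    ranked: pd.DataFrame,
    theme: ThemeSpec,
    qualitative: pd.DataFrame | None = None,
    blups: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop accessions violating the theme's hard filters.

    Comparator filters test the BLUP-predicted value (mu + g_hat) when the
    trait was modelled, else the accession's modal qualitative score.
    Class-set filters test modal qualitative classes. An accession with no
    value for a filtered trait is ineligible (hard filters require data).
    Returns (surviving ranked table, removal log).
    """
    qual_lookup = {}
    if qualitative is not None and len(qualitative):
        qual_lookup = {
            trait: grp.set_index("accession")["value"]
            for trait, grp in qualitative.groupby("trait")
        }
    removals = []
    keep = ranked[ranked["status"] == "ranked"].copy()
    for filt in theme.filters:
        if filt.trait in (blups or {}):
            values = (blups[filt.trait].predicted).reindex(keep["accession"])
        elif filt.trait in qual_lookup:
            values = qual_lookup[filt.trait].reindex(keep["accession"])
        else:
            raise ValueError(
                f"theme {theme.name!r}: filter references trait {filt.trait!r} "
                "absent from both BLUPs and qualitative scores"
            )
        values.index = keep.index
        if filt.op is not None:
            ok = _COMPARATORS[filt.op](values.to_numpy(dtype=float), filt.value)
            detail = f"{filt.trait} {filt.op} {filt.value}"
        else:
            ok = values.isin(list(filt.allowed)).to_numpy()
            detail = f"{filt.trait} in {sorted(filt.allowed)}"
        ok = ok & values.notna().to_numpy()
        for acc in keep.loc[~ok, "accession"]:
            removals.append(
                {"accession": acc, "reason": "filter_violation", "detail": detail}
            )
        keep = keep[ok]
    removal_df = pd.DataFrame(removals, columns=["accession", "reason", "detail"])
    return keep.reset_index(drop=True), removal_df


def truncate(
    ranked: pd.DataFrame, name: str, n_target: int,
    removed: pd.DataFrame | None = None,
) -> ThematicCollection:
    """Keep the top ``n_target`` accessions of a ranked table."""
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    eligible = ranked[ranked["status"] == "ranked"] if "status" in ranked else ranked
    if len(eligible) < n_target:
        warnings.warn(
            f"collection {name!r}: only {len(eligible)} eligible accessions "
            f"for target {n_target}; taking all",
            stacklevel=2,
        )
    top = eligible.head(n_target)
    scores = pd.Series(
        top["composite_score"].to_numpy(), index=top["accession"].to_numpy()
    )
    removed = removed if removed is not None else pd.DataFrame(
        columns=["accession", "reason", "detail"]
    )
    return ThematicCollection(
        name=name,
        members=list(top["accession"]),
        scores=scores,
        stage="initial",
        removed=removed,
    )


def build_collection(
    blups: dict,
    theme: ThemeSpec,
    qualitative: pd.DataFrame | None = None,
) -> ThematicCollection:
    """rank -> eligibility -> truncate for one theme."""
    ranked = rank_candidates(blups, theme)
    low_cov = ranked[ranked["status"] == "excluded_low_coverage"]
    removals = [
        {"accession": a, "reason": "low_trait_coverage", "detail": ""}
        for a in low_cov["accession"]
    ]
    filtered, filt_removed = apply_eligibility(ranked, theme, qualitative, blups)
    removed = pd.concat(
        [pd.DataFrame(removals, columns=["accession", "reason", "detail"]),
         filt_removed],
        ignore_index=True,
    )
    return truncate(filtered, theme.name, theme.n_target, removed=removed)


def selection_summary(collections: list, universe_size: int | None = None) -> dict:
    """Bookkeeping across collections: sizes, removals, shares.

    ``collections`` holds (initial_size, n_removed) pairs or
    ThematicCollection objects (where dedup removals are counted from the
    removal log). Shares of the universe are rounded to the nearest 0.5
    percentage point, matching how such fractions are usually reported.
    """
    per = []
    for item in collections:
        if isinstance(item, ThematicCollection):
            n_dedup = int((item.removed["reason"] == "duplicate").sum())
            initial = item.size + (n_dedup if item.stage == "post_dedup" else 0)
            final = item.size
            name = item.name
        else:
            initial, n_dedup = item
            final = initial - n_dedup
            name = None
        entry = {"name": name, "initial": int(initial), "removed": int(n_dedup),
                 "final": int(final)}
        if universe_size:
            entry["share_pct"] = round(2 * 100.0 * final / universe_size) / 2
        per.append(entry)
    return {
        "collections": per,
        "total_initial": sum(e["initial"] for e in per),
        "total_removed": sum(e["removed"] for e in per),
        "total_final": sum(e["final"] for e in per),
    }
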