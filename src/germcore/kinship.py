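"""Identity-by-state kinship and near-duplicate pruning.

Germplasm banks accumulate duplicated clones through exchange and
renaming; within each thematic collection, pairs sharing almost all of
their genome (IBS above a threshold, 0.95 by default) are treated as
duplicates and one member of each pair is discarded.

IBS here is the average proportion of shared alleles under the dosage
metric: for accessions a, b over loci called in both,
ibs = mean(1 - |d_a - d_b| / 2). Identical genotypes give 1, opposite
homozygotes give 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .select import ThematicCollection

DEFAULT_IBS_THRESHOLD = 0.95


@dataclass
class KinshipMatrix:
    ids: list
    values: np.ndarray  # symmetric, diagonal 1, NaN where no shared loci
    n_loci: np.ndarray  # per-pair count of loci called in both

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def ibs_matrix(gm: GenotypeMatrix, subset=None) -> KinshipMatrix:
    """Pairwise IBS over loci non-missing in both accessions.

    Requires raw (non-imputed) dosages. Pairs with zero comparable loci
    get a NaN entry and a warning.
    """
    if gm.imputed:
        raise ValueError("IBS requires raw (non-imputed) dosage calls")
    sub = gm if subset is None else gm.subset(list(subset))
    if sub.n_accessions == 0:
        raise ValueError("empty accession subset")
    d = sub.dosages
    called = ~np.isnan(d)
    d0 = np.nan_to_num(d, nan=0.0)
    n = sub.n_accessions
    values = np.ones((n, n))
    counts = np.empty((n, n), dtype=int)
    np.fill_diagonal(counts, called.sum(axis=1))
    for i in range(n):
        shared = called[i] & called[i + 1 :]
        diff = np.abs(d0[i] - d0[i + 1 :]) * shared
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 1.0 - (diff.sum(axis=1) / n_shared) / 2.0
        sim[n_shared == 0] = np.nan
        values[i, i + 1 :] = values[i + 1 :, i] = sim
        counts[i, i + 1 :] = counts[i + 1 :, i] = n_shared
    if np.isnan(values).any():
        warnings.warn("some accession pairs share zero called loci", stacklevel=2)
    return KinshipMatrix(ids=list(sub.accession_ids), values=values, n_loci=counts)


def find_duplicate_pairs(
    km: KinshipMatrix, threshold: float = DEFAULT_IBS_THRESHOLD
) -> pd.DataFrame:
    """All unordered pairs with IBS strictly above the threshold.

    Sorted by descending IBS, then lexicographic ids. Columns:
    id1, id2, ibs, n_loci.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    n = len(km.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = km.values[i, j]
            if np.isfinite(v) and v > threshold:
                a, b = sorted((km.ids[i], km.ids[j]))
                rows.append(
                    {"id1": a, "id2": b, "ibs": float(v),
                     "n_loci": int(km.n_loci[i, j])}
                )
    out = pd.DataFrame(rows, columns=["id1", "id2", "ibs", "n_loci"])
    return out.sort_values(
        ["ibs", "id1", "id2"], ascending=[False, True, True]
    ).reset_index(drop=True)


def prune_duplicates(
    collection: ThematicCollection, pairs: pd.DataFrame
) -> ThematicCollection:
    """Remove one member of each duplicate pair, keeping the better rank.

    A greedy pass over pairs in descending-IBS order removes, from each
    pair still fully present, the worse-ranked member (higher accession id
    on a rank tie). A restoration sweep then re-admits, best rank first,
    any removal that no longer conflicts with a survivor, so the result is
    a maximal duplicate-free set. Removals are logged with the retained
    partner and the pair's IBS.
    """
    members = set(collection.members)
    rank = {a: i for i, a in enumerate(collection.members)}
    rel = pairs[pairs["id1"].isin(members) & pairs["id2"].isin(members)]
    removed = {}
    for row in rel.itertuples(index=False):
        a, b = row.id1, row.id2
        if a in removed or b in removed:
            continue
        worse = max(a, b, key=lambda x: (rank[x], x))
        better = a if worse == b else b
        removed[worse] = (better, row.ibs)
    # restoration: a removal whose conflicts were all removed later comes back
    conflicts = {}
    for row in rel.itertuples(index=False):
        conflicts.setdefault(row.id1, set()).add(row.id2)
        conflicts.setdefault(row.id2, set()).add(row.id1)
    surviving = members - set(removed)
    for acc in sorted(removed, key=lambda x: (rank[x], x)):
        if not (conflicts.get(acc, set()) & surviving):
            surviving.add(acc)
            del removed[acc]
    kept = [a for a in collection.members if a in surviving]
    removal_log = pd.DataFrame(
        [
            {
                "accession": acc,
                "reason": "duplicate",
                "detail": f"duplicate_of={partner};ibs={ibs:.4f}",
            }
            for acc, (partner, ibs) in sorted(
                removed.items(), key=lambda kv: (rank[kv[0]], kv[0])
            )
        ],
        columns=["accession", "reason", "detail"],
    )
    return ThematicCollection(
        name=collection.name,
        members=kept,
        scores=collection.scores.loc[kept],
        stage="post_dedup",
        removed=pd.concat([collection.removed, removal_log], ignore_index=True),
    )
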