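"""Phenotypic and molecular diversity of collections versus the full bank.

Four layers of validation:

* Shannon–Weaver index per trait, computed on phenotype classes and
  normalized by ln(number of defined classes) so 0 is monomorphism and 1
  is a uniform spread over every defined class. Quantitative traits are
  first cut into six classes whose boundaries come from the ENTIRE
  collection's range, so a sub-collection that misses classes is
  penalized.
* Per-locus observed heterozygosity Ho, within-population gene diversity
  Hs with the Nei–Chesser small-sample correction, and the inbreeding
  coefficient Fis = 1 - Ho/Hs.
* Allele counting and retention: distinct alleles observed per locus
  summed across loci; retention is the subset count as a percentage of
  the reference count, rounded to 2 decimals.
* Cohen's Kappa between the binary selection vectors of collections over
  a common accession universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

DEFAULT_N_BINS = 6
_BOUNDARY_RTOL = 1e-9


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width class boundaries over a trait's full-collection range.

    Class k covers (min + (k-1)*Amp/k_classes, min + k*Amp/k_classes],
    except class 1 which is closed at the minimum.
    """

    trait: str
    vmin: float
    vmax: float
    k_classes: int = DEFAULT_N_BINS

    @property
    def amplitude(self) -> float:
        return self.vmax - self.vmin

    @property
    def boundaries(self) -> np.ndarray:
        """Upper limits of classes 1..k."""
        return self.vmin + np.arange(1, self.k_classes + 1) * (
            self.amplitude / self.k_classes
        )


def make_binning(values, trait: str, k_classes: int = DEFAULT_N_BINS) -> BinningScheme:
    """Scheme from the entire collection's observed min/max for the trait."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError(f"no finite values to bin for trait {trait!r}")
    return BinningScheme(trait=trait, vmin=float(arr.min()), vmax=float(arr.max()),
                         k_classes=k_classes)


def bin_quantitative(values, scheme: BinningScheme) -> np.ndarray:
    """Assign values to classes 1..k under the half-open-left convention.

    A value exactly on a boundary belongs to the lower class; the minimum
    belongs to class 1. Values outside [min, max] (impossible for subsets
    of the range-defining collection) raise. A zero amplitude puts every
    value in class 1 and flags the trait monomorphic via a warning.
    """
    arr = np.asarray(values, dtype=float)
    tol = _BOUNDARY_RTOL * max(abs(scheme.vmin), abs(scheme.vmax), 1.0)
    if (arr < scheme.vmin - tol).any() or (arr > scheme.vmax + tol).any():
        bad = arr[(arr < scheme.vmin - tol) | (arr > scheme.vmax + tol)][0]
        raise ValueError(
            f"value {bad} outside binning range [{scheme.vmin}, {scheme.vmax}] "
            f"for trait {scheme.trait!r}"
        )
    if scheme.amplitude <= 0:
        warnings.warn(f"trait {scheme.trait!r} is monomorphic (zero range)",
                      stacklevel=2)
        return np.ones(arr.shape, dtype=int)
    inner = scheme.boundaries[:-1]  # k-1 internal upper limits
    classes = 1 + np.searchsorted(inner + tol, arr, side="left")
    return classes.astype(int)


def shannon_weaver(class_labels, k_classes: int, normalized: bool = True) -> float:
    """Shannon–Weaver H' = -sum p_i ln p_i over observed class frequencies.

    Normalized by ln(k_classes) — the number of DEFINED classes, not the
    number realized in the sample — so the index spans monomorphism (0) to
    maximum phenotypic diversity (1). Zero observations -> NaN.
    """
    if k_classes < 1:
        raise ValueError("k_classes must be >= 1")
    labels = np.asarray(class_labels)
    labels = labels[~pd.isna(labels)]
    if labels.size == 0:
        return float("nan")
    if labels.min() < 1 or labels.max() > k_classes:
        raise ValueError("class labels must lie in 1..k_classes")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if not normalized:
        return h
    return h / np.log(k_classes) if k_classes > 1 else 0.0


def molecular_diversity(gm: GenotypeMatrix, subset=None):
    """Per-locus Ho, Hs (Nei–Chesser corrected) and Fis, with means.

    Single-population treatment. Per locus with n~ non-missing diploid
    calls and sample allele frequencies p~:

        Ho  = heterozygote fraction
        Hs  = (n~/(n~-1)) * (1 - sum p~_i^2 - Ho/(2 n~))
        Fis = 1 - Ho/Hs  where Hs > 0

    Loci with n~ < 2 are excluded from Hs/Fis. Means are taken over loci
    with defined values; the mean Fis is reported both as the average of
    per-locus Fis and as 1 - mean(Ho)/mean(Hs) since conventions differ.
    Returns ``(per_locus DataFrame, means dict)``.
    """
    if gm.imputed:
        raise ValueError("diversity statistics require raw (non-imputed) calls")
    sub = gm if subset is None else gm.subset(list(subset))
    d = sub.dosages
    called = ~np.isnan(d)
    n_tilde = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.nansum(d == 1, axis=0) / n_tilde
        p_alt = np.nansum(d, axis=0) / (2 * n_tilde)
        sum_p2 = p_alt**2 + (1 - p_alt) ** 2
        hs = (n_tilde / (n_tilde - 1)) * (1 - sum_p2 - ho / (2 * n_tilde))
        hs = np.where(n_tilde >= 2, hs, np.nan)
        ho = np.where(n_tilde >= 1, ho, np.nan)
        fis = np.where(np.nan_to_num(hs) > 0, 1 - ho / hs, np.nan)
    n_small = int((n_tilde < 2).sum())
    if n_small:
        warnings.warn(
            f"{n_small} loci with fewer than 2 calls excluded from Hs/Fis",
            stacklevel=2,
        )
    per_locus = pd.DataFrame(
        {
            "chrom": sub.loci["chrom"],
            "pos": sub.loci["pos"],
            "n": n_tilde.astype(int),
            "ho": ho,
            "hs": hs,
            "fis": fis,
        }
    )
    means = {
        "ho": float(np.nanmean(ho)) if np.isfinite(ho).any() else float("nan"),
        "hs": float(np.nanmean(hs)) if np.isfinite(hs).any() else float("nan"),
        "fis": float(np.nanmean(fis)) if np.isfinite(fis).any() else float("nan"),
    }
    means["fis_from_means"] = (
        1 - means["ho"] / means["hs"] if means.get("hs") and means["hs"] > 0
        else float("nan")
    )
    return per_locus, means


def allele_count(gm: GenotypeMatrix, subset=None) -> int:
    """Distinct alleles observed, summed over loci.

    At a biallelic locus the alt allele counts as observed when any
    non-missing dosage is >= 1, the ref allele when any is <= 1.
    """
    if gm.imputed:
        raise ValueError("allele counting requires raw (non-imputed) calls")
    sub = gm if subset is None else gm.subset(list(subset))
    d = sub.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        alt_seen = np.nansum(d >= 1, axis=0) > 0
        ref_seen = np.nansum(d <= 1, axis=0) > 0
    return int(alt_seen.sum() + ref_seen.sum())


def retention_percent(subset_count: int, reference_count: int) -> float:
    """100 * subset / reference, rounded to 2 decimals."""
    if reference_count <= 0:
        raise ValueError("reference allele count must be positive")
    return round(100.0 * subset_count / reference_count, 2)


def allele_retention(gm: GenotypeMatrix, subset_ids, reference_ids=None) -> dict:
    """Allele counts of subset vs reference and the retention percentage."""
    ref_ids = list(reference_ids) if reference_ids is not None else list(
        gm.accession_ids
    )
    if not set(subset_ids).issubset(ref_ids):
        raise ValueError("subset accessions must be contained in the reference")
    n_sub = allele_count(gm, subset_ids)
    n_ref = allele_count(gm, ref_ids)
    return {
        "subset_count": n_sub,
        "reference_count": n_ref,
        "retention_pct": retention_percent(n_sub, n_ref),
    }


def cohen_kappa(x, y) -> float:
    """Chance-corrected agreement of two binary vectors from the 2x2 table."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must share one universe")
    n = x.size
    po = float((x == y).sum()) / n
    pe = (x.mean() * y.mean()) + ((1 - x.mean()) * (1 - y.mean()))
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1 - pe)


def kappa_coincidence(membership: dict, universe=None) -> pd.DataFrame:
    """Pairwise Kappa matrix over collections' selection vectors.

    ``membership`` maps collection name -> iterable of selected accession
    ids; ``universe`` defaults to the union of all members (in practice,
    pass every phenotyped accession). Degenerate vectors (all selected or
    none) give NaN against every partner, with a warning.
    """
    names = list(membership)
    if universe is None:
        universe = sorted(set().union(*(set(membership[n]) for n in names)))
    universe = list(universe)
    vecs = {
        n: np.isin(universe, list(membership[n])) for n in names
    }
    for n, v in vecs.items():
        if v.all() or not v.any():
            warnings.warn(
                f"collection {n!r} selects all or none of the universe; "
                "Kappa undefined for its pairs",
                stacklevel=2,
            )
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = cohen_kappa(vecs[a], vecs[b])
            va, vb = vecs[a], vecs[b]
            if va.all() or not va.any() or vb.all() or not vb.any():
                k = float("nan")
            out.loc[a, b] = out.loc[b, a] = k
    return out
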