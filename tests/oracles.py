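"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic from first principles (explicit loops,
direct likelihood evaluation, exhaustive search) so package code can be
checked against an implementation that shares none of its internals.
"""

import itertools
import math

import numpy as np


def ibs_brute_force(dosages):
    """Pairwise IBS by explicit double loop over accessions and loci."""
    n = dosages.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total, count = 0.0, 0
            for a, b in zip(dosages[i], dosages[j]):
                if not (math.isnan(a) or math.isnan(b)):
                    total += 1.0 - abs(a - b) / 2.0
                    count += 1
            out[i, j] = total / count if count else np.nan
    return out


def shannon_brute_force(labels, k_classes):
    """Direct -sum p ln p over realized classes, normalized by ln k."""
    labels = [x for x in labels if x == x]
    n = len(labels)
    h = 0.0
    for cls in set(labels):
        p = sum(1 for x in labels if x == cls) / n
        h -= p * math.log(p)
    return h / math.log(k_classes) if k_classes > 1 else 0.0


def diversity_brute_force(dosages):
    """Per-locus Ho/Hs/Fis by explicit genotype counting."""
    n_acc, n_loci = dosages.shape
    ho = np.full(n_loci, np.nan)
    hs = np.full(n_loci, np.nan)
    fis = np.full(n_loci, np.nan)
    for j in range(n_loci):
        calls = [d for d in dosages[:, j] if not math.isnan(d)]
        n = len(calls)
        if n >= 1:
            ho[j] = sum(1 for d in calls if d == 1) / n
        if n < 2:
            continue
        p = sum(calls) / (2 * n)
        q = 1 - p
        hs[j] = (n / (n - 1)) * (1 - (p * p + q * q) - ho[j] / (2 * n))
        if hs[j] > 0:
            fis[j] = 1 - ho[j] / hs[j]
    return ho, hs, fis


def kappa_brute_force(x, y):
    """Cohen's Kappa from the explicitly tabulated 2x2 table."""
    a = sum(1 for u, v in zip(x, y) if u and v)
    b = sum(1 for u, v in zip(x, y) if u and not v)
    c = sum(1 for u, v in zip(x, y) if not u and v)
    d = sum(1 for u, v in zip(x, y) if not u and not v)
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return (po - pe) / (1 - pe)


def hudson_fst(dos_pop1, dos_pop2):
    """Hudson's FST estimator from per-population sample allele frequencies.

    Per-locus numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    denominator p1(1-p2) + p2(1-p1); ratio-of-sums across loci.
    """
    num_sum, den_sum = 0.0, 0.0
    for j in range(dos_pop1.shape[1]):
        c1 = dos_pop1[:, j]
        c2 = dos_pop2[:, j]
        n1 = 2 * len(c1)
        n2 = 2 * len(c2)
        p1 = c1.sum() / n1
        p2 = c2.sum() / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_sum += num
        den_sum += den
    return num_sum / den_sum


def two_component_reml_loglik(y, accession_codes, s2g, s2e):
    """Restricted log-likelihood of y = mu + g + e evaluated directly via V."""
    n = len(y)
    q = accession_codes.max() + 1
    Z = np.zeros((n, q))
    Z[np.arange(n), accession_codes] = 1.0
    V = s2g * (Z @ Z.T) + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - (X @ beta).ravel()
    _, logdetV = np.linalg.slogdet(V)
    _, logdetXVX = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + logdetXVX + r @ Vi @ r)


def two_component_reml_argmax(y, accession_codes):
    """Grid search + local refinement of the direct restricted likelihood."""
    from scipy.optimize import minimize

    vary = np.var(y)
    grid = vary * np.array([0.05, 0.2, 0.5, 1.0, 2.0])
    best, best_ll = None, -np.inf
    for s2g in grid:
        for s2e in grid:
            ll = two_component_reml_loglik(y, accession_codes, s2g, s2e)
            if ll > best_ll:
                best, best_ll = (s2g, s2e), ll
    res = minimize(
        lambda t: -two_component_reml_loglik(
            y, accession_codes, math.exp(t[0]), math.exp(t[1])
        ),
        x0=np.log(best),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return math.exp(res.x[0]), math.exp(res.x[1])


def minimal_removal_sets(members, pairs):
    """All minimum-size removal sets leaving no duplicate pair (exhaustive)."""
    members = list(members)
    conflict = [(a, b) for a, b in pairs]
    best_size = len(members) + 1
    best = []
    for r in range(len(members) + 1):
        if r > best_size:
            break
        for subset in itertools.combinations(members, r):
            removed = set(subset)
            if all(a in removed or b in removed for a, b in conflict):
                if r < best_size:
                    best_size, best = r, []
                best.append(removed)
        if best:
            break
    return best_size, best


def mean_rank_composite(blup_table, directions):
    """Composite rank scores recomputed with explicit sorting.

    blup_table: dict trait -> dict accession -> value.
    Returns dict accession -> mean rank (average rank for ties).
    """
    all_acc = sorted({a for t in blup_table.values() for a in t})
    per_trait_rank = {}
    for trait, vals in blup_table.items():
        accs = [a for a in all_acc if a in vals]
        reverse = directions[trait] == "higher"
        ordered = sorted(accs, key=lambda a: vals[a], reverse=reverse)
        ranks = {}
        i = 0
        while i < len(ordered):
            j = i
            while j < len(ordered) and vals[ordered[j]] == vals[ordered[i]]:
                j += 1
            avg = (i + 1 + j) / 2.0
            for k in range(i, j):
                ranks[ordered[k]] = avg
            i = j
        per_trait_rank[trait] = ranks
    out = {}
    for a in all_acc:
        rs = [per_trait_rank[t][a] for t in blup_table if a in blup_table[t]]
        if rs:
            out[a] = sum(rs) / len(rs)
    return out
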