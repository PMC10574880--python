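"""Variance components and genotypic BLUPs for unbalanced trials.

Per quantitative trait the model is

    y = mu + Z g + W b + T (g x env) + e

with independent random effects: genotype g ~ N(0, sigma2_g I), block
nested in environment b ~ N(0, sigma2_b I), genotype-by-environment
interaction ~ N(0, sigma2_ge I), residual e ~ N(0, sigma2_e I). Location
x year combinations are one "environment" stratum (trial and environment
are merged), and blocks are aligned within it.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations; this is slow near the boundary but monotone in the restricted
likelihood and robust on the sparse, unbalanced incidence structures
germplasm evaluations produce. Components that collapse are clamped at a
small floor; degenerate strata (a single environment, a single block
level) are dropped with a logged warning rather than failing the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
MAX_ITER = 200
LOGLIK_TOL = 1e-6

_COMPONENT_FIELDS = {"genotype": "sigma2_g", "block": "sigma2_b", "gxe": "sigma2_ge"}


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_b: float
    sigma2_ge: float
    sigma2_e: float
    converged: bool = True
    n_iterations: int = 0
    loglik: float = np.nan
    dropped: tuple = ()

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_b", "sigma2_ge", "sigma2_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    def as_dict(self):
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_b": self.sigma2_b,
            "sigma2_ge": self.sigma2_ge,
            "sigma2_e": self.sigma2_e,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "loglik": float(self.loglik),
            "dropped": list(self.dropped),
        }


@dataclass
class TraitBlup:
    """Per-trait prediction results: grand mean, shrunken genotype effects."""

    trait: str
    mu: float
    g_hat: pd.Series  # index: accession
    vc: VarianceComponents
    h2: float = np.nan

    @property
    def predicted(self) -> pd.Series:
        """mu + g_hat: predicted genotypic value on the trait scale."""
        return self.mu + self.g_hat


def _design(records: pd.DataFrame, trait: str):
    """Incidence structure for one trait: y, and (name, levels, Z) per effect."""
    df = records[records["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    y = df["value"].to_numpy(dtype=float)
    n = len(df)

    def incidence(labels):
        cat = pd.Categorical(labels)
        z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), cat.codes)), shape=(n, len(cat.categories))
        )
        return list(cat.categories), z

    geno_levels, Z = incidence(df["accession"])
    if len(geno_levels) < 2:
        raise ValueError("need >= 2 accessions with records to fit the model")
    blocks = df["environment"].astype(str) + ":" + df["block"].astype(str)
    block_levels, W = incidence(blocks)
    envs = df["environment"].astype(str)
    gxe = df["accession"].astype(str) + ":" + envs
    gxe_levels, T = incidence(gxe)

    components = [("genotype", geno_levels, Z)]
    dropped = []
    if len(block_levels) >= 2:
        components.append(("block", block_levels, W))
    else:
        dropped.append("block")
    if envs.nunique() >= 2 and len(gxe_levels) >= 2:
        components.append(("gxe", gxe_levels, T))
    else:
        dropped.append("gxe")
    if dropped:
        logger.warning(
            "trait %s: dropping degenerate random effects %s", trait, dropped
        )
    return y, components, tuple(dropped)


def _assemble(y, components, sigma2, sigma2_e):
    """Henderson coefficient matrix C (scaled by sigma2_e) and RHS r."""
    n = len(y)
    U = sp.hstack([z for _, _, z in components], format="csr")
    X = np.ones((n, 1))
    XtX = np.array([[n]], dtype=float)
    XtU = np.asarray(U.sum(axis=0), dtype=float)  # X = 1 vector
    UtU = (U.T @ U).toarray()
    Xty = np.array([y.sum()])
    Uty = U.T @ y
    q = [z.shape[1] for _, _, z in components]
    lam = np.concatenate(
        [np.full(qk, sigma2_e / max(s2, VARIANCE_FLOOR)) for qk, s2 in zip(q, sigma2)]
    )
    p = 1
    dim = p + sum(q)
    C = np.empty((dim, dim))
    C[:p, :p] = XtX
    C[:p, p:] = XtU
    C[p:, :p] = XtU.T
    C[p:, p:] = UtU
    C[p:, p:][np.diag_indices(sum(q))] += lam
    r = np.concatenate([Xty, Uty])
    return C, r, q


def _em_reml(y, components, max_iter=MAX_ITER, tol=LOGLIK_TOL):
    n = len(y)
    p = 1
    vary = float(np.var(y))
    K = len(components)
    if vary <= VARIANCE_FLOOR:
        # zero-variance data: every component sits at the floor
        return [VARIANCE_FLOOR] * K, VARIANCE_FLOOR, True, 0, 0.0
    sigma2 = [vary / (K + 1)] * K
    sigma2_e = vary / (K + 1)
    yty = float(y @ y)
    ll_prev = -np.inf
    ll = ll_prev
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C, r, q = _assemble(y, components, sigma2, sigma2_e)
        cho = la.cho_factor(C, lower=True, check_finite=False)
        s = la.cho_solve(cho, r, check_finite=False)
        Cinv = la.cho_solve(cho, np.eye(C.shape[0]), check_finite=False)
        ery = yty - float(s @ r)  # e'y = y'y - beta'X'y - u'U'y
        offs = np.cumsum([p] + q)
        new_sigma2 = []
        for k in range(K):
            a, b = offs[k], offs[k + 1]
            uk = s[a:b]
            tr = float(np.trace(Cinv[a:b, a:b]))
            new_sigma2.append(max((float(uk @ uk) + sigma2_e * tr) / q[k], VARIANCE_FLOOR))
        new_sigma2_e = max(ery / (n - p), VARIANCE_FLOOR)
        # restricted log-likelihood at the *current* parameter values
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        m2ll = (
            (n - p - sum(q)) * np.log(sigma2_e)
            + sum(qk * np.log(s2) for qk, s2 in zip(q, sigma2))
            + logdetC
            + ery / sigma2_e
        )
        ll = -0.5 * m2ll
        sigma2, sigma2_e = new_sigma2, new_sigma2_e
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return sigma2, sigma2_e, converged, it, ll


def fit_reml(records: pd.DataFrame, trait: str, max_iter: int = MAX_ITER,
             tol: float = LOGLIK_TOL) -> VarianceComponents:
    """EM-REML variance components for one trait.

    Convergence: restricted log-likelihood change < ``tol`` or ``max_iter``
    iterations. Dropped (degenerate) components are reported as 0 with
    their names in ``dropped``.
    """
    y, components, dropped = _design(records, trait)
    sigma2, sigma2_e, converged, n_iter, ll = _em_reml(y, components, max_iter, tol)
    est = dict.fromkeys(_COMPONENT_FIELDS.values(), 0.0)
    for (name, _, _), s2 in zip(components, sigma2):
        est[_COMPONENT_FIELDS[name]] = float(s2)
    if not converged:
        warnings.warn(
            f"REML for trait {trait!r} did not converge in {n_iter} iterations",
            stacklevel=2,
        )
    return VarianceComponents(
        sigma2_g=est["sigma2_g"],
        sigma2_b=est["sigma2_b"],
        sigma2_ge=est["sigma2_ge"],
        sigma2_e=float(sigma2_e),
        converged=converged,
        n_iterations=n_iter,
        loglik=float(ll),
        dropped=dropped,
    )


def reml_loglik_path(records: pd.DataFrame, trait: str, max_iter: int = 50):
    """Restricted log-likelihood after each EM step (diagnostic)."""
    y, components, _ = _design(records, trait)
    path = []
    for it in range(1, max_iter + 1):
        *_, ll = _em_reml(y, components, max_iter=it, tol=0.0)
        path.append(ll)
    return path


def predict_blups(records: pd.DataFrame, vc: VarianceComponents, trait: str):
    """Solve Henderson's equations at the given variance components.

    Returns ``(mu_hat, g_hat)`` with ``g_hat`` a Series over the accessions
    that have records for this trait (absent accessions are absent, not
    zero-filled). Components estimated at (or set to) zero are excluded
    from the solve. An ill-conditioned system falls back to a
    pseudo-inverse with the condition number logged.
    """
    y, components, _ = _design(records, trait)
    by_name = {"genotype": vc.sigma2_g, "block": vc.sigma2_b, "gxe": vc.sigma2_ge}
    active, sigma2 = [], []
    for name, levels, z in components:
        s2 = by_name[name]
        if name == "genotype" or s2 > 10 * VARIANCE_FLOOR:
            active.append((name, levels, z))
            sigma2.append(max(s2, VARIANCE_FLOOR))
    C, r, q = _assemble(y, active, sigma2, max(vc.sigma2_e, VARIANCE_FLOOR))
    try:
        s = la.cho_solve(la.cho_factor(C, lower=True, check_finite=False), r,
                         check_finite=False)
    except la.LinAlgError:
        cond = np.linalg.cond(C)
        logger.warning(
            "singular mixed-model equations for %s (cond=%.3g); using pseudo-inverse",
            trait, cond,
        )
        s = np.linalg.pinv(C) @ r
    mu = float(s[0])
    geno_levels = active[0][1]
    g_hat = pd.Series(s[1 : 1 + len(geno_levels)], index=geno_levels, name=trait)
    g_hat.index.name = "accession"
    return mu, g_hat


def heritability(vc: VarianceComponents, n_env: int, n_rep: int) -> float:
    """Broad-sense heritability on an entry-mean basis.

    h2 = sigma2_g / (sigma2_g + sigma2_ge/n_env + sigma2_e/(n_env*n_rep)).
    Defined as 0 when the denominator vanishes.
    """
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    denom = vc.sigma2_g + vc.sigma2_ge / n_env + vc.sigma2_e / (n_env * n_rep)
    if denom <= 0:
        return 0.0
    return float(vc.sigma2_g / denom)


def fit_trait(records: pd.DataFrame, trait: str) -> TraitBlup:
    """Convenience: REML fit, BLUP solve and entry-mean h2 for one trait."""
    vc = fit_reml(records, trait)
    mu, g_hat = predict_blups(records, vc, trait)
    df = records[records["trait"] == trait]
    n_env = max(int(df["environment"].nunique()), 1)
    reps = df.groupby("environment")["block"].nunique()
    n_rep = max(int(round(float(reps.mean()))), 1)
    return TraitBlup(trait=trait, mu=mu, g_hat=g_hat, vc=vc,
                     h2=heritability(vc, n_env, n_rep))


def fit_all_traits(records: pd.DataFrame) -> dict:
    """Fit every trait present in the records; returns {trait: TraitBlup}."""
    return {t: fit_trait(records, t) for t in sorted(records["trait"].unique())}


def blup_frame(blups: dict) -> pd.DataFrame:
    """Long-format table (trait, accession, g_hat, predicted, h2)."""
    rows = []
    for trait, tb in blups.items():
        rows.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "accession": tb.g_hat.index,
                    "g_hat": tb.g_hat.to_numpy(),
                    "predicted": tb.predicted.to_numpy(),
                    "mu": tb.mu,
                    "h2": tb.h2,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
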