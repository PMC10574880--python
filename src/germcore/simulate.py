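"""Synthetic germplasm with known ground truth.

Three generators mirror the data layers the pipeline consumes:

* ``simulate_genotypes`` — a structured biallelic SNP panel under a
  two-level Balding–Nichols model (ancestral frequency, then per-population
  frequencies with divergence ``fst``), with near-identical clone pairs
  planted so duplicate detection has a known answer.
* ``simulate_trials`` — unbalanced multi-environment trial records under
  the additive mixed model y = mu + g + b + ge + e with the stated variance
  components, returning the true genotypic values for recovery tests.
* ``simulate_qualitative`` — repeated yearly ordinal scores around a latent
  class, emulating minor year-to-year fluctuation of descriptor scores.

All generators are deterministic given ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, TRIAL_COLUMNS, QUAL_COLUMNS

N_CHROMOSOMES = 18  # cassava karyotype; loci are spread evenly across these

# Default trial variance components (sigma2_g, sigma2_b, sigma2_ge, sigma2_e)
# and trait means/directions for a germplasm panel spanning the three
# selection themes (yield, disease severity scores, root quality).
DEFAULT_VARIANCE_COMPONENTS = {
    "root_yield": (1.0, 0.3, 0.5, 1.0),
    "dry_matter": (1.0, 0.3, 0.5, 1.0),
    "plant_architecture": (1.0, 0.3, 0.5, 1.0),
    "mite_severity": (1.0, 0.3, 0.5, 1.0),
    "leaf_spot_severity": (1.0, 0.3, 0.5, 1.0),
    "hcn_score": (1.0, 0.3, 0.5, 1.0),
    "cooking_time": (1.0, 0.3, 0.5, 1.0),
}
DEFAULT_TRAIT_MEANS = {
    "root_yield": 17.5,
    "dry_matter": 34.9,
    "plant_architecture": 3.0,
    "mite_severity": 3.0,
    "leaf_spot_severity": 1.6,
    "hcn_score": 5.8,
    "cooking_time": 30.0,
}
DEFAULT_TRAIT_DIRECTIONS = {
    "root_yield": "higher",
    "dry_matter": "higher",
    "plant_architecture": "lower",
    "mite_severity": "lower",
    "leaf_spot_severity": "lower",
    "hcn_score": "lower",
    "cooking_time": "lower",
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic germplasm panel and its trials."""

    n_accessions: int = 300
    n_loci: int = 2000
    n_populations: int = 3
    fst: float = 0.10
    clone_pairs: int = 5
    clone_error_rate: float = 0.01
    maf_floor: float = 0.05
    missing_genotype_rate: float = 0.0
    n_environments: int = 3
    n_blocks_per_env: int = 2
    env_participation: float = 0.8
    variance_components: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_directions: dict = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_DIRECTIONS)
    )
    missing_phenotype_rate: float = 0.05
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        counts = {
            "n_accessions": self.n_accessions,
            "n_loci": self.n_loci,
            "n_populations": self.n_populations,
            "n_environments": self.n_environments,
            "n_blocks_per_env": self.n_blocks_per_env,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not (0 <= self.fst < 1):
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if self.clone_pairs < 0 or 2 * self.clone_pairs > self.n_accessions:
            raise ValueError(
                "clone budget exceeds accession count: need 2*clone_pairs <= n_accessions"
            )
        if not (0 <= self.clone_error_rate <= 0.05):
            raise ValueError("clone_error_rate must lie in [0, 0.05]")
        for p_name in ("missing_phenotype_rate", "missing_genotype_rate",
                       "env_participation"):
            p = getattr(self, p_name)
            if not (0 <= p <= 1):
                raise ValueError(f"{p_name} must lie in [0, 1], got {p}")
        if not (0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5)")
        for trait, vc in self.variance_components.items():
            if len(vc) != 4 or any(v < 0 for v in vc):
                raise ValueError(f"variance components for {trait} must be 4 values >= 0")
        return self


class GenotypeTruth(NamedTuple):
    """Ground truth attached to a simulated genotype panel."""

    clone_pairs: list  # (progenitor_id, clone_id)
    population: pd.Series  # accession -> population index
    pop_freqs: np.ndarray  # populations x loci allele frequencies


def _stage_rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng([int(spec.seed), stage])


def simulate_genotypes(spec: SimulationSpec):
    """Draw a structured SNP dosage panel with planted near-duplicates.

    Returns ``(GenotypeMatrix, GenotypeTruth)``. Accessions are named
    ``ACC0001``...; clones occupy the last ``clone_pairs`` slots and
    duplicate the first ``clone_pairs`` accessions, with each locus
    independently perturbed at ``clone_error_rate`` (a perturbed locus is
    redrawn uniformly from the other two dosage codes, modelling
    genotyping discordance between true duplicates).
    """
    spec.validate()
    rng = _stage_rng(spec, 1)
    n, m = spec.n_accessions, spec.n_loci
    p_anc = rng.uniform(spec.maf_floor, 1 - spec.maf_floor, size=m)
    if spec.fst > 0:
        a = p_anc * (1 - spec.fst) / spec.fst
        b = (1 - p_anc) * (1 - spec.fst) / spec.fst
        pop_freqs = rng.beta(a, b, size=(spec.n_populations, m))
    else:
        pop_freqs = np.tile(p_anc, (spec.n_populations, 1))

    n_founders = n - spec.clone_pairs
    pop = rng.integers(0, spec.n_populations, size=n)
    dos = np.empty((n, m))
    for i in range(n_founders):
        dos[i] = rng.binomial(2, pop_freqs[pop[i]])

    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    pairs = []
    for k in range(spec.clone_pairs):
        src, dst = k, n_founders + k
        pop[dst] = pop[src]
        row = dos[src].copy()
        flip = rng.random(m) < spec.clone_error_rate
        if flip.any():
            # redraw each discordant locus uniformly from the other two codes
            shift = rng.integers(1, 3, size=int(flip.sum()))
            row[flip] = (row[flip] + shift) % 3
        dos[dst] = row
        pairs.append((ids[src], ids[dst]))

    if spec.missing_genotype_rate > 0:
        mask = rng.random(dos.shape) < spec.missing_genotype_rate
        dos[mask] = np.nan

    per_chrom = int(np.ceil(m / N_CHROMOSOMES))
    chroms = [str(1 + j // per_chrom) for j in range(m)]
    positions = [1000 * (1 + j % per_chrom) for j in range(m)]
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ["A"] * m, "alt": ["T"] * m}
    )
    gm = GenotypeMatrix(accession_ids=ids, loci=loci, dosages=dos)
    truth = GenotypeTruth(
        clone_pairs=pairs,
        population=pd.Series(pop, index=ids, name="population"),
        pop_freqs=pop_freqs,
    )
    return gm, truth


def _draw_participation(rng, n_acc, n_env, p):
    """Environment membership per accession; every accession keeps >= 1 env."""
    take = rng.random((n_acc, n_env)) < p
    for _ in range(100):
        empty = ~take.any(axis=1)
        if not empty.any():
            return take
        take[empty] = rng.random((int(empty.sum()), n_env)) < p
    raise RuntimeError(
        "could not assign every accession to at least one environment; "
        "raise env_participation"
    )


def simulate_trials(genotypes, spec: SimulationSpec):
    """Generate unbalanced multi-environment trial records.

    ``genotypes`` may be a GenotypeMatrix or a plain list of accession ids.
    For each trait, per-accession genotypic effects g ~ N(0, sigma2_g),
    block-within-environment effects b ~ N(0, sigma2_b), accession x
    environment interactions ~ N(0, sigma2_ge) and residuals ~ N(0,
    sigma2_e) combine as y = mu + g + b + ge + e. Unbalance comes from
    random environment subsets per accession; records are then deleted
    completely at random at ``missing_phenotype_rate``.

    Returns ``(records, true_g)`` where ``true_g`` is a DataFrame indexed
    by accession with one column per trait.
    """
    spec.validate()
    ids = list(getattr(genotypes, "accession_ids", genotypes))
    rng = _stage_rng(spec, 2)
    n = len(ids)
    envs = [f"env{k + 1:02d}" for k in range(spec.n_environments)]
    take = _draw_participation(rng, n, spec.n_environments, spec.env_participation)

    true_g = {}
    frames = []
    for trait, (s2g, s2b, s2ge, s2e) in spec.variance_components.items():
        mu = spec.trait_means.get(trait, 0.0)
        g = rng.normal(0, np.sqrt(s2g), size=n)
        b = rng.normal(0, np.sqrt(s2b), size=(spec.n_environments, spec.n_blocks_per_env))
        ge = rng.normal(0, np.sqrt(s2ge), size=(n, spec.n_environments))
        true_g[trait] = g
        acc_idx, env_idx = np.where(take)
        reps = spec.n_blocks_per_env
        acc_idx = np.repeat(acc_idx, reps)
        env_idx = np.repeat(env_idx, reps)
        blk_idx = np.tile(np.arange(reps), int(len(acc_idx) / reps))
        e = rng.normal(0, np.sqrt(s2e), size=len(acc_idx))
        y = mu + g[acc_idx] + b[env_idx, blk_idx] + ge[acc_idx, env_idx] + e
        frames.append(
            pd.DataFrame(
                {
                    "accession": np.array(ids)[acc_idx],
                    "environment": np.array(envs)[env_idx],
                    "trial": np.array(envs)[env_idx],
                    "block": [f"b{k + 1}" for k in blk_idx],
                    "trait": trait,
                    "value": y,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    if spec.missing_phenotype_rate > 0:
        keep = rng.random(len(records)) >= spec.missing_phenotype_rate
        records = records[keep].reset_index(drop=True)
    truth = pd.DataFrame(true_g, index=ids)
    truth.index.name = "accession"
    return records, truth


def simulate_qualitative(
    spec: SimulationSpec,
    class_probs: dict,
    n_years: int,
    fidelity: float = 0.9,
    first_year: int = 2011,
):
    """Repeated yearly ordinal scores around a latent per-accession class.

    ``class_probs`` maps trait -> probability vector over classes 1..k.
    Each year's observation equals the latent class with probability
    ``fidelity``; otherwise it is drawn uniformly from the other classes.
    Returns ``(scores, latent)``: a long (accession, year, trait, value)
    table and the latent class table.
    """
    spec.validate()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if not (0 <= fidelity <= 1):
        raise ValueError("fidelity must lie in [0, 1]")
    rng = _stage_rng(spec, 3)
    ids = [f"ACC{i + 1:04d}" for i in range(spec.n_accessions)]
    years = [first_year + t for t in range(n_years)]
    rows = []
    latent_rows = {}
    for trait, probs in class_probs.items():
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"class probabilities for {trait} must sum to 1")
        k = len(probs)
        latent = rng.choice(np.arange(1, k + 1), size=spec.n_accessions, p=probs)
        latent_rows[trait] = latent
        for year in years:
            obs = latent.copy()
            if k > 1 and fidelity < 1:
                perturb = rng.random(spec.n_accessions) >= fidelity
                if perturb.any():
                    shift = rng.integers(1, k, size=int(perturb.sum()))
                    obs[perturb] = 1 + (obs[perturb] - 1 + shift) % k
            rows.append(
                pd.DataFrame(
                    {"accession": ids, "year": year, "trait": trait, "value": obs}
                )
            )
    scores = pd.concat(rows, ignore_index=True)[QUAL_COLUMNS]
    latent_df = pd.DataFrame(latent_rows, index=ids)
    latent_df.index.name = "accession"
    return scores, latent_df
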