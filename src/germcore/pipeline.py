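"""End-to-end orchestration: simulate/load -> BLUP -> select -> dedup ->
diversity -> validate, with TSV/JSON artifacts at every stage.

Each stage reads its inputs from the run directory and writes its outputs
there, so the CLI subcommands can run stages standalone and chaining them
reproduces ``run_pipeline`` exactly. A JSON manifest records input hashes,
the configuration, library versions and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diversity import (
    allele_retention,
    kappa_coincidence,
    make_binning,
    bin_quantitative,
    molecular_diversity,
    shannon_weaver,
)
from .io import (
    aggregate_mode,
    impute_mean,
    qc_filter,
    read_genotypes_vcf,
    read_qualitative,
    read_trial_records,
    write_genotypes_vcf,
    write_qualitative,
    write_trial_records,
)
from .kinship import find_duplicate_pairs, ibs_matrix
from .ordination import dapc, pca
from .reml import blup_frame, fit_all_traits, TraitBlup, VarianceComponents
from .select import (
    ThematicCollection,
    apply_eligibility,
    build_collection,
    rank_candidates,
    selection_summary,
)
from .simulate import simulate_genotypes, simulate_qualitative, simulate_trials
from .kinship import prune_duplicates

logger = logging.getLogger(__name__)

ART = {
    "genotypes": "genotypes.vcf",
    "phenotypes": "phenotypes.tsv",
    "qualitative": "qualitative_scores.tsv",
    "truth_g": "truth_genetic_values.tsv",
    "truth_latent": "truth_latent_classes.tsv",
    "truth_clones": "truth_clone_pairs.tsv",
    "qc_log": "qc_log.json",
    "modes": "qualitative_modes.tsv",
    "blups": "blups.tsv",
    "vc": "variance_components.json",
    "ranking": "ranking.tsv",
    "membership": "membership.tsv",
    "pairs": "duplicate_pairs.tsv",
    "kinship": "kinship_ibs.tsv",
    "summary": "selection_summary.json",
    "shannon": "shannon_weaver.tsv",
    "molecular": "molecular_diversity.tsv",
    "retention": "allele_retention.tsv",
    "kappa": "kappa.tsv",
    "pca_mol": "pca_molecular.tsv",
    "pca_phen": "pca_phenotypic.tsv",
    "dapc": "dapc_assignments.tsv",
    "manifest": "manifest.json",
}


def _path(cfg: PipelineConfig, key: str) -> Path:
    return Path(cfg.output_dir) / ART[key]


def _require(cfg: PipelineConfig, key: str, producer: str) -> Path:
    p = _path(cfg, key)
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {p.name}; run the '{producer}' stage first"
        )
    return p


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate genotypes, trials and qualitative scores (plus truth tables)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cfg.simulation
    if spec is None:
        raise ValueError("config has no simulation spec; provide real inputs instead")
    gm, truth = simulate_genotypes(spec)
    records, true_g = simulate_trials(gm, spec)
    write_genotypes_vcf(gm, _path(cfg, "genotypes"))
    write_trial_records(records, _path(cfg, "phenotypes"))
    true_g.to_csv(_path(cfg, "truth_g"), sep="\t")
    pd.DataFrame(truth.clone_pairs, columns=["progenitor", "clone"]).to_csv(
        _path(cfg, "truth_clones"), sep="\t", index=False
    )
    if cfg.qualitative.class_probs:
        scores, latent = simulate_qualitative(
            spec,
            cfg.qualitative.class_probs,
            n_years=cfg.qualitative.n_years,
            fidelity=cfg.qualitative.fidelity,
        )
        write_qualitative(scores, _path(cfg, "qualitative"))
        latent.to_csv(_path(cfg, "truth_latent"), sep="\t")
    return {"n_accessions": gm.n_accessions, "n_loci": gm.n_loci,
            "n_phenotype_records": len(records)}


def _load_genotypes(cfg: PipelineConfig):
    if cfg.inputs and cfg.inputs.get("genotypes_vcf"):
        path = Path(cfg.inputs["genotypes_vcf"])
    else:
        path = _require(cfg, "genotypes", "simulate")
    gm = read_genotypes_vcf(path)
    gm, log = qc_filter(gm, **cfg.qc)
    return gm, log, path


def _load_phenotypes(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.inputs and cfg.inputs.get("phenotypes_tsv"):
        return read_trial_records(cfg.inputs["phenotypes_tsv"])
    return read_trial_records(_require(cfg, "phenotypes", "simulate"))


def _load_qualitative(cfg: PipelineConfig) -> pd.DataFrame | None:
    if cfg.inputs and cfg.inputs.get("qualitative_tsv"):
        return read_qualitative(cfg.inputs["qualitative_tsv"])
    p = _path(cfg, "qualitative")
    return read_qualitative(p) if p.exists() else None


def stage_blup(cfg: PipelineConfig) -> dict:
    """Mode-aggregate qualitative scores; REML/BLUP per quantitative trait."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _load_phenotypes(cfg)
    qual = _load_qualitative(cfg)
    if qual is not None:
        aggregate_mode(qual).to_csv(_path(cfg, "modes"), sep="\t", index=False)
    blups = fit_all_traits(records)
    blup_frame(blups).to_csv(_path(cfg, "blups"), sep="\t", index=False)
    vc_json = {t: tb.vc.as_dict() | {"mu": tb.mu, "h2": tb.h2}
               for t, tb in blups.items()}
    _path(cfg, "vc").write_text(json.dumps(vc_json, indent=2))
    return {"n_traits": len(blups),
            "n_records": len(records)}


def _read_blups(cfg: PipelineConfig) -> dict:
    frame = pd.read_csv(_require(cfg, "blups", "blup"), sep="\t")
    vc_json = json.loads(_require(cfg, "vc", "blup").read_text())
    blups = {}
    for trait, grp in frame.groupby("trait"):
        meta = vc_json[trait]
        vc = VarianceComponents(
            sigma2_g=meta["sigma2_g"], sigma2_b=meta["sigma2_b"],
            sigma2_ge=meta["sigma2_ge"], sigma2_e=meta["sigma2_e"],
            converged=meta["converged"], n_iterations=meta["n_iterations"],
            loglik=meta["loglik"], dropped=tuple(meta["dropped"]),
        )
        g_hat = pd.Series(
            grp["g_hat"].to_numpy(), index=grp["accession"].to_numpy(), name=trait
        )
        blups[trait] = TraitBlup(trait=trait, mu=float(meta["mu"]), g_hat=g_hat,
                                 vc=vc, h2=float(meta["h2"]))
    return blups


def _read_modes(cfg: PipelineConfig) -> pd.DataFrame | None:
    p = _path(cfg, "modes")
    return pd.read_csv(p, sep="\t") if p.exists() else None


def stage_select(cfg: PipelineConfig) -> dict:
    """Rank, filter and truncate the initial thematic collections.

    Also writes the full post-eligibility ranking per theme so dedup can
    backfill slots from it when requested.
    """
    blups = _read_blups(cfg)
    modes = _read_modes(cfg)
    collections = [build_collection(blups, theme, modes) for theme in cfg.themes]
    ranking_rows = []
    for theme in cfg.themes:
        ranked = rank_candidates(blups, theme)
        filtered, _ = apply_eligibility(ranked, theme, modes, blups)
        filtered = filtered.copy()
        filtered.insert(0, "collection", theme.name)
        ranking_rows.append(filtered)
    pd.concat(ranking_rows, ignore_index=True).to_csv(
        _path(cfg, "ranking"), sep="\t", index=False
    )
    _write_membership(cfg, collections)
    return {c.name: c.size for c in collections}


def _write_membership(cfg: PipelineConfig, collections) -> None:
    rows = []
    for coll in collections:
        for rank_i, acc in enumerate(coll.members, start=1):
            rows.append(
                {"collection": coll.name, "accession": acc,
                 "composite_score": coll.scores[acc], "rank": rank_i,
                 "status": "member", "stage": coll.stage,
                 "removal_reason": ""}
            )
        for row in coll.removed.itertuples(index=False):
            rows.append(
                {"collection": coll.name, "accession": row.accession,
                 "composite_score": np.nan, "rank": np.nan,
                 "status": "removed", "stage": coll.stage,
                 "removal_reason": f"{row.reason}:{row.detail}"}
            )
    pd.DataFrame(rows).to_csv(_path(cfg, "membership"), sep="\t", index=False)


def _read_membership(cfg: PipelineConfig, producer="select") -> list:
    frame = pd.read_csv(_require(cfg, "membership", producer), sep="\t",
                        keep_default_na=False, na_values=[""])
    collections = []
    for theme in cfg.themes:
        sub = frame[frame["collection"] == theme.name]
        members = sub[sub["status"] == "member"].sort_values("rank")
        removed = sub[sub["status"] == "removed"]
        reasons = removed["removal_reason"].str.split(":", n=1, expand=True)
        removed_df = pd.DataFrame(
            {
                "accession": removed["accession"].to_numpy(),
                "reason": reasons[0].to_numpy() if len(removed) else [],
                "detail": (reasons[1].fillna("").to_numpy()
                           if len(removed) and reasons.shape[1] > 1
                           else [""] * len(removed)),
            }
        )
        stage = members["stage"].iloc[0] if len(members) else "initial"
        collections.append(
            ThematicCollection(
                name=theme.name,
                members=list(members["accession"]),
                scores=pd.Series(members["composite_score"].to_numpy(),
                                 index=members["accession"].to_numpy()),
                stage=str(stage),
                removed=removed_df,
            )
        )
    return collections


def stage_dedup(cfg: PipelineConfig) -> dict:
    """IBS kinship among selected members and per-collection pruning."""
    gm, qc_log, _ = _load_genotypes(cfg)
    _path(cfg, "qc_log").write_text(json.dumps(qc_log, indent=2))
    collections = _read_membership(cfg)
    genotyped = set(gm.accession_ids)
    union = sorted(
        {a for c in collections for a in c.members if a in genotyped}
    )
    km = ibs_matrix(gm, union)
    km.to_frame().to_csv(_path(cfg, "kinship"), sep="\t")
    pairs = find_duplicate_pairs(km, cfg.ibs_threshold)
    pruned = [prune_duplicates(c, pairs) for c in collections]
    if cfg.backfill:
        pruned = [_backfill(cfg, c, km) for c in pruned]
    all_removed = set()
    for c in pruned:
        all_removed |= set(
            c.removed.loc[c.removed["reason"] == "duplicate", "accession"]
        )
    pairs["removed_id"] = [
        ";".join(sorted({r.id1, r.id2} & all_removed))
        for r in pairs.itertuples(index=False)
    ]
    pairs.to_csv(_path(cfg, "pairs"), sep="\t", index=False)
    _write_membership(cfg, pruned)
    summary = selection_summary(pruned)
    _path(cfg, "summary").write_text(json.dumps(summary, indent=2))
    return summary


def _backfill(cfg: PipelineConfig, coll: ThematicCollection, km) -> ThematicCollection:
    """Refill slots freed by dedup from the saved post-eligibility ranking.

    Candidates are taken best-first, skipping anyone already a member or
    removed, and skipping candidates whose IBS with a current member
    exceeds the threshold (no new duplicates).
    """
    theme = next(t for t in cfg.themes if t.name == coll.name)
    need = theme.n_target - coll.size
    if need <= 0:
        return coll
    ranking = pd.read_csv(_require(cfg, "ranking", "select"), sep="\t")
    ranking = ranking[ranking["collection"] == coll.name]
    taken = set(coll.members) | set(coll.removed["accession"])
    kin = km.to_frame()
    members = list(coll.members)
    scores = coll.scores.copy()
    added = []
    for row in ranking.itertuples(index=False):
        if need <= 0:
            break
        acc = row.accession
        if acc in taken:
            continue
        if acc in kin.index:
            sim = kin.loc[acc, [m for m in members if m in kin.columns]]
            if len(sim) and np.nanmax(sim.to_numpy(dtype=float)) > cfg.ibs_threshold:
                continue
        members.append(acc)
        scores[acc] = row.composite_score
        added.append(acc)
        need -= 1
    if added:
        logger.info("backfill for %s: added %s", coll.name, added)
    return ThematicCollection(
        name=coll.name, members=members, scores=scores,
        stage=coll.stage, removed=coll.removed,
    )


def stage_diversity(cfg: PipelineConfig) -> dict:
    """Shannon-Weaver, molecular diversity, allele retention and Kappa."""
    gm, _, _ = _load_genotypes(cfg)
    blups = _read_blups(cfg)
    modes = _read_modes(cfg)
    collections = _read_membership(cfg, producer="dedup")
    genotyped = set(gm.accession_ids)

    shannon_rows = []
    for trait, tb in blups.items():
        values = tb.predicted
        scheme = make_binning(values, trait, cfg.shannon_bins)
        entire_classes = bin_quantitative(values.to_numpy(), scheme)
        shannon_rows.append(
            {"trait": trait, "collection": "ENTIRE",
             "h_norm": shannon_weaver(entire_classes, scheme.k_classes)}
        )
        for coll in collections:
            sub = values.reindex(coll.members).dropna()
            h = (shannon_weaver(bin_quantitative(sub.to_numpy(), scheme),
                                scheme.k_classes)
                 if len(sub) else float("nan"))
            shannon_rows.append(
                {"trait": trait, "collection": coll.name, "h_norm": h}
            )
    if modes is not None:
        k_defined = cfg.qualitative.k_classes
        for trait, grp in modes.groupby("trait"):
            k = k_defined.get(trait, int(grp["value"].max()))
            series = grp.set_index("accession")["value"]
            shannon_rows.append(
                {"trait": trait, "collection": "ENTIRE",
                 "h_norm": shannon_weaver(series.to_numpy(), k)}
            )
            for coll in collections:
                sub = series.reindex(coll.members).dropna()
                h = shannon_weaver(sub.to_numpy(), k) if len(sub) else float("nan")
                shannon_rows.append(
                    {"trait": trait, "collection": coll.name, "h_norm": h}
                )
    pd.DataFrame(shannon_rows).to_csv(_path(cfg, "shannon"), sep="\t", index=False)

    mol_rows, ret_rows = [], []
    _, entire_means = molecular_diversity(gm)
    mol_rows.append({"collection": "ENTIRE", "n": gm.n_accessions, **entire_means})
    ref_ids = list(gm.accession_ids)
    for coll in collections:
        ids = [a for a in coll.members if a in genotyped]
        if len(ids) < 2:
            continue
        _, means = molecular_diversity(gm, ids)
        mol_rows.append({"collection": coll.name, "n": len(ids), **means})
        ret = allele_retention(gm, ids, ref_ids)
        ret_rows.append({"collection": coll.name, **ret})
    pd.DataFrame(mol_rows).to_csv(_path(cfg, "molecular"), sep="\t", index=False)
    pd.DataFrame(ret_rows).to_csv(_path(cfg, "retention"), sep="\t", index=False)

    universe = sorted(set().union(*(set(b.g_hat.index) for b in blups.values())))
    kappa = kappa_coincidence(
        {c.name: c.members for c in collections}, universe=universe
    )
    kappa.to_csv(_path(cfg, "kappa"), sep="\t")
    return {
        "retention": {r["collection"]: r["retention_pct"] for r in ret_rows},
        "mean_ho_entire": entire_means["ho"],
    }


def stage_validate(cfg: PipelineConfig) -> dict:
    """PCA on molecular and phenotypic matrices; DAPC over collections."""
    gm, _, _ = _load_genotypes(cfg)
    blups = _read_blups(cfg)
    collections = _read_membership(cfg, producer="dedup")

    gi = impute_mean(gm)
    res_mol = pca(gi.dosages, center=True, scale=False,
                  sample_ids=gi.accession_ids)
    _write_pca(res_mol, _path(cfg, "pca_mol"))

    phen = pd.DataFrame({t: b.g_hat for t, b in blups.items()}).dropna()
    res_phen = pca(phen.to_numpy(), center=True, scale=True,
                   sample_ids=list(phen.index))
    _write_pca(res_phen, _path(cfg, "pca_phen"))

    # one label per accession; earlier themes in the config take priority
    label = {}
    for coll in collections:
        for a in coll.members:
            label.setdefault(a, coll.name)
    members = [a for a in gi.accession_ids if a in label]
    idx = gi.index_of(members)
    groups = np.array([label[a] for a in members])
    res_dapc = dapc(gi.dosages[idx], groups, cfg.dapc_variance_fraction,
                    sample_ids=members)
    pd.DataFrame(
        {
            "accession": members,
            "prior_group": groups,
            "posterior_group": res_dapc.assigned,
            "posterior_probability": res_dapc.posterior.max(axis=1),
        }
    ).to_csv(_path(cfg, "dapc"), sep="\t", index=False)
    return {
        "pca_molecular_pc1": float(res_mol.explained[0]),
        "pca_phenotypic_pc1": float(res_phen.explained[0]),
        "dapc_retained_pcs": res_dapc.retained_pcs,
        "dapc_accuracy": res_dapc.accuracy,
        "dapc_accuracy_by_group": res_dapc.accuracy_by_group,
    }


def _write_pca(res, path) -> None:
    k = min(10, res.scores.shape[1])
    frame = pd.DataFrame(
        res.scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
    )
    if res.sample_ids is not None:
        frame.insert(0, "accession", res.sample_ids)
    frame["explained_pc1"] = res.explained[0]
    frame.to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the run manifest. Returns the manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    if cfg.simulation is not None:
        counts["simulate"] = stage_simulate(cfg)
    counts["blup"] = stage_blup(cfg)
    counts["select"] = stage_select(cfg)
    counts["dedup"] = stage_dedup(cfg)
    counts["diversity"] = stage_diversity(cfg)
    counts["validate"] = stage_validate(cfg)

    for coll in counts["dedup"]["collections"]:
        assert coll["initial"] - coll["removed"] == coll["final"]

    inputs = {}
    for key in ("genotypes", "phenotypes", "qualitative"):
        p = _path(cfg, key)
        if cfg.inputs:
            p = Path(cfg.inputs.get(f"{key}_vcf" if key == "genotypes"
                                    else f"{key}_tsv", p))
        if Path(p).exists():
            inputs[key] = {"path": str(p), "sha256": _sha256(p)}
    cfg_echo = asdict(cfg)
    cfg_echo["output_dir"] = str(cfg_echo["output_dir"])
    cfg_echo["themes"] = [
        {**asdict(t),
         "filters": [
             {k: (sorted(v) if isinstance(v, frozenset) else v)
              for k, v in asdict(f).items()} for f in t.filters
         ]}
        for t in cfg.themes
    ]
    if cfg.simulation is not None:
        cfg_echo["simulation"] = asdict(cfg.simulation)
    manifest = {
        "germcore_version": __version__,
        "versions": _versions(),
        "seed": cfg.seed,
        "config": cfg_echo,
        "inputs": inputs,
        "stage_counts": counts,
    }
    _path(cfg, "manifest").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
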