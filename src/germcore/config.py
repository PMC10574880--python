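"""Pipeline and theme configuration (YAML/JSON) with schema validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinship import DEFAULT_IBS_THRESHOLD
from .diversity import DEFAULT_N_BINS
from .select import EligibilityFilter, ThemeSpec
from .simulate import SimulationSpec

_KNOWN_TOP = {
    "seed", "output_dir", "simulation", "inputs", "qc", "ibs_threshold",
    "shannon_bins", "dapc_variance_fraction", "themes", "qualitative",
    "backfill", "log_level",
}
_KNOWN_THEME = {"name", "n_target", "traits", "filters"}
_KNOWN_FILTER = {"trait", "op", "value", "allowed"}
_KNOWN_QUAL = {"class_probs", "n_years", "fidelity"}


@dataclass
class QualitativeSpec:
    """Which qualitative descriptors to simulate/score and their classes."""

    class_probs: dict = field(default_factory=dict)  # trait -> prob vector
    n_years: int = 3
    fidelity: float = 0.9

    @property
    def k_classes(self) -> dict:
        return {t: len(p) for t, p in self.class_probs.items()}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("germcore_out")
    simulation: SimulationSpec | None = None
    inputs: dict | None = None  # genotypes_vcf, phenotypes_tsv, qualitative_tsv
    qc: dict = field(default_factory=lambda: {"maf_min": 0.05, "max_missing": 0.20})
    ibs_threshold: float = DEFAULT_IBS_THRESHOLD
    shannon_bins: int = DEFAULT_N_BINS
    dapc_variance_fraction: float = 0.80
    themes: list = field(default_factory=list)  # list[ThemeSpec]
    qualitative: QualitativeSpec = field(default_factory=QualitativeSpec)
    backfill: bool = False

    def validate(self) -> "PipelineConfig":
        if self.simulation is None and not self.inputs:
            raise ValueError("config needs either a simulation spec or input paths")
        if not self.themes:
            raise ValueError("config defines no thematic collections")
        if not (0 < self.ibs_threshold <= 1):
            raise ValueError("ibs_threshold must lie in (0, 1]")
        if self.simulation is not None:
            self.simulation.validate()
        return self


def _build_filter(d: dict) -> EligibilityFilter:
    unknown = set(d) - _KNOWN_FILTER
    if unknown:
        raise ValueError(f"unknown filter keys: {sorted(unknown)}")
    allowed = frozenset(d["allowed"]) if "allowed" in d else None
    return EligibilityFilter(
        trait=d["trait"], op=d.get("op"), value=d.get("value"), allowed=allowed
    )


def _build_theme(d: dict) -> ThemeSpec:
    unknown = set(d) - _KNOWN_THEME
    if unknown:
        raise ValueError(f"unknown theme keys: {sorted(unknown)}")
    return ThemeSpec(
        name=d["name"],
        traits=dict(d["traits"]),
        n_target=int(d["n_target"]),
        filters=tuple(_build_filter(f) for f in d.get("filters", ())),
    )


def config_from_dict(data: dict) -> PipelineConfig:
    unknown = set(data) - _KNOWN_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = None
    if data.get("simulation") is not None:
        sim_d = dict(data["simulation"])
        sim_d.setdefault("seed", data.get("seed", 0))
        vc = sim_d.get("variance_components")
        if vc is not None:
            sim_d["variance_components"] = {t: tuple(v) for t, v in vc.items()}
        try:
            sim = SimulationSpec(**sim_d)
        except TypeError as exc:
            raise ValueError(f"invalid simulation key: {exc}") from exc
    qual_d = dict(data.get("qualitative") or {})
    unknown_q = set(qual_d) - _KNOWN_QUAL
    if unknown_q:
        raise ValueError(f"unknown qualitative keys: {sorted(unknown_q)}")
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        output_dir=Path(data.get("output_dir", "germcore_out")),
        simulation=sim,
        inputs=data.get("inputs"),
        qc=dict(data.get("qc") or {"maf_min": 0.05, "max_missing": 0.20}),
        ibs_threshold=float(data.get("ibs_threshold", DEFAULT_IBS_THRESHOLD)),
        shannon_bins=int(data.get("shannon_bins", DEFAULT_N_BINS)),
        dapc_variance_fraction=float(data.get("dapc_variance_fraction", 0.80)),
        themes=[_build_theme(t) for t in data.get("themes", [])],
        qualitative=QualitativeSpec(**qual_d),
        backfill=bool(data.get("backfill", False)),
    )
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return config_from_dict(data)


def demo_config(output_dir, seed: int = 0, n_accessions: int = 300,
                n_loci: int = 2000) -> PipelineConfig:
    """A self-contained simulated-germplasm configuration.

    Three themes mirror the standard breeding targets: yield, pest and
    disease resistance, and root quality (with hard filters on cyanogenic
    score, cooking time, pulp color and cooked friability).
    """
    sim = SimulationSpec(n_accessions=n_accessions, n_loci=n_loci, seed=seed)
    themes = [
        ThemeSpec(
            name="CC_Yield",
            traits={
                "root_yield": "higher",
                "dry_matter": "higher",
                "plant_architecture": "lower",
            },
            n_target=30,
        ),
        ThemeSpec(
            name="CC_Disease",
            traits={"mite_severity": "lower", "leaf_spot_severity": "lower"},
            n_target=30,
        ),
        ThemeSpec(
            name="CC_Root_quality",
            traits={"hcn_score": "lower", "cooking_time": "lower"},
            n_target=30,
            filters=(
                EligibilityFilter(trait="hcn_score", op="<", value=7.0),
                EligibilityFilter(trait="pulp_color", allowed=frozenset({2, 3})),
                EligibilityFilter(trait="friability", allowed=frozenset({3, 4})),
            ),
        ),
    ]
    qualitative = QualitativeSpec(
        class_probs={
            "pulp_color": [0.35, 0.35, 0.30],  # white, cream, yellow
            "friability": [0.15, 0.25, 0.35, 0.25],
        },
        n_years=3,
    )
    return PipelineConfig(
        seed=seed,
        output_dir=Path(output_dir),
        simulation=sim,
        themes=themes,
        qualitative=qualitative,
    ).validate()
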