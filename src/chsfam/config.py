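"""Declarative pipeline configuration (YAML, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from .pipeline import AnalysisParams
from .simulate import SimConfig, default_species_table

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    within_class_divergence: float = 0.05
    between_class_divergence: float = 0.5
    con1_length: int = 141
    n_reference_per_class: int = 3
    head_to_head_fraction: float = 0.95
    intervening_gene_probability: float = 17.0 / 95.0
    species_preset: Literal["default", "mini"] = "default"


class ScreenSection(_Strict):
    evalue_max: float = 1e-5


class PhyloSection(_Strict):
    site_rule: Literal["partial_deletion", "pairwise_deletion"] = "partial_deletion"
    coverage: float = 0.95
    correction: Literal["poisson"] | None = None
    n_reps: int = 100


class ClassifySection(_Strict):
    support_threshold: float = 60.0
    strict_support: bool = True


class SyntenySection(_Strict):
    max_intervening: int = 1
    max_distance: int | None = None


class PipelineConfig(_Strict):
    workdir: str = "chsfam_run"
    seed: int = 0
    pattern_set: Literal["primary", "alternate"] = "primary"
    simulate: SimulateSection = SimulateSection()
    screen: ScreenSection = ScreenSection()
    phylo: PhyloSection = PhyloSection()
    classify: ClassifySection = ClassifySection()
    synteny: SyntenySection = SyntenySection()

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            pattern_set=self.pattern_set,
            evalue_max=self.screen.evalue_max,
            site_rule=self.phylo.site_rule,
            coverage=self.phylo.coverage,
            correction=self.phylo.correction,
            n_reps=self.phylo.n_reps,
            support_threshold=self.classify.support_threshold,
            strict_support=self.classify.strict_support,
            max_intervening=self.synteny.max_intervening,
            max_distance=self.synteny.max_distance,
            seed=self.seed,
        )

    def sim_config(self) -> SimConfig:
        if self.simulate.species_preset == "mini":
            species = _mini_species_table()
        else:
            species = default_species_table()
        return SimConfig(
            seed=self.seed,
            species=species,
            within_class_divergence=self.simulate.within_class_divergence,
            between_class_divergence=self.simulate.between_class_divergence,
            con1_length=self.simulate.con1_length,
            n_reference_per_class=self.simulate.n_reference_per_class,
            head_to_head_fraction=self.simulate.head_to_head_fraction,
            intervening_gene_probability=self.simulate.intervening_gene_probability,
        )


def _mini_species_table():
    from .simulate import SpeciesSpec

    full = {c: 1 for c in ("I", "II", "III", "IV", "V", "VI", "VII")}
    return (
        SpeciesSpec(
            species_id="sp01",
            lineage=("Ascomycota", "Pezizomycotina", "Sordariomycetes"),
            class_counts=dict(full),
            tandem_vii_v=True,
        ),
        SpeciesSpec(
            species_id="sp02",
            lineage=("Ascomycota", "Pezizomycotina", "Sordariomycetes"),
            class_counts=dict(full),
            tandem_vii_v=True,
        ),
        SpeciesSpec(
            species_id="sp03",
            lineage=("Chytridiomycota",),
            tags=("early_diverging",),
            class_counts={"IV": 1, "VI": 1},
            n_noisy_b1=3,
        ),
    )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; a missing path yields the defaults.
    Unknown keys raise a validation error naming the key."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(doc)
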