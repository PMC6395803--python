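"""The default synthetic study system and its headline analysis.

One call builds the standard fixture — a 120x120 mountain landscape with
six latent gradients, 250 virtual species and 1,200 survey plots — and the
recovery analysis runs the predictor-substitution experiment plus the
indicator-mappability cross-validation on it, returning the quantities the
framework is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .eiv_mapping import map_all_dimensions
from .experiment import ExperimentConfig, ExperimentResult, run_experiment
from .importance import shannon_evenness
from .simulate import (
    LandscapeBundle,
    PlotCommunityMatrix,
    VirtualSpecies,
    assemble_communities,
    default_landscape_config,
    default_species_config,
    generate_landscape,
    generate_species_pool,
)
from .site_eiv import SiteEIVCalculator, SpeciesEIVTable

__all__ = ["StudySystem", "default_study_system", "recovery_analysis"]

DEFAULT_N_SPECIES = 250
DEFAULT_N_PLOTS = 1200
DEFAULT_MIN_PRESENCES = 30


@dataclass
class StudySystem:
    landscape: LandscapeBundle
    species_pool: list[VirtualSpecies]
    plots: PlotCommunityMatrix
    eivs: SpeciesEIVTable
    seed: int


def default_study_system(seed: int = 1) -> StudySystem:
    """Generate the default fixture; sub-stage seeds derive from ``seed``."""
    landscape = generate_landscape(default_landscape_config(), seed=seed)
    pool = generate_species_pool(
        landscape, DEFAULT_N_SPECIES, default_species_config(), seed=seed + 1
    )
    plots = assemble_communities(
        landscape, pool, DEFAULT_N_PLOTS, seed=seed + 2
    )
    return StudySystem(
        landscape=landscape,
        species_pool=pool,
        plots=plots,
        eivs=SpeciesEIVTable.from_species_pool(pool),
        seed=seed,
    )


def mean_importance_evenness(
    result: ExperimentResult, predictor_set: str, technique: str = "GLM"
) -> float:
    """Evenness of the species-averaged normalised importance profile."""
    sub = result.importances[
        (result.importances.predictor_set == predictor_set)
        & (result.importances.technique == technique)
    ]
    profile = sub.groupby("variable")["importance_normalised"].mean()
    return shannon_evenness(profile.to_numpy())


def recovery_analysis(
    seed: int = 1,
    techniques: tuple[str, ...] = ("GLM",),
    predictor_sets: tuple[str, ...] = ("M_ref", "M_T", "M_EIV"),
    mapping_techniques: tuple[str, ...] = ("GLM",),
    n_mapping_repeats: int = 25,
) -> dict:
    """Run the substitution experiment and the EIV-mappability analysis on
    the default fixture and collect the headline quantities."""
    system = default_study_system(seed)
    config = ExperimentConfig(
        techniques=techniques,
        predictor_sets=predictor_sets,
        min_presences=DEFAULT_MIN_PRESENCES,
        internal_evaluation=False,
        include_mcor=False,
        compute_importance=True,
        master_seed=seed,
    )
    result = run_experiment(system.plots, system.eivs, config)

    ext = result.metrics[result.metrics.eval_kind == "external"]
    auc_tab = ext.pivot(index="species_id", columns="predictor_set",
                        values="auc")
    d2_tab = ext.pivot(index="species_id", columns="predictor_set",
                       values="d2")
    delta_eiv = (auc_tab["M_EIV"] - auc_tab["M_ref"]).dropna()
    delta_t = (auc_tab["M_T"] - auc_tab["M_ref"]).dropna()

    site = SiteEIVCalculator(system.plots, system.eivs).site_eivs(None)
    mapping = map_all_dimensions(
        site.values,
        system.plots.plot_predictors,
        techniques=mapping_techniques,
        n_repeats=n_mapping_repeats,
        seed=seed,
    )
    best_r = mapping.groupby("dimension")["mean_r"].max()

    return {
        "system": system,
        "result": result,
        "mapping": mapping,
        "n_modelled_species": len(auc_tab),
        "fraction_improved_auc_eiv": float((delta_eiv > 0).mean()),
        "median_delta_auc_eiv": float(delta_eiv.median()),
        "median_delta_auc_t": float(delta_t.median()),
        "median_auc_ref": float(auc_tab["M_ref"].median()),
        "median_auc_eiv": float(auc_tab["M_EIV"].median()),
        "median_d2_ref": float(d2_tab["M_ref"].median()),
        "median_d2_eiv": float(d2_tab["M_EIV"].median()),
        "evenness_ref": mean_importance_evenness(result, "M_ref"),
        "evenness_eiv": mean_importance_evenness(result, "M_EIV"),
        "mapping_r": best_r.to_dict(),
        "best_mapped_dimension": str(best_r.idxmax()),
        "worst_mapped_dimension": str(best_r.idxmin()),
    }
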