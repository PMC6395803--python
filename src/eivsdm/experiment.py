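"""The predictor-substitution experiment.

Ten named predictor sets are compared: a reference set of six mapped
environmental predictors (M_ref); eight sets in which one class of mapped
predictors is replaced by the corresponding site indicator value (M_T,
M_Soil, M_R, M_N, M_M, M_K, M_L) or all of them are (M_EIV); and M_cor,
the mapped candidates most strongly rank-correlated with the six site
EIVs.  For every modellable species the pipeline computes leave-one-out
site EIVs, splits plots 70/30 into calibration and external evaluation,
fits each technique on each predictor set, evaluates internally (repeated
70/30 resplits of the calibration plots) and externally, and measures
permutation variable importance.

External evaluation plots are never used in any fitting step; a guard
raises if a fit ever touches them.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engines import ModelSpec, fit_sdm, predict_sdm
from .evaluation import (
    d2_from_scores,
    evaluate_scores,
    make_split_scheme,
)
from .importance import (
    importance_table,
    pairwise_wilcoxon_holm,
)
from .simulate import PlotCommunityMatrix, filter_species_by_prevalence
from .site_eiv import EIV_DIMENSIONS, SiteEIVCalculator, SpeciesEIVTable

__all__ = [
    "PredictorSource",
    "PredictorSetDefinition",
    "ExperimentConfig",
    "ExperimentResult",
    "LeakageError",
    "DEFAULT_MAPPED_ROLES",
    "PREDICTOR_SET_NAMES",
    "build_predictor_sets",
    "select_best_correlated",
    "run_experiment",
    "summarize",
    "assert_no_leakage",
]

logger = logging.getLogger(__name__)

#: design-matrix column prefix for site-EIV predictors
EIV_PREFIX = "eiv_"

#: default mapping of predictor roles to mapped-layer columns
DEFAULT_MAPPED_ROLES: dict[str, object] = {
    "temperature": "temperature",
    "soil": "ph",
    "water": "precipitation",
    "topography": ["topo_position", "slope"],
    "light": "radiation",
}

PREDICTOR_SET_NAMES = (
    "M_ref", "M_cor", "M_T", "M_Soil", "M_R", "M_N", "M_M", "M_K", "M_L",
    "M_EIV",
)


class LeakageError(RuntimeError):
    """A fit attempted to use external evaluation plots."""


@dataclass(frozen=True)
class PredictorSource:
    kind: str  # "mapped" or "eiv"
    name: str  # mapped column name, or EIV dimension code

    def __post_init__(self) -> None:
        if self.kind not in ("mapped", "eiv"):
            raise ValueError(f"unknown source kind {self.kind!r}")

    @property
    def column(self) -> str:
        return self.name if self.kind == "mapped" else EIV_PREFIX + self.name


@dataclass(frozen=True)
class PredictorSetDefinition:
    name: str
    sources: tuple[PredictorSource, ...]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(s.column for s in self.sources)

    @property
    def eiv_dimensions(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources if s.kind == "eiv")


def _mapped(name: str) -> PredictorSource:
    return PredictorSource("mapped", name)


def _eiv(dim: str) -> PredictorSource:
    return PredictorSource("eiv", dim)


def build_predictor_sets(
    mapped_roles: dict[str, object] | None = None,
    cor_mapping: dict[str, str] | None = None,
) -> list[PredictorSetDefinition]:
    """Construct the named predictor sets from role -> column assignments.

    ``mapped_roles`` assigns a mapped column to each of the roles
    temperature, soil, water, light and a list of columns to topography.
    ``cor_mapping`` (EIV dimension -> best-correlated candidate column)
    enables M_cor; without it the other nine sets are returned.
    """
    roles = dict(DEFAULT_MAPPED_ROLES if mapped_roles is None else mapped_roles)
    required = ("temperature", "soil", "water", "topography", "light")
    for role in required:
        if role not in roles or roles[role] in (None, [], ""):
            raise ValueError(f"missing mapped column for role {role!r}")
    topo = roles["topography"]
    topo = [topo] if isinstance(topo, str) else list(topo)

    temp = _mapped(str(roles["temperature"]))
    soil = _mapped(str(roles["soil"]))
    water = _mapped(str(roles["water"]))
    light = _mapped(str(roles["light"]))
    topo_src = tuple(_mapped(t) for t in topo)

    ref = (temp, soil, water) + topo_src + (light,)

    def substitute(old: PredictorSource, new: tuple[PredictorSource, ...]):
        out: list[PredictorSource] = []
        for s in ref:
            if s == old:
                out.extend(new)
            else:
                out.append(s)
        return tuple(out)

    sets = [
        PredictorSetDefinition("M_ref", ref),
        PredictorSetDefinition("M_T", substitute(temp, (_eiv("T"),))),
        PredictorSetDefinition(
            "M_Soil", substitute(soil, (_eiv("N"), _eiv("R")))
        ),
        PredictorSetDefinition("M_R", substitute(soil, (_eiv("R"),))),
        PredictorSetDefinition("M_N", substitute(soil, (_eiv("N"),))),
        PredictorSetDefinition("M_M", substitute(water, (_eiv("M"),))),
        PredictorSetDefinition("M_L", substitute(light, (_eiv("L"),))),
    ]
    # topography (possibly two columns) collapses to the single
    # continentality indicator value
    mk: list[PredictorSource] = []
    seen_topo = False
    for s in ref:
        if s in topo_src:
            if not seen_topo:
                mk.append(_eiv("K"))
                seen_topo = True
        else:
            mk.append(s)
    sets.append(PredictorSetDefinition("M_K", tuple(mk)))
    sets.append(
        PredictorSetDefinition(
            "M_EIV", tuple(_eiv(d) for d in ("T", "N", "R", "M", "K", "L"))
        )
    )
    if cor_mapping is not None:
        cols: list[PredictorSource] = []
        for d in ("T", "N", "R", "M", "K", "L"):
            if d not in cor_mapping:
                raise ValueError(f"cor_mapping lacks dimension {d!r}")
            src = _mapped(cor_mapping[d])
            if src not in cols:  # duplicates collapse, logged
                cols.append(src)
            else:
                logger.info(
                    "M_cor: column %r selected for several dimensions",
                    cor_mapping[d],
                )
        sets.insert(1, PredictorSetDefinition("M_cor", tuple(cols)))
    return sets


def select_best_correlated(
    site_eivs: pd.DataFrame, candidate_predictors: pd.DataFrame
) -> dict[str, str]:
    """Per EIV dimension, the candidate column with maximum absolute
    Spearman correlation over complete plot rows; ties broken by column
    order."""
    if candidate_predictors.shape[1] == 0:
        raise ValueError("no candidate predictor columns")
    out: dict[str, str] = {}
    for dim in site_eivs.columns:
        best_col, best_rho = None, -np.inf
        for col in candidate_predictors.columns:
            pair = pd.concat(
                [site_eivs[dim], candidate_predictors[col]], axis=1
            ).dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete rows for ({dim}, {col})"
                )
            rho = abs(pair.iloc[:, 0].corr(pair.iloc[:, 1], method="spearman"))
            if rho > best_rho:
                best_col, best_rho = col, rho
        out[dim] = best_col
        logger.debug("M_cor screen: %s -> %s (|rho|=%.3f)", dim, best_col,
                     best_rho)
    return out


@dataclass
class ExperimentConfig:
    techniques: tuple[str, ...] = ("GLM", "GAM", "RF", "MAXENT", "SRE")
    predictor_sets: tuple[str, ...] | None = None  # None = all available
    mapped_roles: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_MAPPED_ROLES)
    )
    min_presences: int = 30
    n_internal: int = 10
    internal_evaluation: bool = True
    compute_importance: bool = True
    n_permutations: int = 10
    include_mcor: bool = True
    #: candidate columns for the M_cor screen; None = all plot predictors
    mcor_candidates: tuple[str, ...] | None = None
    master_seed: int = 0
    hyperparameters: dict[str, dict] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    importances: pd.DataFrame
    comparisons: pd.DataFrame
    summaries: pd.DataFrame
    species: list[str]
    predictor_sets: list[PredictorSetDefinition]
    n_fits: int
    evaluation_id_hash: dict[str, int]
    failures: list[dict]
    master_seed: int = 0


def assert_no_leakage(train_ids, forbidden: frozenset) -> None:
    """Raise if any training plot id belongs to the external evaluation
    set recorded for the current species."""
    leaked = forbidden.intersection(train_ids)
    if leaked:
        raise LeakageError(
            f"fit would use {len(leaked)} external evaluation plot(s)"
        )


def species_seed(master_seed: int, species_id: str) -> int:
    """Stable per-species seed derived from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(species_id.encode())) % (
        2**31
    )


def _guarded_fit(spec, X, y, ids, forbidden):
    assert_no_leakage(ids, forbidden)
    return fit_sdm(spec, X, y)


def run_experiment(
    plots: PlotCommunityMatrix,
    species_eivs: SpeciesEIVTable,
    config: ExperimentConfig,
    species_list: list[str] | None = None,
) -> ExperimentResult:
    """Run the full substitution experiment and aggregate its results."""
    if species_list is None:
        species_list = filter_species_by_prevalence(
            plots, config.min_presences
        )
    species_list = [
        s for s in species_list if s in species_eivs.values.index
    ]
    if not species_list:
        raise ValueError("no modellable species")

    calc = SiteEIVCalculator(plots, species_eivs)

    cor_mapping = None
    if config.include_mcor:
        all_site = calc.site_eivs(None)
        candidates = plots.plot_predictors
        if config.mcor_candidates is not None:
            candidates = candidates[list(config.mcor_candidates)]
        # screen on the calibration side of a master split so the
        # correlation screen never sees external evaluation plots
        master = make_split_scheme(
            plots.presence.index.to_numpy(),
            seed=species_seed(config.master_seed, "__mcor_screen__"),
            n_internal=0,
        )
        calib = pd.Index(master.calibration_ids)
        cor_mapping = select_best_correlated(
            all_site.values.loc[calib], candidates.loc[calib]
        )

    all_sets = build_predictor_sets(config.mapped_roles, cor_mapping)
    if config.predictor_sets is not None:
        by_name = {s.name: s for s in all_sets}
        missing = [n for n in config.predictor_sets if n not in by_name]
        if missing:
            raise ValueError(f"unknown predictor set(s): {missing}")
        sets = [by_name[n] for n in config.predictor_sets]
    else:
        sets = all_sets
    used_dims = sorted(
        {d for s in sets for d in s.eiv_dimensions},
        key=EIV_DIMENSIONS.index,
    )
    absent = [d for d in used_dims if d not in species_eivs.values.columns]
    if absent:
        raise ValueError(
            f"EIV dimension(s) {absent} required by the chosen predictor "
            "sets are missing from the species EIV table"
        )

    metric_rows, imp_rows, failures = [], [], []
    eval_hash: dict[str, int] = {}
    n_fits = 0

    for sp_id in species_list:
        loo = calc.site_eivs(sp_id)
        design = plots.plot_predictors.copy()
        for d in used_dims:
            design[EIV_PREFIX + d] = loo.values[d]
        # plots whose leave-one-out mean is undefined on any used
        # dimension are dropped from this species' model data
        used_cols = sorted({c for s in sets for c in s.columns})
        keep = design[used_cols].notna().all(axis=1)
        design = design.loc[keep]
        y_all = plots.presence[sp_id].loc[keep.index[keep]]
        if y_all.sum() < 2 or (1 - y_all).sum() < 2:
            failures.append({"species": sp_id, "stage": "data",
                             "error": "too few presences after dropping"})
            continue

        seed = species_seed(config.master_seed, sp_id)
        scheme = make_split_scheme(
            design.index.to_numpy(), seed=seed,
            n_internal=config.n_internal,
        )
        forbidden = frozenset(scheme.evaluation_ids)
        eval_hash[sp_id] = zlib.crc32(
            ",".join(sorted(map(str, forbidden))).encode()
        )
        calib_ids = scheme.calibration_ids
        X_cal, y_cal = design.loc[calib_ids], y_all.loc[calib_ids]
        X_ext, y_ext = (
            design.loc[scheme.evaluation_ids],
            y_all.loc[scheme.evaluation_ids],
        )

        for pset in sets:
            Xc = X_cal[list(pset.columns)]
            for tech in config.techniques:
                spec = ModelSpec(
                    technique=tech,
                    predictor_names=pset.columns,
                    hyperparameters=config.hyperparameters.get(tech, {}),
                    seed=seed,
                )
                try:
                    model = _guarded_fit(
                        spec, Xc, y_cal, calib_ids, forbidden
                    )
                    n_fits += 1
                    scores = predict_sdm(model, X_ext[list(pset.columns)])
                    d2 = (
                        d2_from_scores(scores, y_ext)
                        if tech in ("GLM", "GAM")
                        else None
                    )
                    ms = evaluate_scores(scores, y_ext, d2=d2)
                    metric_rows.append(
                        dict(species_id=sp_id, technique=tech,
                             predictor_set=pset.name, eval_kind="external",
                             auc=ms.auc, tss=ms.tss, kappa=ms.kappa,
                             accuracy=ms.accuracy, d2=ms.d2,
                             threshold_tss=ms.threshold_tss,
                             threshold_kappa=ms.threshold_kappa)
                    )
                    if config.compute_importance:
                        raw = importance_table(
                            model, Xc,
                            n_permutations=config.n_permutations,
                            seed=seed,
                        )
                        norm = raw / raw.sum() if raw.sum() > 0 else raw
                        for var in raw.index:
                            imp_rows.append(
                                dict(species_id=sp_id, technique=tech,
                                     predictor_set=pset.name, variable=var,
                                     importance=float(raw[var]),
                                     importance_normalised=float(norm[var]),
                                     n_permutations=config.n_permutations)
                            )
                except Exception as exc:  # per-model failure: continue
                    failures.append(
                        {"species": sp_id, "stage": "external",
                         "technique": tech, "set": pset.name,
                         "error": str(exc)}
                    )
                    continue
                if not config.internal_evaluation:
                    continue
                for i, (tr, te) in enumerate(scheme.internal_splits):
                    try:
                        m_i = _guarded_fit(
                            spec, design.loc[tr, list(pset.columns)],
                            y_all.loc[tr], tr, forbidden,
                        )
                        n_fits += 1
                        sc = predict_sdm(
                            m_i, design.loc[te, list(pset.columns)]
                        )
                        d2_i = (
                            d2_from_scores(sc, y_all.loc[te])
                            if tech in ("GLM", "GAM")
                            else None
                        )
                        ms = evaluate_scores(sc, y_all.loc[te], d2=d2_i)
                        metric_rows.append(
                            dict(species_id=sp_id, technique=tech,
                                 predictor_set=pset.name,
                                 eval_kind=f"internal_{i + 1}",
                                 auc=ms.auc, tss=ms.tss, kappa=ms.kappa,
                                 accuracy=ms.accuracy, d2=ms.d2,
                                 threshold_tss=ms.threshold_tss,
                                 threshold_kappa=ms.threshold_kappa)
                        )
                    except Exception as exc:
                        failures.append(
                            {"species": sp_id, "stage": f"internal_{i + 1}",
                             "technique": tech, "set": pset.name,
                             "error": str(exc)}
                        )

    metrics = pd.DataFrame(metric_rows)
    importances = pd.DataFrame(imp_rows)
    reference = "M_ref" if any(s.name == "M_ref" for s in sets) else sets[0].name
    comparisons = _compare_sets(metrics, reference)
    result = ExperimentResult(
        metrics=metrics,
        importances=importances,
        comparisons=comparisons,
        summaries=pd.DataFrame(),
        species=species_list,
        predictor_sets=sets,
        n_fits=n_fits,
        evaluation_id_hash=eval_hash,
        failures=failures,
        master_seed=config.master_seed,
    )
    result.summaries = summarize(result, reference=reference)
    return result


def _external_pivot(
    metrics: pd.DataFrame, technique: str, metric: str
) -> pd.DataFrame:
    sub = metrics[
        (metrics["technique"] == technique)
        & (metrics["eval_kind"] == "external")
    ]
    return sub.pivot(index="species_id", columns="predictor_set",
                     values=metric)


def _compare_sets(metrics: pd.DataFrame, reference: str) -> pd.DataFrame:
    rows = []
    if metrics.empty:
        return pd.DataFrame()
    for tech in metrics["technique"].unique():
        for metric in ("auc", "tss", "kappa", "accuracy", "d2"):
            table = _external_pivot(metrics, tech, metric).dropna(
                axis=1, how="all"
            )
            if reference not in table.columns or table.shape[1] < 2:
                continue
            if table.dropna().shape[0] < 6:
                continue
            comp = pairwise_wilcoxon_holm(table, reference_set=reference)
            comp.insert(0, "metric", metric)
            comp.insert(0, "technique", tech)
            rows.append(comp)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def summarize(
    result: ExperimentResult, reference: str = "M_ref"
) -> pd.DataFrame:
    """Per predictor set x technique x metric: median difference to the
    reference set over species, 25/75 percentiles of the difference, and
    the fraction of species improved (difference > 0), on the external
    evaluation data."""
    metrics = result.metrics
    if metrics.empty:
        raise ValueError("experiment produced no metrics")
    if reference not in metrics["predictor_set"].unique():
        raise ValueError(f"reference set {reference!r} missing from results")
    rows = []
    for tech in metrics["technique"].unique():
        for metric in ("auc", "tss", "kappa", "accuracy", "d2"):
            table = _external_pivot(metrics, tech, metric)
            if reference not in table.columns or table[reference].isna().all():
                continue
            for pset in table.columns:
                delta = (table[pset] - table[reference]).dropna()
                if delta.empty:
                    continue
                vals = table[pset].dropna()
                rows.append(
                    dict(technique=tech, metric=metric, predictor_set=pset,
                         n_species=len(delta),
                         median=float(vals.median()),
                         median_delta=float(delta.median()),
                         q25_delta=float(np.percentile(delta, 25)),
                         q75_delta=float(np.percentile(delta, 75)),
                         fraction_improved=float((delta > 0).mean()))
                )
    out = pd.DataFrame(rows)
    if not result.comparisons.empty:
        p = result.comparisons.rename(
            columns={"set_a": "predictor_set"}
        )[["technique", "metric", "predictor_set", "p_holm"]]
        out = out.merge(p, on=["technique", "metric", "predictor_set"],
                        how="left")
    return out
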