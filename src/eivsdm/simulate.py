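"""Virtual landscape, species pool and plot community generation.

The simulator emulates a mountain study region surveyed with vegetation
plots: spatially autocorrelated *latent* environmental gradients drive
species occurrence, while the *mapped* layers available to a modeller are
degraded copies of those gradients (latent field plus spatially structured
error).  The gap between latent and mapped layers is the mechanism by which
community-mean indicator values can carry signal that mapped predictors
miss.

Every generator is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfigurationError",
    "LatentLayerConfig",
    "MappedLayerConfig",
    "LandscapeConfig",
    "SpeciesConfig",
    "LandscapeBundle",
    "VirtualSpecies",
    "PlotCommunityMatrix",
    "generate_landscape",
    "generate_species_pool",
    "assemble_communities",
    "filter_species_by_prevalence",
    "presence_probability",
    "expected_presence_count",
    "default_landscape_config",
    "default_species_config",
    "EIV_CODE",
    "DIMENSIONS",
]

#: canonical latent dimensions and their indicator-value codes
#: (T temperature, M moisture, L light, K continentality, R soil pH,
#: N nutrients)
EIV_CODE = {
    "temperature": "T",
    "moisture": "M",
    "light": "L",
    "continentality": "K",
    "reaction": "R",
    "nutrients": "N",
}
DIMENSIONS = tuple(EIV_CODE)
EIV_ORDINAL_MAX = 5


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class LatentLayerConfig:
    #: Gaussian smoothing sigma, in grid cells
    length_scale: float


@dataclass(frozen=True)
class MappedLayerConfig:
    #: name of the latent dimension this map is a proxy for
    source: str
    #: SD of the spatially structured map error, in units of the latent
    #: layer SD (latent layers are standardised); 0 means a perfect map
    error_sd: float
    #: smoothing sigma of the error field; default half the source scale
    error_length_scale: float | None = None


@dataclass(frozen=True)
class LandscapeConfig:
    grid_shape: tuple[int, int] = (120, 120)
    cell_size: float = 25.0
    latent: dict[str, LatentLayerConfig] = field(default_factory=dict)
    mapped: dict[str, MappedLayerConfig] = field(default_factory=dict)


def default_landscape_config() -> LandscapeConfig:
    """Study-system defaults.

    Six latent gradients; seven mapped layers named after commonly used
    GIS predictors.  The temperature map is exact; moisture, light and pH
    maps carry intermediate error; the two topographic layers are poor
    proxies of continentality; the soil-nutrient map is very coarse.
    """
    latent = {
        "temperature": LatentLayerConfig(length_scale=20.0),
        "moisture": LatentLayerConfig(length_scale=8.0),
        "light": LatentLayerConfig(length_scale=8.0),
        "continentality": LatentLayerConfig(length_scale=6.0),
        "reaction": LatentLayerConfig(length_scale=8.0),
        "nutrients": LatentLayerConfig(length_scale=8.0),
    }
    mapped = {
        "temperature": MappedLayerConfig("temperature", 0.0),
        "precipitation": MappedLayerConfig("moisture", 3.0),
        "radiation": MappedLayerConfig("light", 3.5),
        "ph": MappedLayerConfig("reaction", 1.5),
        "soil_nutrients": MappedLayerConfig("nutrients", 4.0),
        "topo_position": MappedLayerConfig("continentality", 8.0),
        "slope": MappedLayerConfig("continentality", 10.0),
    }
    return LandscapeConfig(latent=latent, mapped=mapped)


@dataclass
class LandscapeBundle:
    grid_shape: tuple[int, int]
    cell_size: float
    latent_layers: dict[str, np.ndarray]
    mapped_layers: dict[str, np.ndarray]
    mapped_source: dict[str, str]
    layer_error_sd: dict[str, float]
    rng_seed: int

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def latent_range(self, dimension: str) -> tuple[float, float]:
        layer = self.latent_layers[dimension]
        return float(layer.min()), float(layer.max())


@dataclass
class VirtualSpecies:
    species_id: str
    niche_optima: dict[str, float]
    niche_breadths: dict[str, float]
    prevalence_scale: float
    driving: tuple[str, ...]
    eiv: dict[str, int | None]

    def __post_init__(self) -> None:
        for dim, sd in self.niche_breadths.items():
            if sd <= 0:
                raise ValueError(
                    f"niche breadth for {dim!r} must be positive, got {sd}"
                )


@dataclass
class PlotCommunityMatrix:
    """Plot-by-species occurrences with plot-level predictor values."""

    plot_ids: np.ndarray
    plot_xy: np.ndarray  # (n_plots, 2) integer grid rows/cols
    presence: pd.DataFrame  # plot_id x species_id, values in {0, 1}
    plot_predictors: pd.DataFrame  # plot_id x predictor column
    group: pd.Series | None = None

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def species_ids(self) -> list[str]:
        return list(self.presence.columns)


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], length_scale: float
) -> np.ndarray:
    """Standardised smoothed-white-noise random field.

    Gaussian white noise convolved with a Gaussian kernel of the given
    length scale, then standardised to zero mean / unit variance.
    """
    if length_scale <= 0:
        raise ConfigurationError(
            f"smoothing length scale must be positive, got {length_scale}"
        )
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=length_scale, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - degenerate grid
        raise ConfigurationError("degenerate (constant) random field")
    return (smooth - smooth.mean()) / sd


def generate_landscape(config: LandscapeConfig, seed: int) -> LandscapeBundle:
    """Generate latent gradients and their degraded mapped counterparts.

    Mapped layer = latent source + ``error_sd`` x a standardised smoothed
    noise field, so the latent/mapped Pearson correlation is
    ``1 / sqrt(1 + error_sd**2)`` in expectation.
    """
    rows, cols = config.grid_shape
    if rows < 16 or cols < 16:
        raise ConfigurationError(
            f"grid_shape must be at least 16x16, got {config.grid_shape}"
        )
    if not config.latent:
        raise ConfigurationError("no latent dimensions configured")
    for name, mcfg in config.mapped.items():
        if mcfg.source not in config.latent:
            raise ConfigurationError(
                f"mapped layer {name!r} references unknown dimension "
                f"{mcfg.source!r}"
            )
        if mcfg.error_sd < 0:
            raise ConfigurationError(
                f"error SD for mapped layer {name!r} must be >= 0"
            )

    ss = np.random.SeedSequence(seed)
    # one child stream per layer, in declaration order, so adding a layer
    # does not reshuffle the others' fields
    latent_names = list(config.latent)
    mapped_names = list(config.mapped)
    children = ss.spawn(len(latent_names) + len(mapped_names))

    latent_layers: dict[str, np.ndarray] = {}
    for name, child in zip(latent_names, children[: len(latent_names)]):
        lcfg = config.latent[name]
        rng = np.random.default_rng(child)
        latent_layers[name] = _smooth_field(
            rng, config.grid_shape, lcfg.length_scale
        )

    mapped_layers: dict[str, np.ndarray] = {}
    mapped_source: dict[str, str] = {}
    layer_error_sd: dict[str, float] = {}
    for name, child in zip(mapped_names, children[len(latent_names):]):
        mcfg = config.mapped[name]
        base = latent_layers[mcfg.source]
        mapped_source[name] = mcfg.source
        layer_error_sd[name] = mcfg.error_sd
        if mcfg.error_sd == 0:
            mapped_layers[name] = base.copy()
            continue
        err_scale = (
            mcfg.error_length_scale
            if mcfg.error_length_scale is not None
            else config.latent[mcfg.source].length_scale / 2.0
        )
        rng = np.random.default_rng(child)
        err = _smooth_field(rng, config.grid_shape, err_scale)
        mapped_layers[name] = base + mcfg.error_sd * base.std() * err

    for name, layer in {**latent_layers, **mapped_layers}.items():
        if not np.all(np.isfinite(layer)):  # pragma: no cover
            raise ConfigurationError(f"layer {name!r} contains non-finite cells")

    return LandscapeBundle(
        grid_shape=config.grid_shape,
        cell_size=config.cell_size,
        latent_layers=latent_layers,
        mapped_layers=mapped_layers,
        mapped_source=mapped_source,
        layer_error_sd=layer_error_sd,
        rng_seed=seed,
    )


@dataclass(frozen=True)
class SpeciesConfig:
    #: dimensions every species responds to
    always_driving: tuple[str, ...] = ("temperature",)
    #: number of additional randomly chosen driving dimensions (the
    #: default drives every gradient: the six dimensions are exactly the
    #: factors indicator systems score because they matter to all plants)
    n_extra_driving: int = 5
    #: uniform range for niche breadths (latent-SD units)
    breadth_range: tuple[float, float] = (1.8, 3.5)
    #: per-dimension overrides of the breadth range; by default thermal
    #: niches are narrower than the rest, the dominant sorting axis of
    #: mountain floras
    breadth_overrides: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"temperature": (1.0, 2.0)}
    )
    #: uniform range for the maximum occurrence probability at the optimum
    prevalence_range: tuple[float, float] = (0.7, 1.0)
    #: fraction of (species, dimension) indicator values set to missing
    eiv_missing_fraction: float = 0.05


def default_species_config() -> SpeciesConfig:
    return SpeciesConfig()


def eiv_bin(optimum: float, lo: float, hi: float, n_bins: int = EIV_ORDINAL_MAX) -> int:
    """Ordinal indicator value: equal-width bin of the optimum over the
    landscape-wide latent range, 1-based, clipped at the top edge."""
    if hi <= lo:
        raise ValueError("degenerate layer range")
    raw = 1 + int(np.floor(n_bins * (optimum - lo) / (hi - lo)))
    return min(max(raw, 1), n_bins)


def generate_species_pool(
    landscape: LandscapeBundle,
    n_species: int,
    config: SpeciesConfig | None = None,
    seed: int = 0,
) -> list[VirtualSpecies]:
    """Draw a virtual species pool with Gaussian niches on the latent
    gradients and ordinal indicator values discretising the optima."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not landscape.latent_layers:
        raise ConfigurationError("landscape has no latent layers")
    config = config or default_species_config()
    dims = list(landscape.latent_layers)
    for d in config.always_driving:
        if d not in dims:
            raise ConfigurationError(f"always_driving dimension {d!r} unknown")
    optional_dims = [d for d in dims if d not in config.always_driving]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ranges = {d: landscape.latent_range(d) for d in dims}
    breadth_ranges = {
        d: config.breadth_overrides.get(d, config.breadth_range)
        for d in dims
    }
    lo_p, hi_p = config.prevalence_range

    pool: list[VirtualSpecies] = []
    width = len(str(n_species))
    for i in range(n_species):
        optima = {
            d: float(rng.uniform(ranges[d][0], ranges[d][1])) for d in dims
        }
        breadths = {
            d: float(rng.uniform(*breadth_ranges[d])) for d in dims
        }
        prevalence = float(rng.uniform(lo_p, hi_p))
        n_extra = min(config.n_extra_driving, len(optional_dims))
        extra = rng.choice(optional_dims, size=n_extra, replace=False)
        driving = tuple(config.always_driving) + tuple(sorted(extra))
        eiv: dict[str, int | None] = {}
        for d in dims:
            if rng.random() < config.eiv_missing_fraction:
                eiv[d] = None
            else:
                eiv[d] = eiv_bin(optima[d], *ranges[d])
        pool.append(
            VirtualSpecies(
                species_id=f"sp{i + 1:0{width}d}",
                niche_optima=optima,
                niche_breadths=breadths,
                prevalence_scale=prevalence,
                driving=driving,
                eiv=eiv,
            )
        )
    return pool


def presence_probability(
    species: VirtualSpecies, env: dict[str, np.ndarray | float]
) -> np.ndarray | float:
    """Gaussian niche response over the species' driving latent dimensions:
    P = prevalence * prod_d exp(-(x_d - opt_d)^2 / (2 sigma_d^2))."""
    p = species.prevalence_scale
    for d in species.driving:
        x = np.asarray(env[d], dtype=float)
        opt = species.niche_optima[d]
        sd = species.niche_breadths[d]
        p = p * np.exp(-((x - opt) ** 2) / (2.0 * sd**2))
    return p


def assemble_communities(
    landscape: LandscapeBundle,
    species_pool: list[VirtualSpecies],
    n_plots: int,
    seed: int = 0,
    include_latent: bool = False,
    group_fractions: dict[str, float] | None = None,
    detection: dict[str, float] | None = None,
) -> PlotCommunityMatrix:
    """Sample survey plots and realise Bernoulli occurrences.

    Plot cells are sampled without replacement; occurrence probability is
    the Gaussian niche response evaluated on the LATENT gradients, while
    ``plot_predictors`` records the MAPPED layer values at the plot cells
    (optionally also the latent values, prefixed ``latent_``).

    ``group_fractions`` optionally assigns each plot a survey-group label
    (e.g. forest/grassland) with the given probabilities; ``detection``
    multiplies occurrence probabilities by a per-group factor (default 1
    for every group — plot size is assumed not to modulate detection).
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if n_plots > landscape.n_cells:
        raise ValueError(
            f"n_plots={n_plots} exceeds the {landscape.n_cells} grid cells"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = rng.choice(landscape.n_cells, size=n_plots, replace=False)
    rows, cols = np.unravel_index(cells, landscape.grid_shape)
    plot_xy = np.column_stack([rows, cols])
    plot_ids = np.array([f"plot{i + 1:05d}" for i in range(n_plots)])

    group = None
    detect = np.ones(n_plots)
    if group_fractions:
        labels = list(group_fractions)
        p = np.array([group_fractions[g] for g in labels], dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "group fractions must be nonnegative and sum to 1"
            )
        assigned = rng.choice(labels, size=n_plots, p=p)
        group = pd.Series(assigned, name="group")
        if detection:
            detect = np.array([detection.get(g, 1.0) for g in assigned])
            if detect.min() < 0 or detect.max() > 1:
                raise ConfigurationError(
                    "detection factors must lie in [0, 1]"
                )

    latent_at = {
        d: layer[rows, cols] for d, layer in landscape.latent_layers.items()
    }
    prob = np.empty((n_plots, len(species_pool)))
    for j, sp in enumerate(species_pool):
        prob[:, j] = presence_probability(sp, latent_at)
    prob *= detect[:, None]
    presence = (rng.random(prob.shape) < prob).astype(np.int8)

    species_ids = [sp.species_id for sp in species_pool]
    presence_df = pd.DataFrame(
        presence, index=pd.Index(plot_ids, name="plot_id"), columns=species_ids
    )
    pred = {
        name: layer[rows, cols]
        for name, layer in landscape.mapped_layers.items()
    }
    if include_latent:
        for d, vals in latent_at.items():
            pred[f"latent_{d}"] = vals
    pred_df = pd.DataFrame(pred, index=presence_df.index)
    if pred_df.columns.duplicated().any():  # pragma: no cover
        raise ConfigurationError("duplicate predictor column names")
    if group is not None:
        group.index = presence_df.index
    return PlotCommunityMatrix(
        plot_ids=plot_ids,
        plot_xy=plot_xy,
        presence=presence_df,
        plot_predictors=pred_df,
        group=group,
    )


def expected_presence_count(
    species: VirtualSpecies, latent_at: dict[str, np.ndarray]
) -> float:
    """Analytic expectation of a species' presence count over given plots."""
    return float(np.sum(presence_probability(species, latent_at)))


def filter_species_by_prevalence(
    plots: PlotCommunityMatrix, min_presences: int = 50
) -> list[str]:
    """Species with strictly more than ``min_presences`` occurrences,
    in column order."""
    if min_presences < 1:
        raise ValueError("min_presences must be >= 1")
    counts = plots.presence.sum(axis=0)
    return [s for s in plots.presence.columns if counts[s] > min_presences]
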