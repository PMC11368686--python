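"""Synthetic spatially structured expression data for end-to-end testing.

The generator emulates the statistical structure the contrastive method
assumes: cells scattered in the unit square, discrete tissue zones (Voronoi
regions of seeded centers) carrying zone-specific expression programs, and
smooth continuous spatial gradients (random Fourier features approximating
a Gaussian-process field with a chosen length-scale). As in real tissue,
only a minority of genes (25%) carry the spatial signal; every gene is
additionally modulated by a few shared per-cell "cell-state" factors
(size, stress, cycle-like variation) and iid measurement noise, both
scaled by ``dispersion``. The correlated cell-state component is what
makes naive expression-distance neighbor search fail on this data while a
trained encoder, whose positives share location but not cell state, can
cancel it.

Because the latent tissue (positions, zones, gradient fields) is a pure
function of the config seed, an independent query replicate of the same
tissue — new measurement noise, optional coordinate jitter and dropout —
can be drawn with :func:`make_query`, mimicking a dissociated single-cell
sample taken from the same biological specimen as the spatial reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import ExpressionProfile, SpatialDataset, ValidationError

NOISE_MODELS = ("gaussian", "poisson", "negative_binomial")

# independent seed streams derived from the config seed
_LATENT_STREAM = 11
_NOISE_STREAM = 17
_QUERY_STREAM = 23


#: fraction of genes carrying zone/gradient signal; the rest are
#: housekeeping-like (baseline + cell-state + noise only)
FRAC_INFORMATIVE = 0.25
#: number of shared per-cell nuisance (cell-state) factors
N_STATE_FACTORS = 3
#: log-scale amplitude of zone programs and spatial gradients
SIGNAL_AMPLITUDE = 0.8


@dataclass
class SimConfig:
    """Parameters of the synthetic tissue.

    smoothness is the spatial kernel length-scale in unit-square units.
    dispersion sets the non-spatial variation scale: the iid measurement
    noise sd (gaussian), the negative-binomial overdispersion, and the
    log-scale amplitude of the shared cell-state factors in every model.
    """

    n_cells: int = 800
    n_genes: int = 100
    n_zones: int = 5
    smoothness: float = 0.3
    noise_model: str = "gaussian"
    dispersion: float = 1.0
    spot_bin: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_zones) < 1:
            raise ValidationError("n_cells, n_genes and n_zones must be positive")
        if self.n_zones > self.n_cells:
            raise ValidationError("n_zones cannot exceed n_cells")
        if not (np.isfinite(self.smoothness) and self.smoothness > 0):
            raise ValidationError("smoothness must be finite and positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"noise_model must be one of {NOISE_MODELS}")


def _latent_tissue(config: SimConfig):
    """Positions, zones, latent log-rates and state loadings (seed-pure)."""
    rng = np.random.default_rng([config.seed, _LATENT_STREAM])
    coords = rng.uniform(0, 1, size=(config.n_cells, 2))
    centers = rng.uniform(0, 1, size=(config.n_zones, 2))
    zones = np.argmin(cdist(coords, centers), axis=1)
    # zone programs: each zone up/down-regulates a random subset of genes
    programs = rng.normal(0.0, 1.0, size=(config.n_zones, config.n_genes))
    # smooth gradients: random Fourier features of an RBF kernel with the
    # requested length-scale; each gene mixes a few components
    n_feat = 32
    omega = rng.normal(0.0, 1.0 / config.smoothness, size=(n_feat, 2))
    phase = rng.uniform(0, 2 * np.pi, size=n_feat)
    basis = np.sqrt(2.0 / n_feat) * np.cos(coords @ omega.T + phase)
    mix = rng.normal(0.0, 1.0, size=(n_feat, config.n_genes))
    informative = rng.uniform(size=config.n_genes) < FRAC_INFORMATIVE
    baseline = rng.normal(1.0, 0.5, size=config.n_genes)
    loadings = rng.normal(0.0, 1.0, size=(N_STATE_FACTORS, config.n_genes))
    signal = SIGNAL_AMPLITUDE * (programs[zones] + basis @ mix)
    log_rate = baseline + np.where(informative, signal, 0.0)
    return coords, zones, log_rate, loadings


def _observe(log_rate: np.ndarray, loadings: np.ndarray, config: SimConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Draw non-negative observed counts around the latent log-rates.

    Per-cell nuisance: cell-state factors drawn fresh per observation,
    added on the log scale with amplitude ``dispersion`` across all genes,
    then the chosen measurement-noise model on the count scale.
    """
    n_cells = log_rate.shape[0]
    state = rng.normal(size=(n_cells, N_STATE_FACTORS))
    amp = config.dispersion / np.sqrt(N_STATE_FACTORS)
    rate = np.exp(log_rate + amp * (state @ loadings))
    if config.noise_model == "gaussian":
        values = rate + config.dispersion * rng.normal(size=rate.shape)
        return np.clip(values, 0.0, None)
    if config.noise_model == "poisson":
        return rng.poisson(rate).astype(float)
    # negative binomial as gamma-poisson: var = mu + dispersion * mu^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, rate / shape)
    return rng.poisson(lam).astype(float)


def generate_spatial_dataset(config: SimConfig) -> SpatialDataset:
    """Generate a spatial reference dataset; fully reproducible from seed."""
    coords, zones, log_rate, loadings = _latent_tissue(config)
    noise_rng = np.random.default_rng([config.seed, _NOISE_STREAM])
    values = _observe(log_rate, loadings, config, noise_rng)
    profile = ExpressionProfile(
        values=values,
        gene_ids=np.array([f"g{j}" for j in range(config.n_genes)], object),
        cell_ids=np.array([f"cell_{i}" for i in range(config.n_cells)], object),
        cell_types=np.array([f"zone_{z}" for z in zones], object),
    )
    dataset = SpatialDataset(profile=profile, coords=coords,
                             platform="single_cell")
    dataset.sim_config = config
    return dataset


def make_query(reference: SpatialDataset, jitter: float = 0.0,
               dropout_rate: float = 0.0, seed: int = 1,
               ) -> Tuple[ExpressionProfile, np.ndarray]:
    """An independent measurement replicate of the reference tissue.

    Same latent tissue (cells, zones, gradients), new observation noise
    drawn from ``seed``; coordinates are optionally jittered and withheld
    from the profile, returned separately as evaluation truth. With
    ``seed`` equal to the reference's config seed and no jitter/dropout the
    query reproduces the reference expression exactly.
    """
    config: SimConfig = reference.sim_config
    if config is None:
        raise ValidationError("reference was not produced by this generator")
    if jitter < 0:
        raise ValidationError("jitter must be non-negative")
    if not 0 <= dropout_rate < 1:
        raise ValidationError("dropout_rate must be in [0, 1)")
    coords, zones, log_rate, loadings = _latent_tissue(config)
    noise_rng = np.random.default_rng([seed, _NOISE_STREAM])
    values = _observe(log_rate, loadings, config, noise_rng)
    aux_rng = np.random.default_rng([seed, _QUERY_STREAM])
    if dropout_rate > 0:
        values = values * (aux_rng.uniform(size=values.shape) >= dropout_rate)
    true_coords = coords.copy()
    if jitter > 0:
        true_coords = true_coords + aux_rng.normal(0, jitter, size=true_coords.shape)
    profile = ExpressionProfile(
        values=values,
        gene_ids=np.array([f"g{j}" for j in range(config.n_genes)], object),
        cell_ids=np.array([f"query_{i}" for i in range(config.n_cells)], object),
        cell_types=np.array([f"zone_{z}" for z in zones], object),
    )
    return profile, true_coords


def bin_to_spots(dataset: SpatialDataset, spot_bin: int) -> SpatialDataset:
    """Pool cells into regular grid spots of ~``spot_bin`` cells each.

    The grid side is round(sqrt(n_cells / spot_bin)); spot expression is
    the sum over member cells, the spot coordinate the grid-cell center,
    and the spot's type the majority member type. Empty grid cells are
    dropped.
    """
    if spot_bin < 1:
        raise ValidationError("spot_bin must be >= 1")
    n = dataset.n_cells
    side = max(1, round(np.sqrt(n / spot_bin)))
    coords = dataset.coords
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0] = 1.0
    ix = np.minimum((coords - lo) / span * side, side - 1).astype(int)
    bin_id = ix[:, 0] * side + ix[:, 1]
    occupied = np.unique(bin_id)
    profile = dataset.profile
    values = np.zeros((len(occupied), profile.n_genes))
    spot_coords = np.zeros((len(occupied), 2))
    spot_types = np.empty(len(occupied), object)
    for s, b in enumerate(occupied):
        members = bin_id == b
        values[s] = profile.values[members].sum(axis=0)
        gx, gy = divmod(int(b), side)
        spot_coords[s] = lo + (np.array([gx, gy]) + 0.5) / side * span
        if profile.cell_types is not None:
            types, counts = np.unique(profile.cell_types[members],
                                      return_counts=True)
            spot_types[s] = types[np.argmax(counts)]
    spot_profile = ExpressionProfile(
        values=values,
        gene_ids=profile.gene_ids.copy(),
        cell_ids=np.array([f"spot_{s}" for s in range(len(occupied))], object),
        cell_types=spot_types if profile.cell_types is not None else None,
    )
    binned = SpatialDataset(profile=spot_profile, coords=spot_coords,
                            platform="spot")
    binned.sim_config = dataset.sim_config
    return binned
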