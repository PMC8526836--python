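"""Synthetic ground-truth data generators for every pipeline stage.

Each generator is a pure function of its arguments (including the seed):
identical inputs give bit-identical outputs.  Random streams are derived
from the master seed with counter-based `numpy.random.SeedSequence` keys,
so enlarging one dimension (e.g. adding subjects) never perturbs the draws
of earlier items.

The generators emulate the structure of the real inputs — symmetric
weighted connectomes, group BOLD whose interareal correlation grows with a
planted coupling G, voxel data with planted seed networks and group
hyperconnectivity, donor-wise expression coupled to a reference map, gene
universes with planted overlaps, and subject-by-feature maps with planted
cluster structure — not their anatomy or scanner noise spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import VoxelDataset
from .dmf import DMFParameters, SimulationError, StructuralConnectome, calibrate_fic
from .enrichment import GeneExpressionAtlas, GeneSet
from .hemodynamics import BOLDTimeseries, HemodynamicParameters, simulate_bold

__all__ = ["SyntheticConfig", "GroundTruth", "make_connectome",
           "make_group_bold", "make_voxel_dataset", "make_expression_atlas",
           "make_gene_lists", "make_subject_maps"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Default study conditions for the synthetic pipeline."""

    seed: int = 0
    n_regions: int = 74
    n_subjects_per_group: int = 20
    duration_s: float = 300.0
    n_donors: int = 6
    n_genes: int = 1000
    n_locations: int = 200
    connectome_density: float = 0.3
    coupling_beta: float = 1.0
    expression_noise_sd: float = 0.2
    cluster_separation: float = 10.0
    map_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_subjects_per_group", "n_donors",
                     "n_genes", "n_locations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("expression_noise_sd", "map_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, so downstream stages can be scored against it."""

    planted_G: np.ndarray | None = None           # per subject
    planted_gene_indices: np.ndarray | None = None
    planted_cluster_labels: np.ndarray | None = None
    planted_overlap_k: int | None = None
    extra: dict = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + key))


def make_connectome(n_regions: int, density: float = 0.3,
                    seed: int = 0) -> StructuralConnectome:
    """Random symmetric weighted connectome with heavy-tailed weights.

    Off-diagonal pairs are present with probability ``density``; present
    weights are log-normal (mu=0, sigma=1) and rescaled so the mean row
    strength (sum of each region's couplings, averaged over regions) is 1.
    Diagonal is zero.  Unit mean row strength keeps the mean-field model's
    low-activity branch stable across the whole operating range of the
    global coupling G; normalizing the mean single weight to 1 instead
    would destabilize it already at G ~ 0.25 for the default density.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = _rng(seed, 0)
    n = n_regions
    C = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < density
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=iu[0].size) * present
    C[iu] = weights
    C = C + C.T
    strength = C.sum(axis=1).mean()
    if strength > 0:
        C /= strength
    labels = [f"region{i:03d}" for i in range(n)]
    return StructuralConnectome(labels=labels, C=C)


def make_group_bold(connectome: StructuralConnectome, g_values,
                    duration_s: float, tr_s: float = 1.0, seed: int = 0,
                    dt_s: float = 0.0012,
                    params: DMFParameters | None = None,
                    hemo: HemodynamicParameters | None = None,
                    fic_cache: dict | None = None
                    ) -> tuple[list[BOLDTimeseries], GroundTruth]:
    """Simulate one BOLD run per subject at its planted coupling G.

    Inhibitory weights are recalibrated per distinct G (cached across
    subjects).  Simulator divergence is re-raised naming the offending G.
    """
    params = params or DMFParameters()
    hemo = hemo or HemodynamicParameters()
    g_values = np.asarray(g_values, dtype=float)
    n_timepoints = int(round(duration_s / tr_s))
    if n_timepoints < 2:
        raise ValueError("duration_s must cover >= 2 TRs")
    cache = fic_cache if fic_cache is not None else {}
    runs = []
    for s, g in enumerate(g_values):
        key = round(float(g), 10)
        try:
            if key not in cache:
                cache[key] = calibrate_fic(params, connectome, float(g),
                                           seed=seed, dt_s=dt_s)
            bold = simulate_bold(params, hemo, connectome, float(g),
                                 cache[key], n_timepoints, tr_s,
                                 seed=int(_rng(seed, 1, s).integers(2**31)),
                                 dt_s=dt_s)
        except SimulationError as exc:
            raise SimulationError(f"subject {s} at G = {g}: {exc}") from exc
        runs.append(bold)
    return runs, GroundTruth(planted_G=g_values.copy())


def _region_block_coords(n_regions: int, n_voxels_per_region: int,
                         voxel_size_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Regular 3-D grid geometry: one cube of voxels per region.

    Region cubes are laid out along x with a one-voxel gap; coordinates are
    grid index times the physical voxel size.
    """
    k = int(np.ceil(n_voxels_per_region ** (1.0 / 3.0)))
    while k**3 < n_voxels_per_region:  # guard against fp rounding
        k += 1
    coords = []
    region_of = []
    for r in range(n_regions):
        x0 = r * (k + 1)
        count = 0
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    if count == n_voxels_per_region:
                        break
                    coords.append((x0 + dx, dy, dz))
                    region_of.append(r)
                    count += 1
    return (np.asarray(coords, dtype=float) * voxel_size_um,
            np.asarray(region_of))


def make_voxel_dataset(n_voxels_per_region: int, n_regions: int,
                       n_subjects: int, group_effect: float = 0.5,
                       voxel_size_um: float = 300.0, noise_sd: float = 0.5,
                       seed: int = 0, n_timepoints: int = 200,
                       base_coupling: float = 0.2
                       ) -> tuple[list[VoxelDataset], list[VoxelDataset], GroundTruth]:
    """Two groups of voxelwise timeseries with planted hyperconnectivity.

    Voxels within a region share a latent signal plus i.i.d. noise.  Each
    latent mixes an independent component with a global common component;
    group 2's common-factor loading is raised by ``group_effect``, so its
    interregional (and hence voxel-voxel) correlations are higher.  With
    ``group_effect=0`` the groups are exchangeable.
    """
    for name, v in (("n_voxels_per_region", n_voxels_per_region),
                    ("n_regions", n_regions), ("n_subjects", n_subjects),
                    ("n_timepoints", n_timepoints)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    coords, region_of = _region_block_coords(n_regions, n_voxels_per_region,
                                             voxel_size_um)
    rho1 = base_coupling
    rho2 = base_coupling + group_effect
    if not (0 <= rho1 <= 1 and 0 <= rho2 <= 1):
        raise ValueError("base_coupling + group_effect must lie in [0, 1]")

    def subjects(group: int, rho: float) -> list[VoxelDataset]:
        a = np.sqrt(rho)
        b = np.sqrt(1.0 - rho)
        out = []
        for s in range(n_subjects):
            rng = _rng(seed, 2, group, s)
            common = rng.standard_normal(n_timepoints)
            indep = rng.standard_normal((n_regions, n_timepoints))
            latents = a * common + b * indep
            data = latents[region_of]
            if noise_sd > 0:
                data = data + noise_sd * rng.standard_normal(data.shape)
            out.append(VoxelDataset(data=data, coords=coords.copy(), tr_s=1.0))
        return out

    group1 = subjects(0, rho1)
    group2 = subjects(1, rho2)
    gt = GroundTruth(extra={"region_of_voxel": region_of,
                            "latent_corr_group1": rho1,
                            "latent_corr_group2": rho2,
                            "affected_regions": np.arange(n_regions)})
    return group1, group2, gt


def make_expression_atlas(n_donors: int = 6, n_genes: int = 1000,
                          n_locations: int = 200, n_coupled: int = 50,
                          beta: float = 1.0, noise_sd: float = 0.2,
                          seed: int = 0
                          ) -> tuple[GeneExpressionAtlas, np.ndarray, GroundTruth]:
    """Donor x gene x location expression with planted map-coupled genes.

    Coupled genes satisfy expression = beta * map + noise in every donor;
    the remaining genes are map-independent noise of the same scale.
    """
    if n_coupled > n_genes:
        raise ValueError("n_coupled cannot exceed n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, 3)
    reference_map = rng.standard_normal(n_locations)
    coupled = np.sort(rng.choice(n_genes, size=n_coupled, replace=False))
    X = np.empty((n_donors, n_genes, n_locations))
    for d in range(n_donors):
        drng = _rng(seed, 3, d + 1)
        X[d] = noise_sd * drng.standard_normal((n_genes, n_locations))
        X[d, coupled] += beta * reference_map
    atlas = GeneExpressionAtlas(
        donors=[f"donor{d}" for d in range(n_donors)],
        genes=[f"gene{g:05d}" for g in range(n_genes)],
        locations=[f"loc{l:04d}" for l in range(n_locations)],
        X=X)
    gt = GroundTruth(planted_gene_indices=coupled)
    return atlas, reference_map, gt


def make_gene_lists(n_universe: int, size_a: int, size_b: int,
                    overlap_k: int, seed: int = 0
                    ) -> tuple[GeneSet, GeneSet, GeneSet, GroundTruth]:
    """Universe plus two lists with an exact planted overlap.

    Returns (universe set, list A, list B, ground truth) with
    |A ∩ B| = overlap_k exactly.
    """
    if overlap_k > min(size_a, size_b):
        raise ValueError("overlap_k cannot exceed the smaller list")
    if size_a + size_b - overlap_k > n_universe:
        raise ValueError("lists cannot exceed the universe")
    rng = _rng(seed, 4)
    ids = [f"gene{g:05d}" for g in range(n_universe)]
    perm = rng.permutation(n_universe)
    shared = [ids[i] for i in perm[:overlap_k]]
    only_a = [ids[i] for i in perm[overlap_k:size_a]]
    only_b = [ids[i] for i in perm[size_a:size_a + size_b - overlap_k]]
    universe = set(ids)
    gs_universe = GeneSet(name="universe", members=universe, universe=universe)
    gs_a = GeneSet(name="listA", members=set(shared + only_a), universe=universe)
    gs_b = GeneSet(name="listB", members=set(shared + only_b), universe=universe)
    return gs_universe, gs_a, gs_b, GroundTruth(planted_overlap_k=overlap_k)


def make_subject_maps(cluster_sizes, n_features: int, separation: float = 10.0,
                      noise_sd: float = 1.0, seed: int = 0
                      ) -> tuple[np.ndarray, GroundTruth]:
    """Subject x feature maps with planted, equally separated clusters.

    Cluster prototypes are scaled unit basis vectors, so every pair of
    prototypes is exactly ``separation`` apart in Euclidean norm; subjects
    are their cluster's prototype plus isotropic Gaussian noise.
    """
    cluster_sizes = [int(c) for c in cluster_sizes]
    if min(cluster_sizes) < 1:
        raise ValueError("cluster sizes must be >= 1")
    k = len(cluster_sizes)
    if n_features < k:
        raise ValueError("need n_features >= number of clusters")
    if separation < 0 or noise_sd < 0:
        raise ValueError("separation and noise_sd must be >= 0")
    prototypes = np.zeros((k, n_features))
    for c in range(k):
        prototypes[c, c] = separation / np.sqrt(2.0)
    labels = np.repeat(np.arange(1, k + 1), cluster_sizes)
    rng = _rng(seed, 5)
    M = prototypes[labels - 1] + noise_sd * rng.standard_normal(
        (labels.size, n_features))
    return M, GroundTruth(planted_cluster_labels=labels)
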