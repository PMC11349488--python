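"""Synthetic scenes, phylogenies, traits and plot communities.

These generators produce every input the analysis pipeline consumes, with
the statistical structure the downstream methods assume:

* scenes are mosaics of spatially coherent patches drawn from a small set of
  spectral archetypes (e.g. dark bare substrate, bright bare substrate,
  sparse pioneer vegetation, dense low herbaceous vegetation, tall woody
  vegetation), with per-band Gaussian noise and optional per-date cloud
  masks;
* phylogenies are ultrametric pure-birth (Yule) trees;
* continuous traits evolve by Brownian motion along the tree, categorical
  traits arise by quantile-thresholding latent Brownian traits, and entries
  are removed completely at random;
* plot communities carry a heap / block / cluster design with planted
  cluster-exclusive indicator species and an arch-shaped richness gradient
  across clusters (richness peaking in mid-succession).

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import BAND_NAMES, GridGeoref, RasterScene


# --------------------------------------------------------------------------- #
# Scenes
# --------------------------------------------------------------------------- #

@dataclass
class ClassArchetype:
    """Spectral/structural prototype of one land-cover class.

    band_means may be a single 6-vector (reused for every date) or an
    (n_dates, 6) array. vh_mean/vh_sd parameterize vegetation height (m).
    """

    label: int
    band_means: np.ndarray
    vh_mean: float = 0.0
    vh_sd: float = 0.0

    def __post_init__(self) -> None:
        self.band_means = np.atleast_2d(np.asarray(self.band_means, dtype=float))
        if self.band_means.shape[-1] != len(BAND_NAMES):
            raise ValueError("band_means must have 6 bands")
        if self.vh_mean < 0:
            raise ValueError("vh_mean must be >= 0")


def default_archetypes() -> list[ClassArchetype]:
    """Five archetypes spanning a post-mining successional gradient.

    Band means (SB460, SB555, SB655, SB850, SB1580, SB2180) are plausible
    surface-reflectance values: dark coal-rich substrate is uniformly dark,
    bright mineral substrate bright in all bands, vegetated classes show the
    red-edge jump at 850 nm; woody vegetation adds height.
    """
    return [
        ClassArchetype(1, [0.04, 0.05, 0.05, 0.08, 0.10, 0.09], 0.0, 0.0),     # dark bare
        ClassArchetype(2, [0.22, 0.26, 0.30, 0.38, 0.42, 0.38], 0.0, 0.0),     # bright bare
        ClassArchetype(3, [0.08, 0.11, 0.12, 0.22, 0.24, 0.18], 0.1, 0.05),    # sparse pioneer
        ClassArchetype(4, [0.05, 0.09, 0.07, 0.42, 0.22, 0.12], 0.5, 0.2),     # dense herbaceous
        ClassArchetype(5, [0.03, 0.06, 0.04, 0.35, 0.15, 0.08], 12.0, 3.0),    # woody, tall
    ]


@dataclass
class SceneSpec:
    """Parameters of a synthetic multi-date scene."""

    height_px: int = 200
    width_px: int = 200
    pixel_size: float = 10.0
    n_dates: int = 3
    archetypes: list[ClassArchetype] = field(default_factory=default_archetypes)
    patch_scale: float = 100.0       # correlation length of the class field (m)
    noise_sd: float = 0.01           # reflectance units, per band
    cloud_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if len(self.archetypes) < 2:
            raise ValueError("need at least 2 archetypes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")


def generate_scene(spec: SceneSpec) -> tuple[RasterScene, np.ndarray]:
    """Generate a scene and the planted per-pixel class map.

    The latent class field is the argmax over one smoothed Gaussian random
    field per archetype (kernel width = patch_scale), giving spatially
    coherent patches. Each pixel's reflectance is its archetype's band mean
    plus N(0, noise_sd) noise; DSM - DEM ~ N(vh_mean, vh_sd) truncated at 0.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    n_arch = len(spec.archetypes)
    sigma_px = max(spec.patch_scale / spec.pixel_size, 1e-9)

    fields = rng.standard_normal((n_arch,) + shape)
    for i in range(n_arch):
        fields[i] = ndimage.gaussian_filter(fields[i], sigma=sigma_px, mode="reflect")
    class_idx = np.argmax(fields, axis=0)
    labels = np.array([a.label for a in spec.archetypes])
    true_map = labels[class_idx]

    bands = np.empty((spec.n_dates, len(BAND_NAMES)) + shape)
    for d in range(spec.n_dates):
        for b in range(len(BAND_NAMES)):
            mean_grid = np.empty(shape)
            for i, arch in enumerate(spec.archetypes):
                means = arch.band_means
                row = means[d % means.shape[0]]
                mean_grid[class_idx == i] = row[b]
            noise = rng.standard_normal(shape) * spec.noise_sd if spec.noise_sd > 0 else 0.0
            bands[d, b] = mean_grid + noise

    # gently rolling terrain; heights ride on top of it
    dem = ndimage.gaussian_filter(rng.standard_normal(shape) * 40.0, sigma=max(sigma_px, 3.0))
    dem += 250.0
    vh = np.zeros(shape)
    for i, arch in enumerate(spec.archetypes):
        sel = class_idx == i
        if arch.vh_sd > 0:
            h = rng.normal(arch.vh_mean, arch.vh_sd, size=int(sel.sum()))
        else:
            h = np.full(int(sel.sum()), arch.vh_mean)
        vh[sel] = np.clip(h, 0.0, None)
    dsm = dem + vh

    if spec.cloud_fraction > 0:
        for d in range(spec.n_dates):
            cloud = rng.random(shape) < spec.cloud_fraction
            bands[d, :, cloud] = np.nan

    scene = RasterScene(
        bands=bands, dem=dem, dsm=dsm,
        georef=GridGeoref(pixel_size=spec.pixel_size),
    )
    return scene, true_map


# --------------------------------------------------------------------------- #
# Phylogenies and traits
# --------------------------------------------------------------------------- #

def generate_phylogeny(n_species: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with labelled tips.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); all tips are extended to the present, so every root-to-tip
    path length is equal. Tips are labelled ``sp001`` ... in birth order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    left, right = tree.seed_node.new_child(), tree.seed_node.new_child()
    tips = [left, right]
    birth_time = {left: 0.0, right: 0.0}
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = rng.integers(len(tips))
        parent = tips.pop(i)
        parent.edge.length = t - birth_time[parent]
        a, b = parent.new_child(), parent.new_child()
        birth_time[a] = birth_time[b] = t
        tips.extend([a, b])
    t += rng.exponential(1.0 / (birth_rate * len(tips)))
    for node in tips:
        node.edge.length = t - birth_time[node]
    tree.seed_node.edge.length = None
    for i, node in enumerate(tree.leaf_node_iter()):
        node.taxon = taxa.new_taxon(label=f"sp{i + 1:03d}")
    return tree


@dataclass
class TraitSpec:
    """Parameters of simulated species traits."""

    n_numeric: int = 4
    n_categorical: int = 2
    categories_per_trait: int = 3
    bm_sigma2: float = 1.0
    missing_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.bm_sigma2 <= 0:
            raise ValueError("bm_sigma2 must be > 0")
        if self.categories_per_trait < 2:
            raise ValueError("need >= 2 categories per trait")


def _brownian_tips(tree: dendropy.Tree, sigma2: float, rng: np.random.Generator) -> pd.Series:
    """One Brownian trait: root value 0, increments N(0, sigma2 * edge length)."""
    value = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
    return pd.Series({n.taxon.label: value[n] for n in tree.leaf_node_iter()})


def simulate_traits(tree: dendropy.Tree, spec: TraitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate traits on a tree; returns (observed-with-gaps, complete).

    Continuous traits are Brownian; categorical traits threshold independent
    latent Brownian traits at equally spaced quantiles. Missing entries are
    MCAR at rate ``missing_fraction`` (the complete copy is kept for
    evaluating imputation).
    """
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, pd.Series] = {}
    for j in range(spec.n_numeric):
        cols[f"num{j + 1}"] = _brownian_tips(tree, spec.bm_sigma2, rng)
    for j in range(spec.n_categorical):
        latent = _brownian_tips(tree, spec.bm_sigma2, rng)
        qs = np.quantile(latent, np.linspace(0, 1, spec.categories_per_trait + 1)[1:-1])
        codes = np.searchsorted(qs, latent.to_numpy())
        cols[f"cat{j + 1}"] = pd.Series(
            pd.Categorical.from_codes(codes, categories=[f"c{i}" for i in range(spec.categories_per_trait)]),
            index=latent.index,
        )
    complete = pd.DataFrame(cols)
    observed = complete.copy()
    if spec.missing_fraction > 0:
        mask = rng.random(complete.shape) < spec.missing_fraction
        observed = observed.mask(pd.DataFrame(mask, index=complete.index, columns=complete.columns))
    return observed, complete


# --------------------------------------------------------------------------- #
# Communities
# --------------------------------------------------------------------------- #

@dataclass
class CommunitySpec:
    """Design of synthetic plot communities.

    Each (heap, cluster) combination holds ``blocks_per_heap_per_cluster``
    blocks of ``plots_per_block`` plots. ``indicator_design`` maps cluster
    label -> (n_indicator_species, p_inside, p_outside): species planted to
    occur with probability p_inside in their cluster's plots and p_outside
    elsewhere. Remaining pool species are background, occurring at rates set
    so mean plot richness tracks ``cluster_richness_means`` (arch-shaped by
    default: richness peaks in mid-succession and dips in late succession).
    """

    n_heaps: int = 4
    blocks_per_heap_per_cluster: int = 1
    plots_per_block: int = 5
    pool_size: int = 120
    cluster_richness_means: tuple[float, ...] = (8.0, 9.0, 5.0, 9.0, 14.0)
    indicator_design: dict[int, tuple[int, float, float]] = field(
        default_factory=lambda: {c: (4, 0.6, 0.0) for c in (1, 2, 3, 4, 5)}
    )
    abundance_beta: tuple[float, float] = (1.0, 3.0)
    empty_plot_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.cluster_richness_means):
            raise ValueError("richness means must be >= 0")
        if not 0 <= self.empty_plot_fraction <= 1:
            raise ValueError("empty_plot_fraction must be in [0, 1]")
        for c, (_, p_in, p_out) in self.indicator_design.items():
            if not p_in > p_out:
                raise ValueError(f"indicator p_inside must exceed p_outside (cluster {c})")
        n_ind = sum(n for n, _, _ in self.indicator_design.values())
        if n_ind > self.pool_size:
            raise ValueError("species pool too small for indicator design")


def generate_communities(spec: CommunitySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (community matrix, plot metadata).

    Returns a plots x species cover-fraction matrix (values in (0, 1]) and a
    metadata frame with heap, block and cluster labels per plot.
    """
    rng = np.random.default_rng(spec.seed)
    clusters = sorted(spec.indicator_design) or list(
        range(1, len(spec.cluster_richness_means) + 1)
    )
    richness = dict(zip(clusters, spec.cluster_richness_means))

    species = [f"sp{i + 1:03d}" for i in range(spec.pool_size)]
    indicator_of: dict[str, int] = {}
    cursor = 0
    ind_params: dict[int, tuple[list[str], float, float]] = {}
    for c in clusters:
        n_ind, p_in, p_out = spec.indicator_design[c]
        names = species[cursor:cursor + n_ind]
        cursor += n_ind
        ind_params[c] = (names, p_in, p_out)
        for s in names:
            indicator_of[s] = c
    background = species[cursor:]

    rows, meta = [], []
    for heap in range(1, spec.n_heaps + 1):
        for c in clusters:
            for blk in range(1, spec.blocks_per_heap_per_cluster + 1):
                block_id = f"h{heap}c{c}b{blk}"
                for p in range(1, spec.plots_per_block + 1):
                    meta.append(
                        {"plot": f"{block_id}p{p}", "heap": f"h{heap}",
                         "block": block_id, "cluster": c}
                    )

    n_bg = max(len(background), 1)
    for m in meta:
        c = m["cluster"]
        present = np.zeros(spec.pool_size, dtype=bool)
        exp_ind = 0.0
        for cc, (names, p_in, p_out) in ind_params.items():
            p = p_in if cc == c else p_out
            exp_ind += p * len(names)
            if p > 0:
                idx = [species.index(s) for s in names]
                present[idx] = rng.random(len(idx)) < p
        p_bg = min(max(richness.get(c, 0.0) - exp_ind, 0.0) / n_bg, 1.0)
        if background and p_bg > 0:
            idx0 = species.index(background[0])
            sel = rng.random(len(background)) < p_bg
            present[idx0:idx0 + len(background)] = sel
        covers = np.zeros(spec.pool_size)
        n_pres = int(present.sum())
        if n_pres:
            a, b = spec.abundance_beta
            draw = rng.beta(a, b, size=n_pres)
            covers[present] = np.clip(draw, 1e-4, 1.0)
        rows.append(covers)

    comm = pd.DataFrame(rows, columns=species, index=[m["plot"] for m in meta])
    meta_df = pd.DataFrame(meta).set_index("plot")
    if spec.empty_plot_fraction > 0:
        n_empty = int(round(spec.empty_plot_fraction * len(comm)))
        empty_idx = rng.choice(len(comm), size=n_empty, replace=False)
        comm.iloc[empty_idx] = 0.0
    meta_df.attrs["indicator_of"] = indicator_of
    return comm, meta_df
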