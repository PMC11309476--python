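"""Seedable generators for every input the pipeline consumes.

These emulate the statistical structure of the real study inputs — a dated
phylogeny, phylogenetically correlated traits generated under a causal DAG,
k-mer and per-contig coverage spectra with a realistic error spike,
exponential-phase growth curves, and strictly positive relative-abundance
tables whose log-mean carries a genome-size-by-environment interaction —
so every stage of the analysis can be exercised and its parameter recovery
measured without any external downloads.

Every generator is a pure function of its arguments including the mandatory
seed: the same call is byte-identical across runs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genomesize import ContigCoverageTable, DepthHistogram
from .pathanalysis import CausalModel
from .phylo import Phylogeny, lambda_transform, phylo_covariance, read_newick
from .traits import GrowthCurve

__all__ = [
    "sim_tree",
    "sim_traits_dag",
    "sim_kmer_histogram",
    "sim_coverage_table",
    "sim_growth_curve",
    "sim_abundance_dataset",
]


def sim_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, rescaled to unit height.

    Lineages split at exponential waiting times until ``n_tips`` are alive;
    tips are labelled ``t1..tn`` in birth order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    # each active lineage: (newick subtree string builder via parent times)
    # represent as list of (label or subtree, birth_time)
    class _Node:
        __slots__ = ("left", "right", "label", "time")

        def __init__(self, label=None, time=0.0):
            self.left = self.right = None
            self.label = label
            self.time = time  # birth time of this node

    t = 0.0
    root = _Node(label="t1", time=0.0)
    active = [root]
    next_label = 2
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        node = active[i]
        node.left = _Node(label=node.label, time=t)
        node.right = _Node(label=f"t{next_label}", time=t)
        node.label = None
        node.time = t
        next_label += 1
        active[i] = node.left
        active.append(node.right)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    height = t
    scale = height - root.time  # unit height below the root split

    def newick(node: _Node, parent_time: float) -> str:
        end = node.time if node.left is not None else height
        bl = (end - parent_time) / scale
        if node.left is None:
            return f"{node.label}:{bl:.10f}"
        return f"({newick(node.left, end)},{newick(node.right, end)}):{bl:.10f}"

    if root.left is None:  # only possible if n_tips == 1, guarded above
        raise AssertionError
    text = f"({newick(root.left, root.time)},{newick(root.right, root.time)}):0;"
    return read_newick(text)


def sim_traits_dag(
    tree: Phylogeny,
    dag: CausalModel,
    path_coefficients: dict[tuple[str, str], float],
    lambda_true: float = 1.0,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetically correlated traits generated under a causal DAG.

    Vertices are generated in topological order: each is the sum of its
    standardized parents weighted by the path coefficients plus a
    phylogenetically correlated Gaussian residual (covariance proportional
    to ``lambda_transform(C, lambda_true)``, which has unit diagonal on the
    unit-height trees of :func:`sim_tree`). The residual is scaled so each
    vertex has unit variance: the supplied coefficients are therefore
    standardized effects directly comparable with fitted path coefficients.
    ``residual_sd`` multiplies the residual further (1 keeps the
    standardized-effect interpretation). All columns are standardized on
    output.
    """
    import networkx as nx

    g = dag.graph()
    for e in g.edges:
        if tuple(e) not in path_coefficients:
            raise ValueError(f"missing path coefficient for edge {e[0]}->{e[1]}")
    rng = np.random.default_rng(seed)
    cov = lambda_transform(phylo_covariance(tree), lambda_true)
    L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(len(cov.labels)))
    n = len(cov.labels)
    vals: dict[str, np.ndarray] = {}
    for v in nx.topological_sort(g):
        eps = L @ rng.standard_normal(n)
        lin = np.zeros(n)
        for parent in g.predecessors(v):
            pv = vals[parent]
            lin = lin + path_coefficients[(parent, v)] * (pv - pv.mean()) / pv.std(ddof=1)
        # scale the residual so the vertex has (close to) unit variance and
        # the coefficients remain standardized effects
        explained = float(lin.var(ddof=1))
        resid_var = max(1.0 - explained, 0.05)
        vals[v] = lin + residual_sd * math.sqrt(resid_var) * eps
    frame = pd.DataFrame(vals, index=cov.labels)
    frame = (frame - frame.mean()) / frame.std(ddof=1)
    frame.index.name = "species"
    return frame


def sim_kmer_histogram(
    genome_size_bp: int,
    depth_mean: float,
    k: int = 21,
    ploidy: int = 1,
    error_rate: float = 0.01,
    seed: int = 0,
    max_depth: int | None = None,
) -> DepthHistogram:
    """k-mer frequency histogram: low-depth error spike plus genomic peak.

    The genomic peak holds ``genome_size_bp * ploidy`` distinct k-mers with
    Poisson(depth_mean) depths, so its total mass is about
    ``GS * ploidy * depth_mean`` and the peak estimator's GS = N / (C p)
    recovers the haploid size. Errors contribute
    ``error_rate * GS * depth_mean`` distinct low-depth k-mers split 80/15/5
    across depths 1-3 (each sequencing error yields roughly one never-seen
    k-mer per errored base). Bin counts are Poisson-sampled around their
    expectations.
    """
    if genome_size_bp <= 0 or depth_mean <= 0:
        raise ValueError("genome size and depth must be positive")
    from scipy import stats

    rng = np.random.default_rng(seed)
    if max_depth is None:
        max_depth = int(depth_mean + 8 * math.sqrt(depth_mean)) + 3
    depths = np.arange(1, max_depth + 1)
    expected = genome_size_bp * ploidy * stats.poisson.pmf(depths, depth_mean)
    if error_rate > 0:
        n_err = error_rate * genome_size_bp * depth_mean
        expected[0] += 0.80 * n_err
        if max_depth >= 2:
            expected[1] += 0.15 * n_err
        if max_depth >= 3:
            expected[2] += 0.05 * n_err
    counts = rng.poisson(expected).astype(float)
    return DepthHistogram(depth=depths, count=counts, kind="kmer")


def sim_coverage_table(
    genome_size_bp: int,
    n_contigs: int = 200,
    depth_mean: float = 30.0,
    read_length: int = 150,
    seed: int = 0,
):
    """Per-contig coverage table from a fragmented assembly.

    Contig lengths partition ``genome_size_bp`` (lognormal proportions).
    Per-contig mean coverage reflects Poisson read sampling (read count ~
    Poisson(L * C / read_length), so longer contigs have tighter coverage)
    times a 3% lognormal mapping/GC bias; a small fraction (5%, collapsed
    repeats) sits around twice the genomic depth. Returns
    ``(ContigCoverageTable, n_mapped_reads)`` with
    ``n_mapped_reads = round(GS * depth_mean / read_length)``.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=0.8, size=n_contigs)
    lengths = np.floor(raw / raw.sum() * genome_size_bp).astype(np.int64)
    lengths = np.maximum(lengths, read_length)
    lengths[-1] += genome_size_bp - int(lengths.sum())
    lengths[-1] = max(lengths[-1], read_length)
    depth = np.full(n_contigs, float(depth_mean))
    repeat = rng.uniform(size=n_contigs) < 0.05
    depth[repeat] = 2 * depth_mean
    bias = rng.lognormal(mean=0.0, sigma=0.03, size=n_contigs)
    expected_reads = lengths * depth * bias / read_length
    cov = read_length * rng.poisson(expected_reads) / lengths
    cov = np.maximum(cov, 0.1)
    frame = pd.DataFrame(
        {"contig_id": [f"contig_{i + 1}" for i in range(n_contigs)],
         "length": lengths, "mean_coverage": cov}
    )
    n_reads = int(round(genome_size_bp * depth_mean / read_length))
    return ContigCoverageTable(frame), n_reads


def sim_growth_curve(
    mu: float,
    lag_h: float = 24.0,
    carrying_capacity: float = 200.0,
    noise_cv: float = 0.02,
    dt_h: float = 24.0,
    n_points: int = 15,
    rf0: float = 1.0,
    seed: int = 0,
    temperature_c: float | None = None,
) -> GrowthCurve:
    """Lag + logistic growth curve with multiplicative lognormal noise.

    RF stays at ``rf0`` until ``lag_h``, then follows logistic growth with
    intrinsic rate ``mu`` toward ``carrying_capacity``; observation noise is
    lognormal with coefficient of variation ``noise_cv`` (mean 1).
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * dt_h
    rf = np.empty(n_points)
    for i, ti in enumerate(t):
        if ti <= lag_h:
            rf[i] = rf0
        else:
            te = ti - lag_h
            rf[i] = carrying_capacity / (
                1.0 + (carrying_capacity / rf0 - 1.0) * math.exp(-mu * te)
            )
    if noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + noise_cv**2))
        rf = rf * rng.lognormal(-0.5 * sig * sig, sig, size=n_points)
    return GrowthCurve(time_h=t, rf=rf, temperature_c=temperature_c)


REGION_BANDS = (
    (60.0, 90.0, "Arctic Ocean"),
    (23.0, 60.0, "North Temperate"),
    (-23.0, 23.0, "Tropical"),
    (-60.0, -23.0, "South Temperate"),
    (-90.0, -60.0, "Southern Ocean"),
)


def _region_of(lat: float) -> str:
    for lo, hi, name in REGION_BANDS:
        if lo <= lat <= hi:
            return name
    raise ValueError(f"latitude {lat} out of range")


def sim_station_metadata(n_stations: int, rng: np.random.Generator) -> pd.DataFrame:
    """Station latitudes, temperatures and regions with realistic covariance.

    Temperature decreases deterministically with absolute latitude
    (28 - 0.3 |lat| plus noise) so the latitude, region and temperature
    model variants are mutually consistent.
    """
    lat = rng.uniform(-80, 80, size=n_stations)
    temp = 28.0 - 0.3 * np.abs(lat) + rng.normal(0, 1.5, size=n_stations)
    lon = rng.uniform(-180, 180, size=n_stations)
    return pd.DataFrame(
        {
            "sample_id": [f"station_{i + 1}" for i in range(n_stations)],
            "latitude_deg": lat,
            "longitude_deg": lon,
            "ocean_region": [_region_of(x) for x in lat],
            "temperature_c": temp,
        }
    )


def sim_abundance_dataset(
    tree: Phylogeny,
    genome_sizes: "dict[str, float] | None" = None,
    n_stations: int = 40,
    interaction_beta: float = -0.5,
    gamma_shape: float = 5.0,
    phylo_sd: float = 0.5,
    seed: int = 0,
    intercept: float = -4.6,
    beta_temp: float = -0.05,
    beta_gs: float = 0.3,
):
    """Strictly positive species-by-station abundances with a genome-size
    by temperature interaction.

    The response is drawn from the same gamma model the abundance module
    fits: ``log mu = b0 + b_t temp_c + b_g g + interaction_beta temp_c g
    + u``, with temperature centered, ``g`` the centered log10 genome size,
    and ``u`` phylogenetic species intercepts (Brownian correlation,
    standard deviation ``phylo_sd``). With ``interaction_beta < 0``, large
    genomes are more abundant at cold (high-latitude) stations by
    construction. ``genome_sizes`` maps species to haploid bp; omitted, they
    are simulated by Brownian motion on the tree (log10 sizes around 7.8,
    sd 0.3).

    Returns ``(AbundanceTable rows, StationMetadata)``.
    """
    rng = np.random.default_rng(seed)
    cov = phylo_covariance(tree)
    species = cov.labels
    n_sp = len(species)
    corr = cov.to_correlation()
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n_sp))

    if genome_sizes is None:
        bm = L @ rng.standard_normal(n_sp)
        log_gs = 7.8 + 0.3 * (bm - bm.mean()) / bm.std(ddof=1)
        genome_sizes = {s: 10.0 ** v for s, v in zip(species, log_gs)}
    missing = set(species) - set(genome_sizes)
    if missing:
        raise ValueError(f"genome_sizes missing species: {sorted(missing)}")
    log_gs = np.array([math.log10(genome_sizes[s]) for s in species])

    stations = sim_station_metadata(n_stations, rng)
    u = phylo_sd * (L @ rng.standard_normal(n_sp))

    g_c = log_gs - log_gs.mean()
    t_c = stations["temperature_c"].to_numpy() - stations["temperature_c"].mean()
    eta = (
        intercept
        + beta_temp * t_c[None, :]
        + beta_gs * g_c[:, None]
        + interaction_beta * t_c[None, :] * g_c[:, None]
        + u[:, None]
    )  # (species, stations)
    mu = np.exp(eta)
    y = rng.gamma(shape=gamma_shape, scale=mu / gamma_shape)
    y = np.maximum(y, 1e-12)

    rows = pd.DataFrame(
        {
            "species": np.repeat(species, n_stations),
            "sample_id": np.tile(stations["sample_id"].to_numpy(), n_sp),
            "rel_abundance": y.ravel(),
            "genome_size_log10": np.repeat(log_gs, n_stations),
        }
    )
    table = rows.merge(stations, on="sample_id", how="left")
    return table, stations
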