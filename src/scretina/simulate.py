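"""Synthetic single-cell and bulk data with the structure the pipeline assumes.

The generator emulates droplet scRNA-seq of developing retinal tissue:
negative-binomial (gamma-Poisson) unique-transcript counts with per-cell
library-size variation, cluster-specific mean profiles, a mitochondrial
transcript share drawn per cell from a beta distribution (with a small
"damaged" subpopulation at an inflated share), region-specific expression
shifts on a designated gene set, age-dependent composition and expression
drift, and injected doublets formed by summing the counts of two parent
cells from distinct clusters.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator`` handed to each sub-step in fixed order, so any
simulation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import ExpressionMatrix

__all__ = [
    "ClusterSpec",
    "AgeStage",
    "SimConfig",
    "SyntheticTruth",
    "BulkSeries",
    "simulate_counts",
    "simulate_timecourse",
    "simulate_embedding",
    "retina_like_config",
    "write_truth_csv",
    "write_bulk_tsv",
]


@dataclass
class ClusterSpec:
    """One simulated cell population.

    ``profile`` is the mean expression per gene in expected transcripts per
    cell; it is renormalized to each cell's drawn library size, so only its
    shape matters.
    """

    name: str
    n_cells: int
    profile: np.ndarray
    embedding_center: tuple[float, float] | None = None
    embedding_sd: float = 0.8

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, float)
        if self.n_cells < 1:
            raise ValueError(f"cluster {self.name!r}: n_cells must be >= 1")
        if (self.profile < 0).any():
            raise ValueError(f"cluster {self.name!r}: mean profile must be nonnegative")


@dataclass
class AgeStage:
    """One time point of a developmental series."""

    age_weeks: float
    proportions: dict[str, float]  # cluster name -> fraction of cells
    n_cells: int = 500


@dataclass
class SimConfig:
    """Full description of a simulated dataset.

    Defaults are chosen to resemble a small 10x v2 retina experiment:
    median library near 2,000 transcripts, NB dispersion 0.1, ~5% resting
    mitochondrial share with a 5% damaged subpopulation near 40%.
    """

    n_genes: int
    clusters: list[ClusterSpec]
    library_log_mean: float = np.log(2000.0)
    library_log_sd: float = 0.35
    nb_dispersion: float = 0.1
    mito_gene_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    mito_beta: tuple[float, float] = (2.0, 38.0)          # mean 0.05
    damaged_fraction: float = 0.0
    damaged_beta: tuple[float, float] = (8.0, 12.0)       # mean 0.40
    regional_gene_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    regional_log2fc: np.ndarray = field(default_factory=lambda: np.array([], float))
    fovea_fraction: float = 0.0
    age_series: list[AgeStage] = field(default_factory=list)
    trajectory_gene_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    trajectory_base: np.ndarray = field(default_factory=lambda: np.array([], float))
    trajectory_slope: np.ndarray = field(default_factory=lambda: np.array([], float))
    bulk_noise_sd: float = 0.0   # noise sd as a fraction of each gene's range
    doublet_rate: float = 0.0
    embedding_range: float = 17.0
    sample_id: str = "sim"
    age_weeks: float = 38.0
    gene_names: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.clusters:
            raise ValueError("at least one cluster is required")
        for c in self.clusters:
            if len(c.profile) != self.n_genes:
                raise ValueError(f"cluster {c.name!r}: profile length != n_genes")
        for frac, name in [
            (self.doublet_rate, "doublet_rate"),
            (self.fovea_fraction, "fovea_fraction"),
            (self.damaged_fraction, "damaged_fraction"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.mito_gene_idx = np.asarray(self.mito_gene_idx, int)
        self.regional_gene_idx = np.asarray(self.regional_gene_idx, int)
        self.regional_log2fc = np.asarray(self.regional_log2fc, float)
        if len(self.regional_gene_idx) != len(self.regional_log2fc):
            raise ValueError("regional gene index and log2fc lengths differ")
        self.trajectory_gene_idx = np.asarray(self.trajectory_gene_idx, int)
        self.trajectory_base = np.asarray(self.trajectory_base, float)
        self.trajectory_slope = np.asarray(self.trajectory_slope, float)
        if not (len(self.trajectory_gene_idx) == len(self.trajectory_base)
                == len(self.trajectory_slope)):
            raise ValueError("trajectory gene index/base/slope lengths differ")
        if (self.trajectory_base <= 0).any():
            raise ValueError("trajectory baselines must be positive")
        ages = [s.age_weeks for s in self.age_series]
        if ages and any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("age_series must be strictly increasing in age")

    def gene_ids(self) -> pd.Index:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names length != n_genes")
            return pd.Index(np.asarray(self.gene_names, object))
        ids = np.array([f"G{j:05d}" for j in range(self.n_genes)], object)
        for j in self.mito_gene_idx:
            ids[j] = f"MT-{ids[j]}"
        return pd.Index(ids)


@dataclass
class SyntheticTruth:
    """Ground-truth labels for a simulated matrix."""

    cluster: np.ndarray
    region: np.ndarray
    is_doublet: np.ndarray
    is_damaged: np.ndarray
    sample_id: np.ndarray
    age_weeks: np.ndarray
    cell_ids: pd.Index
    regional_gene_mask: np.ndarray
    trajectory_gene_mask: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "region": self.region,
                "age_weeks": self.age_weeks,
                "is_doublet": self.is_doublet,
                "is_damaged": self.is_damaged,
                "sample_id": self.sample_id,
            },
            index=self.cell_ids,
        )


@dataclass
class BulkSeries:
    """Gene x sample bulk expression with per-sample ages (weeks)."""

    values: pd.DataFrame   # genes x samples
    ages: pd.Series        # per sample

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.ages.index):
            raise ValueError("bulk sample columns and age index differ")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("bulk expression must be nonnegative")


# ---------------------------------------------------------------------

def _cell_means(config: SimConfig, cluster: ClusterSpec, region: str,
                age_weeks: float) -> np.ndarray:
    """Expected per-gene share of a cell's library for one cluster/region/age."""
    prof = cluster.profile.astype(float).copy()
    if region == "fovea" and len(config.regional_gene_idx):
        prof[config.regional_gene_idx] *= 2.0 ** config.regional_log2fc
    if len(config.trajectory_gene_idx) and config.age_series:
        a0 = config.age_series[0].age_weeks
        rel = np.clip(
            (config.trajectory_base + config.trajectory_slope * (age_weeks - a0))
            / config.trajectory_base, 0.0, None)
        prof[config.trajectory_gene_idx] *= rel
    s = prof.sum()
    if s <= 0:
        raise ValueError(f"cluster {cluster.name!r}: profile sums to zero")
    return prof / s


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Gamma-Poisson (NB) draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig, *, rng: np.random.Generator | None = None,
    age_weeks: float | None = None, proportions: dict[str, float] | None = None,
    sample_id: str | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate one cell x gene count matrix plus ground-truth labels.

    ``proportions`` overrides the per-cluster cell counts (used by
    :func:`simulate_timecourse` for composition drift); the total cell
    count is then the sum of configured cluster sizes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    age = config.age_weeks if age_weeks is None else age_weeks
    sample = config.sample_id if sample_id is None else sample_id

    if proportions is None:
        sizes = {c.name: c.n_cells for c in config.clusters}
    else:
        total = sum(c.n_cells for c in config.clusters)
        names = [c.name for c in config.clusters]
        p = np.array([proportions.get(n, 0.0) for n in names], float)
        p = p / p.sum()
        raw = np.floor(p * total).astype(int)
        raw[: total - raw.sum()] += 1  # distribute remainder deterministically
        sizes = dict(zip(names, raw))

    rows: list[np.ndarray] = []
    labels: list[str] = []
    regions: list[str] = []
    damaged_flags: list[bool] = []
    by_cluster: dict[str, list[int]] = {}
    i = 0
    for c in config.clusters:
        n = sizes.get(c.name, 0)
        if n == 0:
            continue
        n_fov = int(round(config.fovea_fraction * n))
        for k in range(n):
            region = "fovea" if k < n_fov else "periphery"
            share = _cell_means(config, c, region, age)
            lib = rng.lognormal(config.library_log_mean, config.library_log_sd)
            mean = share * lib
            # beta-distributed mitochondrial share, inflated for damaged cells
            damaged = False
            if len(config.mito_gene_idx):
                damaged = rng.random() < config.damaged_fraction
                a, b = config.damaged_beta if damaged else config.mito_beta
                f = rng.beta(a, b)
                nonmito = np.ones(config.n_genes, bool)
                nonmito[config.mito_gene_idx] = False
                mean = mean.copy()
                mean[nonmito] *= (1.0 - f)
                mito_share = np.full(len(config.mito_gene_idx), 1.0 / len(config.mito_gene_idx))
                mean[config.mito_gene_idx] = f * lib * mito_share
            rows.append(_draw_counts(rng, mean, config.nb_dispersion))
            labels.append(c.name)
            regions.append(region)
            damaged_flags.append(damaged)
            by_cluster.setdefault(c.name, []).append(i)
            i += 1

    n_cells = len(rows)
    counts = np.vstack(rows)
    is_doublet = np.zeros(n_cells, bool)

    # doublets: a host cell absorbs the counts of a parent from another cluster
    n_doub = int(round(config.doublet_rate * n_cells))
    if n_doub and len(by_cluster) < 2:
        raise ValueError("doublet injection requires at least two clusters")
    if n_doub:
        hosts = rng.choice(n_cells, size=n_doub, replace=False)
        cluster_names = list(by_cluster)
        for h in hosts:
            others = [c for c in cluster_names if c != labels[h]]
            partner_cluster = others[rng.integers(len(others))]
            partner = by_cluster[partner_cluster][
                rng.integers(len(by_cluster[partner_cluster]))
            ]
            counts[h] += counts[partner]
            is_doublet[h] = True

    cell_ids = pd.Index([f"{sample}_C{i:05d}" for i in range(n_cells)])
    regional_mask = np.zeros(config.n_genes, bool)
    regional_mask[config.regional_gene_idx] = True
    traj_mask = np.zeros(config.n_genes, bool)
    traj_mask[config.trajectory_gene_idx] = True
    truth = SyntheticTruth(
        cluster=np.array(labels, object),
        region=np.array(regions, object),
        is_doublet=is_doublet,
        is_damaged=np.array(damaged_flags, bool),
        sample_id=np.full(n_cells, sample, object),
        age_weeks=np.full(n_cells, float(age)),
        cell_ids=cell_ids,
        regional_gene_mask=regional_mask,
        trajectory_gene_mask=traj_mask,
    )
    matrix = ExpressionMatrix(sp.csr_matrix(counts), cell_ids, config.gene_ids())
    return matrix, truth


def simulate_timecourse(
    config: SimConfig,
) -> tuple[list[tuple[ExpressionMatrix, SyntheticTruth]], BulkSeries]:
    """Simulate one matrix per age plus a matched bulk reference table.

    The bulk table's designated trajectory genes follow linear (monotone)
    trajectories ``base + slope * (age - age0)``, clipped at zero, on a
    TPM-like scale; other genes stay at their average cluster-profile
    level.  Gaussian noise with sd ``bulk_noise_sd`` times each gene's
    noise-free range is added when nonzero.
    """
    if not config.age_series:
        raise ValueError("age_series is empty")
    rng = np.random.default_rng(config.seed)
    out = []
    for stage in config.age_series:
        m, t = simulate_counts(
            config, rng=rng, age_weeks=stage.age_weeks,
            proportions=stage.proportions,
            sample_id=f"{config.sample_id}_w{stage.age_weeks:g}",
        )
        out.append((m, t))

    # bulk values on a TPM-like scale (expressed genes ~ tens to hundreds)
    base = np.mean([c.profile for c in config.clusters], axis=0)
    base = 10_000.0 * base / base.sum()
    if len(config.trajectory_gene_idx):
        base[config.trajectory_gene_idx] = config.trajectory_base
    ages = np.array([s.age_weeks for s in config.age_series], float)
    a0 = ages[0]
    clean = {}
    for age in ages:
        v = base.copy()
        if len(config.trajectory_gene_idx):
            v[config.trajectory_gene_idx] = np.clip(
                config.trajectory_base + config.trajectory_slope * (age - a0),
                0.0, None)
        clean[f"w{age:g}"] = v
    bulk = pd.DataFrame(clean, index=config.gene_ids())
    if config.bulk_noise_sd > 0:
        span = (bulk.max(axis=1) - bulk.min(axis=1)).to_numpy()
        noise = rng.normal(0.0, 1.0, bulk.shape) * (config.bulk_noise_sd * span)[:, None]
        bulk = (bulk + noise).clip(lower=0.0)
    series = BulkSeries(bulk, pd.Series(ages, index=bulk.columns, name="age_weeks"))
    return out, series


def simulate_embedding(
    truth: SyntheticTruth, config: SimConfig, *, rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place each cell at its cluster's 2D Gaussian; columns x, y.

    Cluster centers default to a circle of radius ``0.5 * embedding_range``;
    explicit centers must lie inside ``[-range, +range]^2``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    names = [c.name for c in config.clusters]
    r = config.embedding_range
    centers = {}
    for idx, c in enumerate(config.clusters):
        if c.embedding_center is not None:
            cx, cy = c.embedding_center
        else:
            ang = 2.0 * np.pi * idx / len(names)
            cx, cy = 0.5 * r * np.cos(ang), 0.5 * r * np.sin(ang)
        if abs(cx) > r or abs(cy) > r:
            raise ValueError(
                f"cluster {c.name!r}: embedding center ({cx}, {cy}) outside "
                f"[-{r}, {r}]^2"
            )
        centers[c.name] = (cx, cy, c.embedding_sd)
    xy = np.empty((len(truth.cluster), 2))
    for i, lab in enumerate(truth.cluster):
        cx, cy, sd = centers[lab]
        pt = rng.normal([cx, cy], sd)
        # resample the rare tail draw that would leave the grid
        while abs(pt[0]) > r or abs(pt[1]) > r:
            pt = rng.normal([cx, cy], sd)
        xy[i] = pt
    return pd.DataFrame(xy, columns=["x", "y"], index=truth.cell_ids)


# ---------------------------------------------------------------------

def retina_like_config(
    *, n_genes: int = 300, cells_per_cluster: int = 150, seed: int = 0,
    doublet_rate: float = 0.0, damaged_fraction: float = 0.0,
    fovea_fraction: float = 0.0, n_regional: int = 0,
    classes: tuple[str, ...] = ("rods", "cones", "bipolar cells",
                                "amacrine cells", "glial cells", "pigmented cells"),
) -> SimConfig:
    """A small retina-flavored configuration used throughout the tests.

    The first genes are renamed to each class's marker genes so the packaged
    marker sets apply; every class overexpresses its own markers ~30x over a
    shared baseline, giving well-separated transcriptomic types.
    """
    from .multiplet import PACKAGED_MARKER_SETS

    rng = np.random.default_rng(seed + 7)
    marker_map: dict[str, list[int]] = {}
    next_idx = 0
    gene_names = [f"G{j:05d}" for j in range(n_genes)]
    for cls in classes:
        genes = PACKAGED_MARKER_SETS[cls]
        idx = list(range(next_idx, next_idx + len(genes)))
        for i, g in zip(idx, genes):
            gene_names[i] = g
        marker_map[cls] = idx
        next_idx += len(genes)

    n_mito = 10
    mito_idx = np.arange(n_genes - n_mito, n_genes)

    clusters = []
    for cls in classes:
        prof = rng.uniform(0.2, 1.0, n_genes)
        prof[mito_idx] = 0.05
        prof[marker_map[cls]] = 30.0
        clusters.append(ClusterSpec(cls, cells_per_cluster, prof))

    regional_idx = np.arange(next_idx, next_idx + n_regional)
    regional_fc = rng.uniform(1.0, 2.0, n_regional) * rng.choice([-1.0, 1.0], n_regional)

    # marker genes keep their real names; mito genes get the MT- prefix
    ids = np.array(gene_names, object)
    for j in mito_idx:
        ids[j] = f"MT-{ids[j]}"
    return SimConfig(
        n_genes=n_genes,
        clusters=clusters,
        mito_gene_idx=mito_idx,
        damaged_fraction=damaged_fraction,
        regional_gene_idx=regional_idx,
        regional_log2fc=regional_fc,
        fovea_fraction=fovea_fraction,
        doublet_rate=doublet_rate,
        gene_names=ids,
        seed=seed,
    )


def developmental_timecourse_config(
    *, n_genes: int = 200, n_trajectory: int = 50,
    ages: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 16.0),
    noise: float = 0.05, cells_per_stage: int = 200, seed: int = 0,
) -> SimConfig:
    """Configuration for a developing-tissue series with a bulk reference.

    Trajectory genes follow linear monotone trajectories between a baseline
    (log-uniform on [2, 30] TPM-like units) and a level 4-12x higher, half
    rising and half falling, so every one clears the median-normalized
    range (dnr) selection while ranks between nearby ages stay highly
    correlated — the banded Spearman structure of real developmental bulk
    series.  Noise sd is ``noise`` times each gene's range.  Cell-type
    composition drifts with age (progenitors give way to neurons).
    """
    rng = np.random.default_rng(seed + 13)
    prof_a = rng.uniform(0.2, 1.0, n_genes)
    prof_b = prof_a * rng.uniform(0.5, 2.0, n_genes)
    idx = np.arange(n_trajectory)
    base = np.exp(rng.uniform(np.log(2.0), np.log(30.0), n_trajectory))
    factor = np.exp(rng.uniform(np.log(4.0), np.log(12.0), n_trajectory))
    rising = rng.random(n_trajectory) < 0.5
    start = np.where(rising, base, base * factor)
    end = np.where(rising, base * factor, base)
    # single-cell baselines of trajectory genes mirror the bulk baselines,
    # so pseudo-bulk rank profiles track the reference series
    prof_a[idx] = prof_b[idx] = start / start.mean()
    clusters = [
        ClusterSpec("progenitors", cells_per_stage // 2, prof_a),
        ClusterSpec("neurons", cells_per_stage // 2, prof_b),
    ]
    span = ages[-1] - ages[0]
    stages = []
    for a in ages:
        f = (a - ages[0]) / span
        stages.append(AgeStage(a, {"progenitors": 0.8 - 0.6 * f,
                                   "neurons": 0.2 + 0.6 * f}))
    return SimConfig(
        n_genes=n_genes,
        clusters=clusters,
        age_series=stages,
        trajectory_gene_idx=idx,
        trajectory_base=start,
        trajectory_slope=(end - start) / span,
        bulk_noise_sd=noise,
        seed=seed,
    )


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    df = truth.frame().reset_index(names="cell_id")
    df.to_csv(path, index=False)


def write_bulk_tsv(series: BulkSeries, path, ages_path=None) -> None:
    series.values.to_csv(path, sep="\t")
    if ages_path is not None:
        series.ages.rename_axis("sample").to_csv(ages_path)
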