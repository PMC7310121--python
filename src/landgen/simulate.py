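"""Synthetic landscape-genetics data with known ground truth.

The generator emulates the statistical structure of a regional survey of a
selfing annual plant: ~278 populations of ~6 haploid individuals genotyped
at 240 biallelic SNPs over a ~800 x 700 km landscape, with

* spatially autocorrelated environmental covariates (Gaussian random fields
  with exponential covariance),
* a habitat-suitability surface that is a logistic function of those fields,
* per-population gene diversity from the hurdle-Beta generative model
  (a Bernoulli presence process and a conditional Beta process, each with a
  spatial Gaussian-process term) with roughly a quarter of populations in
  the (near-)zero class,
* haploid genotypes whose allele frequencies drift around a spatially
  correlated local mean, so pairwise F_ST rises with geographic distance
  (isolation by distance), and
* pairwise tables drawn directly from the MLPE generative model so the
  mixed-model machinery can be tested against exact truth.

Every stage consumes a named substream of one seed sequence, so adding draws
to one stage never perturbs another, and all outputs are bit-reproducible
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit, logit

from .raster import Raster, write_ascii_grid
from .genotypes import GenotypeMatrix, write_genotype_csv, write_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_landscape",
    "simulate_populations",
    "simulate_genotypes",
    "simulate_pairwise",
    "write_fixture_set",
]

_STREAMS = ("landscape", "populations", "genotypes", "pairwise")


@dataclass
class SimConfig:
    """Generator settings; the defaults mirror the emulated study design."""

    seed: int = 0
    # landscape grid (cellsize in km)
    ncols: int = 40
    nrows: int = 35
    cellsize: float = 20.0
    barrier: bool = False          # nodata strip splitting the mask
    # sampling design
    n_populations: int = 278
    n_individuals_per_pop: int = 6
    n_loci: int = 240
    # environment
    env_n_variables: int = 3
    env_gp_sd: float = 1.0
    env_gp_range: float = 150.0
    # hurdle truth (covariates standardized; diversity on H_S scale)
    alpha_z: float = 1.2
    beta_z: tuple[float, ...] = (-0.6, 0.3, 0.0)
    alpha_y: float = -2.2
    beta_y: tuple[float, ...] = (-0.4, 0.2, 0.0)
    phi: float = 30.0
    sigma_z: float = 0.75
    sigma_y: float = 0.5
    gp_range: float = 150.0
    threshold: float = 0.009
    # pairwise (MLPE) truth over standardized predictors
    beta0: float = 0.64
    beta_ibd: float = 0.08
    beta_ibe: float = 0.04
    beta_ibr: float = 0.0
    sigma_pop: float = 0.05
    sigma_res: float = 0.08
    # genotype drift
    f_min: float = 0.3
    f_max: float = 0.9
    drift_scale: float = 2.0
    ibd_range: float = 150.0
    geno_spatial_sd: float = 1.2

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        if stream not in _STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class SimTruth:
    """Realized latent values, packaged for test assertions."""

    env_fields: np.ndarray | None = None          # (k, nrows, ncols)
    suitability_weights: np.ndarray | None = None
    u_z: np.ndarray | None = None
    u_y: np.ndarray | None = None
    z: np.ndarray | None = None
    pi: np.ndarray | None = None
    mu: np.ndarray | None = None
    allele_freq: np.ndarray | None = None         # (n_pops, n_loci)
    pop_effects: np.ndarray | None = None
    expected_pairwise: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _gp_draws(
    coords: np.ndarray, sd: float, rng_scale: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Zero-mean Gaussian-field draws with covariance sd^2 exp(-d / range)."""
    n = len(coords)
    if sd == 0.0:
        return np.zeros((size, n))
    corr = np.exp(-cdist(coords, coords) / rng_scale)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    return sd * (rng.standard_normal((size, n)) @ L.T)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_landscape(cfg: SimConfig) -> tuple[dict[str, Raster], Raster, Raster, SimTruth]:
    """Environmental rasters, suitability surface and land mask.

    Returns ``(env_stack, suitability, mask, truth)``.  Each environmental
    variable is an independent Gaussian random field on the grid; suitability
    is the logistic of a fixed, recorded linear combination of the fields.
    """
    rng = cfg.rng("landscape")
    rows, cols = np.meshgrid(np.arange(cfg.nrows), np.arange(cfg.ncols), indexing="ij")
    xs = (cols + 0.5) * cfg.cellsize
    ys = (cfg.nrows - rows - 0.5) * cfg.cellsize
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    fields = _gp_draws(centers, cfg.env_gp_sd, cfg.env_gp_range, rng, cfg.env_n_variables)
    fields = fields.reshape(cfg.env_n_variables, cfg.nrows, cfg.ncols)
    weights = np.array(
        [0.8 * (-1.0) ** k / (k + 1.0) for k in range(cfg.env_n_variables)]
    )
    lin = np.tensordot(weights, fields, axes=1)
    suit_vals = expit(lin)
    mask_vals = np.ones((cfg.nrows, cfg.ncols))
    if cfg.barrier:
        mask_vals[:, cfg.ncols // 2] = np.nan
    mask = Raster(mask_vals, 0.0, 0.0, cfg.cellsize)
    env = {
        f"env{k + 1}": Raster(np.where(np.isnan(mask_vals), np.nan, fields[k]), 0.0, 0.0, cfg.cellsize)
        for k in range(cfg.env_n_variables)
    }
    suit = Raster(np.where(np.isnan(mask_vals), np.nan, suit_vals), 0.0, 0.0, cfg.cellsize)
    truth = SimTruth(env_fields=fields, suitability_weights=weights,
                     params={"env_gp_sd": cfg.env_gp_sd, "env_gp_range": cfg.env_gp_range})
    return env, suit, mask, truth


def simulate_populations(
    landscape: tuple[dict[str, Raster], Raster, Raster, SimTruth], cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Population table (id, x, y, hs, covariates) from the hurdle truth."""
    env, _suit, mask, _ = landscape
    rng = cfg.rng("populations")
    land = np.argwhere(mask.data_mask)
    pick = land[rng.integers(0, len(land), cfg.n_populations)]
    jitter = rng.uniform(0.05, 0.95, size=(cfg.n_populations, 2))
    x = (pick[:, 1] + jitter[:, 0]) * cfg.cellsize
    y = (mask.nrows - pick[:, 0] - jitter[:, 1]) * cfg.cellsize
    coords = np.column_stack([x, y])
    X = np.column_stack([env[f"env{k + 1}"].values[pick[:, 0], pick[:, 1]]
                         for k in range(cfg.env_n_variables)])
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    bz = np.asarray(cfg.beta_z, dtype=float)[: cfg.env_n_variables]
    by = np.asarray(cfg.beta_y, dtype=float)[: cfg.env_n_variables]
    u_z = _gp_draws(coords, cfg.sigma_z, cfg.gp_range, rng)[0]
    u_y = _gp_draws(coords, cfg.sigma_y, cfg.gp_range, rng)[0]
    pi = expit(cfg.alpha_z + Xs @ bz + u_z)
    z = (rng.uniform(size=cfg.n_populations) < pi).astype(int)
    mu = expit(cfg.alpha_y + Xs @ by + u_y)
    hs = np.zeros(cfg.n_populations)
    pos = z == 1
    a = mu[pos] * cfg.phi
    b = (1.0 - mu[pos]) * cfg.phi
    hs[pos] = rng.beta(a, b)
    table = pd.DataFrame(
        {"id": [f"pop{i + 1}" for i in range(cfg.n_populations)], "x": x, "y": y, "hs": hs}
    )
    for k in range(cfg.env_n_variables):
        table[f"env{k + 1}"] = X[:, k]
    truth = SimTruth(
        u_z=u_z, u_y=u_y, z=z, pi=pi, mu=mu,
        params={
            "alpha_z": cfg.alpha_z, "beta_z": list(bz), "alpha_y": cfg.alpha_y,
            "beta_y": list(by), "phi": cfg.phi, "sigma_z": cfg.sigma_z,
            "sigma_y": cfg.sigma_y, "range": cfg.gp_range,
        },
    )
    return table, truth


def simulate_genotypes(pops: pd.DataFrame, cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Haploid biallelic genotypes with isolation by distance.

    Per locus the ancestral frequency p0 ~ U(0.1, 0.9); population
    frequencies are logit-normal perturbations of p0 with a spatially
    correlated component (correlation decaying over ``ibd_range``, which
    creates IBD) plus independent drift whose scale grows with the
    population's inbreeding-drift coefficient F_i ~ U(f_min, f_max).
    Populations with hs = 0 in the table are forced monomorphic.
    """
    rng = cfg.rng("genotypes")
    n_pops = len(pops)
    coords = pops[["x", "y"]].to_numpy(dtype=float)
    p0 = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    g = _gp_draws(coords, cfg.geno_spatial_sd, cfg.ibd_range, rng, cfg.n_loci).T  # (pops, loci)
    f_i = rng.uniform(cfg.f_min, cfg.f_max, size=n_pops)
    drift_sd = cfg.drift_scale * np.sqrt(2.0 * f_i / (1.0 - f_i))
    e = drift_sd[:, None] * rng.standard_normal((n_pops, cfg.n_loci))
    freq = expit(logit(p0)[None, :] + g + e)
    zero_div = pops["hs"].to_numpy(dtype=float) == 0.0
    individuals, populations, calls = [], [], []
    for i in range(n_pops):
        pid = pops["id"].iloc[i]
        n_ind = cfg.n_individuals_per_pop
        if zero_div[i]:
            fixed = (rng.uniform(size=cfg.n_loci) < freq[i]).astype(np.int16)
            block = np.tile(fixed, (n_ind, 1))
        else:
            block = (rng.uniform(size=(n_ind, cfg.n_loci)) < freq[i]).astype(np.int16)
        for j in range(n_ind):
            individuals.append(f"{pid}_i{j + 1}")
            populations.append(pid)
        calls.append(block)
    gm = GenotypeMatrix(
        individuals,
        np.array(populations, dtype=object),
        [f"snp{k + 1}" for k in range(cfg.n_loci)],
        np.vstack(calls),
    )
    truth = SimTruth(allele_freq=freq, params={"f": f_i.tolist(), "p0": p0.tolist()})
    return gm, truth


def simulate_pairwise(
    pops: pd.DataFrame,
    distances: dict[str, pd.DataFrame],
    cfg: SimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Pairwise table drawn from the MLPE generative model.

    The response is beta0 + sum_k beta_k x_k + a_i + a_j + eps over the
    z-scored distance predictors, with additive population effects
    a ~ N(0, sigma_pop^2) and residual eps ~ N(0, sigma_res^2).
    """
    rng = cfg.rng("pairwise")
    ids = pops["id"].tolist()
    n = len(ids)
    betas = {"ibd": cfg.beta_ibd, "ibe": cfg.beta_ibe, "ibr": cfg.beta_ibr}
    rows = []
    iu = np.triu_indices(n, k=1)
    cols: dict[str, np.ndarray] = {}
    for name, mat in distances.items():
        vals = mat.loc[ids, ids].to_numpy(dtype=float)[iu]
        cols[name] = (vals - vals.mean()) / vals.std(ddof=1)
    a = cfg.sigma_pop * rng.standard_normal(n)
    eps = cfg.sigma_res * rng.standard_normal(len(iu[0]))
    expected = np.full(len(iu[0]), cfg.beta0)
    for name, vals in cols.items():
        expected = expected + betas.get(name, 0.0) * vals
    y = expected + a[iu[0]] + a[iu[1]] + eps
    table = pd.DataFrame(
        {
            "pop_i": [ids[i] for i in iu[0]],
            "pop_j": [ids[j] for j in iu[1]],
            "loc_i": [ids[i] for i in iu[0]],
            "loc_j": [ids[j] for j in iu[1]],
            "fst": y,
        }
    )
    for name, vals in cols.items():
        table[name] = vals
    truth = SimTruth(
        pop_effects=a,
        expected_pairwise=expected,
        params={
            "beta0": cfg.beta0,
            **{f"beta_{k}": betas.get(k, 0.0) for k in distances},
            "sigma_pop": cfg.sigma_pop,
            "sigma_res": cfg.sigma_res,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixture_set(outdir, cfg: SimConfig) -> dict[str, str]:
    """Generate the full synthetic fixture set into a directory.

    Writes genotype CSV and VCF with a popmap, the population table, the
    environmental/suitability/mask rasters, a pairwise table built from the
    geographic distances, and a JSON file with the generating truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = simulate_landscape(cfg)
    env, suit, mask, land_truth = landscape
    pops, pop_truth = simulate_populations(landscape, cfg)
    gm, geno_truth = simulate_genotypes(pops, cfg)
    coords = pops[["x", "y"]].to_numpy(dtype=float)
    geo = pd.DataFrame(cdist(coords, coords), index=pops["id"], columns=pops["id"])
    pair, pair_truth = simulate_pairwise(pops, {"ibd": geo}, cfg)

    paths = {}
    paths["population_csv"] = str(outdir / "populations.csv")
    pops.to_csv(paths["population_csv"], index=False)
    paths["genotype_csv"] = str(outdir / "genotypes.csv")
    write_genotype_csv(gm, paths["genotype_csv"])
    paths["vcf"] = str(outdir / "genotypes.vcf")
    write_vcf(gm, paths["vcf"])
    paths["popmap"] = str(outdir / "popmap.csv")
    pd.DataFrame({"individual": gm.individuals, "population": gm.populations}).to_csv(
        paths["popmap"], index=False
    )
    for name, r in {**env, "suitability": suit, "mask": mask}.items():
        paths[name] = str(outdir / f"{name}.asc")
        write_ascii_grid(r, paths[name])
    paths["pairwise_csv"] = str(outdir / "pairwise.csv")
    pair.to_csv(paths["pairwise_csv"], index=False)
    truth = {
        "landscape": land_truth.params,
        "hurdle": pop_truth.params,
        "pairwise": pair_truth.params,
        "seed": cfg.seed,
    }
    paths["truth_json"] = str(outdir / "truth.json")
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
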