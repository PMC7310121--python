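"""Environmental ordination, cluster-membership classification and habitat
change summaries.

The ordination is a PCA of z-scored environmental variables followed by a
varimax rotation (with Kaiser normalization) of the leading components, the
standard way landscape studies turn many collinear climate/soil layers into a
few interpretable gradients.  Per-population scores on the rotated axes feed
the isolation-by-environment distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "EnvScores",
    "pca_varimax",
    "env_distances",
    "classify_populations",
    "habitat_change",
    "HABITAT_CATEGORIES",
]


@dataclass
class EnvScores:
    """Rotated PCA loadings, per-population scores and variance shares."""

    loadings: pd.DataFrame   # variables x components
    scores: pd.DataFrame     # populations x components
    varexp: pd.Series        # percent variance per rotated component


def pca_varimax(env: pd.DataFrame, n_components: int = 3) -> EnvScores:
    """PCA with varimax-rotated leading components.

    Variables are z-scored; the first ``n_components`` correlation-scale
    loading columns (eigenvector * sqrt(eigenvalue)) are varimax-rotated with
    Kaiser normalization; scores are recomputed for the rotated components by
    the regression method; the percent variance explained per component is
    recomputed after rotation from the sums of squared loadings.  The sign of
    each loading column is fixed so its largest-magnitude entry is positive.
    """
    X = env.to_numpy(dtype=float)
    n, p = X.shape
    if p < n_components:
        raise ValueError("fewer variables than requested components")
    if np.isnan(X).any():
        raise ValueError("missing values in the environmental table")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = env.columns[sd == 0].tolist()
        raise ValueError(f"constant environmental variable(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])

    # Kaiser normalization: rotate rows scaled to unit communality
    h = np.sqrt((lam**2).sum(axis=1))
    h[h == 0] = 1.0
    rotated_norm, _ = rotate_factors(lam / h[:, None], "varimax", tol=1e-10, max_tries=1000)
    lam_rot = rotated_norm * h[:, None]

    # deterministic column order (descending variance) and signs
    ss = (lam_rot**2).sum(axis=0)
    col_order = np.argsort(ss)[::-1]
    lam_rot = lam_rot[:, col_order]
    for k in range(n_components):
        col = lam_rot[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            lam_rot[:, k] = -col
    varexp = 100.0 * (lam_rot**2).sum(axis=0) / p

    # regression-method scores on the correlation matrix
    weights = np.linalg.solve(R, lam_rot)
    scores = Z @ weights

    comps = [f"PC{k + 1}" for k in range(n_components)]
    return EnvScores(
        loadings=pd.DataFrame(lam_rot, index=env.columns, columns=comps),
        scores=pd.DataFrame(scores, index=env.index, columns=comps),
        varexp=pd.Series(varexp, index=comps),
    )


def env_distances(scores: EnvScores, axes: str | int = "all") -> pd.DataFrame:
    """Pairwise environmental distance from rotated PC scores.

    ``axes='all'`` gives the Euclidean distance over every retained component
    (the IBE predictor); an integer k gives |score_i,k - score_j,k| for that
    single axis.
    """
    S = scores.scores
    if axes == "all":
        d = squareform(pdist(S.to_numpy()))
    else:
        k = int(axes)
        if not 1 <= k <= S.shape[1]:
            raise ValueError(f"axis {k} out of range 1..{S.shape[1]}")
        v = S.iloc[:, k - 1].to_numpy()
        d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=S.index, columns=S.index)


def classify_populations(q: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Assign populations to genetic clusters from a STRUCTURE-style Q matrix.

    ``q`` has one row per individual: a ``population`` column plus one
    membership column per cluster (rows summing to 1).  Per population the
    unweighted mean membership per cluster is computed; the population is
    assigned to every cluster whose mean is >= ``threshold`` and flagged
    homogeneous iff exactly one cluster qualifies.
    """
    if "population" not in q.columns:
        raise ValueError("Q table needs a 'population' column")
    clusters = [c for c in q.columns if c not in ("individual", "population")]
    vals = q[clusters].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("membership proportions must lie in [0, 1]")
    if np.abs(vals.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("membership rows must sum to 1")
    rows = []
    for pop, grp in q.groupby("population", sort=False):
        means = grp[clusters].mean(axis=0)
        assigned = [c for c in clusters if means[c] >= threshold]
        rows.append(
            {
                "population": pop,
                **{f"mean_{c}": means[c] for c in clusters},
                "assigned": ";".join(assigned),
                "n_clusters": len(assigned),
                "homogeneous": len(assigned) == 1,
            }
        )
    return pd.DataFrame(rows).set_index("population")


HABITAT_CATEGORIES = (
    "forest",
    "scrubland",
    "dehesa",
    "bare_soil",
    "crop",
    "urban",
    "infrastructure",
    "water",
)

GRID_SQUARES = 80  # fixed 100-m squares in the 500-m census circle


def habitat_change(snapshots: pd.DataFrame) -> pd.DataFrame:
    """Mean percent change per habitat type across orthophoto snapshots.

    ``snapshots`` is long format with columns population, year, square_id,
    category over the fixed 80-square grid.  For each population and habitat
    the percent of squares occupied is computed per year; the output is the
    mean, over consecutive year intervals, of the change in that percentage
    (percentage points of the 80-square grid).
    """
    needed = {"population", "year", "square_id", "category"}
    if not needed.issubset(snapshots.columns):
        raise ValueError(f"snapshot table needs columns {sorted(needed)}")
    bad = set(snapshots["category"]) - set(HABITAT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown habitat categories: {sorted(bad)}")
    rows = []
    for pop, grp in snapshots.groupby("population", sort=False):
        years = sorted(grp["year"].unique())
        if len(years) < 2:
            raise ValueError(f"population {pop} needs >=2 snapshots")
        pct = {}
        for year in years:
            snap = grp[grp["year"] == year]
            if len(snap) != GRID_SQUARES:
                raise ValueError(
                    f"population {pop} year {year}: {len(snap)} squares, expected {GRID_SQUARES}"
                )
            frac = snap["category"].value_counts()
            pct[year] = {
                h: 100.0 * frac.get(h, 0) / GRID_SQUARES for h in HABITAT_CATEGORIES
            }
        for h in HABITAT_CATEGORIES:
            deltas = [pct[y2][h] - pct[y1][h] for y1, y2 in zip(years, years[1:])]
            rows.append((pop, h, float(np.mean(deltas))))
    return pd.DataFrame(rows, columns=["population", "habitat", "mean_change"]).pivot(
        index="population", columns="habitat", values="mean_change"
    )
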