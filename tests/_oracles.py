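"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and dense linear
algebra, independent of the package's own computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def wc_theta_oracle(calls: np.ndarray, populations: np.ndarray, pop_a, pop_b) -> float:
    """Two-population multilocus Weir-Cockerham theta from first principles.

    Materializes the full per-locus ANOVA tables (MSP, MSG, n_c) allele by
    allele with explicit Python loops.
    """
    sum_a = 0.0
    sum_ab = 0.0
    n_alleles = int(calls.max()) + 1 if (calls >= 0).any() else 1
    for locus in range(calls.shape[1]):
        col_a = [c for c, p in zip(calls[:, locus], populations) if p == pop_a and c != MISSING]
        col_b = [c for c, p in zip(calls[:, locus], populations) if p == pop_b and c != MISSING]
        n1, n2 = len(col_a), len(col_b)
        if n1 < 1 or n2 < 1 or (n1 - 1) + (n2 - 1) <= 0:
            continue
        for allele in range(n_alleles):
            p1 = sum(1 for c in col_a if c == allele) / n1
            p2 = sum(1 for c in col_b if c == allele) / n2
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (2 - 1)
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
            nc = ((n1 + n2) - (n1**2 + n2**2) / (n1 + n2)) / (2 - 1)
            a = (msp - msg) / nc
            sum_a += a
            sum_ab += a + msg
    return sum_a / sum_ab if sum_ab != 0.0 else np.nan


def nmlpe_loglik_oracle(
    y: np.ndarray,
    X: np.ndarray,
    pairs: list[tuple[str, str]],
    locs: dict[str, str],
    beta: np.ndarray,
    sigma_g2: float,
    sigma_c2: float,
    sigma_e2: float,
) -> float:
    """Gaussian log likelihood from the explicitly materialized covariance."""
    pops = sorted({p for ab in pairs for p in ab})
    loc_levels = sorted({locs[p] for p in pops})
    n = len(pairs)
    Zc = np.zeros((n, len(pops)))
    Zg = np.zeros((n, len(loc_levels)))
    for k, (a, b) in enumerate(pairs):
        Zc[k, pops.index(a)] += 1
        Zc[k, pops.index(b)] += 1
        Zg[k, loc_levels.index(locs[a])] += 1
        Zg[k, loc_levels.index(locs[b])] += 1
    V = sigma_g2 * Zg @ Zg.T + sigma_c2 * Zc @ Zc.T + sigma_e2 * np.eye(n)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))


def effective_resistance_oracle(lap_dense: np.ndarray, a: int, b: int) -> float:
    """R_ab = L+_aa + L+_bb - 2 L+_ab from the dense pseudo-inverse.

    For a connected graph the pseudo-inverse is computed by the deflation
    identity L+ = (L + J/n)^-1 - J/n, which avoids SVD cutoff choices.
    """
    n = lap_dense.shape[0]
    J = np.ones((n, n)) / n
    lplus = np.linalg.inv(lap_dense + J) - J
    return lplus[a, a] + lplus[b, b] - 2.0 * lplus[a, b]


def varimax_oracle(A: np.ndarray, max_iter: int = 2000, tol: float = 1e-12) -> np.ndarray:
    """Classic pairwise-free SVD varimax iteration (no normalization)."""
    p, k = A.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return A @ R


def align_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Permute and sign-flip columns of B to best match A (greedy)."""
    B = B.copy()
    k = A.shape[1]
    out = np.empty_like(A)
    used = set()
    for i in range(k):
        best, best_j, best_s = -np.inf, None, 1.0
        for j in range(k):
            if j in used:
                continue
            c = float(A[:, i] @ B[:, j])
            if abs(c) > best:
                best, best_j, best_s = abs(c), j, np.sign(c) or 1.0
        used.add(best_j)
        out[:, i] = best_s * B[:, best_j]
    return out


def pca_varimax_oracle(env: np.ndarray, n_components: int) -> np.ndarray:
    """Independent z-score -> eigen -> Kaiser-normalized varimax pipeline."""
    Z = (env - env.mean(axis=0)) / env.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    lam = eigvec[:, order[:n_components]] * np.sqrt(eigval[order[:n_components]])
    h = np.sqrt((lam**2).sum(axis=1))
    h[h == 0] = 1.0
    rot = varimax_oracle(lam / h[:, None]) * h[:, None]
    return rot


def random_genotype_matrix(rng: np.random.Generator, n_pops=None, n_loci=None):
    """Random small haploid matrix with missing calls, for oracle sweeps."""
    from landgen import GenotypeMatrix

    n_pops = n_pops or rng.integers(2, 6)
    n_loci = n_loci or rng.integers(1, 11)
    sizes = rng.integers(2, 7, size=n_pops)
    inds, pops, blocks = [], [], []
    for p in range(n_pops):
        freq = rng.uniform(0.05, 0.95, size=n_loci)
        block = (rng.uniform(size=(sizes[p], n_loci)) < freq).astype(np.int16)
        miss = rng.uniform(size=block.shape) < 0.1
        block[miss] = MISSING
        blocks.append(block)
        for j in range(sizes[p]):
            inds.append(f"p{p}_i{j}")
            pops.append(f"pop{p}")
    return GenotypeMatrix(
        inds, np.array(pops, dtype=object), [f"L{k}" for k in range(n_loci)], np.vstack(blocks)
    )
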