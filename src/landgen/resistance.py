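"""Circuit-theory resistance distances over raster landscapes.

Pixels of a resistance raster become graph nodes; neighboring data pixels are
joined by resistors whose resistance is the mean of the two pixel values
(scaled by sqrt(2) for diagonal moves).  The effective resistance between two
focal pixels — the voltage needed to push a unit current from one to the
other — is the isolation-by-resistance distance: low when many
low-resistance paths connect the pair, high when the landscape funnels
current through costly corridors.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .raster import Raster

__all__ = [
    "suitability_to_resistance",
    "uniform_resistance",
    "build_resistance_graph",
    "effective_resistance",
    "resistance_distances",
]

RESISTANCE_FLOOR = 1e-6  # fully suitable pixels would otherwise short to 0


def suitability_to_resistance(s: Raster, floor: float = RESISTANCE_FLOOR) -> Raster:
    """Resistance = 1 - habitat suitability, floored to keep conductance finite."""
    vals = s.values
    bad = (~np.isnan(vals)) & ((vals < 0) | (vals > 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"suitability outside [0, 1] at pixel (row={r}, col={c})")
    out = 1.0 - vals
    out = np.where(out < floor, floor, out)
    return s.like(out)


def uniform_resistance(mask: Raster, value: float = 0.5) -> Raster:
    """Constant resistance on land, nodata elsewhere (sea = absolute barrier)."""
    out = np.where(mask.data_mask, value, np.nan)
    return mask.like(out)


def build_resistance_graph(
    r: Raster, neighborhood: int = 8
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Graph Laplacian over data pixels.

    Returns ``(laplacian, node_index)`` where ``node_index`` maps (row, col)
    to the node id (-1 for nodata).  Edge conductance between neighboring
    pixels a, b is ``1 / (scale * (r_a + r_b) / 2)`` with scale 1 for rook
    moves and sqrt(2) for diagonal moves (average-resistance connection).
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    vals = r.values
    mask = r.data_mask
    node_index = np.full(vals.shape, -1, dtype=np.int64)
    node_index[mask] = np.arange(mask.sum())
    n = int(mask.sum())
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    cc: list[np.ndarray] = []
    nrows, ncols = vals.shape
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = mask[r0, c0] & mask[r1, c1]
        if not ok.any():
            continue
        a = node_index[r0, c0][ok]
        b = node_index[r1, c1][ok]
        res = scale * 0.5 * (vals[r0, c0][ok] + vals[r1, c1][ok])
        cond = 1.0 / res
        ii.append(a)
        jj.append(b)
        cc.append(cond)
    if ii:
        i = np.concatenate(ii)
        j = np.concatenate(jj)
        c = np.concatenate(cc)
        adj = sp.coo_matrix((np.r_[c, c], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    else:
        adj = sp.csr_matrix((n, n))
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    return lap.tocsr(), node_index


def _focal_nodes(r: Raster, points: pd.DataFrame, node_index: np.ndarray) -> np.ndarray:
    nodes = np.empty(len(points), dtype=np.int64)
    for k, (_, row) in enumerate(points.iterrows()):
        rr, cc = r.cell_of(float(row["x"]), float(row["y"]))
        node = node_index[rr, cc]
        if node < 0:
            raise ValueError(f"point ({row['x']}, {row['y']}) falls on a nodata pixel")
        nodes[k] = node
    return nodes


def _check_connected(lap: sp.csr_matrix, focal: np.ndarray) -> None:
    n_comp, labels = sp.csgraph.connected_components(lap, directed=False)
    if n_comp > 1 and len(set(labels[focal])) > 1:
        parts = {int(l): int((labels[focal] == l).sum()) for l in set(labels[focal])}
        raise ValueError(f"focal nodes fall in disconnected components: {parts}")


def effective_resistance(
    r: Raster,
    points: pd.DataFrame,
    neighborhood: int = 8,
    dense_threshold: int = 2500,
    cg_tol: float = 1e-10,
) -> pd.DataFrame:
    """Pairwise effective resistance between focal points on a raster.

    ``points`` needs columns id, x, y in raster coordinates; each point is
    snapped to its containing pixel center.  Small graphs (< ``dense_threshold``
    nodes) use the dense Laplacian pseudo-inverse, R_ij = L+_ii + L+_jj -
    2 L+_ij; larger graphs solve one reduced linear system per pair by
    conjugate gradient with a pinned reference node.
    """
    lap, node_index = build_resistance_graph(r, neighborhood)
    focal = _focal_nodes(r, points, node_index)
    _check_connected(lap, focal)
    n = lap.shape[0]
    ids = points["id"].tolist()
    m = len(ids)
    out = np.zeros((m, m))
    if n <= dense_threshold:
        import scipy.linalg as sla

        lplus = sla.pinvh(lap.toarray())
        for i, j in itertools.combinations(range(m), 2):
            a, b = focal[i], focal[j]
            rij = 0.0 if a == b else lplus[a, a] + lplus[b, b] - 2.0 * lplus[a, b]
            out[i, j] = out[j, i] = rij
    else:
        ref = int(focal[0])
        keep = np.ones(n, dtype=bool)
        keep[ref] = False
        lred = lap[keep][:, keep].tocsc()
        remap = np.cumsum(keep) - 1
        ml = spla.spilu(lred.tocsc(), drop_tol=1e-5)
        precond = spla.LinearOperator(lred.shape, ml.solve)
        for i, j in itertools.combinations(range(m), 2):
            a, b = int(focal[i]), int(focal[j])
            if a == b:
                continue
            rhs = np.zeros(n)
            rhs[a] += 1.0
            rhs[b] -= 1.0
            v, info = spla.cg(lred, rhs[keep], rtol=cg_tol, atol=0.0, M=precond)
            if info != 0:
                raise RuntimeError(f"conjugate gradient failed for pair ({ids[i]}, {ids[j]})")
            va = v[remap[a]] if a != ref else 0.0
            vb = v[remap[b]] if b != ref else 0.0
            out[i, j] = out[j, i] = va - vb
    return pd.DataFrame(out, index=ids, columns=ids)


def resistance_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (id_i, id_j, resistance) view of a symmetric matrix."""
    ids = list(matrix.index)
    rows = [
        (ids[i], ids[j], matrix.iat[i, j])
        for i, j in itertools.combinations(range(len(ids)), 2)
    ]
    return pd.DataFrame(rows, columns=["id_i", "id_j", "resistance"])
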