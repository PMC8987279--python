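"""Population structure: IBS distances, neighbor-joining tree, GRM PCA.

IBS similarity between two diploids is the mean, over pairwise co-genotyped
sites, of (shared alleles)/2 (0, 0.5 or 1 per site); distance is one minus
similarity. The tree is built by Saitou–Nei neighbor joining on that distance
matrix and returned as an skbio TreeNode (lossless Newick round trip). PCA
follows the GCTA convention: the genomic relationship matrix
G_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)) over
polymorphic sites (alt-allele dosages x in {0,1,2}, missing dosages imputed
to 2 p_k), eigendecomposed, with coordinates scaled by sqrt(eigenvalue) and
variance fractions eigenvalue / trace.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import HaplotypePanel


def _dosage_matrix(panel: HaplotypePanel) -> np.ndarray:
    """(n_samples, n_sites) alt-allele dosage matrix, NaN for missing."""
    blocks = []
    for chrom in sorted(panel.chroms):
        gt = panel.chroms[chrom].gt.astype(np.float64)  # (m, n, 2)
        called = (gt >= 0).all(axis=2)
        dos = gt.sum(axis=2)
        dos[~called] = np.nan
        blocks.append(dos.T)
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((panel.n_samples, 0))


# --------------------------------------------------------------------- IBS --

def ibs_distance(panel: HaplotypePanel) -> tuple[list[str], np.ndarray]:
    """Pairwise IBS distance matrix (symmetric, zero diagonal)."""
    dos = _dosage_matrix(panel)
    n = panel.n_samples
    D = np.zeros((n, n))
    called = np.isfinite(dos)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise ValueError(
                    f"samples {panel.samples[i]!r} and {panel.samples[j]!r} "
                    "share no co-genotyped site"
                )
            sim = 1.0 - np.abs(dos[i, both] - dos[j, both]).sum() / (2.0 * n_sites)
            D[i, j] = D[j, i] = 1.0 - sim
    return list(panel.samples), D


def breed_distance(
    panel: HaplotypePanel, ids: list[str], D: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Breed-level matrix: mean of inter-breed pairwise individual distances."""
    pops = panel.populations()
    idx = {p: [k for k, s in enumerate(ids) if panel.pop_of[s] == p] for p in pops}
    B = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            block = D[np.ix_(idx[pops[a]], idx[pops[b]])]
            B[a, b] = B[b, a] = block.mean()
    return pops, B


# ---------------------------------------------------------------------- NJ --

def nj_tree(ids: list[str], D: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Pair selection minimizes Q(i,j) = (n-2) d(i,j) - r_i - r_j with a
    deterministic lexicographic tie-break on the pair's labels. Negative
    branch lengths are clamped to 0 with the deficit transferred to the
    sister branch. The returned tree is unrooted (trifurcating root).
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = np.asarray(D, dtype=np.float64)
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")

    nodes = [TreeNode(name=name) for name in ids]
    labels = list(ids)  # tie-break labels, one per active node
    dist = D.copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = dist.sum(axis=1)
        Q = (k - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                if Q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        dij = dist[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        new_d = (dist[i, :] + dist[j, :] - dij) / 2.0
        keep = [x for x in range(k) if x not in (i, j)]
        dist = np.vstack([dist[keep][:, keep],
                          new_d[keep][None, :]])
        dist = np.hstack([dist, np.append(new_d[keep], 0.0)[:, None]])
        new_label = min(labels[i], labels[j])
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [new_label]

    # terminal 3-node star: closed-form branch lengths
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    lens = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lens):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def tree_to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


# --------------------------------------------------------------------- PCA --

def grm(panel: HaplotypePanel) -> tuple[list[str], np.ndarray]:
    """GCTA-style genomic relationship matrix over polymorphic sites."""
    dos = _dosage_matrix(panel)
    p = np.nanmean(dos, axis=0) / 2.0
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("no polymorphic sites usable for the GRM")
    dos = dos[:, usable]
    p = p[usable]
    dos = np.where(np.isfinite(dos), dos, 2.0 * p)  # mean imputation
    z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = z @ z.T / z.shape[1]
    return list(panel.samples), G


def grm_pca(
    panel: HaplotypePanel, n_pcs: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top principal components of the GRM.

    Returns a frame (sample, pop, PC1..PCk) with coordinates scaled by
    sqrt(eigenvalue), plus the variance fraction of every eigenvalue
    (eigenvalue / trace), in non-increasing order.
    """
    ids, G = grm(panel)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    varfrac = vals / vals.sum()
    coords = vecs[:, :n_pcs] * np.sqrt(np.clip(vals[:n_pcs], 0.0, None))
    out = pd.DataFrame({"sample": ids, "pop": [panel.pop_of[s] for s in ids]})
    for k in range(n_pcs):
        out[f"PC{k + 1}"] = coords[:, k]
    return out, varfrac
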