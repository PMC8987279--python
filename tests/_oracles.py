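"""Independent brute-force oracles used by the tests.

Everything here is deliberately written the slow, literal way — full-prefix
hashing for EHH, scalar loops for the variance components, quadratic joins —
so the fast implementations are checked against an independent code path.
"""

import numpy as np


# ------------------------------------------------------------- EHH / XP-EHH --

def ehh_prefix_oracle(haps, positions, core_index, direction):
    """EHH at every extension by hashing the full core..j allele prefix.

    Returns (positions, ehh values) including the core point, mirroring one
    arm of the decay curve with no gap rule.
    """
    haps = np.asarray(haps)
    n, m = haps.shape
    npairs = n * (n - 1) / 2
    idx = [core_index]
    j = core_index + direction
    while 0 <= j < m:
        idx.append(j)
        j += direction
    out_pos, out_ehh = [], []
    for k in range(1, len(idx) + 1):
        prefixes = {}
        for h in range(n):
            key = tuple(haps[h, i] for i in idx[:k])
            prefixes[key] = prefixes.get(key, 0) + 1
        pairs = sum(c * (c - 1) / 2 for c in prefixes.values())
        out_pos.append(int(positions[idx[k - 1]]))
        out_ehh.append(pairs / npairs)
    return np.array(out_pos), np.array(out_ehh)


def trapezoid_ihh_oracle(arm_pos, arm_ehh, cutoff):
    """Arm integral over |pos - core| with the include-first-sub-cutoff rule."""
    if arm_ehh[0] < cutoff:
        return 0.0
    core = arm_pos[0]
    total = 0.0
    for k in range(1, len(arm_ehh)):
        x0, x1 = abs(arm_pos[k - 1] - core), abs(arm_pos[k] - core)
        total += (arm_ehh[k - 1] + arm_ehh[k]) / 2 * (x1 - x0)
        if arm_ehh[k] < cutoff:
            break
    return total


def xpehh_oracle(hapsA, hapsB, positions, core_index, cutoff=0.05):
    """Raw XP-EHH recomputed end to end from the prefix-hash oracle."""
    ihh = {}
    for name, haps in (("A", hapsA), ("B", hapsB)):
        total = 0.0
        for direction in (-1, 1):
            p, e = ehh_prefix_oracle(haps, positions, core_index, direction)
            total += trapezoid_ihh_oracle(p, e, cutoff)
        ihh[name] = total
    if ihh["A"] == 0.0 or ihh["B"] == 0.0:
        return float("nan")
    return float(np.log(ihh["A"] / ihh["B"]))


# ------------------------------------------------------------------- WC84 ---

def wc84_scalar(ns, ps, hs):
    """Literal Weir & Cockerham (1984) a/b/c for r populations, one site.

    ``ns``: diploid sample sizes; ``ps``: alt frequencies; ``hs``: observed
    heterozygote *proportions*. Scalar arithmetic, general r.
    """
    r = len(ns)
    ns = [float(x) for x in ns]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


# ----------------------------------------------------------------- trees ----

def random_additive_tree(n_taxa, rng):
    """Random binary tree (newick string) with uniform branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    order = list(rng.permutation(labels))

    def build(subset):
        if len(subset) == 1:
            return f"{subset[0]}:{rng.uniform(0.1, 2.0):.6f}"
        k = int(rng.integers(1, len(subset)))
        return (
            f"({build(subset[:k])},{build(subset[k:])})"
            f":{rng.uniform(0.1, 2.0):.6f}"
        )

    k = int(rng.integers(1, n_taxa))
    return f"({build(order[:k])},{build(order[k:])});", labels


def tree_splits(tree, taxa):
    """Non-trivial bipartitions of a tree, normalized for unrooted comparison."""
    all_taxa = frozenset(taxa)
    ref = min(taxa)
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        if ref in side:
            side = all_taxa - side
        out.add(side)
    return out


def rf_distance(tree_a, tree_b, taxa):
    sa, sb = tree_splits(tree_a, taxa), tree_splits(tree_b, taxa)
    return len(sa ^ sb)


# ------------------------------------------------------------- intervals ----

def allpairs_overlaps(regions, features):
    """Quadratic all-pairs interval join: {region index: [feature index]}."""
    out = {}
    for i, r in enumerate(regions):
        hits = []
        for j, f in enumerate(features):
            if r.chrom == f.chrom and r.start < f.end and f.start < r.end:
                hits.append(j)
        out[i] = hits
    return out
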