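"""Population distance trees.

Nei's (1972) standard genetic distance D = -ln I between population
allele-frequency vectors (ratio-of-sums over loci, both alleles of each
biallelic SNP), neighbor-joining with the Studier–Keppler Q criterion,
a locus-resampling bootstrap with majority-rule consensus (optional greedy
completion to a fully resolved tree), and Newick round-trip I/O.

Trees are :class:`skbio.TreeNode` objects; bootstrap supports live both in
``node.support`` (float, percent) and the internal node name.
"""

from __future__ import annotations

import io as _io
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotypes import GenotypeMatrix, freq_matrix

logger = logging.getLogger(__name__)

INF_D = np.inf


# ---------------------------------------------------------------------------
# Nei's standard distance
# ---------------------------------------------------------------------------

def nei_distance(freqA: np.ndarray, freqB: np.ndarray) -> float:
    """Nei (1972) D = -ln I from two allele2-frequency vectors.

    I = sum_l sum_u x_lu y_lu / sqrt(sum x^2 · sum y^2) with both alleles
    of each SNP entering the sums (ratio-of-sums over loci).  Loci
    undefined (NaN) in either population are excluded.  I <= 0 yields the
    +inf sentinel.
    """
    x = np.asarray(freqA, float)
    y = np.asarray(freqB, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return INF_D
    jxy = (x * y + (1 - x) * (1 - y)).sum()
    jx = (x**2 + (1 - x) ** 2).sum()
    jy = (y**2 + (1 - y) ** 2).sum()
    I = jxy / np.sqrt(jx * jy)
    if I <= 0:
        logger.warning("gene identity I <= 0; returning infinite distance")
        return INF_D
    return float(-np.log(min(I, 1.0)))


def nei_distance_matrix(freqs) -> pd.DataFrame:
    """All-pairs Nei D from per-population frequencies.

    ``freqs`` is either the tidy frame from
    :func:`breeddiv.genotypes.allele_frequencies` (by_population=True) or a
    (populations × loci) DataFrame of allele2 frequencies.
    """
    if isinstance(freqs, pd.DataFrame) and "population" in freqs.columns:
        P = freqs.pivot(index="population", columns="locus", values="p")
    else:
        P = pd.DataFrame(freqs)
    pops = list(P.index)
    k = len(pops)
    D = np.zeros((k, k))
    M = P.to_numpy(float)
    for i, j in combinations(range(k), 2):
        D[i, j] = D[j, i] = nei_distance(M[i], M[j])
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q_ij = (r-2) d_ij - R_i - R_j; ties pick the lexicographically
    smallest label pair (clusters keyed by their smallest leaf name).
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge.  Returns an unrooted tree (trifurcating root).
    """
    labels = list(D.index)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    M = np.asarray(D, float)
    if not np.all(np.isfinite(M)):
        raise ValueError(
            "distance matrix contains non-finite entries; handle infinite-"
            "distance sentinels upstream (e.g. drop or cap the pair)"
        )
    if not np.allclose(M, M.T):
        raise ValueError("distance matrix must be symmetric")

    nodes = {lab: TreeNode(name=lab) for lab in labels}
    keys = {lab: lab for lab in labels}  # cluster key = smallest leaf name
    active = list(labels)
    d = {frozenset((a, b)): M[i, j] for (i, a) in enumerate(labels) for (j, b) in enumerate(labels) if i < j}

    counter = 0
    while len(active) > 3:
        r = len(active)
        R = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for a, b in combinations(active, 2):
            q = (r - 2) * d[frozenset((a, b))] - R[a] - R[b]
            pair_key = tuple(sorted((keys[a], keys[b])))
            if best is None or (q, pair_key) < best[:2]:
                best = (q, pair_key, a, b)
        _, _, a, b = best
        dij = d[frozenset((a, b))]
        va = dij / 2 + (R[a] - R[b]) / (2 * (r - 2))
        vb = dij - va
        if va < 0:
            vb += va
            va = 0.0
            logger.info("clamped negative branch at %s", a)
        if vb < 0:
            va += vb
            vb = 0.0
            logger.info("clamped negative branch at %s", b)
        counter += 1
        u = f"_nj{counter}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = float(va), float(vb)
        parent = TreeNode(name=None, children=[na, nb])
        nodes[u] = parent
        keys[u] = min(keys[a], keys[b])
        for cidx in active:
            if cidx in (a, b):
                continue
            d[frozenset((u, cidx))] = (
                d[frozenset((a, cidx))] + d[frozenset((b, cidx))] - dij
            ) / 2
        active = [x for x in active if x not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: keys[x])
    dab, dac, dbc = d[frozenset((a, b))], d[frozenset((a, c))], d[frozenset((b, c))]
    va = max((dab + dac - dbc) / 2, 0.0)
    vb = max((dab + dbc - dac) / 2, 0.0)
    vc = max((dac + dbc - dab) / 2, 0.0)
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length, nb.length, nc.length = float(va), float(vb), float(vc)
    root = TreeNode(name=None, children=[na, nb, nc])
    return root


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, consensus
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as leaf sets not containing the reference
    (alphabetically first) leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if ref in below:
            below = frozenset(leaves - below)
        if 1 < len(below) < len(leaves) - 1:
            out.add(below)
    return out


def _compatible(clade: frozenset, accepted: list[frozenset]) -> bool:
    for other in accepted:
        inter = clade & other
        if inter and inter != clade and inter != other:
            return False
    return True


def _tree_from_clades(leaves: list[str], clades: list[tuple[frozenset, float]]) -> TreeNode:
    """Build a tree from mutually compatible clades (w.r.t. the reference
    leaf); supports attach to the clade's node."""
    full = frozenset(leaves)
    ordered = sorted(clades, key=lambda cs: -len(cs[0]))
    root = TreeNode(name=None)
    node_of: dict[frozenset, TreeNode] = {full: root}
    placed: list[frozenset] = [full]
    for clade, supp in ordered:
        parent = min((c for c in placed if clade < c), key=len)
        node = TreeNode(name=None)
        node.support = float(supp)
        node_of[parent].append(node)
        node_of[clade] = node
        placed.append(clade)
    for leaf in sorted(leaves):
        containing = [c for c in placed if leaf in c]
        parent = min(containing, key=len)
        node_of[parent].append(TreeNode(name=leaf))
    return root


def majority_rule_consensus(
    replicate_trees: list[TreeNode], greedy: bool = True
) -> TreeNode:
    """Majority-rule (>50%) consensus; with ``greedy`` the remaining
    bipartitions are added in frequency order while compatible."""
    n = len(replicate_trees)
    leaves = sorted(t.name for t in replicate_trees[0].tips())
    counts: dict[frozenset, int] = {}
    for t in replicate_trees:
        for bp in _bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    )
    accepted: list[tuple[frozenset, float]] = []
    for clade, cnt in ranked:
        freq = 100.0 * cnt / n
        if freq > 50.0:
            accepted.append((clade, freq))
        elif greedy and _compatible(clade, [c for c, _ in accepted]):
            accepted.append((clade, freq))
    return _tree_from_clades(leaves, accepted)


def bootstrap_consensus(
    source,
    n_boot: int = 1000,
    seed: int = 0,
    greedy: bool = True,
    snp_set=None,
) -> TreeNode:
    """Locus-resampling bootstrap of the Nei-D neighbor-joining tree.

    ``source`` is a GenotypeMatrix (frequencies computed per population) or
    a (populations × loci) frequency DataFrame.  Each replicate resamples
    loci (columns) with replacement, recomputes Nei D and NJ; the result is
    the majority-rule consensus with supports = bipartition frequency × 100.
    """
    if isinstance(source, GenotypeMatrix):
        sub = source if snp_set is None else source.subset(locus_ids=list(snp_set.locus_ids))
        P, _, pops = freq_matrix(sub)
        P = pd.DataFrame(P, index=pops)
    else:
        P = pd.DataFrame(source)
    rng = np.random.default_rng(seed)
    L = P.shape[1]
    trees = []
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        Db = nei_distance_matrix(P.iloc[:, cols])
        trees.append(neighbor_joining(Db))
    return majority_rule_consensus(trees, greedy=greedy)


def bipartition_support(tree: TreeNode, group: set[str]) -> float:
    """Support (percent) of the bipartition splitting ``group`` from the
    rest, or 0 if the consensus does not contain it."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    target = frozenset(group) if ref not in group else frozenset(leaves - set(group))
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if ref in below:
            below = frozenset(leaves - below)
        if below == target:
            return getattr(node, "support", np.nan)
    return 0.0


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path) -> None:
    """Write Newick; bootstrap supports become internal node labels
    (skbio serialises the ``support`` attribute)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    """Read Newick; numeric internal labels are interpreted as supports."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=True):
        if node.name is not None and getattr(node, "support", None) is None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return tree


def to_newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
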