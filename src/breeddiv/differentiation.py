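"""Among-population differentiation: Weir–Cockerham theta and AMOVA.

Pairwise and global FST use the Weir & Cockerham (1984) variance-component
estimator theta-hat, combined over loci as the ratio of summed ``a``
components to summed ``a + b + c`` — the standard ratio-of-sums rule that
keeps the estimator well behaved at loci of low information.  Significance
comes from permuting individuals between populations.

AMOVA is the three-level nested analysis of molecular variance on allele
copies with the 0/1 (same/different allele) distance: variance is
partitioned among populations, among individuals within populations, and
within individuals, with unequal-sample-size coefficients and permutation
p-values per level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(calls_by_pop: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC (1984) a, b, c for r populations given dosage blocks.

    Each block is an n_i × L int8 array with MISSING = -1.  Loci where
    fewer than two populations have data contribute NaN components.
    """
    r_all = len(calls_by_pop)
    L = calls_by_pop[0].shape[1]
    n_i = np.empty((r_all, L))
    p_i = np.empty((r_all, L))
    h_i = np.empty((r_all, L))
    for k, calls in enumerate(calls_by_pop):
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h_i[k] = (calls == 1).sum(axis=0) / np.maximum(n, 1)
        n_i[k] = n
    has = n_i > 0
    r = has.sum(axis=0).astype(float)
    usable = r >= 2
    n_i = np.where(has, n_i, 0.0)
    p_i = np.where(has, p_i, 0.0)
    h_i = np.where(has, h_i, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.sum(axis=0) / np.maximum(r, 1)
        n_c = (r * nbar - (n_i**2).sum(axis=0) / np.maximum(r * nbar, 1)) / np.maximum(r - 1, 1)
        pbar = (n_i * p_i).sum(axis=0) / np.maximum(r * nbar, 1)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / np.maximum((r - 1) * nbar, 1)
        hbar = (n_i * h_i).sum(axis=0) / np.maximum(r * nbar, 1)
        a = (nbar / np.maximum(n_c, 1e-300)) * (
            s2
            - (1 / np.maximum(nbar - 1, 1e-300))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
    c = hbar / 2
    bad = ~usable | (nbar <= 1) | (n_c <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _theta_from_blocks(blocks: list[np.ndarray]) -> float:
    a, b, c = _wc_components(blocks)
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0 or not ok.any():
        return np.nan
    return float(a[ok].sum() / denom)


def _pop_blocks(G: GenotypeMatrix, pops: list[str], snp_set=None) -> list[np.ndarray]:
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    return [sub.calls[sub.pop_mask(p)] for p in pops]


def pairwise_fst(G: GenotypeMatrix, popA: str, popB: str, snp_set=None) -> float:
    """Two-population Weir–Cockerham theta-hat (ratio of sums over loci).

    Negative estimates are reported as computed, not clamped.
    """
    blocks = _pop_blocks(G, [popA, popB], snp_set)
    if any(b.shape[0] < 2 for b in blocks):
        raise ValueError("both populations need >= 2 samples")
    theta = _theta_from_blocks(blocks)
    if np.isnan(theta):
        logger.warning("theta undefined for %s vs %s (no shared polymorphism)", popA, popB)
    return theta


def global_fst(G: GenotypeMatrix, snp_set=None, populations=None) -> float:
    """r-population Weir–Cockerham theta-hat."""
    pops = populations or G.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    return _theta_from_blocks(_pop_blocks(G, pops, snp_set))


def fst_permutation_test(
    G: GenotypeMatrix,
    popA: str,
    popB: str,
    snp_set=None,
    n_perm: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for pairwise theta.

    The null reassigns individuals to the two populations at random,
    keeping sizes; p = (1 + #{theta_perm >= theta_obs})/(1 + n_perm).
    Returns (theta_obs, p).
    """
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    mA, mB = sub.pop_mask(popA), sub.pop_mask(popB)
    callsA, callsB = sub.calls[mA], sub.calls[mB]
    theta_obs = _theta_from_blocks([callsA, callsB])
    pool = np.vstack([callsA, callsB])
    nA = callsA.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(pool.shape[0])
        t = _theta_from_blocks([pool[idx[:nA]], pool[idx[nA:]]])
        if not np.isnan(t) and t >= theta_obs:
            count += 1
    return theta_obs, (1 + count) / (1 + n_perm)


def fst_matrix(
    G: GenotypeMatrix,
    snp_set=None,
    n_perm: int = 0,
    seed: int = 0,
    min_pop_size: int = 8,
    reynolds_linearized: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise theta for all population pairs of size >= ``min_pop_size``.

    Returns (theta matrix, p-value matrix or None).  With
    ``reynolds_linearized`` the export is -ln(1 - theta) (display option;
    theta < 0 is clamped to 0 there).
    """
    pops = [p for p in G.populations if G.pop_mask(p).sum() >= min_pop_size]
    excluded = [p for p in G.populations if p not in pops]
    if excluded:
        logger.info("fst_matrix: excluded small populations %s", excluded)
    k = len(pops)
    vals = np.zeros((k, k))
    pvals = np.zeros((k, k)) if n_perm else None
    for i in range(k):
        for j in range(i + 1, k):
            if n_perm:
                t, p = fst_permutation_test(
                    G, pops[i], pops[j], snp_set, n_perm=n_perm,
                    seed=seed + 1000003 * i + j,
                )
                pvals[i, j] = pvals[j, i] = p
            else:
                t = pairwise_fst(G, pops[i], pops[j], snp_set)
            if reynolds_linearized:
                t = -np.log(1 - max(t, 0.0))
            vals[i, j] = vals[j, i] = t
    theta_df = pd.DataFrame(vals, index=pops, columns=pops)
    p_df = pd.DataFrame(pvals, index=pops, columns=pops) if n_perm else None
    return theta_df, p_df


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma2_among_pops: float
    sigma2_among_ind_within: float
    sigma2_within_ind: float
    pct_among_pops: float
    pct_among_ind: float
    pct_within_ind: float
    phi_ST: float
    phi_IS: float
    phi_IT: float
    p_among: float = np.nan
    p_within_pops: float = np.nan
    p_within_ind: float = np.nan

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _amova_ss(calls_by_pop: list[np.ndarray]):
    """Summed sums of squares and df over loci for the 3-level design.

    Distance between allele copies is 0/1; for a group of k copies the SS
    is (#allele2 copies × #allele1 copies)/k.  Individuals missing at a
    locus are excluded from that locus entirely.
    Returns (SS_a, SS_b, SS_c, df_a, df_b, df_c, sum over loci of the
    n_c coefficient weighted by df_a, and summed df_a for the weight).
    """
    r = len(calls_by_pop)
    L = calls_by_pop[0].shape[1]
    SSa = SSb = SSc = 0.0
    dfa = dfb = dfc = 0.0
    ncw = 0.0
    ncw_w = 0.0
    # per-pop per-locus: individuals genotyped, allele2 copies, hets
    n_i = np.empty((r, L))
    x_i = np.empty((r, L))
    het_i = np.empty((r, L))
    for k, calls in enumerate(calls_by_pop):
        obs = calls != MISSING
        n_i[k] = obs.sum(axis=0)
        x_i[k] = np.where(obs, calls, 0).sum(axis=0)
        het_i[k] = (calls == 1).sum(axis=0)
    c_i = 2 * n_i  # copies per pop
    C = c_i.sum(axis=0)
    X = x_i.sum(axis=0)
    N_ind = n_i.sum(axis=0)
    r_eff = (n_i > 0).sum(axis=0)
    usable = (r_eff >= 2) & (C > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ss_total = X * (C - X) / np.maximum(C, 1)
        ss_within_pop = np.where(c_i > 0, x_i * (c_i - x_i) / np.maximum(c_i, 1), 0.0).sum(axis=0)
    ss_within_ind = het_i.sum(axis=0) * 0.5
    ss_among_ind = ss_within_pop - ss_within_ind
    ss_among_pop = ss_total - ss_within_pop

    SSa = ss_among_pop[usable].sum()
    SSb = ss_among_ind[usable].sum()
    SSc = ss_within_ind[usable].sum()
    dfa = (r_eff[usable] - 1).sum()
    dfb = (N_ind[usable] - r_eff[usable]).sum()
    dfc = N_ind[usable].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (C - (c_i**2).sum(axis=0) / np.maximum(C, 1)) / np.maximum(r_eff - 1, 1)
    w = (r_eff - 1).astype(float)
    ncw = (n_c[usable] * w[usable]).sum()
    ncw_w = w[usable].sum()
    return SSa, SSb, SSc, dfa, dfb, dfc, ncw, ncw_w


def _amova_components(calls_by_pop: list[np.ndarray]):
    SSa, SSb, SSc, dfa, dfb, dfc, ncw, ncw_w = _amova_ss(calls_by_pop)
    if dfa <= 0 or dfc <= 0:
        raise ValueError("AMOVA needs >= 2 populations with data")
    MSa, MSb, MSc = SSa / dfa, SSb / max(dfb, 1), SSc / dfc
    n_c = ncw / ncw_w  # df-weighted mean coefficient (copies per population)
    sigma_c = MSc
    sigma_b = (MSb - sigma_c) / 2.0
    sigma_a = (MSa - sigma_c - 2.0 * sigma_b) / n_c
    return sigma_a, sigma_b, sigma_c


def amova(
    G: GenotypeMatrix,
    snp_set=None,
    populations=None,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA on allele copies (0/1 distance), summed over loci.

    Permutation schemes per level: sigma_a — individuals among populations;
    sigma_b — allele copies among individuals within populations;
    sigma_c — allele copies among all individuals.  Populations with a
    single individual are excluded with a warning.
    """
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    pops = populations or sub.populations
    keep = [p for p in pops if sub.pop_mask(p).sum() >= 2]
    dropped = set(pops) - set(keep)
    if dropped:
        logger.warning("AMOVA: dropping single-individual populations %s", sorted(dropped))
    blocks = [sub.calls[sub.pop_mask(p)] for p in keep]
    sa, sb, sc = _amova_components(blocks)
    total = sa + sb + sc
    res = AmovaResult(
        sigma2_among_pops=sa,
        sigma2_among_ind_within=sb,
        sigma2_within_ind=sc,
        pct_among_pops=100 * sa / total,
        pct_among_ind=100 * sb / total,
        pct_within_ind=100 * sc / total,
        phi_ST=sa / total,
        phi_IS=sb / (sb + sc) if (sb + sc) != 0 else np.nan,
        phi_IT=(sa + sb) / total,
    )
    if n_perm:
        rng = np.random.default_rng(seed)
        pool = np.vstack(blocks)
        sizes = [b.shape[0] for b in blocks]
        cuts = np.cumsum(sizes)[:-1]
        ge_a = ge_b = ge_c = 0
        n_tot, L = pool.shape
        # copy-level representation for the within-level permutations
        copies = np.empty((2 * n_tot, L))
        gg = pool.astype(float)
        gg[pool == MISSING] = np.nan
        copies[0::2] = np.where(gg >= 1, 1.0, 0.0)
        copies[1::2] = np.where(gg == 2, 1.0, 0.0)
        copies[0::2][np.isnan(gg)] = np.nan
        copies[1::2][np.isnan(gg)] = np.nan
        for _ in range(n_perm):
            # sigma_a: permute individuals among populations
            idx = rng.permutation(n_tot)
            pblocks = np.split(pool[idx], cuts)
            pa, _, _ = _amova_components(pblocks)
            ge_a += pa >= sa
            # sigma_b: permute copies among individuals within populations
            g_new = np.empty_like(pool, dtype=float)
            start = 0
            for b_i, sz in enumerate(sizes):
                blk = copies[2 * start : 2 * (start + sz)]
                order = np.argsort(rng.random(blk.shape), axis=0)
                pblk = np.take_along_axis(blk, order, axis=0)
                g_new[start : start + sz] = pblk[0::2] + pblk[1::2]
                start += sz
            g8 = np.where(np.isnan(g_new), MISSING, g_new).astype(np.int8)
            _, pb, _ = _amova_components(np.split(g8, cuts))
            ge_b += pb >= sb
            # sigma_c: permute copies among all individuals
            order = np.argsort(rng.random(copies.shape), axis=0)
            pall = np.take_along_axis(copies, order, axis=0)
            g_all = pall[0::2] + pall[1::2]
            g8 = np.where(np.isnan(g_all), MISSING, g_all).astype(np.int8)
            _, _, pc = _amova_components(np.split(g8, cuts))
            ge_c += pc <= sc  # heterozygosity deficit shrinks sigma_c
        res.p_among = (1 + ge_a) / (1 + n_perm)
        res.p_within_pops = (1 + ge_b) / (1 + n_perm)
        res.p_within_ind = (1 + ge_c) / (1 + n_perm)
    return res
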