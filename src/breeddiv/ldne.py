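"""Linkage disequilibrium and LD-based effective population size.

Two-locus r2 is estimated from unphased genotypes by an
Excoffier–Slatkin-style EM over haplotype frequencies (the double
heterozygote is the only ambiguous configuration).  Per population, all
same-chromosome pairs within 4 Mb are collected, binned in 50-kb distance
increments, and Ne per bin follows the drift-recombination expectation
E[r2] ≈ 1/(1 + 4·Ne·c) after a small-sample correction subtracting 1/ñ
(ñ = 2 × individuals) from the bin mean.  Physical distance is converted
at 1 Mb = 1 cM by default.  The per-breed summary is the median of
per-bin Ne over usable bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _em_r2_batch(counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Vectorised EM over P pairs of loci.

    ``counts``: (P, 3, 3) genotype-pair counts, axes = dosage at locus A,
    dosage at locus B.  Returns (haplotype freqs (P,4) as [h00,h01,h10,h11],
    D, r2), with NaN where either locus is monomorphic.
    """
    counts = np.asarray(counts, float)
    P = counts.shape[0]
    n = counts.sum(axis=(1, 2))
    # known haplotype contributions (double het excluded)
    idx = np.arange(3)
    ga = idx[:, None] * np.ones((1, 3))
    gb = np.ones((3, 1)) * idx[None, :]
    amb = (ga == 1) & (gb == 1)
    # per genotype cell: counts of haplotypes (a,b) from the two copies
    # copy composition: locus A gives alleles sorted (0...,1...) but pairing
    # with B is known except in the double het
    contrib = np.zeros((3, 3, 4))  # -> h00,h01,h10,h11 per individual
    for i in range(3):
        for j in range(3):
            if amb[i, j]:
                continue
            # the two haplotypes of an (i,j) individual: when either locus is
            # homozygous the pairing is forced
            a_alleles = [0, 0] if i == 0 else ([1, 1] if i == 2 else [0, 1])
            b_alleles = [0, 0] if j == 0 else ([1, 1] if j == 2 else [0, 1])
            # for het x hom or hom x hom, any pairing gives the same multiset
            for a, b in zip(a_alleles, b_alleles):
                contrib[i, j, 2 * a + b] += 1
    base = np.einsum("pij,ijh->ph", counts, contrib)
    n_amb = counts[:, 1, 1]

    pA = (counts * ga[None]).sum(axis=(1, 2)) / np.maximum(2 * n, 1)
    pB = (counts * gb[None]).sum(axis=(1, 2)) / np.maximum(2 * n, 1)
    mono = (pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1) | (n < 2)

    h = np.column_stack(
        [(1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB]
    )  # linkage-equilibrium start
    h = np.clip(h, 1e-12, None)
    h /= h.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        coup = h[:, 0] * h[:, 3]
        rep = h[:, 1] * h[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(coup + rep > 0, coup / np.maximum(coup + rep, 1e-300), 0.5)
        new = base.copy()
        new[:, 0] += n_amb * w
        new[:, 3] += n_amb * w
        new[:, 1] += n_amb * (1 - w)
        new[:, 2] += n_amb * (1 - w)
        new /= np.maximum(new.sum(axis=1, keepdims=True), 1e-300)
        delta = np.abs(new - h).max()
        h = new
        if delta < tol:
            break
    pA_h = h[:, 2] + h[:, 3]
    pB_h = h[:, 1] + h[:, 3]
    D = h[:, 3] - pA_h * pB_h
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = pA_h * (1 - pA_h) * pB_h * (1 - pB_h)
        r2 = np.where(denom > 0, D**2 / np.maximum(denom, 1e-300), np.nan)
    r2 = np.where(mono, np.nan, np.minimum(r2, 1.0))
    D = np.where(mono, np.nan, D)
    return h, D, r2


def em_haplotype_r2(g1: np.ndarray, g2: np.ndarray):
    """EM haplotype frequencies, D and r2 for one pair of loci.

    ``g1``, ``g2``: dosage vectors over the same individuals (MISSING = -1
    allowed; only doubly complete individuals are used).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    both = (g1 != MISSING) & (g2 != MISSING)
    if both.sum() < 2:
        raise ValueError("need >= 2 doubly complete individuals")
    counts = np.zeros((1, 3, 3))
    for a, b in zip(g1[both], g2[both]):
        counts[0, a, b] += 1
    h, D, r2 = _em_r2_batch(counts)
    return h[0], float(D[0]), float(r2[0])


# ---------------------------------------------------------------------------
# pair collection and binning
# ---------------------------------------------------------------------------

def per_breed_snp_filter(
    G: GenotypeMatrix, population: str, min_maf: float = 0.01, min_call_rate: float = 0.95
) -> list[str]:
    """Within-population locus filter ahead of LD: MAF >= min_maf and call
    rate >= min_call_rate, both computed on this population's samples."""
    calls = G.calls[G.pop_mask(population)]
    obs = calls != MISSING
    rate = obs.mean(axis=0)
    n = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(n, 1)
    maf = np.minimum(p, 1 - p)
    keep = (rate >= min_call_rate) & (n > 0) & (maf >= min_maf)
    return [l.id for l, k in zip(G.loci, keep) if k]


def within_breed_ld(
    G: GenotypeMatrix,
    population: str,
    max_dist: int = 4_000_000,
    locus_ids: list[str] | None = None,
) -> pd.DataFrame:
    """r2 for all same-chromosome locus pairs within ``max_dist`` bp.

    Returns columns locus_i, locus_j, dist_bp, r2, n_used.
    """
    sub = G if locus_ids is None else G.subset(locus_ids=locus_ids)
    calls = sub.calls[sub.pop_mask(population)]
    if calls.shape[0] == 0:
        return pd.DataFrame(columns=["locus_i", "locus_j", "dist_bp", "r2", "n_used"])
    chroms = np.array([l.chrom for l in sub.loci])
    pos = np.array([l.pos_bp for l in sub.loci])
    ids = np.array(sub.locus_ids)

    pairs_i, pairs_j = [], []
    for ch in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == ch)
        p = pos[idx]
        for a in range(len(idx)):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                pairs_i.append(idx[a])
                pairs_j.append(idx[b])
    if not pairs_i:
        return pd.DataFrame(columns=["locus_i", "locus_j", "dist_bp", "r2", "n_used"])
    pairs_i = np.array(pairs_i)
    pairs_j = np.array(pairs_j)

    # batched 3x3 count tables via one-hot contractions, chunked over pairs
    onehot = np.stack([(calls == k) for k in (0, 1, 2)], axis=2).astype(float)  # n×L×3
    P = len(pairs_i)
    counts = np.empty((P, 3, 3))
    chunk = 20000
    for s in range(0, P, chunk):
        e = min(s + chunk, P)
        A = onehot[:, pairs_i[s:e], :]  # n×c×3
        B = onehot[:, pairs_j[s:e], :]
        counts[s:e] = np.einsum("nca,ncb->cab", A, B, optimize=True)
    _, _, r2 = _em_r2_batch(counts)
    n_used = counts.sum(axis=(1, 2)).astype(int)
    return pd.DataFrame(
        {
            "locus_i": ids[pairs_i],
            "locus_j": ids[pairs_j],
            "dist_bp": np.abs(pos[pairs_i] - pos[pairs_j]),
            "r2": r2,
            "n_used": n_used,
        }
    )


def bin_ld(records: pd.DataFrame, bin_width: int = 50_000) -> pd.DataFrame:
    """Mean r2 and pair count per half-open distance bin [k·w, (k+1)·w)."""
    rec = records.dropna(subset=["r2"])
    if rec.empty:
        return pd.DataFrame(columns=["bin", "midpoint_bp", "mean_r2", "n_pairs"])
    b = (rec["dist_bp"] // bin_width).astype(int)
    grouped = rec.groupby(b)["r2"].agg(["mean", "size"])
    return pd.DataFrame(
        {
            "bin": grouped.index,
            "midpoint_bp": (grouped.index + 0.5) * bin_width,
            "mean_r2": grouped["mean"].to_numpy(),
            "n_pairs": grouped["size"].to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ne
# ---------------------------------------------------------------------------

def estimate_ne(
    binned: pd.DataFrame,
    n_individuals: int,
    cm_per_mb: float = 1.0,
    min_pairs: int = 50,
    summary: str = "median",
) -> dict:
    """Per-bin and summary Ne from binned LD decay.

    c = midpoint × cm_per_mb × 1e-8 Morgans; r2_adj = mean_r2 − 1/ñ with
    ñ = 2·n_individuals; Ne_bin = (1/(4c))·(1/r2_adj − 1).  Bins with
    fewer than ``min_pairs`` pairs or r2_adj <= 0 are skipped.  Summary is
    the median (or mean / first bin) of the usable per-bin values.
    """
    if summary not in ("median", "mean", "first-bin"):
        raise ValueError("summary must be median, mean or first-bin")
    nn = 2 * n_individuals
    rows = []
    for _, row in binned.iterrows():
        if row["n_pairs"] < min_pairs:
            continue
        c = row["midpoint_bp"] * cm_per_mb * 1e-8
        r2_adj = row["mean_r2"] - 1.0 / nn
        if r2_adj <= 0 or c <= 0:
            logger.info("bin at %.0f bp skipped (r2_adj <= 0)", row["midpoint_bp"])
            ne = np.nan
        else:
            ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - 1.0)
        rows.append(
            {
                "c_morgans": c,
                "mean_r2": row["mean_r2"],
                "r2_adj": r2_adj,
                "n_pairs": int(row["n_pairs"]),
                "Ne_bin": ne,
            }
        )
    bins = pd.DataFrame(rows)
    usable = bins["Ne_bin"].dropna() if not bins.empty else pd.Series(dtype=float)
    usable = usable[usable > 0]
    if usable.empty:
        ne_summary = np.nan
        logger.warning("no usable bins; Ne undefined")
    elif summary == "median":
        ne_summary = float(usable.median())
    elif summary == "mean":
        ne_summary = float(usable.mean())
    else:
        ne_summary = float(usable.iloc[0])
    return {"bins": bins, "Ne_summary": ne_summary, "n_individuals": n_individuals}


def ne_for_population(
    G: GenotypeMatrix,
    population: str,
    max_dist: int = 4_000_000,
    bin_width: int = 50_000,
    min_maf: float = 0.01,
    cm_per_mb: float = 1.0,
    summary: str = "median",
    min_pairs: int = 50,
) -> dict:
    """Full per-breed chain: per-breed SNP filter → pairwise EM r2 →
    binning → Ne."""
    loci = per_breed_snp_filter(G, population, min_maf=min_maf)
    rec = within_breed_ld(G, population, max_dist=max_dist, locus_ids=loci)
    binned = bin_ld(rec, bin_width=bin_width)
    n_ind = int(G.pop_mask(population).sum())
    out = estimate_ne(binned, n_ind, cm_per_mb=cm_per_mb, summary=summary, min_pairs=min_pairs)
    out["population"] = population
    out["n_loci"] = len(loci)
    out["records"] = rec
    return out
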