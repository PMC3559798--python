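"""Sample and SNP quality control.

Implements the pruning ladder used for array-based breed panels:

* call-rate filters (per SNP, then per sample),
* pooled-MAF removal with an inclusive boundary (MAF <= threshold goes),
* an ascertainment-aware MAF filter that recomputes MAF after excluding
  the SNP-discovery breeds, then removes the failing loci for everyone,
* method-of-moments IBD (pi-hat) and greedy relatedness pruning,
* windowed LD pruning in two modes: pairwise dosage-r2 and VIF
  (multiple-correlation) — both over sliding windows of SNPs,
* construction of the four nested analysis SNP sets (VIF 0.1, r2 0.1,
  0.2, 0.4) with full provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class SnpSet:
    """Named ordered subset of loci plus the filter log that produced it."""

    name: str
    locus_ids: list[str]
    provenance: list[dict] = field(default_factory=list)

    def log(self, filter_name: str, removed: int, **params) -> None:
        self.provenance.append(
            {"filter": filter_name, "params": params, "removed": int(removed)}
        )

    def __len__(self) -> int:
        return len(self.locus_ids)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            fh.write("\n".join(self.locus_ids) + "\n")
        with open(path + ".provenance.json", "w") as fh:
            json.dump({"name": self.name, "provenance": self.provenance}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SnpSet":
        path = str(path)
        with open(path) as fh:
            ids = [ln.strip() for ln in fh if ln.strip()]
        try:
            with open(path + ".provenance.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"name": path, "provenance": []}
        return cls(meta["name"], ids, meta["provenance"])


def _pooled_freqs(G: GenotypeMatrix, locus_ids=None) -> pd.Series:
    sub = G if locus_ids is None else G.subset(locus_ids=locus_ids)
    f = allele_frequencies(sub, by_population=False)
    return pd.Series(f["p"].to_numpy(), index=f["locus"])


# ---------------------------------------------------------------------------
# call rate / MAF
# ---------------------------------------------------------------------------

def filter_call_rate(
    G: GenotypeMatrix,
    min_snp_rate: float = 0.99,
    min_sample_rate: float = 0.90,
    name: str = "call_rate",
) -> tuple[SnpSet, list[str]]:
    """Drop loci with call rate below ``min_snp_rate``, then samples below
    ``min_sample_rate`` (sample rates recomputed on the kept loci)."""
    obs = G.calls != MISSING
    locus_rate = obs.mean(axis=0)
    keep_l = locus_rate >= min_snp_rate
    sample_rate = obs[:, keep_l].mean(axis=1) if keep_l.any() else obs.mean(axis=1)
    keep_s = sample_rate >= min_sample_rate
    if not keep_l.any() or not keep_s.any():
        raise ValueError("call-rate filter removed everything")
    snp_set = SnpSet(name, [l.id for l, k in zip(G.loci, keep_l) if k])
    snp_set.log(
        "snp_call_rate", int((~keep_l).sum()), min_snp_rate=min_snp_rate
    )
    snp_set.log(
        "sample_call_rate", int((~keep_s).sum()), min_sample_rate=min_sample_rate
    )
    kept_samples = [s.id for s, k in zip(G.samples, keep_s) if k]
    return snp_set, kept_samples


def filter_maf(
    G: GenotypeMatrix,
    snp_set: SnpSet | None = None,
    min_maf: float = 0.05,
    name: str = "maf",
) -> SnpSet:
    """Remove loci with pooled MAF <= ``min_maf`` (inclusive boundary)."""
    ids = snp_set.locus_ids if snp_set is not None else G.locus_ids
    p = _pooled_freqs(G, ids)
    maf = np.minimum(p, 1 - p)
    keep = [i for i in ids if not (np.isnan(maf[i]) or maf[i] <= min_maf)]
    out = SnpSet(name, keep, list(snp_set.provenance) if snp_set else [])
    out.log("maf_pooled", len(ids) - len(keep), min_maf=min_maf)
    return out


def ascertainment_aware_maf_filter(
    G: GenotypeMatrix,
    discovery_pops: list[str],
    min_maf: float = 0.05,
    snp_set: SnpSet | None = None,
    name: str = "ascertainment_maf",
) -> SnpSet:
    """MAF filter computed on non-discovery samples only.

    SNPs ascertained in a subset of breeds are biased toward being common
    there; recomputing MAF with the discovery breeds excluded and removing
    the failing loci from the *full* dataset reduces that bias.  With an
    empty discovery list this reduces to :func:`filter_maf`.
    """
    pops = set(G.populations)
    unknown = set(discovery_pops) - pops
    if unknown:
        raise ValueError(f"unknown discovery populations: {sorted(unknown)}")
    if set(discovery_pops) >= pops:
        raise ValueError("discovery set covers all populations; no samples left")
    ids = snp_set.locus_ids if snp_set is not None else G.locus_ids
    keep_samples = [s.id for s in G.samples if s.population not in set(discovery_pops)]
    sub = G.subset(sample_ids=keep_samples, locus_ids=ids)
    p = _pooled_freqs(sub)
    maf = np.minimum(p, 1 - p)
    keep = [i for i in ids if not (np.isnan(maf[i]) or maf[i] <= min_maf)]
    out = SnpSet(name, keep, list(snp_set.provenance) if snp_set else [])
    out.log(
        "ascertainment_maf",
        len(ids) - len(keep),
        min_maf=min_maf,
        discovery_pops=list(discovery_pops),
        excluded_samples=G.n_samples - len(keep_samples),
    )
    return out


# ---------------------------------------------------------------------------
# relatedness (pi-hat)
# ---------------------------------------------------------------------------

def pihat_matrix(
    G: GenotypeMatrix, freq_source: np.ndarray | None = None, min_loci: int = 100
) -> pd.DataFrame:
    """Method-of-moments genome-wide IBD for every sample pair.

    Expected IBS-state proportions conditional on IBD state are computed
    from pooled allele frequencies with sampling-without-replacement
    (falling-factorial) bias corrections; P(IBD=0,1,2) are solved from the
    observed IBS counts, truncated into [0,1] and renormalised;
    pi-hat = P(IBD=1)/2 + P(IBD=2).

    ``freq_source`` optionally supplies known per-locus allele2 frequencies
    (aligned to ``G.loci``), e.g. from a larger reference cohort; the
    conditional expectations then use the exact (infinite-sample) forms.
    Without it, frequencies are counted from ``G`` itself — adequate for a
    cohort, badly biased for an isolated pair.

    Returns a frame with one row per unordered pair: ibs0/1/2 counts,
    Z0/Z1/Z2, ``pi_hat`` and a ``low_confidence`` flag for pairs sharing
    fewer than ``min_loci`` comparable loci.
    """
    calls = G.calls
    n, L = calls.shape
    obs = calls != MISSING

    def ff(a, k):  # falling factorial a(a-1)...(a-k+1)
        out = np.ones_like(a)
        for i in range(k):
            out = out * (a - i)
        return out

    if freq_source is not None:
        p = np.asarray(freq_source, float)
        if p.shape != (L,):
            raise ValueError(f"freq_source must have length {L}")
        poly = (p > 0) & (p < 1)
        pq = p[poly]
        q = 1 - pq
        use = np.flatnonzero(poly)
        e00 = 2 * pq**2 * q**2
        e01 = 4 * pq**3 * q + 4 * pq * q**3
        e02 = pq**4 + q**4 + 4 * pq**2 * q**2
        e11 = 2 * pq**2 * q + 2 * pq * q**2
        e12 = pq**3 + q**3 + pq**2 * q + pq * q**2
    else:
        # pooled allele counts per locus
        x = np.where(obs, calls, 0).sum(axis=0).astype(float)  # copies of allele2
        X = 2.0 * obs.sum(axis=0)
        ok = X >= 4  # need 4 distinct draws for the IBD=0 terms
        x, X = x[ok], X[ok]
        y = X - x
        poly = (x > 0) & (y > 0)
        x, X, y = x[poly], X[poly], y[poly]
        use = np.flatnonzero(ok)[poly]
        D3, D4 = ff(X, 3), ff(X, 4)
        # E[P(IBS=s | IBD=z)] per locus, bias-corrected
        e00 = 2 * ff(x, 2) * ff(y, 2) / D4
        e01 = 4 * ff(x, 3) * y / D4 + 4 * x * ff(y, 3) / D4
        e02 = ff(x, 4) / D4 + ff(y, 4) / D4 + 4 * ff(x, 2) * ff(y, 2) / D4
        e11 = 2 * ff(x, 2) * y / D3 + 2 * x * ff(y, 2) / D3
        e12 = ff(x, 3) / D3 + ff(y, 3) / D3 + ff(x, 2) * y / D3 + x * ff(y, 2) / D3

    calls_u = calls[:, use]
    obs_u = obs[:, use]

    rows = []
    for i in range(n):
        gi, oi = calls_u[i], obs_u[i]
        for j in range(i + 1, n):
            both = oi & obs_u[j]
            diff = np.abs(gi - calls_u[j])[both]
            n_loci = both.sum()
            ibs0 = int((diff == 2).sum())
            ibs1 = int((diff == 1).sum())
            ibs2 = n_loci - ibs0 - ibs1
            E00, E01, E02 = e00[both].sum(), e01[both].sum(), e02[both].sum()
            E11, E12 = e11[both].sum(), e12[both].sum()
            z0 = ibs0 / E00 if E00 > 0 else 0.0
            z1 = (ibs1 - z0 * E01) / E11 if E11 > 0 else 0.0
            z2 = (ibs2 - z0 * E02 - z1 * E12) / n_loci if n_loci > 0 else 0.0
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            s = z.sum()
            z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
            rows.append(
                {
                    "sample_i": G.samples[i].id,
                    "sample_j": G.samples[j].id,
                    "ibs0": ibs0,
                    "ibs1": ibs1,
                    "ibs2": ibs2,
                    "z0": z[0],
                    "z1": z[1],
                    "z2": z[2],
                    "pi_hat": z[1] / 2 + z[2],
                    "low_confidence": n_loci < min_loci,
                }
            )
    return pd.DataFrame(rows)


def prune_related(kinship: pd.DataFrame, threshold: float = 0.3) -> list[str]:
    """Iteratively drop the sample in the most pairs with pi-hat > threshold
    (tie → lexicographically larger id) until no pair exceeds it."""
    over = kinship[kinship["pi_hat"] > threshold][["sample_i", "sample_j"]]
    edges = {frozenset((a, b)) for a, b in over.itertuples(index=False)}
    all_samples = sorted(set(kinship["sample_i"]) | set(kinship["sample_j"]))
    removed: set[str] = set()
    while edges:
        deg: dict[str, int] = {}
        for e in edges:
            for s in e:
                deg[s] = deg.get(s, 0) + 1
        worst = max(deg.items(), key=lambda kv: (kv[1], kv[0]))[0]
        removed.add(worst)
        edges = {e for e in edges if worst not in e}
    return [s for s in all_samples if s not in removed]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation over pairwise-complete samples.

    X: n×w dosages with missing set to 0; M: n×w 0/1 presence mask.
    """
    Xm = X * M
    N = M.T @ M  # pairwise complete counts
    S1 = Xm.T @ M
    S2 = (Xm**2).T @ M
    P = Xm.T @ Xm
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = P - S1 * S1.T / np.maximum(N, 1)
        var_i = S2 - S1**2 / np.maximum(N, 1)
        denom = var_i * var_i.T
        r2 = np.where(denom > 0, cov**2 / np.where(denom > 0, denom, 1), np.nan)
    np.fill_diagonal(r2, 1.0)
    return r2


def _windows(n: int, window: int, step: int):
    start = 0
    while True:
        yield start, min(start + window, n)
        if start + window >= n:
            break
        start += step


def ld_prune_pairwise(
    G: GenotypeMatrix,
    snp_set: SnpSet | None = None,
    window: int = 100,
    step: int = 25,
    r2_max: float = 0.1,
    name: str | None = None,
) -> SnpSet:
    """Sliding-window pairwise LD pruning on dosage r2.

    Within each window, while any same-chromosome pair exceeds ``r2_max``,
    the member of the worst pair with the lower pooled MAF is removed
    (tie → later map position); the window then shifts by ``step`` kept
    SNPs.  r2 is the squared Pearson correlation of dosage codes over
    samples complete for both loci.
    """
    ids = list(snp_set.locus_ids) if snp_set is not None else list(G.locus_ids)
    sub = G.subset(locus_ids=ids)
    ids = sub.locus_ids  # map order
    maf_s = _pooled_freqs(sub)
    maf = np.minimum(maf_s.to_numpy(float), 1 - maf_s.to_numpy(float))
    pos = np.array([l.pos_bp for l in sub.loci])
    chrom = np.array([l.chrom for l in sub.loci])
    calls = sub.calls.astype(float)
    M = (sub.calls != MISSING).astype(float)
    calls[sub.calls == MISSING] = 0.0

    keep = np.ones(len(ids), dtype=bool)
    n_before = len(ids)
    for lo, hi in _windows(len(ids), window, step):
        idx = np.flatnonzero(keep[:n_before])
        idx = idx[(idx >= lo) & (idx < hi)]
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(calls[:, idx], M[:, idx])
        same = chrom[idx][:, None] == chrom[idx][None, :]
        r2 = np.where(same, r2, 0.0)
        np.fill_diagonal(r2, 0.0)
        active = np.ones(len(idx), dtype=bool)
        while True:
            sub_r2 = np.where(np.outer(active, active), r2, 0.0)
            mx = np.nanmax(sub_r2)
            if not (mx > r2_max):
                break
            a, b = np.unravel_index(np.nanargmax(sub_r2), sub_r2.shape)
            ia, ib = idx[a], idx[b]
            # victim: lower pooled MAF, tie -> later map position
            if (maf[ia], -pos[ia]) < (maf[ib], -pos[ib]):
                victim_local, victim = a, ia
            else:
                victim_local, victim = b, ib
            active[victim_local] = False
            keep[victim] = False
    kept_ids = [ids[i] for i in range(len(ids)) if keep[i]]
    out = SnpSet(
        name or f"ld_pairwise_r2_{r2_max}",
        kept_ids,
        list(snp_set.provenance) if snp_set else [],
    )
    out.log(
        "ld_prune_pairwise",
        n_before - len(kept_ids),
        window=window,
        step=step,
        r2_max=r2_max,
    )
    return out


def ld_prune_vif(
    G: GenotypeMatrix,
    snp_set: SnpSet | None = None,
    window: int = 100,
    step: int = 25,
    vif_max: float = 1 / (1 - 0.1),
    name: str | None = None,
) -> SnpSet:
    """Sliding-window VIF pruning.

    Within each window, the SNP whose variance-inflation factor
    1/(1−R²) — R² from regressing its dosage on the other retained window
    SNPs — is largest is removed while any VIF exceeds ``vif_max``.
    Exact collinearity (R² = 1) yields an infinite VIF; the later-positioned
    offender is dropped first.
    """
    ids = list(snp_set.locus_ids) if snp_set is not None else list(G.locus_ids)
    sub = G.subset(locus_ids=ids)
    ids = sub.locus_ids
    calls = sub.calls.astype(float)
    obs = sub.calls != MISSING
    # mean-impute for the regression design
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(obs, calls, 0).sum(0) / np.maximum(obs.sum(0), 1)
    calls = np.where(obs, calls, col_mean)

    keep = np.ones(len(ids), dtype=bool)
    n_before = len(ids)
    for lo, hi in _windows(len(ids), window, step):
        while True:
            idx = np.flatnonzero(keep)
            idx = idx[(idx >= lo) & (idx < hi)]
            if len(idx) < 2:
                break
            X = calls[:, idx]
            X = X - X.mean(axis=0)
            vifs = np.empty(len(idx))
            for a in range(len(idx)):
                yv = X[:, a]
                tss = yv @ yv
                if tss <= 1e-12:
                    vifs[a] = 1.0  # monomorphic: no inflation
                    continue
                Z = np.delete(X, a, axis=1)
                coef, *_ = np.linalg.lstsq(Z, yv, rcond=None)
                rss = yv - Z @ coef
                r2 = 1 - (rss @ rss) / tss
                vifs[a] = np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2)
            worst = np.max(vifs)
            if not (worst > vif_max):
                break
            # drop the later-positioned SNP among the (near-)worst
            cand = np.flatnonzero(vifs >= worst - 1e-9)
            keep[idx[cand[-1]]] = False
    kept_ids = [ids[i] for i in range(len(ids)) if keep[i]]
    out = SnpSet(
        name or f"ld_vif_{vif_max:g}",
        kept_ids,
        list(snp_set.provenance) if snp_set else [],
    )
    out.log(
        "ld_prune_vif", n_before - len(kept_ids), window=window, step=step, vif_max=vif_max
    )
    return out


# ---------------------------------------------------------------------------
# the four analysis SNP sets
# ---------------------------------------------------------------------------

def build_paper_snp_sets(
    G: GenotypeMatrix,
    discovery_pops: list[str] | None = None,
    min_maf: float = 0.05,
    min_snp_rate: float = 0.99,
    window: int = 100,
    step: int = 25,
) -> dict[str, SnpSet]:
    """Construct the four nested analysis sets from a post-sample-QC matrix.

    Order: ascertainment-aware MAF → SNP call rate → pooled MAF → the four
    LD prunes (pairwise r2 at 0.1/0.2/0.4 and VIF at 1.11, i.e. R² < 0.1).
    Non-autosomes are assumed dropped at load.
    """
    discovery_pops = discovery_pops or []
    base: SnpSet | None = None
    if discovery_pops:
        base = ascertainment_aware_maf_filter(G, discovery_pops, min_maf)
    cr, _ = filter_call_rate(G.subset(locus_ids=base.locus_ids) if base else G,
                             min_snp_rate=min_snp_rate, min_sample_rate=0.0)
    if base is not None:
        cr.provenance = base.provenance + cr.provenance
    base = filter_maf(G, cr, min_maf=min_maf)
    sets = {
        "primary": ld_prune_pairwise(G, base, window, step, 0.1, name="primary"),
        "vif01": ld_prune_vif(G, base, window, step, 1 / (1 - 0.1), name="vif01"),
        "r2_02": ld_prune_pairwise(G, base, window, step, 0.2, name="r2_02"),
        "r2_04": ld_prune_pairwise(G, base, window, step, 0.4, name="r2_04"),
    }
    return sets


def thin_samples_per_pop(
    G: GenotypeMatrix, max_per_pop: int, seed: int
) -> tuple[list[str], list[str]]:
    """Randomly remove surplus samples from overrepresented populations
    (seeded).  Returns (kept ids, removed ids)."""
    rng = np.random.default_rng(seed)
    kept, removed = [], []
    for pop in G.populations:
        ids = [s.id for s in G.samples if s.population == pop]
        if len(ids) > max_per_pop:
            sel = rng.choice(len(ids), size=max_per_pop, replace=False)
            sel = set(np.sort(sel).tolist())
            for i, sid in enumerate(ids):
                (kept if i in sel else removed).append(sid)
        else:
            kept.extend(ids)
    return kept, removed
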