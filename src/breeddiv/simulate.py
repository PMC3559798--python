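"""Synthetic genotype generators with controlled population structure.

Every generator returns a :class:`GenotypeMatrix`, so the whole pipeline
can be exercised through the same readers and statistics as real data.

* :func:`balding_nichols` — populations drifted from common ancestral
  allele frequencies; the Balding–Nichols F parameter is the expected
  FST, and within-population inbreeding F_IS tunes heterozygote deficit.
* :func:`admixed_individuals` — individuals whose allele copies draw
  their source cluster from given (or Dirichlet-sampled) ancestry q.
* :func:`wright_fisher_ld` — forward-in-time Wright–Fisher simulation of
  linked loci so that true N is a controlled input for Ne recovery;
  recombination follows Haldane's map (independent per-interval
  crossovers), and the emitted map uses 1 cM = 1 Mb.
* :func:`related_pair` — Mendelian construction of duplicate /
  parent-offspring / full-sib / unrelated pairs for pi-hat validation.
* :func:`paper_like_panel` — a ~12-breed panel with heterogeneous drift,
  one split sampling location, one admixed breed and one small breed:
  the structural features a real breed panel exhibits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Locus, Sample


@dataclass
class SimConfig:
    n_pops: int = 2
    samples_per_pop: int = 30
    n_loci: int = 1000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    fst_per_pop: list[float] | float = 0.1
    fis_per_pop: list[float] | float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def fst_list(self) -> list[float]:
        f = self.fst_per_pop
        return list(f) if isinstance(f, (list, tuple)) else [f] * self.n_pops

    def fis_list(self) -> list[float]:
        f = self.fis_per_pop
        return list(f) if isinstance(f, (list, tuple)) else [f] * self.n_pops


def _make_loci(n_loci: int, chrom: str = "1", spacing_bp: int = 100_000) -> list[Locus]:
    return [
        Locus(f"snp{j+1}", chrom, (j + 1) * spacing_bp, "A", "G") for j in range(n_loci)
    ]


def _genotypes_with_inbreeding(rng, p_row: np.ndarray, n: int, fis: float) -> np.ndarray:
    """Draw n diploid genotypes at loci with freqs p_row under inbreeding.

    P(het) = 2p(1-p)(1-F); the removed heterozygosity is returned to the
    homozygote classes in proportion to their HWE weights plus pF(1-p)
    each — i.e. the standard inbreeding genotype frequencies
    p^2 + Fp(1-p), 2p(1-p)(1-F), (1-p)^2 + Fp(1-p).
    """
    p = p_row[None, :]
    u = rng.random((n, p_row.size))
    p_hom2 = p**2 + fis * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - fis)
    g = np.where(u < p_hom2, 2, np.where(u < p_hom2 + p_het, 1, 0))
    return g.astype(np.int8)


def balding_nichols(config: SimConfig) -> GenotypeMatrix:
    """Multi-population drift model with tunable FST and F_IS per population."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)
    fst = config.fst_list()
    fis = config.fis_list()
    if any(f >= 1 for f in fst):
        raise ValueError("F = 1 is degenerate for the Balding-Nichols Beta")
    # all frequency draws precede all genotype draws so that
    # population_frequencies() can replay the identical stream
    pop_freqs = []
    for F in fst:
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pop_freqs.append(rng.beta(a, b))
        else:
            pop_freqs.append(p_anc.copy())
    samples, blocks = [], []
    for k in range(config.n_pops):
        g = _genotypes_with_inbreeding(rng, pop_freqs[k], config.samples_per_pop, fis[k])
        blocks.append(g)
        samples += [
            Sample(f"pop{k+1}_ind{i+1}", f"pop{k+1}") for i in range(config.samples_per_pop)
        ]
    calls = np.vstack(blocks)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)
    return GenotypeMatrix(samples, _make_loci(config.n_loci), calls)


def population_frequencies(config: SimConfig) -> np.ndarray:
    """The drifted per-population frequencies a config implies — exactly
    those :func:`balding_nichols` uses for the same config and seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)
    out = []
    for F in config.fst_list():
        if F > 0:
            out.append(rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F))
        else:
            out.append(p_anc.copy())
    return np.vstack(out)


def admixed_individuals(
    P: np.ndarray,
    q: np.ndarray | None = None,
    n: int | None = None,
    alpha: float | np.ndarray | None = None,
    seed: int = 0,
    population: str = "admixed",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes for admixed individuals given cluster freqs P (K×L).

    Either ``q`` (n×K ancestry rows on the simplex) or ``alpha`` (+ ``n``)
    for Dirichlet-sampled rows.  Each allele copy draws its source cluster
    from Cat(q) then its allele from Bernoulli(p_kl).  Returns the matrix
    and the q actually used.
    """
    rng = np.random.default_rng(seed)
    P = np.asarray(P, float)
    K, L = P.shape
    if q is None:
        if alpha is None or n is None:
            raise ValueError("give q, or alpha and n")
        a = np.full(K, alpha, float) if np.isscalar(alpha) else np.asarray(alpha, float)
        q = rng.dirichlet(a, size=n)
    q = np.asarray(q, float)
    if not np.allclose(q.sum(axis=1), 1, atol=1e-8):
        raise ValueError("q rows must lie on the simplex")
    n = q.shape[0]
    calls = np.empty((n, L), dtype=np.int8)
    for i in range(n):
        z = rng.choice(K, size=(2, L), p=None if K == 1 else q[i]) if K > 1 else np.zeros((2, L), int)
        alleles = rng.random((2, L)) < P[z, np.arange(L)]
        calls[i] = alleles.sum(axis=0)
    samples = [Sample(f"{population}_ind{i+1}", population) for i in range(n)]
    return GenotypeMatrix(samples, _make_loci(L), calls), q


def wright_fisher_ld(
    N_diploid: int,
    n_loci: int,
    chrom_length_morgans: float,
    generations: int,
    seed: int = 0,
    n_sample: int | None = None,
    population: str = "wf",
) -> GenotypeMatrix:
    """Forward Wright–Fisher simulation of equally spaced linked loci.

    Founder haplotypes are at linkage equilibrium with frequencies
    U(0.1, 0.9).  Each offspring picks two random parents; each gamete
    recombines between adjacent loci independently with Haldane's
    probability (1 - exp(-2d))/2.  The map is emitted at 1 cM = 1 Mb so
    downstream bp→Morgan handling is exercised.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    H = (rng.random((2 * N_diploid, n_loci)) < p0).astype(np.int8)
    d = chrom_length_morgans / max(n_loci - 1, 1)
    r = 0.5 * (1 - np.exp(-2 * d))
    n_gam = 2 * N_diploid
    for _ in range(generations):
        parents = rng.integers(0, N_diploid, size=n_gam)
        # per-gamete per-interval crossover indicators -> haplotype chooser
        switch = rng.random((n_gam, n_loci - 1)) < r if n_loci > 1 else np.zeros((n_gam, 0), bool)
        start = rng.integers(0, 2, size=n_gam)
        chooser = np.empty((n_gam, n_loci), dtype=np.int64)
        chooser[:, 0] = start
        if n_loci > 1:
            chooser[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
        H = H[2 * parents[:, None] + chooser, np.arange(n_loci)[None, :]]
    G_all = H[0::2] + H[1::2]
    if n_sample is not None and n_sample < N_diploid:
        idx = rng.choice(N_diploid, size=n_sample, replace=False)
        G_all = G_all[np.sort(idx)]
    n = G_all.shape[0]
    spacing_bp = int(round(d * 100 * 1e6)) if n_loci > 1 else 1_000_000  # 1 cM = 1 Mb
    loci = [Locus(f"snp{j+1}", "1", 1 + j * max(spacing_bp, 1), "A", "G") for j in range(n_loci)]
    samples = [Sample(f"{population}_ind{i+1}", population) for i in range(n)]
    return GenotypeMatrix(samples, loci, G_all.astype(np.int8))


def related_pair(
    freqs: np.ndarray, relationship: str, seed: int = 0, population: str = "fam"
) -> GenotypeMatrix:
    """A two-sample matrix with a planted relationship.

    ``relationship`` is one of duplicate, parent_offspring, full_sib,
    unrelated.  Construction is Mendelian: parental haploid gametes are
    drawn from the population frequencies and transmitted.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, float)
    L = p.size

    def gamete_from(g_mat):  # one allele per locus from a diploid
        pick = rng.integers(0, 2, size=L)
        return g_mat[pick, np.arange(L)]

    def random_diploid():
        return (rng.random((2, L)) < p).astype(np.int8)

    if relationship == "duplicate":
        a = random_diploid()
        b = a.copy()
    elif relationship == "parent_offspring":
        a = random_diploid()  # parent
        other = random_diploid()
        b = np.vstack([gamete_from(a), gamete_from(other)])
    elif relationship == "full_sib":
        pa, ma = random_diploid(), random_diploid()
        a = np.vstack([gamete_from(pa), gamete_from(ma)])
        b = np.vstack([gamete_from(pa), gamete_from(ma)])
    elif relationship == "unrelated":
        a, b = random_diploid(), random_diploid()
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    calls = np.vstack([a.sum(axis=0), b.sum(axis=0)]).astype(np.int8)
    samples = [Sample(f"{population}_a", population), Sample(f"{population}_b", population)]
    return GenotypeMatrix(samples, _make_loci(L), calls)


def paper_like_panel(seed: int = 0, n_loci: int = 800) -> GenotypeMatrix:
    """A breed-panel fixture with realistic structural features.

    12 breeds with drift F spanning 0.02–0.25 and mild inbreeding in a
    few; one breed sampled at two "locations" (two labels drawn from the
    same drifted frequencies); one admixed breed (Dirichlet ancestry
    between two others); one small breed (n = 7); ~0.5% missing calls.
    """
    rng = np.random.default_rng(seed)
    F_values = [0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.15, 0.18, 0.20, 0.25]
    fis_values = [0.0, 0.0, 0.05, 0.0, 0.10, 0.0, 0.0, 0.05, 0.0, 0.0]
    n_per = [20, 20, 18, 22, 20, 16, 20, 18, 20, 7]  # last breed small
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    samples, blocks = [], []
    pop_freqs = {}
    for k, (F, fis, n) in enumerate(zip(F_values, fis_values, n_per)):
        p_pop = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        pop_freqs[k] = p_pop
        g = _genotypes_with_inbreeding(rng, p_pop, n, fis)
        name = f"breed{k+1:02d}"
        blocks.append(g)
        samples += [Sample(f"{name}_ind{i+1}", name) for i in range(n)]
    # breed sampled at two locations: same frequencies, second label
    g = _genotypes_with_inbreeding(rng, pop_freqs[0], 12, 0.0)
    blocks.append(g)
    samples += [Sample(f"breed01b_ind{i+1}", "breed01_siteB") for i in range(12)]
    # admixed breed between breeds 2 and 3
    P = np.vstack([pop_freqs[1], pop_freqs[2]])
    qrows = rng.dirichlet([3.0, 3.0], size=15)
    calls_ad = np.empty((15, n_loci), dtype=np.int8)
    for i in range(15):
        z = rng.choice(2, size=(2, n_loci), p=qrows[i])
        calls_ad[i] = ((rng.random((2, n_loci)) < P[z, np.arange(n_loci)]).sum(axis=0))
    blocks.append(calls_ad)
    samples += [Sample(f"admix_ind{i+1}", "breed_admixed") for i in range(15)]
    calls = np.vstack(blocks)
    mask = rng.random(calls.shape) < 0.005
    calls = np.where(mask, MISSING, calls).astype(np.int8)
    # spread loci over 4 chromosomes
    per = max(n_loci // 4, 1)
    loci = [
        Locus(f"snp{j+1}", str(min(j // per, 3) + 1), 1 + (j % per) * 100_000, "A", "G")
        for j in range(n_loci)
    ]
    return GenotypeMatrix(samples, loci, calls)
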