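"""Genotype containers and text-format I/O.

The canonical in-memory object is :class:`GenotypeMatrix`: an N-sample by
L-locus table of diploid allele-dosage codes (0/1/2 copies of ``allele2``,
``-1`` for missing) with a locus map and per-sample population labels.
Everything downstream — QC, diversity, F-statistics, trees, PCA, LD and
admixture — consumes this one substrate.

Supported formats are PLINK text PED/MAP and VCF (via cyvcf2), plus a
two-column sample→population TSV.  Binary PLINK, phasing and imputation
are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: chromosome labels dropped at load (non-autosomal); case-insensitive
NON_AUTOSOMES = {"x", "ecax", "chrx", "y", "ecay", "chry", "mt", "m", "chrm", "chrmt"}


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: identifier, map position and the two allele letters.

    ``allele2`` is the allele counted by the dosage codes.  For PED input
    (which carries no REF/ALT) the first allele letter encountered in file
    order becomes ``allele1``; the assignment is recorded here so codes are
    reproducible run to run.
    """

    id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"locus {self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.allele1 == self.allele2 and self.allele1 != "0":
            raise ValueError(f"locus {self.id}: alleles must differ")


@dataclass(frozen=True)
class Sample:
    id: str
    population: str
    attrs: tuple = ()  # opaque PED header fields (family, parents, sex, phenotype)

    def __post_init__(self):
        if not self.population:
            raise ValueError(f"sample {self.id}: population label must be non-empty")


class GenotypeMatrix:
    """Samples × loci matrix of diploid dosage codes in {0, 1, 2, MISSING}.

    Codes count copies of each locus's ``allele2``.  Heterozygotes are 1
    regardless of allele order; phase is never retained.  Within each
    chromosome, loci are kept sorted by physical position.
    """

    def __init__(self, samples: list[Sample], loci: list[Locus], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        bad = ~np.isin(calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls contain codes outside {0, 1, 2, MISSING}")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate sample id(s): {dup[dup > 1].index.tolist()}")
        lids = [l.id for l in loci]
        if len(set(lids)) != len(lids):
            dup = pd.Series(lids).value_counts()
            raise ValueError(f"duplicate locus id(s): {dup[dup > 1].index.tolist()}")
        order = _map_order(loci)
        self.samples = list(samples)
        self.loci = [loci[i] for i in order]
        self.calls = np.ascontiguousarray(calls[:, order])
        self._sample_index = {s.id: i for i, s in enumerate(self.samples)}
        self._locus_index = {l.id: j for j, l in enumerate(self.loci)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def population_of(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])

    def pop_mask(self, population: str) -> np.ndarray:
        return np.array([s.population == population for s in self.samples])

    def locus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [l.id for l in self.loci],
                "chrom": [l.chrom for l in self.loci],
                "pos_bp": [l.pos_bp for l in self.loci],
                "allele1": [l.allele1 for l in self.loci],
                "allele2": [l.allele2 for l in self.loci],
            }
        )

    # -- subsetting ------------------------------------------------------
    def subset(self, sample_ids=None, locus_ids=None) -> "GenotypeMatrix":
        si = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self._sample_index[s] for s in sample_ids])
        )
        lj = (
            np.arange(self.n_loci)
            if locus_ids is None
            else np.array([self._locus_index[l] for l in locus_ids])
        )
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.loci[j] for j in lj],
            self.calls[np.ix_(si, lj)],
        )

    def align_alleles(self, reference: "GenotypeMatrix") -> "GenotypeMatrix":
        """Recode dosages so allele2 matches the reference's assignment.

        PED carries no REF/ALT, so a written-then-reread matrix may have
        allele1/allele2 swapped at loci where the first allele encountered
        differs; this flips those codes (2 - code) and restores identity.
        """
        ref_by_id = {l.id: l for l in reference.loci}
        loci, calls = [], self.calls.copy()
        for j, l in enumerate(self.loci):
            r = ref_by_id.get(l.id)
            if r is not None and {l.allele1, l.allele2} == {r.allele1, r.allele2} and l.allele2 != r.allele2:
                m = calls[:, j] != MISSING
                calls[m, j] = 2 - calls[m, j]
                loci.append(r)
            else:
                loci.append(l)
        return GenotypeMatrix(self.samples, loci, calls)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci, "
            f"{len(self.populations)} populations)"
        )


def _map_order(loci: list[Locus]) -> np.ndarray:
    """Stable order sorting by position within each chromosome block."""
    chrom = np.array([l.chrom for l in loci])
    pos = np.array([l.pos_bp for l in loci])
    # preserve first-appearance chromosome order
    chrom_rank = {c: r for r, c in enumerate(dict.fromkeys(chrom))}
    key = np.array([chrom_rank[c] for c in chrom])
    return np.lexsort((pos, key))


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path, pop_table=None, drop_non_autosomes: bool = True) -> GenotypeMatrix:
    """Read PLINK text PED + MAP into a :class:`GenotypeMatrix`.

    MAP columns: chrom, id, cM, bp.  PED rows: 6 header columns then two
    allele characters per locus; ``0`` marks a missing allele.  The first
    allele letter encountered in file order becomes ``allele1``.

    ``pop_table`` maps sample id → population; without it the PED family
    column is the population label.  Non-autosomal loci are dropped with a
    logged count.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    n_loci = len(map_rows)

    pops = dict(pop_table) if pop_table is not None else None

    sample_rows: list[tuple] = []
    geno_rows: list[np.ndarray] = []
    # allele registry per locus: first seen letter -> allele1, second -> allele2
    a1 = np.array([""] * n_loci, dtype=object)
    a2 = np.array([""] * n_loci, dtype=object)

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_loci} fields "
                    f"({n_loci} loci), got {len(parts)} (ragged row)"
                )
            fam, iid = parts[0], parts[1]
            alleles = parts[6:]
            codes = np.empty(n_loci, dtype=np.int8)
            for j in range(n_loci):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x == "0" or y == "0":
                    codes[j] = MISSING
                    continue
                for al in (x, y):
                    if a1[j] == "":
                        a1[j] = al
                    elif al != a1[j] and a2[j] == "":
                        a2[j] = al
                    elif al != a1[j] and al != a2[j]:
                        raise ValueError(
                            f"{ped_path}:{ln}: locus {map_rows[j][1]} has >2 alleles "
                            f"({a1[j]}, {a2[j]}, {al})"
                        )
                codes[j] = (x == a2[j]) + (y == a2[j])
            pop = pops[iid] if pops is not None else fam
            sample_rows.append((iid, pop, (fam, *parts[2:6])))
            geno_rows.append(codes)

    # monomorphic loci: give allele2 a placeholder so the Locus is well formed
    for j in range(n_loci):
        if a1[j] == "":
            a1[j], a2[j] = "0", "0"
        elif a2[j] == "":
            a2[j] = "0"

    samples = [Sample(iid, pop, attrs) for iid, pop, attrs in sample_rows]
    loci = [
        Locus(mid, chrom, bp, a1[j], a2[j])
        for j, (chrom, mid, _cm, bp) in enumerate(map_rows)
    ]
    calls = np.vstack(geno_rows) if geno_rows else np.empty((0, n_loci), dtype=np.int8)
    G = GenotypeMatrix(samples, loci, calls)
    if drop_non_autosomes:
        G = _drop_non_autosomes(G)
    return G


def _drop_non_autosomes(G: GenotypeMatrix) -> GenotypeMatrix:
    keep = [l.id for l in G.loci if l.chrom.lower() not in NON_AUTOSOMES]
    n_drop = G.n_loci - len(keep)
    if n_drop:
        logger.info("dropped %d non-autosomal loci at load", n_drop)
        return G.subset(locus_ids=keep)
    return G


def write_ped_map(G: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP re-readable by :func:`read_ped_map` to an equal matrix."""
    with open(map_path, "w") as fh:
        for l in G.loci:
            fh.write(f"{l.chrom}\t{l.id}\t0\t{l.pos_bp}\n")
    a1 = np.array([l.allele1 for l in G.loci], dtype=object)
    a2 = np.array([l.allele2 for l in G.loci], dtype=object)
    with open(ped_path, "w") as fh:
        for i, s in enumerate(G.samples):
            attrs = s.attrs if len(s.attrs) == 5 else (s.population, "0", "0", "0", "-9")
            head = [attrs[0], s.id, *attrs[1:]]
            fields = []
            for j, c in enumerate(G.calls[i]):
                if c == MISSING:
                    fields.append("0 0")
                elif c == 0:
                    fields.append(f"{a1[j]} {a1[j]}")
                elif c == 1:
                    fields.append(f"{a1[j]} {a2[j]}")
                else:
                    fields.append(f"{a2[j]} {a2[j]}")
            fh.write(" ".join(head) + " " + " ".join(fields) + "\n")


def read_pop_table(path) -> dict[str, str]:
    """Two-column TSV sample_id → population."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, pop_table, drop_non_autosomes: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only diploid GT fields are used; the dosage code counts ALT alleles.
    Multiallelic or symbolic sites are skipped with a logged count; ``./.``
    becomes MISSING and phased separators are treated as unphased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    pops = dict(pop_table)
    missing_pops = [s for s in vcf.samples if s not in pops]
    if missing_pops:
        raise ValueError(f"samples absent from population table: {missing_pops}")
    samples = [Sample(s, pops[s]) for s in vcf.samples]

    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0].startswith("<") or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(Locus(vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        cols.append(g)
    if n_skipped:
        logger.info("skipped %d multiallelic/symbolic/non-SNP sites", n_skipped)
    calls = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(samples, loci, calls)
    G.n_skipped_sites = n_skipped
    if drop_non_autosomes:
        G = _drop_non_autosomes(G)
        G.n_skipped_sites = n_skipped
    return G


# ---------------------------------------------------------------------------
# Allele frequencies and missingness
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix, by_population: bool = True) -> pd.DataFrame:
    """Per-(population, locus) frequency of allele2 and gene-copy counts.

    Returns a tidy frame with columns ``population`` (absent when pooled),
    ``locus``, ``p``, ``n_copies``, ``defined``.  ``p`` is NaN (flagged
    undefined) where no copies were observed.
    """
    groups = G.populations if by_population else [None]
    frames = []
    for pop in groups:
        mask = G.pop_mask(pop) if pop is not None else np.ones(G.n_samples, bool)
        calls = G.calls[mask]
        obs = calls != MISSING
        n_copies = 2 * obs.sum(axis=0)
        count2 = np.where(calls == MISSING, 0, calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_copies > 0, count2 / np.maximum(n_copies, 1), np.nan)
        df = pd.DataFrame(
            {
                "locus": G.locus_ids,
                "p": p,
                "n_copies": n_copies,
                "defined": n_copies > 0,
            }
        )
        if pop is not None:
            df.insert(0, "population", pop)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def freq_matrix(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(pops × loci) allele2 frequencies and copy counts, NaN where undefined."""
    pops = G.populations
    P = np.empty((len(pops), G.n_loci))
    N = np.empty((len(pops), G.n_loci), dtype=np.int64)
    for k, pop in enumerate(pops):
        calls = G.calls[G.pop_mask(pop)]
        obs = calls != MISSING
        n = 2 * obs.sum(axis=0)
        c2 = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P[k] = np.where(n > 0, c2 / np.maximum(n, 1), np.nan)
        N[k] = n
    return P, N, pops


def missingness(G: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-locus call rates (non-missing / total)."""
    obs = G.calls != MISSING
    sample_rate = pd.Series(obs.mean(axis=1), index=G.sample_ids, name="call_rate")
    locus_rate = pd.Series(obs.mean(axis=0), index=G.locus_ids, name="call_rate")
    return sample_rate, locus_rate
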