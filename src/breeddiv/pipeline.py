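"""End-to-end pipeline: load → sample QC → SNP sets → diversity →
FST/AMOVA → tree → PCA → LD/Ne → admixture.

A :class:`PipelineConfig` (YAML-serializable) plus a master seed fully
determine every output, stochastic stages included: each stage draws its
own seed from the master by a fixed offset so stages can be rerun in
isolation.  Every removal (sample or SNP) carries a reason code in the
structured JSON-lines log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adx
from . import differentiation as diff
from . import diversity as dv
from . import ldne
from . import ordination as ord_
from . import qc
from . import trees as tr
from .genotypes import GenotypeMatrix, read_ped_map, read_pop_table, read_vcf

logger = logging.getLogger(__name__)

SEED_OFFSETS = {
    "thin": 11,
    "fis_perm": 23,
    "fst_perm": 37,
    "amova": 41,
    "bootstrap": 53,
    "admixture": 67,
}


@dataclass
class PipelineConfig:
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    pop_table: str | None = None
    out_dir: str = "results/pipeline"
    discovery_pops: list[str] = field(default_factory=list)
    min_maf: float = 0.05
    min_snp_call_rate: float = 0.99
    min_sample_call_rate: float = 0.90
    pihat_threshold: float = 0.3
    max_per_pop: int | None = None
    ld_window: int = 100
    ld_step: int = 25
    fis_permutations: int = 10000
    fst_permutations: int = 20000
    amova_permutations: int = 1000
    n_bootstrap: int = 1000
    min_pop_size_fst: int = 8
    ld_max_dist: int = 4_000_000
    ld_bin_width: int = 50_000
    ne_min_pairs: int = 50
    k_values: list[int] = field(default_factory=lambda: [1, 2, 3])
    admixture_replicates: int = 3
    admixture_reps: int = 35000
    admixture_burnin: int = 15000
    admixture_model: str = "correlated"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + SEED_OFFSETS[stage]) % (2**31 - 1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.events: list[dict] = []

    def add(self, stage: str, **info):
        evt = {"stage": stage, **info}
        self.events.append(evt)
        logger.info("%s: %s", stage, info)

    def flush(self):
        with open(self.path, "w") as fh:
            for evt in self.events:
                fh.write(json.dumps(evt, sort_keys=True, default=str) + "\n")


def _load(config: PipelineConfig) -> GenotypeMatrix:
    if config.ped and config.map:
        pops = read_pop_table(config.pop_table) if config.pop_table else None
        return read_ped_map(config.ped, config.map, pop_table=pops)
    if config.vcf:
        if not config.pop_table:
            raise ValueError("VCF input needs a population table")
        return read_vcf(config.vcf, read_pop_table(config.pop_table))
    raise ValueError("config must give ped+map or vcf")


def run_pipeline(config: PipelineConfig, G: GenotypeMatrix | None = None) -> dict:
    """Run every stage; returns a dict of in-memory results and writes the
    full artifact bundle under ``config.out_dir``.

    ``G`` may be passed directly (e.g. a synthetic panel), bypassing file
    input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    results: dict = {}
    stage = "load"
    try:
        if G is None:
            G = _load(config)
        log.add("load", n_samples=G.n_samples, n_loci=G.n_loci,
                n_populations=len(G.populations))

        # ---- sample QC -------------------------------------------------
        stage = "sample_qc"
        cr_set, kept_samples = qc.filter_call_rate(
            G, config.min_snp_call_rate, config.min_sample_call_rate, name="call_rate"
        )
        removed_lowcall = sorted(set(G.sample_ids) - set(kept_samples))
        for s in removed_lowcall:
            log.add("sample_qc", removed_sample=s, reason="low_call_rate")
        G1 = G.subset(sample_ids=kept_samples)

        # kinship within each population with its own allele frequencies:
        # pooled frequencies over a drifted panel would inflate pi-hat for
        # every within-breed pair (breed-shared drift mimics IBD)
        kin_frames = []
        for pop in G1.populations:
            ids = [s.id for s in G1.samples if s.population == pop]
            if len(ids) < 2:
                continue
            sub = G1.subset(sample_ids=ids)
            maf_set = qc.filter_maf(sub, min_maf=0.05, name="ibd_maf")
            if len(maf_set) < 20:
                continue
            kin_frames.append(qc.pihat_matrix(sub.subset(locus_ids=maf_set.locus_ids)))
        kin = pd.concat(kin_frames, ignore_index=True)
        in_kin = set(kin["sample_i"]) | set(kin["sample_j"])
        removed_rel = sorted(in_kin - set(qc.prune_related(kin, threshold=config.pihat_threshold)))
        for s in removed_rel:
            log.add("sample_qc", removed_sample=s, reason="pi_hat_above_threshold")
        G2 = G1.subset(sample_ids=[s for s in G1.sample_ids if s not in set(removed_rel)])

        if config.max_per_pop:
            kept_thin, removed_thin = qc.thin_samples_per_pop(
                G2, config.max_per_pop, seed=config.stage_seed("thin")
            )
            for s in removed_thin:
                log.add("sample_qc", removed_sample=s, reason="random_thinning")
            G2 = G2.subset(sample_ids=kept_thin)
        kin.to_csv(out / "pihat.tsv", sep="\t", index=False)
        results["genotypes_qc"] = G2
        results["kinship"] = kin

        # ---- SNP sets --------------------------------------------------
        stage = "snp_sets"
        snp_sets = qc.build_paper_snp_sets(
            G2,
            discovery_pops=config.discovery_pops,
            min_maf=config.min_maf,
            min_snp_rate=config.min_snp_call_rate,
            window=config.ld_window,
            step=config.ld_step,
        )
        for name, ss in snp_sets.items():
            ss.save(out / f"snp_set_{name}.txt")
            log.add("snp_sets", snp_set=name, n_loci=len(ss))
        # the PCA set: MAF + call rate only, no LD pruning
        cr2, _ = qc.filter_call_rate(G2, config.min_snp_call_rate, 0.0, name="pca_cr")
        pca_set = qc.filter_maf(G2, cr2, min_maf=config.min_maf, name="pca_set")
        results["snp_sets"] = snp_sets
        results["pca_set"] = pca_set

        # ---- diversity -------------------------------------------------
        stage = "diversity"
        div = dv.diversity_table(
            G2, snp_sets, primary="primary",
            n_perm=config.fis_permutations, seed=config.stage_seed("fis_perm"),
        )
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = div

        # ---- FST / AMOVA ----------------------------------------------
        stage = "differentiation"
        theta, pvals = diff.fst_matrix(
            G2, snp_sets["primary"], n_perm=config.fst_permutations,
            seed=config.stage_seed("fst_perm"), min_pop_size=config.min_pop_size_fst,
        )
        theta.to_csv(out / "fst_matrix.tsv", sep="\t")
        if pvals is not None:
            pvals.to_csv(out / "fst_pvalues.tsv", sep="\t")
        big_pops = list(theta.index)
        g_fst = diff.global_fst(G2, snp_sets["primary"], populations=big_pops)
        am = diff.amova(
            G2, snp_sets["primary"], populations=big_pops,
            n_perm=config.amova_permutations, seed=config.stage_seed("amova"),
        )
        with open(out / "amova.json", "w") as fh:
            json.dump({"global_fst": g_fst, **am.as_dict()}, fh, indent=1)
        results["fst_matrix"] = theta
        results["fst_pvalues"] = pvals
        results["global_fst"] = g_fst
        results["amova"] = am

        # ---- tree ------------------------------------------------------
        stage = "tree"
        tree = tr.bootstrap_consensus(
            G2, n_boot=config.n_bootstrap, seed=config.stage_seed("bootstrap"),
            snp_set=snp_sets["primary"],
        )
        tr.write_newick(tree, out / "nj_consensus.nwk")
        results["tree"] = tree

        # ---- PCA -------------------------------------------------------
        stage = "pca"
        pres = ord_.pca(G2, pca_set, n_components=10)
        pres.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": pres.eigenvalues, "explained": pres.explained_fraction}
        ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
        results["pca"] = pres

        # ---- LD / Ne ---------------------------------------------------
        stage = "ld_ne"
        ne_rows = []
        ld_frames = []
        for pop in G2.populations:
            r = ldne.ne_for_population(
                G2, pop, max_dist=config.ld_max_dist, bin_width=config.ld_bin_width,
                min_pairs=config.ne_min_pairs,
            )
            ne_rows.append(
                {"population": pop, "Ne": r["Ne_summary"], "n_loci": r["n_loci"]}
            )
            b = r["bins"].copy()
            b.insert(0, "population", pop)
            ld_frames.append(b)
        pd.DataFrame(ne_rows).to_csv(out / "ne.tsv", sep="\t", index=False)
        if ld_frames:
            pd.concat(ld_frames, ignore_index=True).to_csv(
                out / "ld_decay.tsv", sep="\t", index=False
            )
        results["ne"] = pd.DataFrame(ne_rows)

        # ---- admixture -------------------------------------------------
        stage = "admixture"
        reps_by_k: dict[int, list] = {}
        vif_set = snp_sets["vif01"]
        for K in config.k_values:
            reps_by_k[K] = [
                adx.admixture_gibbs(
                    G2, vif_set, K=K, burnin=config.admixture_burnin,
                    reps=config.admixture_reps, model=config.admixture_model,
                    seed=config.stage_seed("admixture") + 97 * K + rep,
                )
                for rep in range(config.admixture_replicates)
            ]
        lnp = adx.log_prob_of_K(reps_by_k)
        lnp.to_csv(out / "lnP_by_K.tsv", sep="\t", index=False)
        if len(config.k_values) >= 3:
            adx.evanno_delta_k(lnp).to_csv(out / "evanno.tsv", sep="\t", index=False)
        pops_arr = G2.population_of()
        for K, reps in reps_by_k.items():
            aligned = adx.align_replicates([r.Q for r in reps], sample_ids=G2.sample_ids)
            qdf = pd.DataFrame(
                aligned.Q_mean, columns=[f"q{k+1}" for k in range(K)]
            )
            qdf.insert(0, "population", pops_arr)
            qdf.insert(0, "sample", G2.sample_ids)
            qdf.to_csv(out / f"admixture_Q_K{K}.tsv", sep="\t", index=False)
            adx.breed_mean_q(aligned, list(pops_arr)).to_csv(
                out / f"admixture_breed_q_K{K}.tsv", sep="\t", index=False
            )
        results["admixture"] = reps_by_k
        results["lnP_table"] = lnp

        config.save(out / "config.yaml")
        log.flush()
        make_report(out)
        return results
    except Exception:
        log.add(stage, error="stage failed; partial outputs retained")
        log.flush()
        logger.exception("pipeline aborted in stage %r (outputs in %s)", stage, out)
        raise


def make_report(out_dir) -> Path:
    """Assemble a Markdown summary from the artifact bundle on disk."""
    out = Path(out_dir)
    lines = ["# Pipeline report", ""]
    artifacts = {
        "QC + kinship": "pihat.tsv",
        "Diversity table": "diversity.tsv",
        "Pairwise FST": "fst_matrix.tsv",
        "AMOVA": "amova.json",
        "NJ consensus tree": "nj_consensus.nwk",
        "PCA coordinates": "pca_coordinates.tsv",
        "LD decay": "ld_decay.tsv",
        "Effective population size": "ne.tsv",
        "Admixture lnP(K)": "lnP_by_K.tsv",
    }
    for title, fname in artifacts.items():
        f = out / fname
        if not f.exists():
            lines += [f"## {title}", "", "_skipped_", ""]
            continue
        lines += [f"## {title}", ""]
        if f.suffix == ".json":
            data = json.loads(f.read_text())
            lines += [f"- {k}: {v:.4g}" if isinstance(v, float) else f"- {k}: {v}"
                      for k, v in data.items()]
        elif f.suffix == ".nwk":
            lines += ["```", f.read_text().strip(), "```"]
        else:
            df = pd.read_csv(f, sep="\t")
            lines += [df.head(12).to_markdown(index=False)]
        lines += [""]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
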