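"""Run the whole pipeline end-to-end from one config on the panel files.

Everything the numbered drivers do piecewise — QC, SNP sets, diversity,
FST/AMOVA, tree, PCA, LD/Ne, admixture — in one seeded, reproducible
invocation writing a complete artifact bundle plus a Markdown report.
Desk-scale permutation/bootstrap/MCMC sizes keep the run to minutes.
"""

from _common import RESULTS, load_panel, make_panel, panel_paths

from breeddiv.pipeline import PipelineConfig, run_pipeline


def main():
    ped, mp, pops = panel_paths()
    if not ped.exists():
        make_panel()
    cfg = PipelineConfig(
        ped=str(ped), map=str(mp), pop_table=str(pops),
        out_dir=str(RESULTS / "pipeline"),
        fis_permutations=500, fst_permutations=200, amova_permutations=100,
        n_bootstrap=200, k_values=[1, 2, 3], admixture_replicates=2,
        admixture_reps=1000, admixture_burnin=300, seed=9,
    )
    res = run_pipeline(cfg)
    print(f"global FST = {res['global_fst']:.4f}")
    am = res["amova"]
    print(f"AMOVA among-population variance: {am.pct_among_pops:.2f}%")
    print(f"artifact bundle + report under {cfg.out_dir}")


if __name__ == "__main__":
    main()
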