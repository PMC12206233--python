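"""Fit the resilience statistics: beta GLMMs, moderation models, JN regions.

Per network (global, SMN, DMN, ATN, FPN): a logit-link beta mixed model of
NAT on putaminal DaT, PA, education, age, sex, density and sequence with
participant random intercepts (198 observations each); OLS moderation
models of GMP (moderator: PA) and GCP (moderator: education) on mean NAT;
and analytic Johnson-Neyman significance regions. Writes the coefficient
tables and JN regions to results/ and prints the key effects.
"""

import pathlib

import pandas as pd

from natpipe.pipeline import RunConfig, _glmm_long_table, _jn_long_table, \
    _moderation_long_table, _write_tsv, fit_stage

SEED = 1
ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def load_inputs():
    cohort = pd.read_csv(RESULTS / "cohort.tsv", sep="\t")
    nat = pd.read_csv(RESULTS / "nat_table.tsv", sep="\t")
    mean_nat = pd.read_csv(RESULTS / "mean_nat.tsv",
                           sep="\t").set_index("participant")
    comps = pd.read_csv(RESULTS / "composites.tsv",
                        sep="\t").set_index("participant")
    pa = pd.read_csv(RESULTS / "lifetime_pa.tsv",
                     sep="\t").set_index("participant")["pa"]
    cohort["pa"] = cohort["participant"].map(pa)
    return cohort, nat, mean_nat, comps, pa


def main():
    cohort, nat, mean_nat, comps, pa = load_inputs()
    cfg = RunConfig(out_dir=str(RESULTS), seed=SEED)
    glmm, mod, jn = fit_stage(cohort, nat, mean_nat, comps, pa, cfg)
    _write_tsv(_glmm_long_table(glmm), RESULTS / "glmm_coefficients.tsv")
    _write_tsv(_moderation_long_table(mod),
               RESULTS / "moderation_coefficients.tsv")
    _write_tsv(_jn_long_table(jn), RESULTS / "jn_regions.tsv")

    smn = glmm["SMN"].table.loc["dat"]
    atn = glmm["ATN"].table.loc["education"]
    print(f"DaT -> SMN NAT: beta={smn.estimate:.3f}, p={smn.p:.4f}")
    print(f"education -> ATN NAT: beta={atn.estimate:.4f}, p={atn.p:.4f}")
    for net in ("global", "SMN"):
        fit = mod[("gmp", net)]
        row = fit.table.loc["nat"]
        inter = fit.table.loc[fit.interaction_term]
        region = jn[("gmp", net)]
        print(f"{net}: NAT -> GMP beta={row.estimate:.1f} (p={row.p:.3f}); "
              f"NATxPA beta={inter.estimate:.2f} (p={inter.p:.3f}); "
              f"JN {region.status} "
              f"{[(round(l, 2), round(u, 2)) for l, u, _ in region.regions]}")
    gcp_f = {net: mod[("gcp", net)].f_pvalue
             for net in ("global", "SMN", "DMN", "ATN", "FPN")}
    print("GCP model F-test p-values:",
          {k: round(v, 3) for k, v in gcp_f.items()})


if __name__ == "__main__":
    main()
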