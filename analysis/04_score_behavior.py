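"""Score lifestyle and behavior: lifetime PA, test batteries, composites.

Evaluates the WEE formula on the activity diaries (19-35 and 35-50 year
periods only), generates the motor/cognitive batteries (their planted
motor structure depends on each participant's realized global NAT), and
z-standardizes PD scores against the 39 HC to form GMP and GCP. Writes
mean NAT per network, lifetime PA and the composite table to results/.
"""

import pathlib

import pandas as pd

from natpipe.attack import mean_nat_table
from natpipe.behavior import composite_scores, composites_frame, \
    lifetime_pa_from_diary
from natpipe.pipeline import _write_tsv
from natpipe.synthetic import CohortConfig, generate_batteries, \
    generate_cohort

SEED = 1
ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    cfg = CohortConfig(seed=SEED)
    profiles = generate_cohort(cfg)
    nat = pd.read_csv(RESULTS / "nat_table.tsv", sep="\t")
    wide = mean_nat_table(nat)
    _write_tsv(wide.reset_index(), RESULTS / "mean_nat.tsv")

    diaries = pd.read_csv(RESULTS / "diaries.tsv", sep="\t")
    pa = lifetime_pa_from_diary(diaries)
    _write_tsv(pa.rename_axis("participant").reset_index(),
               RESULTS / "lifetime_pa.tsv")

    nat_global = wide["nat_global"]
    lookup = {p.id: nat_global.get(p.id, 0.5) for p in profiles}
    batteries = generate_batteries(profiles, lookup, cfg)
    pd_batts = [b for b, p in zip(batteries, profiles) if p.group == "PD"]
    hc_batts = [b for b, p in zip(batteries, profiles) if p.group == "HC"]
    comps = composites_frame(composite_scores(pd_batts, hc_batts))
    _write_tsv(comps.reset_index(), RESULTS / "composites.tsv")

    print(f"lifetime PA (PD): median "
          f"{pa[[p.id for p in profiles if p.group == 'PD']].median():.1f}")
    print(f"GMP mean {comps.gmp.mean():.2f} (sd {comps.gmp.std():.2f}); "
          f"GCP missing for {comps.gcp.isna().sum()} participant(s)")


if __name__ == "__main__":
    main()
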