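"""Synthesize the study cohort: 22 PD + 39 HC with covariates and diaries.

Writes the participant table and the long-format activity diaries under
results/. ROI time series are regenerated deterministically by later
stages (same seed), so they are not persisted here.
"""

import pathlib

import pandas as pd

from natpipe.atlas import synthetic_atlas, write_atlas
from natpipe.synthetic import CohortConfig, generate_cohort, generate_diary, \
    profiles_frame

SEED = 1
RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    profiles = generate_cohort(cfg)
    frame = profiles_frame(profiles)
    frame.to_csv(RESULTS / "cohort.tsv", sep="\t", index=False,
                 float_format="%.12g")
    diaries = pd.concat([generate_diary(p, cfg) for p in profiles],
                        ignore_index=True)
    diaries.to_csv(RESULTS / "diaries.tsv", sep="\t", index=False,
                   float_format="%.12g")
    write_atlas(synthetic_atlas(), RESULTS / "atlas.tsv")

    pd_rows = frame[frame.group == "PD"]
    print(f"cohort: {len(frame)} participants "
          f"({len(pd_rows)} PD, {(frame.group == 'HC').sum()} HC)")
    print(f"PD age {pd_rows.age.mean():.1f} ({pd_rows.age.std():.1f}), "
          f"DaT z {pd_rows.dat.mean():.2f} ({pd_rows.dat.std():.2f}), "
          f"PA median {pd_rows.pa.median():.1f}")
    print(f"sequences (PD): {pd_rows.sequence.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
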