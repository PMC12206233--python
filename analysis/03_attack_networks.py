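"""Attack every network at nine densities and tabulate NAT.

For each PD participant, the whole-brain graph and the four subnetworks
(SMN, DMN, FPN, ATN) are proportionally thresholded at 10%..50%, binarized,
and attacked by iterative removal of the highest-degree node; the
normalized area under the efficiency curve is the NAT score. Writes the
990-row long table (22 PD x 5 networks x 9 densities) to results/.
"""

import pathlib
import time

import numpy as np
import pandas as pd

from natpipe.atlas import synthetic_atlas
from natpipe.attack import nat_table
from natpipe.connectome import ConnectivityMatrix
from natpipe.pipeline import _write_tsv

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    atlas = synthetic_atlas()
    cohort = pd.read_csv(ROOT / "results" / "cohort.tsv", sep="\t")
    pd_ids = cohort.loc[cohort.group == "PD", "participant"]
    matrices = {}
    for pid in pd_ids:
        values = np.loadtxt(ROOT / "scratch" / "matrices" / f"{pid}.tsv",
                            delimiter="\t")
        matrices[pid] = ConnectivityMatrix(values=values,
                                           roi_ids=atlas.roi_ids)
    t0 = time.perf_counter()
    nat = nat_table(matrices, atlas)
    _write_tsv(nat, ROOT / "results" / "nat_table.tsv")
    print(f"{len(nat)} NAT records in {time.perf_counter() - t0:.0f}s")
    summary = nat.groupby("network")["nat"].agg(["mean", "min", "max"])
    print(summary.round(3))


if __name__ == "__main__":
    main()
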