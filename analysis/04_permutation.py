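#!/usr/bin/env python
"""Pseudo-group permutation validation of the INS increase.

Reassigns all participants to new triads (roles preserved) 200 times,
recomputes the group-mean dz at the coupled pair for each pseudo assignment,
and locates the true pairing in that null distribution.
"""

from pathlib import Path

import pandas as pd

from hypersync.config import SimConfig
from hypersync.permutation import PermutationScheme, null_distribution
from hypersync.synth import simulate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "04_permutation"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    groups, _ = simulate_study(SimConfig(seed=1))
    res = null_distribution(groups, PermutationScheme(n_perm=200, seed=1))
    df = pd.DataFrame({
        "pair": ["3-3"], "dyad": [res["dyad"]],
        "observed_mean_dz": [res["observed"]],
        "null_q2.5": [res["q2.5"]], "null_q97.5": [res["q97.5"]],
        "p_empirical": [res["p"]],
    })
    df.to_csv(OUT / "null_summary.tsv", sep="\t", index=False,
              float_format="%.5g")
    pd.DataFrame({"null_mean_dz": res["null"]}).to_csv(
        OUT / "null_samples.tsv", sep="\t", index=False, float_format="%.5g")
    print(df.round(4).to_string(index=False))
    print("true pairing exceeds the 97.5th null percentile:"
          f" {res['observed'] > res['q97.5']}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
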