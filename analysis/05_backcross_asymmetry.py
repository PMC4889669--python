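#!/usr/bin/env python
"""Recombination-dependent backcross asymmetry.

With a jointly-lethal linked pair far from the assay marker, backcrosses
through achiasmatic F1 females (whole chromosomes transmitted intact) are
fully distorted at the assay marker while backcrosses through recombining F1
males stay near 1:1.  Runs one illustrative seeded panel of all eight
backcross types plus the 100-seed contrast summary.  Writes
results/backcross_contrast.tsv.
"""

from pathlib import Path

import pandas as pd

from dmscan import gof_test, marginal_counts
from dmscan import experiments as ex
from dmscan.simulate import simulate_backcross_panel

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921


def main() -> None:
    panel = ex.backcross_contrast_panel()
    vm = ex.jointly_lethal_viability()
    tables = simulate_backcross_panel(panel, 200, SEED, viability=vm)
    rows = []
    for label, t in tables.items():
        counts = marginal_counts(t, "M")
        res = gof_test(counts, t.design_of(0).expected_ratio())
        rows.append(
            {"cross": label, "n_het": counts.n[1],
             "n_hom_recurrent": counts.n[0] + counts.n[2],
             "chi2": res.statistic, "p": res.p_value,
             "significant": int(res.p_value < 0.05 / 8)}
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "backcross_contrast.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(df.to_string(index=False))

    summary = ex.backcross_asymmetry(SEED, n_seeds=100, n=200)
    print(
        f"\nover {summary['n_seeds']} seeds: female-F1 crosses to the "
        f"incompatible background distorted in {summary['female_sig_rate']:.0%} "
        f"of tests, male-F1 in {summary['male_sig_rate']:.0%}; full contrast "
        f"holds in {summary['success_rate']:.0%} of seeds"
    )


if __name__ == "__main__":
    main()
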