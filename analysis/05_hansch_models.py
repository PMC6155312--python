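#!/usr/bin/env python
"""2D descriptor (Hansch/Free-Wilson) modelling.

Part 1 evaluates the frozen published equation on a small descriptor grid
(its own table was never published, so it is evaluable but not refittable).
Part 2 simulates a 21-compound descriptor table from that equation with
noise sd 0.321 (the published residual SE), refits it, and runs the
exhaustive subset search.  Writes results/hansch_search.csv.
"""

from pathlib import Path

import pandas as pd

from comsiakit import EQ1, eq1_predict, exhaustive_subset_search, mlr_fit
from comsiakit.hansch import search_table
from comsiakit.synthetic import generate_hansch_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    probe = pd.DataFrame([
        {"CMR": 0.0, "S": 0, "pi_x": 0.0, "pi_y": 0.0},
        {"CMR": 10.0, "S": 1, "pi_x": 0.0, "pi_y": 0.0},
        {"CMR": 12.0, "S": 1, "pi_x": 1.0, "pi_y": 1.0},
    ])
    print("frozen equation spot checks (pEC50):")
    for _, row in probe.iterrows():
        print(f"  CMR={row.CMR:4.1f} S={int(row.S)} pix={row.pi_x} "
              f"piy={row.pi_y} -> {eq1_predict(dict(row)):.3f}")

    df, y = generate_hansch_table(n=21, noise_sd=0.321, seed=SEED)
    refit = mlr_fit(df, y, EQ1.terms)
    print("\nrefit on simulated table (n=21, noise sd 0.321):")
    print(" ", refit.summary().replace("\n", "\n  "))

    models = exhaustive_subset_search(df, y, list(EQ1.terms), max_terms=5)
    tab = search_table(models)
    tab.round(4).to_csv(OUT / "hansch_search.csv", index=False)
    print(f"\nsubset search: {len(models)} models; top terms "
          f"{'+'.join(models[0].terms)} (q2={models[0].q2:.3f})")
    print(f"wrote {OUT / 'hansch_search.csv'}")


if __name__ == "__main__":
    main()
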