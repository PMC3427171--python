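#!/usr/bin/env python
"""Trans-splicing kinetics of the split constructs.

Generates three replicate ligated-product time courses per split pairing
from the pseudo-first-order model A(t) = A0(1 - e^{-kt}) at the published
rate constants (SP102: 9.0e-3 1/s, ~80% plateau; SP36: 6.2e-4 1/s, ~65%
plateau) with densitometry noise, then refits each globally across
replicates and reports k, plateau, half-life, and early yields.

Writes results/pts_kinetics.tsv.
"""

import pandas as pd

from splitscan.pts import fit_first_order, yield_at
from splitscan.simulate import gen_pts_timecourse

# pairing -> (k 1/s, plateau)
TRUTH = {"SP102": (9.0e-3, 0.80), "SP36": (6.2e-4, 0.65)}
NOISE_SD = 0.02
OUT = "results/pts_kinetics.tsv"


def main() -> None:
    rows = []
    for i, (name, (k, a0)) in enumerate(TRUTH.items()):
        tcs = gen_pts_timecourse(k, a0, replicates=3, noise_sd=NOISE_SD,
                                 seed=600 + i)
        fit = fit_first_order(tcs)
        rows.append(
            {
                "pairing": name,
                "k_per_s": f"{fit.k_per_s:.2e}",
                "k_se": f"{fit.k_se:.1e}",
                "plateau": round(fit.a0, 3),
                "t_half_min": round(fit.t_half_min, 2),
                "yield_5min": round(yield_at(fit, 300.0), 3),
                "yield_60min": round(yield_at(fit, 3600.0), 3),
                "n_replicates": fit.n_replicates,
            }
        )
        print(
            f"{name}: k = {fit.k_per_s:.2e} +/- {fit.k_se:.1e} 1/s "
            f"(truth {k:.1e}), t1/2 = {fit.t_half_min:.2f} min, "
            f"plateau {fit.a0:.2f}"
        )

    df = pd.DataFrame(rows)
    df.to_csv(OUT, sep="\t", index=False)
    print(
        f"\nTable written to {OUT}.  The naturally split pairing (SP102) "
        "ligates with a ~1.3 min half-life and is near-complete by 5 min; "
        "the engineered N-proximal pairing (SP36) is ~15-fold slower "
        "(t1/2 ~ 19 min) but still reaches its ~65% plateau within an hour "
        "- fast for a split site this close to the N-terminus."
    )


if __name__ == "__main__":
    main()
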