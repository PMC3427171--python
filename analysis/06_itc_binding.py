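#!/usr/bin/env python
"""Fragment self- and cross-association by single-site ITC analysis.

Generates synthetic titrations (1.4 mL cell, 30 x 5 uL injections, 25 C)
for the cognate pairings at their published affinities (SP102 pair: Kd
1.7 nM, dH -36.6 kcal/mol; SP36 pair: 1.2 uM, -16.6 kcal/mol), one
measurable cross-pairing, and one non-binding cross-pairing, fits the
single-site model to each, and tabulates Kd, dH, dG, TdS with the affinity
fold ratio between the cognate pairs.

Writes results/itc_binding.tsv.
"""

import numpy as np

from splitscan.itc import affinity_fold_ratio, cross_pairing_report, fit_single_site
from splitscan.simulate import gen_itc_isotherm

OUT = "results/itc_binding.tsv"

# pairing -> (Kd M, dH kcal/mol, cell uM, syringe uM) or None for no binding
TRUTH = {
    "SP102N/SP102C": (1.7e-9, -36.6, 0.5, 7.5),
    "SP36N/SP36C": (1.2e-6, -16.6, 20.0, 300.0),
    "SP102N/SP36C": (5.0e-6, -12.0, 40.0, 600.0),
    "SP36N/SP102C": None,
}


def main() -> None:
    fits = {}
    for i, (name, truth) in enumerate(TRUTH.items()):
        if truth is None:
            fits[name] = None
            print(f"{name}: no detectable binding")
            continue
        kd, dh, cell, syringe = truth
        clean = gen_itc_isotherm(kd, dh, cell_conc_um=cell, syringe_conc_um=syringe)
        sd = 0.01 * np.abs(clean.heats_ucal).max()
        iso = gen_itc_isotherm(kd, dh, cell_conc_um=cell, syringe_conc_um=syringe,
                               noise_sd_ucal=sd, seed=700 + i)
        fit = fit_single_site(iso)
        fits[name] = fit
        print(
            f"{name}: Kd = {fit.kd_molar:.2e} M (truth {kd:.1e}), "
            f"dH = {fit.dh_kcal:.1f} kcal/mol, dG = {fit.dg_kcal:.2f}, "
            f"TdS = {fit.tds_kcal:.2f}, n = {fit.n:.2f}"
        )

    report = cross_pairing_report(fits)
    report.to_csv(OUT, sep="\t", index=False)

    ratio, _ = affinity_fold_ratio(fits["SP36N/SP36C"], fits["SP102N/SP102C"])
    print(
        f"\nTable written to {OUT}.  The SP36 pairing binds ~{ratio:.0f}-fold "
        "more weakly than the naturally split SP102 pairing; the difference "
        "is carried almost entirely by binding enthalpy, and the weakest "
        "cross-pairing (SP36N/SP102C) shows no measurable association - the "
        "orthogonality that makes the two split systems usable side by side."
    )


if __name__ == "__main__":
    main()
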