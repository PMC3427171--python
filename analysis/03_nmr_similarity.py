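#!/usr/bin/env python
"""Chemical-shift similarity of a CP variant against the parent protein.

Generates a synthetic backbone shift-table pair in which the CP36 variant
differs from the parent only by amide perturbations planted at
termini-proximal residues (2, 35, 71, 119, 136 — the old and new chain
ends), then computes both similarity statistics through the CP residue map:

* composite amide CSP, Δδ_N+NH = sqrt((Δδ_NH² + Δδ_N²/25)/2), with a
  mean + 1 SD significance cutoff;
* smoothed secondary-shift difference ΔΔδ = Δ(Δδ_Cα − Δδ_Cβ).

A well-chosen split site perturbs only the chain ends, so the significant
CSP set should equal the planted set and ΔΔδ should stay small everywhere.

Writes results/csp_profile.tsv and results/delta_delta.tsv.
"""

from splitscan.shifts import csp, delta_delta, secondary_shift
from splitscan.simulate import gen_shift_pair

PLANTED = (2, 35, 71, 119, 136)


def main() -> None:
    reference, variant, cmap = gen_shift_pair(
        n=137, perturb_sites=PLANTED, cp_site=36, linker_len=3, seed=3
    )

    csp_profile = csp(variant, reference, residue_map=cmap)
    csp_profile.to_csv("results/csp_profile.tsv", sep="\t", index=False)
    significant = sorted(csp_profile.loc[csp_profile["significant"], "residue"])

    dd = delta_delta(
        secondary_shift(variant), secondary_shift(reference), residue_map=cmap
    )
    dd.to_csv("results/delta_delta.tsv", sep="\t", index=False)

    print(f"CSP computed for {len(csp_profile)} mappable residues "
          f"(cutoff {csp_profile.attrs['cutoff']:.3f} ppm).")
    print(f"Significant residues: {significant}")
    print(f"Planted perturbations: {sorted(PLANTED)} -> "
          f"{'recovered exactly' if significant == sorted(PLANTED) else 'MISMATCH'}")
    print(f"Max |ΔΔδ| across mapped residues: "
          f"{dd['delta_delta'].abs().max():.2f} ppm "
          "(values well below 2 ppm indicate a conserved secondary structure).")


if __name__ == "__main__":
    main()
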