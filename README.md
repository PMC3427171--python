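# splitscan

Tools for turning **circular-permutation (CP) viability predictions into
split-protein designs**, and for quantitatively validating those designs.

A circular permutant joins a protein's native termini and opens the backbone
at an internal site; a split protein opens the same bond but expresses the
two pieces separately. The premise this package operationalizes is that a
backbone opening tolerated in a circular permutant is a strong candidate for
a split site. Given a per-residue CP-viability score profile (0–1, as
produced by a CP predictor from a structure), `splitscan` selects and ranks
candidate split sites, builds the corresponding constructs, and provides the
four quantitative assays used to validate them — with synthetic-data
generators so the whole chain runs and is tested without any experimental
download. The reference system throughout is a 137-residue DnaE intein
split at residue 36, which yields an N-fragment short enough for chemical
synthesis while retaining fast protein trans-splicing.

## What it computes

**Site selection** (`splitscan.sites`). Favorable sites are strict local
maxima of the score profile (±3-residue window by default) with score > 0.7
(scores < 0.5 mark invalid openings); candidates must be ≥ `min_sep`
residues from active-site residues and ties are broken toward the
N-terminal half. Gaps (residues without scores, e.g. missing coordinates)
are "no call", never zero.

**Construct design** (`splitscan.design`). For split site *i* (the bond
between residues *i* and *i+1*) of an *n*-residue parent:
CP = parent[i+1..n] + GSS + parent[1..i]; SP = the fragment pair
(parent[1..i], parent[i+1..n]); precursor = the permuted chain with a
self-excising CFNGSS junction. A position map connects CP and native
numbering for spectral comparison.

**NMR similarity** (`splitscan.shifts`). Secondary shifts
Δδ_Cα − Δδ_Cβ against a pinned random-coil table, 3-residue smoothed, with
the between-variant difference ΔΔδ; and the composite amide perturbation
Δδ_N+NH = [(Δδ_NH² + Δδ_N²/25)/2]^½ with a mean + 1 SD significance cutoff.

**Unfolding thermodynamics** (`splitscan.melt`). Two-state van't Hoff
analysis of a CD melt: linear baselines → folded fraction →
ln K = −ΔH/RT + ΔS/R regression (K = [D]/[F]), with self-consistent
baseline refinement and a maximum-likelihood polish; reports ΔH, ΔS, both
T_M definitions, and TΔS and ΔG at 298 K.

**Trans-splicing kinetics** (`splitscan.pts`). Global fit of
A(t) = A₀(1 − e^(−kt)) across replicates; t½ = ln 2/k in minutes.

**Binding** (`splitscan.itc`). Single-site total-heat isotherm fit with
displaced-volume correction for (n, K_d, ΔH) plus a dilution offset;
ΔG = RT ln K_d, TΔS = ΔH − ΔG, affinity fold ratios and cross-pairing
reports.

## Worked example

```python
from splitscan.simulate import gen_score_profile, gen_melt_curve
from splitscan.sites import rank_candidates
from splitscan.melt import fit_melt

profile = gen_score_profile(137, peaks=[(12, 0.55, 3.0), (36, 0.55, 3.0),
                                        (102, 0.5, 3.0)],
                            noise_sd=0.03, seed=20120824)
for c in rank_candidates(profile, active_sites=[1, 137], min_sep=10):
    print(c.rank, c.site, round(c.score, 3))

fit = fit_melt(gen_melt_curve(77.3, 226.7, noise_sd=0.15, seed=104))
print(f"T_M {fit.tm_c:.1f} C, dH {fit.dh_kcal:.1f} kcal/mol, "
      f"dG(298K) {fit.dg_kcal:.2f} kcal/mol")
```

prints

```
1 12 0.876
2 36 0.835
3 102 0.798
T_M 67.9 C, dH 76.9 kcal/mol, dG(298K) 9.69 kcal/mol
```

— the three planted viable sites ranked with the N-terminal ones first, and
a split-construct melt whose fitted unfolding enthalpy (76.9 ± ~1 kcal/mol
here) recovers the generating value of 77.3 within noise, with a folding
free energy still favorable at 25 °C.

The full analysis chain lives in `analysis/01_select_split_sites.py` …
`analysis/06_itc_binding.py`; each script prints what it found and writes a
table under `results/`. A `splitscan` CLI exposes the same steps
(`splitscan scan`, `design`, `nmr-compare`, `melt-fit`, `pts-fit`,
`itc-fit`, `simulate`).

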