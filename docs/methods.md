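# Methods

This note documents the models behind each `splitscan` module, the defaults
that matter, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Site selection from CP-score profiles

A CP-viability profile assigns each residue a score in [0, 1]; the package
consumes these profiles (it does not compute them from structure — that is
the job of an upstream predictor). "Split site *i*" always means the
peptide bond between residues *i* and *i+1*, 1-based.

*Local maximum.* A residue is a local maximum when its score is ≥ every
score within ±3 residues (window 7; configurable, odd, ≥ 3) and strictly
greater than at least one of them. Plateaus report their leftmost residue.
Windows truncate at gaps — missing residue indices or rows without a score
(e.g. unresolved loops in the underlying structure) — so scores are never
compared across a break. Gap residues are "no call", deliberately distinct
from score 0, which asserts an invalid opening.

*Classification.* Favorable iff score > 0.7, unfavorable iff score < 0.5,
otherwise indeterminate. Both comparisons are strict and both thresholds
configurable. The 0.7/0.5 defaults reflect the empirical behavior of such
scores: essentially all known-functional split sites score above 0.7, while
scores below 0.5 track invalid openings (about half the sites between the
thresholds work, hence "indeterminate").

*Ranking.* Candidates are favorable local maxima. Sites closer than
`min_sep` (default 10 residues, sequence separation) to any active-site
residue are dropped; the default is a deliberate placeholder — "moderate
separation from the active site" has no published number — and is flagged
as configurable for that reason. Sequence separation, not spatial distance,
is the filter because it needs no structure; when Cα coordinates are
supplied the minimum Cα–Cα distance to the active site is annotated but
never filters. Ordering is by score descending with ties (at 0.01
resolution) broken toward the N-terminal half, then toward the lower index.
The N-half preference is a soft criterion only — a short N-fragment is
chemically synthesizable, which is what makes N-proximal split sites
valuable — so it acts only as a tie-break.

## Construct design

Mutations are given in native numbering (e.g. the catalytic knockouts C1G
and N137A used to trap inactive complexes) and applied before permutation.
The CP linker default GSS and the precursor junction CFNGSS are the
standard choices for this system: CFN is an optimal splicing junction, so a
single-chain permuted precursor with intact catalytic termini excises the
linker in vivo, releasing exactly the two split fragments. Length
invariants (CP = n + linker; SP fragments = i and n − i; composition
conservation) are enforced by tests, and `cp_residue_map` provides the
bijection between CP positions and native numbering (linker positions map
to a tag) used by every cross-numbering comparison.

## NMR shift analytics

*Secondary shifts.* raw = (δ_Cα − rc_Cα) − (δ_Cβ − rc_Cβ), with random-coil
values taken from a pinned, versioned table (Wishart 1995 values shipped as
`data/random_coil_wishart1995.tsv`); glycine uses the Cα term only. The
published analyses of this kind do not name their random-coil table, so
per-residue values are not bit-reproducible against any particular figure;
the table is pinned to make *this* package reproducible, and comparisons
are treated as qualitative. Smoothing is a 3-residue running mean using
available values only, requiring ≥ 2 contributors (chain ends and gap edges
average over what exists). Secondary-structure calls use |smoothed| > κ
with κ = 0.7 ppm by default; sign-only mode (κ = None) is available since
the sign alone distinguishes helix (+) from strand (−).

*CSP.* Δδ_N+NH = [(Δδ_NH² + Δδ_N²/25)/2]^½ exactly; the 1/25 weight
compresses the ¹⁵N difference by its larger dispersion. Prolines and
unassigned residues drop out (no amide); at least 5 mappable residues are
required. Significance defaults to mean + 1 SD over computed values — a
rule chosen here because published "significant shift" calls of this kind
are typically visual — with an absolute-ppm override.

## Two-state unfolding thermodynamics

The equilibrium model has exactly two states with temperature-independent
ΔH (no ΔCp term). The unfolding constant K = [D]/[F] = (1 − f)/f obeys
ln K = −ΔH/RT + ΔS/R; R = 1.987 cal mol⁻¹ K⁻¹, ΔH reported in kcal mol⁻¹,
ΔS in cal mol⁻¹ K⁻¹, and derived quantities TΔS = T_ref·ΔS and
ΔG = ΔH − TΔS at T_ref = 298 K (configurable). Both midpoint definitions
are reported: the f = 0.5 crossing of the curve (linear interpolation) and
ΔH/ΔS; they agree to ~0.1 °C on well-behaved data, and when the melt lies
beyond the scanned range the crossing is reported absent (the ">T_max"
case) rather than extrapolated.

Estimation proceeds in three stages:

1. **Baselines.** Linear θ_F(T), θ_D(T) fit on pre/post-transition windows
   (user-specified, or `auto` = outer 15% of the range). Degenerate
   baselines (no spectroscopic separation) raise; windows that cross inside
   the range warn.
2. **van't Hoff regression.** f = (θ − θ_D)/(θ_F − θ_D), clipped to [0, 1];
   points with f outside (0.05, 0.95) are excluded to keep ln K finite and
   the regression conditioned (≥ 5 points required); OLS of ln K on 1/T.
3. **Refinement.** Fixed windows always contain some minority-state
   population, which biases the baselines and hence ΔH. `fit_melt`
   therefore iterates: the current (ΔH, ΔS) predicts the minority fraction
   at each window point, its contribution is subtracted before the lines
   are refit, and the regression repeats until ΔH converges. A final
   nonlinear least-squares fit of the full six-parameter ellipticity model
   (ΔH, ΔS, both baselines), seeded by the regression, is the reported
   estimate: for Gaussian noise on the ellipticity it is the
   maximum-likelihood estimator, whereas the ln K transform weights noise
   near the fraction bounds very unevenly. On noiseless two-state data all
   three stages agree and recover the generating parameters to machine
   precision; under 2% ellipticity noise the polished fit recovers ΔH with
   ~2–3% median error where the plain regression scatters tenfold wider.

Fit standard errors come from the regression (stage 2) or the NLLS Jacobian
(stage 3). Published error bars for this kind of analysis are not
reproducible without the raw scans and fit windows, so tests pin the
derived-quantity arithmetic and generator round-trips instead.

## Trans-splicing kinetics

A(t) = A₀(1 − e^(−kt)) with (k, A₀) shared across replicates and every
point weighted equally; unweighted least squares by default (densitometry
errors are rarely reported), soft-L1 loss behind a flag. A₀ is bounded
(0, 1.05] — densitometry can slightly exceed 1, and observed plateaus
(~0.65–0.8) sit well below it. Initial guesses: A₀ from the maximum
observed fraction, k from the earliest usable point via
k ≈ −ln(1 − A/A₀)/t. t½ = ln 2/k is reported in minutes. The
excess-short-fragment assumption that makes the reaction pseudo-first-order
is recorded but not modelled: the fit is strictly single-exponential, and
no attempt is made to resolve branched intermediates.

## ITC single-site binding

Standard single-site total-heat model. After injection *i* (cumulative
volume V_i into a cell of volume V₀), concentrations follow the
continuous-displacement dilution M_i = M₀e^(−V_i/V₀),
X_i = X₀(1 − e^(−V_i/V₀)); the complex concentration is the closed-form
root of the binding quadratic; and the per-injection heat is the difference
of total heat contents plus the displaced-volume correction
(dV_i/V₀)(Q_i + Q_{i−1})/2 and a constant dilution offset fit jointly (no
separate blank). Parameters (n, K_d, ΔH, offset) by nonlinear least
squares with K_d in log space; the first injection is excluded by default
(syringe-tip diffusion); a c-value n·K_a·M₀ outside [1, 10⁴] warns that the
affinity is shape-underdetermined. ΔG = RT ln K_d at the experiment
temperature (25 °C default geometry), TΔS = ΔH − ΔG, so thermodynamic
closure is exact by construction.

The default geometry is 1.4 mL cell, 30 × 5 µL injections, 25 °C.
Concentrations are explicit arguments: the c-value, not a fixed
concentration, decides whether an isotherm determines K_d, so each
experiment (nanomolar vs micromolar pairings) chooses cell/syringe
concentrations to land at a usable c-value.

## Synthetic data and what passing tests show

Every generator inverts the forward model its analysis module fits, with
independent Gaussian noise per observation and all randomness through a
seeded generator (fixed seed ⇒ byte-identical output). Defaults are the
study conditions: melt parameters from the published unfolding table, PTS
rate constants 9.0×10⁻³ and 6.2×10⁻⁴ s⁻¹ with plateaus 0.8/0.65, binding
affinities 1.7 nM and 1.2 µM with ΔH −36.6/−16.6 kcal mol⁻¹, score
profiles with favorable maxima planted at sites 12/36/102 of a 137-residue
chain, and shift pairs with amide perturbations planted at the
termini-proximal residues 2/35/71/119/136. Noise magnitudes are
instrument-plausible and documented per generator (CD ~1–2% of the
ellipticity range; densitometry 2–3% absolute; ITC ~1% of the largest
heat).

Because generator and fitter share the model family, recovery tests
demonstrate *estimator correctness and calibration* — not that real data
follow the model. Real melts have sloped, curved baselines and sometimes
ΔCp ≠ 0; real densitometry has correlated, non-Gaussian errors; real
isotherms have drifting dilution heats; real shift perturbations are not
confined to planted sites. The analysis drivers under `analysis/` should
be read with that in mind: their tables show the pipeline reproducing known
inputs through realistic noise, which is the strongest claim synthetic data
can support.

Problem sizes used by the test suite and drivers (137-residue profiles,
141-point melts, 12-point × 3-replicate time courses, 30-injection
isotherms, 10–100-seed calibration studies) match the scale of the real
experiments they emulate.

## Known limitations

- Site selection consumes scores; it cannot rescue a poor upstream
  predictor, and the `min_sep` default is a placeholder judgment.
- The melt model excludes ΔCp and multi-state unfolding; strongly curved
  pre-transition baselines will bias ΔH.
- The PTS fit reports a single apparent rate constant; published bounds of
  the form "k > x, t½ > y" can be internally inconsistent with t½ = ln 2/k
  and are reported as given, not reconciled.
- The ITC module fits one site class only; competitive or multi-site
  titrations are out of scope, as is raw power-trace integration.
- NMR analytics compare assigned shift tables; peak picking, assignment,
  and structure calculation are upstream of this package.
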