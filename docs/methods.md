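# Methods

This note records the models behind `oxidha`, the defaults and why they were
chosen, and what the simulation-based tests do and do not demonstrate.

## Isomer model and the double-bond shift rule

A fatty-acid chain is numbered from the carboxyl carbon (C1); a double bond
Δd joins Cd and Cd+1. Oxygenation (ene-type or radical addition) at one
carbon of a double bond converts that carbon to sp³ and moves the bond one
position away from the oxygen, with *E* geometry:

* proximal carbon *n* of Δn: Δn → Δ(n+1) *E*;
* distal carbon *n* of Δ(n−1): Δ(n−1) → Δ(n−2) *E*.

All other bonds keep position and geometry, so the bond count (six for DHA
derivatives) is conserved and exactly twelve positions per series are
constructible (4, 5, 7, 8, 10, 11, 13, 14, 16, 17, 19, 20); any other
position raises. The full per-isomer rearranged layout is not tabulated in
the primary sources, so the rule is validated two ways: it reproduces the
literature structures of 5-HETE (6*E*,8*Z*,11*Z*,14*Z*) and 12-HETE
(5*Z*,8*Z*,10*E*,14*Z*) from arachidonate, and the fragment masses computed
from the resulting layouts match the printed SRM product ions (below).
Isomers whose printed transitions cannot be matched under this layout are
reported as `unassigned` rather than silently re-fitted.

Stereochemistry (R/S), UV-spectroscopic distinction of conjugated dienes,
and secondary products (epoxides, neuroprostanes, neurofurans, aldehydes)
are out of scope. Z/E geometry is carried for documentation; it never enters
a mass.

## Masses

Monoisotopic constants (C 12.000000, H 1.0078250319, O 15.9949146,
D 2.0141018, electron 0.0005486 Da) are named module constants so the test
oracles agree bit-for-bit. Anion m/z includes the electron mass
(m = Σ atoms − H + e⁻). Deuterium in the d8 internal standards is modeled
as a count, not site-specifically: only the precursor masses of the
standards are needed (C20H24D8O3, [M−H]⁻ = 327.278; the quadrupole setting
is 327.20). Printed transition values are unit-resolution instrument
settings, typically 0.05–0.2 Da above the theoretical monoisotopic value,
hence the default ±0.5 Da matching tolerance.

## Fragment enumeration

Segment compositions are assigned per carbon of the rearranged layout:
C1 contributes no hydrogens and two oxygens (deprotonated carboxylate), a
double-bond carbon one hydrogen, interior sp³ carbons two, the terminal
methyl three, and the oxygenated carbon one plus one for its terminal O–H,
with one or two added oxygens for OH/OOH. Atom conservation (carboxy +
methyl segment = precursor) holds identically and is property-tested over
all 24 isomers and both precursor forms.

The enumeration is the Cartesian product of the four cleavable bonds
(α/β × carboxy/methyl side), both charge-retaining segments, hydrogen shifts
in [−2, +2], and neutral losses: at most one CO2, only from a segment
containing C1; H2O only from a segment containing the oxygenated carbon, at
most one for OH and two for OOH. Cleavage through a double-bond carbon is
allowed compositionally — no mechanism is modeled. Duplicated compositions
keep the lowest-rearrangement label. The peripheral series ([M−H−H2O]⁻,
[M−H−CO2]⁻, [M−H−H2O−CO2]⁻, plus −2H2O variants for hydroperoxides) is
appended and flagged non-specific. Hydroperoxides dehydrate in-source; the
[M−H−H2O]⁻ precursor is handled by assigning the lost water to the
oxygenated site (OOH → one remaining oxygen, no O–H), which makes the 359-
and 341-derived fragment sets largely coincide, as observed experimentally.

Annotation ranks candidates by modification cost = |H shift| + number of
losses, ties by |mass error| — minimal-rearrangement assignments first.
Known limitation: a few printed transitions arise from chain fragmentations
outside the α/β taxonomy (notably the 5-HDoHE qualitative ion at *m/z*
93.10, and the 11-/5-HpDoHE selections); the engine reports them as
`unassigned` by design rather than stretching the chemistry to fit.

## Reference methods

The two 26-transition methods are verbatim fixtures (transitions, cone
voltages, collision energies, retention times, peak groups, 9 ms dwell),
including their quirks: per-row precursor settings of 341.10/.20/.30 and
359.10/.20/.30, and 8-HpDoHE's asymmetric transition pair. Per-analyte
reported LOD/r²/calibrated-range figures are exposed as metadata
(`reference_performance`) — they are instrument- and matrix-dependent and
are never asserted by the pipeline. Peak-group numbers link the co-eluting
pairs (10/11-HpDoHE, 7/8-HpDoHE, 7/8-HDoHE), which are distinguished by
transition, not retention time; `validate_method` reports these as soft
notes and reserves hard errors for analytes sharing an identical transition
at the same RT.

## Simulator

Peaks are exponentially modified Gaussians with σ = 0.02 min and
τ = 0.01 min by default (tailing factor < 2; the sources give no peak
widths, so these are fixture choices exposed in the plan). `rt_apex` is the
Gaussian-component center; at τ/σ = 0.5 the mode shift (≈0.008 min) is well
inside the 0.05 min RT-matching tolerance. The default grid (0–10 min at
0.005 min) spans the reference retention times (5.95–8.84 min) and keeps
≥ 16 points across 4σ, honoring the ≈15-points-per-peak design target of
the split acquisition methods.

Areas are response_factor × concentration × recovery (× the
qualitative/quantitative intensity ratio, default 0.5). Default response
factors are 2×10⁵ area/(ng/µL) for hydroxides and internal standards and
2×10⁴ for hydroperoxides, encoding the ~10× poorer hydroperoxide
sensitivity. The default IS level is 1.25 ng/µL in the extract (10 µL of
12.5 ng/µL in 100 µL). Baseline noise is additive Gaussian floored at zero
counts above an optional constant detector offset (`baseline_level`,
default 0 so that a blank, noise-free trace is exactly zero; noise-recovery
and LOD studies should set a positive offset, since a baseline clipped at
zero degenerates the MAD estimator). Area noise is unit-mean lognormal, so
a stated CV is exact in expectation. Multi-day designs multiply unit-mean
lognormal day effects (between-day CV) and replicate effects (within-day
CV); the realized effects are recorded for parameter-recovery checks. All
randomness flows from one `SeedSequence`, making batches byte-reproducible.

The simulator emulates peak areas, elution positions and the stated noise
structure. It does **not** emulate ion statistics, retention-time drift,
carryover, matrix interferences beyond scalar recovery factors, or real
detector saturation — so passing tests demonstrate the correctness of the
computational pipeline, not instrument performance: printed detection
limits (1–670 pg HpDoHE; 0.5–8.5 pg HDoHE), matrix recoveries and tissue
concentrations are not reproducible from simulation and are treated as
metadata only.

## Quantification choices

* Baseline and noise come from a declared peak-free region (default
  0–1 min): level = median, noise = 1.4826 × MAD. S/N = baseline-corrected
  height / noise sd (the common quadrupole convention; the LOD criterion
  S/N = 3 does not itself fix the estimator).
* Peak bounds extend from the apex until the signal re-enters the baseline
  envelope (baseline + 0.5 noise sd); the area is the trapezoidal integral
  above the baseline. On noise-free EMG peaks this recovers the planned
  area to < 0.5 %.
* Identity: both transitions present with apexes within 0.05 min (printed
  RTs have 0.01 min precision; co-eluting isomers are separated by
  transition). Unconfirmed analytes get flags, never concentrations.
* Calibration: unweighted OLS of area ratio vs concentration by default
  ("linear regression" unqualified); 1/x weighting is an option and is what
  the demo uses, because unweighted OLS lets the top of a 1000-fold ladder
  tilt the intercept by more than a low-level signal — a visible bias when
  quantifying near the low end.
* LOD/LOQ: S/N predicted through the origin from the calibration batch
  (S/N is zero at zero concentration; an intercept term extrapolated from
  levels far above the LOD is numerically unstable), evaluated at 3 and 10,
  converted to pg on column via the 10 µL injection. A blank-noise path
  (`lod_from_blank`) is provided for the alternative convention.
* Unit conversion to the original sample uses the preparation volumes
  (500 µL sample, 100 µL reconstitution, 10 µL injection), i.e. ×200 from
  ng/µL extract to ng/mL sample.
* Precision: intra-day RSD = mean of per-day RSDs; inter-day RSD = RSD of
  day means; accuracy = 100 × measured/expected.
* Profiles: one-way ANOVA, then Tukey–Kramer (statsmodels `pairwise_tukeyhsd`,
  valid for unequal n). Compact letters are the maximal cliques of the
  not-significantly-different graph, so two groups share a letter iff they
  do not differ at the chosen α.

## Problem sizes in tests and the acceptance script

Fragment-level checks are exact and run over all 24 isomers. The
calibration study uses the stated design — 8 levels × 5 replicates per
class, 2 % area CV — i.e. 80 simulated injections of 26 transitions each;
Monte-Carlo convergence checks (noise-sd recovery, within-day RSD) use
500–1000 draws at the area level, where trace simulation adds nothing. The
demo quantifies three replicate injections of an eleven-isomer plasma-like
profile against a 5(S)-HETE-d8-normalized ladder.
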