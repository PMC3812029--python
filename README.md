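# oxidha

Targeted LC-MS/MS (SRM) analysis of the oxygenated derivatives of
docosahexaenoic acid (DHA, 22:6 *n*-3): the twelve hydroperoxy-DHA (HpDoHE)
and twelve hydroxy-DHA (HDoHE) positional isomers produced by enzymatic and
non-enzymatic lipid oxidation. These species are structurally near-identical
— every HDoHE shares the composition C22H32O3 ([M−H]⁻ at nominal *m/z* 343)
and every HpDoHE C22H32O4 (*m/z* 359) — so telling 4-HDoHE from 20-HDoHE
rests entirely on position-specific collision-induced dissociation (CID)
fragments and on chromatographic retention. `oxidha` is for analysts building
or auditing such assays: it predicts the fragments, encodes the optimized
transition tables, and provides a fully simulatable quantification and
validation pipeline.

## What it computes

**Isomer structures.** Oxygenation at carbon *n* of a double bond Δm shifts
that bond by one position away from the oxygen with *E* geometry (proximal
attack: Δn → Δ(n+1)*E*; distal: Δ(n−1) → Δ(n−2)*E*). Applied to DHA
(4*Z*,7*Z*,10*Z*,13*Z*,16*Z*,19*Z*) this generates the twelve isomers of each
series, e.g. 17-HDoHE = 4*Z*,7*Z*,10*Z*,13*Z*,15*E*,19*Z* with OH at C17.

**Fragments.** Negative-mode CID cleaves the C–C bond α or β to the
oxygenated carbon, on its carboxy (c) or methyl (m) side; either segment can
keep the charge, with hydrogen shifts of up to ±2 and neutral losses of H2O
(from the oxygenated segment) and CO2 (from the carboxylate segment). Ions
are named by the three-letter code, e.g.

```
[αcc+H]−      carboxy segment of the α-cleavage, carboxy side, +1 H
[αcc+H−CO2]−  the same after decarboxylation
[βcm+H−H2O]−  methyl segment of the β-cleavage (carboxy side), +H, −H2O
```

For 17-HDoHE the engine computes [αcc+H]⁻ = C16H21O2⁻ at *m/z* 245.155 and
[αcc+H−CO2]⁻ at 201.165 — the two ions monitored for that isomer. Losses of
H2O/CO2 from the intact precursor (*m/z* 325/299/281 for HDoHE, 341/315/297
for HpDoHE) are enumerated as the non-specific series.

**SRM methods.** The two optimized 26-transition reference methods (12
analytes × quantitative + qualitative transition + two HETE-d8 internal
standards, 9 ms dwell) are packaged with their cone voltages, collision
energies, retention times and peak groups, and can be annotated, validated
(duplicates, missing roles, co-elution conflicts) and round-tripped as CSV.

**Quantification.** Peaks are integrated above a robust (MAD) baseline,
identity requires both transitions co-eluting, areas are normalized to
5(S)-HETE-d8, and concentrations come from linear calibration
(ratio = a·c + b, optionally 1/x-weighted), with LOD/LOQ at S/N = 3/10,
recovery from before/after-extraction spikes, intra-/inter-day RSD and
accuracy, and one-way ANOVA + Tukey–Kramer letters for isomer profiles.

**Simulation.** Because every pipeline stage is exercised against synthetic
chromatograms (EMG peaks at the reference retention times, lognormal area
noise, hierarchical day/replicate effects) with known ground truth, the whole
workflow is testable without instrument data.

## Worked example

```
$ oxidha demo --seed 1 --out-dir demo_out
ANOVA F = 1256.7, p = 6.30e-28
analyte_id  mean_ng_per_mL  sd_ng_per_mL tukey_letters
  14-HDoHE       52.001074      2.129573             d
  11-HDoHE        7.843844      0.147078             c
  17-HDoHE        7.399557      0.209920            bc
   7-HDoHE        6.991967      0.212891           abc
  20-HDoHE        6.814714      0.220168           abc
  10-HDoHE        6.742565      0.300537           abc
  13-HDoHE        6.342741      0.060094           abc
   4-HDoHE        6.035637      0.246059           abc
  16-HDoHE        5.863479      0.208484            ab
  19-HDoHE        5.518883      0.120945            ab
   8-HDoHE        5.349528      0.230021             a
```

The demo simulates a plasma-like HDoHE profile (dominant 14-HDoHE at
51.55 ng/mL ground truth, 5-HDoHE absent), calibrates each isomer from a
simulated 8-level × 5-replicate ladder, quantifies three replicate
injections end-to-end and ranks the isomers: the read-back means match the
simulation inputs within the injected 2 % area noise, and 14-HDoHE is the
only isomer carrying letter `d`, i.e. it is separated from all others at
p < 0.05. Other entry points: `predict-fragments`, `build-method`,
`annotate`, `simulate`, `quantify`, `validate` (see `oxidha --help`).

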