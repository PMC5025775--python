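# metaii

Inference toolkit for the retinal-binding pocket of activated rhodopsin:
solid-state NMR DARR build-up calibration and distance inversion, restraint
scoring of candidate retinal orientations in coordinate models, and FTIR
difference-spectrum titration analysis of the Meta-I ⇔ Meta-IIbH⁺
equilibrium.  Written for structural biologists and spectroscopists who
want the inference steps between raw spectroscopic observables and
structural conclusions — calibration, inversion, restraint bookkeeping and
titration fitting — as tested, reusable code, with a synthetic-data
generator providing ground-truthed inputs for every step.

## The models

**DARR build-up → distance.**  Crosspeak intensity between two ¹³C labels
grows with the mixing time *t* and decays with relaxation:

    I(t) = A (1 − e^{−k(r) t}) e^{−t/T},   k(r) = k_ref (r_ref / r)^6.

The inverse-sixth-power transfer rate makes intensity a strictly
decreasing function of internuclear distance *r*, so a measured curve
inverts uniquely.  Curves are normalized to an internal-control crosspeak
at fixed distance (retinal C12–C20, 2.4 Å), the free parameters
(k_ref, T, A) are calibrated by joint least squares on pairs of known
distance (1.4, 2.4, 3.6, 4.6, 5.3 Å), and observed curves are inverted by
least squares with Monte-Carlo uncertainties.  Crosspeaks are observable
only below ~6–6.5 Å; a peak below 3× the noise RMS is reported as *absent*
(distance ≥ 6.0 Å) rather than as a number.

**Distances → orientation.**  Inverted distances become restraints
(positive r±σ, upper-bound ≤ 6.5 Å, absent ≥ 6.0 Å) and candidate
coordinate models are ranked by the fraction of restraints satisfied.
This operationalizes the argument that in trapped Meta-II the retinal C20
methyl is *closer* to Tyr268 (~4.4 Å) than C12 is (~5.6 Å), the reverse of
the Meta-II crystal structures (~3.9 / ~5.9 Å).

**FTIR titration → apparent pK.**  Each pH point of a difference-spectrum
series (1800–1600 cm⁻¹, 4 cm⁻¹ step) is unmixed onto Meta-I and
Meta-IIbH⁺ reference spectra by non-negative least squares with a
sum-to-one constraint; the Meta-IIbH⁺ fraction follows a
Henderson–Hasselbalch law

    f(pH) = 1 / (1 + 10^{n (pH − pK)}),

fitted with slope n = 1 to give the apparent pK (wild type ≈ 6.8).
Mutant series are classified against the wild type as forward-shifted
(elevated Meta-II fraction at alkaline pH), Meta-I-stabilized
(pK downshift), unaffected, or complex.

## Worked example

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_calibrate_and_infer.py --seed 0
python analysis/03_score_orientations.py
python analysis/04_titration_analysis.py
```

The second step calibrates on the five known-distance curves and inverts
the three retinal–Tyr268 curves (ground truth 4.4, 5.6 and 7.0 Å):

```
calibration: k_ref=0.0101 /ms at 2.4 Å, T_damp=400 ms, amp=0.997
C20-Tyr268: r = 4.45 +- 0.03 Å
C12-Tyr268: r = 5.65 +- 0.12 Å
C19-Tyr268: absent, distance >= 6.0 Å
```

i.e. the quantified pairs are recovered within their uncertainties and the
out-of-range pair is correctly reported only as a ≥ 6.0 Å bound.  The third
step scores the two candidate orientations against these restraints —
`nmr_orientation: score 1.00` vs `crystal_orientation: score 0.00`, so the
NMR-derived orientation is the one the measured distances support.  The
fourth step fits the titrations:

```
wild-type: apparent pK 6.80, two-state ok
  Y268F-like: forward_shifted (ΔpK +1.20, alkaline-plateau Δ +0.45)
  M288A-like: meta_I_stabilized (ΔpK -1.00, alkaline-plateau Δ -0.01)
  Y178F-like: unaffected (ΔpK +0.00, alkaline-plateau Δ +0.00)
```

The same operations are exposed as a CLI (`metaii simulate-darr`,
`calibrate`, `infer`, `restrain`, `score`, `simulate-ftir`, `decompose`,
`titrate`, `classify`, `run-all`); `metaii run-all --seed 1 --outdir out`
runs both branches end to end.  Real depositions can be scored directly,
e.g. `metaii score --model 1U19 --restraints r.tsv --out s.json` (fetching
a PDB-ID requires network access; a local file path always works).

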