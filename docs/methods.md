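# Methods

## Build-up model

Magnetization exchange between two ¹³C labels during the DARR mixing
period is modelled as first-order transfer with relaxation damping:

    I(t; r) = A (1 − e^{−k(r) t}) e^{−t/T},   k(r) = k_ref (r_ref/r)^p.

No closed form for DARR build-up in a multi-spin membrane protein exists;
this is the minimal model that reproduces the observed rise-and-decay
shape and a steep distance dependence.  The exponent p defaults to 6 (the
two-spin dipolar value) but is configurable, since spin diffusion in
multi-spin systems can deviate from 6.  Assumptions: sparse labelling (no
relay through third spins), a single effective relaxation time shared by
all pairs in a sample, and noise that is additive, Gaussian and i.i.d.
across mixing times — the simplest model consistent with quoting a single
signal-to-noise figure per spectrum.

Parameters and defaults (one set of study conditions, fixed before any
recovery experiment and not revisited):

| parameter | default | units | why |
|---|---|---|---|
| mixing grid | 50, 100, 200, 400, 600, 800 | ms | spans the rise (short r) and the damped tail (long r) |
| k_ref at r_ref = 2.4 Å | 0.01 | ms⁻¹ | control-pair build-up time ~100 ms, typical of methyl-methyl DARR transfer |
| T (damping) | 400 | ms | places the intensity maximum inside the grid |
| A (plateau) | 1 | – | curves are normalized to the internal control |
| noise RMS | 0.004 | normalized units | see below |
| detection threshold | 3 × noise RMS | – | conventional peak-picking criterion |
| search bracket | 1.0–8.0 | Å | brackets every physically plausible pair |
| Monte-Carlo replicates | 500 | – | σ stable to ~3% |

The default noise RMS is the one knob that ties the synthetic conditions
to the experiment's two stated facts: crosspeaks vanish beyond ~6–6.5 Å,
and distance estimates near the detection limit carry ±0.3 Å.  At
0.004, a 7 Å pair falls below the 3×RMS threshold in ≥95% of replicates
while the replicate spread of a 5.6 Å inversion is ≈0.25 Å — both facts
hold simultaneously, which is itself a consistency check of the model.

**Normalization** divides all intensities by the fitted plateau amplitude
of the internal-control curve (a 3-parameter fit; the plateau is well
determined even where the control is fully saturated).  It is idempotent
and scale-invariant, and rescales the noise RMS by the same factor.

**Calibration** fits (k_ref, T, A) jointly to all known-distance curves by
Levenberg–Marquardt in log-parameters (enforcing positivity).  At least
three distinct distances are required.  Outlier flagging is leave-one-out:
a calibration pair is flagged when it misfits a refit on the remaining
pairs by more than 5× their median residual *and* removing it collapses
the joint misfit — the second condition prevents innocent pairs from being
flagged when some other pair has contaminated the fit.

**Inversion** minimizes the squared deviation from the model over the
bracket; a 0.01 Å grid scan locates the global minimum before bounded
refinement (xatol 1e-7).  Monotonicity of I in r makes the minimum unique
for clean curves.  Where the objective is flat (fully saturated curves at
very short distance), the shorter end of the flat region is reported and
the flat half-width is folded into σ in quadrature.  Detection gates the
observed curve only; the Monte-Carlo replicates measure parameter
uncertainty around the fitted curve and are not re-gated, as is standard
for error propagation.  Estimates refining beyond 6.5 Å are reported as
upper-bound-only rather than as numbers.  The absent/upper limits (6.0 /
6.5 Å) resolve the 6–6.5 Å observability band conservatively: a model
distance in the ambiguous zone satisfies both kinds of restraint.

## Structure measurements and restraint scoring

Coordinate models are read with gemmi (PDB format; mmCIF via the same
reader), chain selection defaulting to the first protein chain since
rhodopsin crystal forms carry two copies.  Selectors use PDB v3 names
(Tyr ζ-carbon CZ, Gly α-carbon CA, backbone carbonyl C, retinal HETATM
residue RET with atoms C1–C20); generic-numbering superscripts are label
metadata only.  Distances are kept at full precision and rounded to 0.1 Å
only for comparison with published values.

A restraint is POSITIVE (satisfied within 2σ by default), UPPER (≤ 6.5 Å)
or ABSENT (≥ 6.0 Å); a model's score is the satisfied fraction, with
unresolvable selectors excluded from the denominator under a warning.
Ranking ties on score break by summed normalized violation magnitude
(|d−r|/σ for POSITIVE, fractional exceedance for the bounds); exact ties
are reported as ties.  Scoring depends only on internal distances, hence
is rigid-motion invariant.

Because the deposited rhodopsin entries cannot be assumed reachable
(fetching requires network), the analysis also ships synthetic stand-in
pocket models (`metaii.reference`): toy structures whose atoms are placed
to encode the published pocket distances exactly.  They validate the
measurement and enumeration machinery, not the depositions; distances on
the real entries can be reproduced with `read_structure("1U19")` when
online.  Toy placement lays out connected constraint groups on
well-spread directions (tree constraints are realized exactly; entries
closing an inconsistent cycle are rejected), with unrelated groups 100 Å
apart so they cannot create spurious contacts.

## Chemical-shift bookkeeping

Shifts are recorded with their reference scale; TMS↔DSS conversion is the
fixed 2.01 p.p.m. offset.  Changes within ±0.2 p.p.m. (the run-to-run
reproducibility of the measurements) are "unchanged"; larger positive
deltas are downfield (higher p.p.m., the standard convention).  The
hydrogen-bonding rule — downfield Ser ¹³Cβ ⇒ increased Cβ-OH hydrogen
bonding — is implemented only for Ser Cβ sites; the analogous reading for
Tyr ¹³Cζ is not formalized as a rule because its shift also responds to
ring electrostatics.

## FTIR unmixing and titration

Unmixing solves min ‖Bc − y‖ subject to c ≥ 0, Σc = 1 per pH point, with
the equality imposed as a heavily weighted augmented NNLS row and a final
renormalization; on any noiseless in-span mixture this is exact.  The
basis condition number is checked (reject above 1e8).  The decomposition
window is 1800–1600 cm⁻¹ at 4 cm⁻¹ steps — the amide I region plus the
protonated carboxylic C=O region, the range most diagnostic of the
Meta-I/Meta-II transition.

The titration model is a single-site Henderson–Hasselbalch logistic with
the Hill slope fixed at 1 by default (a single apparent pK is the reported
quantity; the slope can be freed).  `two_state_ok` fails when any
per-point residual exceeds 0.05 — a biphasic profile (sum of two
logistics) fails this flag, which is how "complex" titrations are
detected.  A fitted pK more than one unit outside the sampled range is
flagged extrapolated.

Mutant classification against the wild type uses two invented, documented
thresholds chosen to separate the qualitative categories robustly on
synthetic data: alkaline-plateau excess > 0.2 ⇒ forward-shifted (also
when a non-two-state curve shows a plateau excess above half that), pK
downshift > 0.3 ⇒ Meta-I-stabilized, both within threshold ⇒ unaffected,
anything else complex.  Comparing a fit against itself is always
unaffected.

## Synthetic generator: what it does and does not emulate

The generator produces build-up tables (closed-form curves plus seeded
Gaussian noise, optional replicates), toy coordinate files, and titration
series (logistic mixtures of two synthetic reference spectra, with an
optional fraction override for biphasic/plateaued mutant curves).  The
synthetic reference spectra are sums of Gaussians with invented band
constants: an amide-I feature near 1644/1661 cm⁻¹ and carboxylic markers
in 1700–1780 cm⁻¹, widths 8–15 cm⁻¹.  Only the window and step are tied
to the experimental design.

Not emulated: 2D frequency-domain lineshapes, relayed spin diffusion,
temperature-dependent Meta-II substates (Meta-IIa/IIb deconvolution),
photoproduct decay kinetics, and baseline/scattering artefacts of real
FTIR difference spectra.  Passing recovery tests therefore demonstrates
that the inference machinery is correct and well-conditioned under the
stated noise model, not that the functional forms capture every physical
effect in the real spectra.

## Problem sizes

Default runs use 6 mixing times × 4 replicates for build-up tables, 500
Monte-Carlo replicates for uncertainties and stochastic recovery, 10 pH
points per titration, and 200 replicates for noisy-titration recovery;
all analyses complete in seconds on one CPU.

## Known limitations

The transfer-rate law is phenomenological; absolute calibrated rates are
meaningful only within a labelling scheme.  Near the detection limit the
distance estimator is mildly biased upward (convexity of r(I); ≈ +0.04 Å
at 5.6 Å under default noise), well inside the quoted ±0.3 Å.  The
restraint score treats restraints as independent and equally weighted.
The extraction of basis spectra from extreme-pH endpoints (supported as a
fallback when no reference spectra are available) inherits whatever
Meta-I/Meta-II contamination those endpoints carry.
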