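"""Decompose the FTIR pH series, fit apparent pKs and classify the mutants.

Reads the titration series written by 01_simulate_inputs.py, unmixes each
pH point onto the Meta-I / Meta-IIbH+ reference spectra over
1800-1600 cm^-1, fits the Henderson-Hasselbalch titration, and classifies
each mutant analogue against the wild type.  Expected outcome: wild-type
apparent pK of 6.8 with a clean two-state titration; the Y268F/Y191F/M288L
analogues forward-shifted (elevated Meta-II fraction at alkaline pH, Meta-I
destabilized); the M288A analogue pK-downshifted (Meta-I stabilized); the
Y178F/W175F analogues unaffected.

Writes results/fractions.csv, results/titration.json and
results/titration.png.
"""

import json
from pathlib import Path

import pandas as pd

from metaii.pipeline import MUTANT_SCENARIOS, plot_titration
from metaii.titration import BasisSet, classify_shift, decompose, fit_titration

results = Path(__file__).resolve().parents[1] / "results"
data = results / "data"
basis = BasisSet.from_frame(pd.read_csv(data / "basis.csv"))

fits = {}
frames = []
for name in MUTANT_SCENARIOS:
    series = pd.read_csv(data / f"titration_{name}.csv")
    fractions = decompose(series, basis)
    fractions.insert(0, "sample", name)
    frames.append(fractions)
    fits[name] = fit_titration(fractions["pH"].to_numpy(),
                               fractions["Meta-IIbH+"].to_numpy(), label=name)
pd.concat(frames, ignore_index=True).to_csv(results / "fractions.csv",
                                            index=False)

wt = fits["wild-type"]
print(f"wild-type: apparent pK {wt.pK:.2f}, two-state "
      f"{'ok' if wt.two_state_ok else 'violated'}")
phenotypes = {}
for name, fit in fits.items():
    if name == "wild-type":
        continue
    ph = classify_shift(wt, fit)
    phenotypes[name] = ph
    print(f"  {name}: {ph.label} (ΔpK {ph.delta_pK:+.2f}, "
          f"alkaline-plateau Δ {ph.delta_plateau:+.2f})")

report = {
    "fits": {n: f.to_json_dict() for n, f in fits.items()},
    "phenotypes": {n: {"label": p.label, "delta_pK": p.delta_pK,
                       "delta_plateau": p.delta_plateau}
                   for n, p in phenotypes.items()},
}
with open(results / "titration.json", "w") as fh:
    json.dump(report, fh, indent=2)
plot_titration(report, results / "titration.png")
print(f"wrote {results / 'titration.json'}, fractions.csv and titration.png")
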