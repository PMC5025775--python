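"""Score the two candidate Meta-II retinal orientations against the NMR restraints.

Turns the inverted distance estimates (results/estimates.csv, from
02_calibrate_and_infer.py) into a restraint set and scores the two toy
orientation models from 01_simulate_inputs.py: the NMR-derived orientation
(C20 methyl swung toward Tyr268, C12 further away, C19 out of range) and
the crystallographic orientation (the reverse).  Expected outcome: the
NMR-derived orientation satisfies every restraint and ranks first; the
crystal orientation violates the measured C12-Tyr268 separation.

Also measures the published dark-state pocket distances on synthetic
stand-in models (the depositions are fetched only when network allows).

Writes results/scores.json and results/pocket_distances.csv.
"""

import json
from pathlib import Path

import pandas as pd

from metaii.buildup import DistanceEstimate
from metaii.pipeline import TARGET_SELECTORS
from metaii.reference import (
    ORIENTATION_1GZM,
    POCKET_DISTANCES_1U19,
    TYR_GLY_CONTACTS_1U19,
    synthetic_pocket_model,
)
from metaii.structure import (
    discriminate_models,
    enumerate_contacts,
    pair_distance,
    read_structure,
    restraints_from_estimates,
)

results = Path(__file__).resolve().parents[1] / "results"
data = results / "data"

df = pd.read_csv(results / "estimates.csv")
estimates = [
    DistanceEstimate(pair_label=row["pair"],
                     r_hat=None if pd.isna(row["r_hat"]) else float(row["r_hat"]),
                     sigma=float(row["sigma"]), status=row["status"],
                     detection_limit=float(row["detection_limit"]))
    for _, row in df.iterrows()
]
restraints = restraints_from_estimates(estimates, TARGET_SELECTORS)
restraints.to_tsv(results / "restraints.tsv")

models = {
    name: read_structure(data / f"{name}.pdb")
    for name in ("nmr_orientation", "crystal_orientation")
}
ranking = discriminate_models(models, restraints)
with open(results / "scores.json", "w") as fh:
    json.dump(ranking, fh, indent=2)

print(f"restraints: {len(restraints)} "
      f"({', '.join(f'{r.label} {r.kind}' for r in restraints)})")
for name in ranking["ranking"]:
    sc = ranking["scores"][name]
    print(f"  {name}: score {sc['score']:.2f}, "
          f"violations {sc['violations'] or 'none'}")
print(f"best-supported orientation: {ranking['best']}")

# published pocket distances, measured on synthetic stand-in models
rows = []
pocket = synthetic_pocket_model(POCKET_DISTANCES_1U19, source="synthetic-1U19")
for (a, b), d in POCKET_DISTANCES_1U19.items():
    rows.append({"model": "synthetic-1U19", "selector_a": a, "selector_b": b,
                 "reference_A": d,
                 "measured_A": round(pair_distance(pocket, a, b), 1)})
gzm = synthetic_pocket_model(ORIENTATION_1GZM, source="synthetic-1GZM")
for (a, b), d in ORIENTATION_1GZM.items():
    rows.append({"model": "synthetic-1GZM", "selector_a": a, "selector_b": b,
                 "reference_A": d,
                 "measured_A": round(pair_distance(gzm, a, b), 1)})
pd.DataFrame(rows).to_csv(results / "pocket_distances.csv", index=False)

contacts = enumerate_contacts(
    synthetic_pocket_model(TYR_GLY_CONTACTS_1U19, source="synthetic-1U19"),
    "TYR:CZ", "GLY:CA", 6.0)
print(f"Tyr(CZ)-Gly(CA) contacts at 6.0 Å cutoff: {len(contacts)} "
      f"(extracellular tyrosine-glycine network)")
print(f"wrote {results / 'scores.json'} and pocket_distances.csv")
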