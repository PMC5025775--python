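"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/:
  crosspeaks.tsv         noisy DARR build-up table: the five fixed-distance
                         calibration pairs plus the three Meta-II
                         retinal-Tyr268 target pairs (C20 at 4.4 Å, C12 at
                         5.6 Å, C19 beyond the detection limit at 7.0 Å)
  titration_<sample>.csv wild-type and mutant-analogue FTIR difference
                         pH series (1800-1600 cm^-1, 4 cm^-1 step)
  nmr_orientation.pdb /  toy coordinate models encoding the two competing
  crystal_orientation.pdb  Meta-II retinal orientations

Run: python analysis/01_simulate_inputs.py [--seed N]
"""

import argparse
from pathlib import Path

from metaii.buildup import CALIBRATION_DISTANCES, BuildupParams
from metaii.pipeline import (
    CRYSTAL_ORIENTATION,
    META_II_TARGETS,
    MUTANT_SCENARIOS,
    NMR_ORIENTATION,
    RunConfig,
    _scenario_series,
)
from metaii.synthetic import (
    GroundTruthGeometry,
    NoiseModel,
    default_basis,
    generate_buildup_dataset,
    generate_toy_structure,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

outdir = Path(__file__).resolve().parents[1] / "results" / "data"
outdir.mkdir(parents=True, exist_ok=True)
cfg = RunConfig(seed=args.seed)

geometry = GroundTruthGeometry(
    pairs={**CALIBRATION_DISTANCES, **META_II_TARGETS},
    control_pairs=tuple(CALIBRATION_DISTANCES))
table = generate_buildup_dataset(
    geometry, BuildupParams(), cfg.mixing_grid,
    NoiseModel(noise_rms=cfg.noise_rms, seed=cfg.seed,
               replicate_count=cfg.replicate_count))
table.to_tsv(outdir / "crosspeaks.tsv")
print(f"crosspeaks.tsv: {len(geometry.pairs)} pairs x {len(cfg.mixing_grid)} "
      f"mixing times x {cfg.replicate_count} replicates, "
      f"noise RMS {cfg.noise_rms}")

basis = default_basis()
basis.to_csv(outdir / "basis.csv", index=False)
for i, (name, scenario) in enumerate(MUTANT_SCENARIOS.items()):
    series = _scenario_series(name, scenario, cfg, basis,
                              seed=cfg.seed + 2000 + i)
    series.to_csv(outdir / f"titration_{name}.csv", index=False)
print(f"titration series: {', '.join(MUTANT_SCENARIOS)} "
      f"({len(cfg.pH_grid)} pH points each)")

generate_toy_structure(NMR_ORIENTATION, path=outdir / "nmr_orientation.pdb")
generate_toy_structure(CRYSTAL_ORIENTATION,
                       path=outdir / "crystal_orientation.pdb")
print("toy orientation models written (NMR-derived vs crystallographic)")
print(f"all inputs under {outdir}")
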