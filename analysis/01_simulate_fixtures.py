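"""Simulate the synthetic study system and write its fixture files.

Generates a 1-D stepping-stone population with known effective density
(50 fish/km) and dispersal spread (8 km), samples seven sites of twenty
fish, and writes the Genepop genotypes plus the matched site table,
distance matrix, connectivity matrix (with one anomalous high-connectivity
corridor between the outermost sites) and survey table that the later
analysis steps consume.

Run from the repository root:  python analysis/01_simulate_fixtures.py
"""

import json
from pathlib import Path

from seakernel.synthetic_data import SteppingStoneConfig, make_fixture_suite

OUT = Path("results/fixtures")
SEED = 2022

# the gene-flow corridor links the outermost sampled demes, so the most
# distant site behaves like a current-connected outlier from the IBD pattern
cfg = SteppingStoneConfig(seed=SEED, corridor_demes=(3, 33), corridor_strength=0.25)

if __name__ == "__main__":
    paths = make_fixture_suite(cfg, OUT)
    truth = json.loads(paths["truth"].read_text())
    print(f"wrote fixture suite to {OUT}/")
    print(f"  demes: {cfg.n_demes} x {cfg.deme_size} diploids, spacing {cfg.deme_spacing} km")
    print(f"  true effective density: {truth['de_true']} fish/km")
    print(f"  true dispersal spread:  {truth['sigma_true']} km")
    print(f"  slope IBD theory predicts: {truth['expected_slope']:.3e} per km")
    print(f"  sampled demes (km): {truth['positions_km']}")
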