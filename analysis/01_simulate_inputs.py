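"""Generate every synthetic input with planted ground truth.

Writes the raw screen plates (2,000-gene library, two induction
conditions, 20 genes spiked 6 SD down in the induced condition), a
signed regulator->target network with a regulator planted "inhibited"
in three of five contrasts, and leaves the cohort to be generated after
the signature is built (04). All downstream scripts read from
results/synthetic/.

Run: python analysis/01_simulate_inputs.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from wntpipe import io
from wntpipe.simulate import random_network, simulate_contrasts, simulate_screen

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path("results/synthetic")
out.mkdir(parents=True, exist_ok=True)

spiked = [f"GENE{i + 1:05d}" for i in range(20)]
plates, screen_truth = simulate_screen(
    n_genes=2000,
    gradient_amplitude=1.0,
    noise_sd=0.3,
    spikes=[(g, "induced", -6.0) for g in spiked],
    seed=args.seed,
)
io.write_plates(plates, out / "screen_raw.csv")
(out / "screen_truth.json").write_text(json.dumps(
    {"spiked_genes": spiked, "effect_sigma": -6.0, "condition": "induced",
     "noise_sd": screen_truth.noise_sd}, indent=2))

network = random_network(n_regulators=5, targets_per_regulator=20,
                         frac_unknown_sign=0.0, seed=args.seed + 1)
io.write_network(network, out / "network.tsv")

planted_regulator = "REG001"
activity = {f"cellline{i + 1}": ({planted_regulator: -1} if i < 3 else {})
            for i in range(5)}
tables, truth = simulate_contrasts(network, activity, effect_mu=2.0,
                                   noise_sd=0.5, seed=args.seed + 2)
for contrast, de in tables.items():
    io.write_de_table(de, out / f"de_{contrast}.tsv")
(out / "contrast_truth.json").write_text(json.dumps(
    {"planted_regulator": planted_regulator,
     "planted_state": "inhibited",
     "active_contrasts": [c for c, s in activity.items() if s],
     "true_targets": truth}, indent=2))

print(f"screen: {len(plates.plates)} plates x 2 conditions, "
      f"{len(spiked)} spiked genes at -6 sigma (induced only)")
print(f"network: {len(network.regulators)} regulators, "
      f"{len(network.edges)} signed edges")
print(f"contrasts: {len(tables)} DE tables, {planted_regulator} planted "
      f"inhibited in {sum(bool(s) for s in activity.values())} of 5")
print(f"inputs written to {out}")
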