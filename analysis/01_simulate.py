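"""Simulate the synthetic study cohort.

Generates 45 infants x 20 pressure-mat snippets (5 s at 100 Hz, 32x32
8-bit frames) with the class-conditional motion laws: fidgety-absent
snippets oscillate at 0.3-1.0 Hz with 2-4 cell amplitudes, fidgety-present
snippets at 1.5-4.0 Hz with 0.5-1.5 cells.  Writes the frames container
and manifest under results/data/ and prints the cohort composition.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
import time

import matmotion as mm
from matmotion import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

t0 = time.time()
config = mm.CohortConfig(n_infants=45, snippets_per_infant=20, rng_seed=SEED)
snippets, manifest = mm.generate_cohort(config)
io.write_cohort("results/data", snippets, manifest)

counts = manifest["label"].value_counts()
print(f"simulated {len(snippets)} snippets from {config.n_infants} infants "
      f"in {time.time() - t0:.0f}s")
print(f"  FM+ {counts.get('FMplus', 0)}, FM- {counts.get('FMminus', 0)} "
      f"(target positive fraction {config.class_ratio:.3f})")
print("wrote results/data/frames.h5 and results/data/manifest.csv")
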