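"""Shared configuration for the numbered analysis drivers.

Both study bundles are pure functions of the seed, so every driver
regenerates them in memory instead of reading files; 01_simulate.py
additionally materializes them (under scratch/) for inspection.
"""

from pathlib import Path

import ppl

SEED = 20211026
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def tall_bundle() -> ppl.StudyBundle:
    return ppl.simulate_study(ppl.scaled_config(
        ppl.TALL_CONFIG, n_taxa=ppl.TALL_CONFIG.n_taxa, seed=SEED))


def broad_bundle() -> ppl.StudyBundle:
    return ppl.simulate_study(ppl.scaled_config(
        ppl.BROAD_CONFIG, n_taxa=ppl.BROAD_CONFIG.n_taxa, seed=SEED + 1))
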