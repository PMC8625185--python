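#!/usr/bin/env python
"""k-NN placement of molecularly unsampled taxa.

Withholds the molecular data of a random 15% of the tall bundle's taxa
and re-places them into sections from morphology alone, against a
combined molecular + morphological reference, with character-bootstrap
confidence.  Reports leave-one-out accuracy of the morphology space as a
baseline sanity check and the proportion of placements above the 0.90
confidence threshold.
"""

import numpy as np
import pandas as pd

import ppl
from common import RESULTS, tall_bundle
from ppl import pipeline
from ppl.classification import HIGH_CONFIDENCE


def main() -> None:
    bundle = tall_bundle()
    loo = pipeline.section_loo_accuracy(bundle, k=5)
    print(f"leave-one-out section accuracy of morphology (k=5): {loo:.3f}")

    rng = np.random.default_rng(6)
    taxa = list(bundle.morphology.taxa)
    masked = sorted(rng.choice(taxa, size=int(round(0.15 * len(taxa))),
                               replace=False))
    kept = [t for t in taxa if t not in set(masked)]
    morph = bundle.morphology.to_dataframe()
    res = ppl.placement_confidence(
        morph.loc[kept], bundle.sections.loc[kept], morph.loc[masked],
        k=5, n_bootstrap=1000, seed=7)

    table = res.table.copy()
    table["true_label"] = bundle.sections.loc[masked]
    table["correct"] = table["predicted_label"] == table["true_label"]
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "06_placements.csv", float_format="%.4g")

    acc = table["correct"].mean()
    high = table["high_confidence"].mean()
    print(f"placed {len(masked)} withheld taxa: accuracy {acc:.3f}; "
          f"{high:.0%} of placements above the {HIGH_CONFIDENCE:.2f} "
          f"bootstrap-confidence threshold")


if __name__ == "__main__":
    main()
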