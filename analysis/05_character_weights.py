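#!/usr/bin/env python
"""Character "molecular weights" and categorical association tests.

Ranks every binary morphological character and every morphometric trait
by the bootstrap Spearman correlation of its pairwise dissimilarities
with the cophenetic distances of the generating tree (the broad bundle),
then tests whether the binary morphometric traits (taproot, inflorescence
gaps) associate with section membership (chi-square + bias-corrected
Cramér's V).
"""

import pandas as pd

import ppl
from common import RESULTS, broad_bundle


def main() -> None:
    bundle = broad_bundle()
    ref = ppl.cophenetic_distances(bundle.tree)

    binary = ppl.character_weights(bundle.morphology, ref, n_bootstrap=200,
                                   seed=3)
    metric = ppl.character_weights(bundle.morphometrics, ref,
                                   n_bootstrap=200, seed=4)
    RESULTS.mkdir(exist_ok=True)
    binary.ranked().to_csv(RESULTS / "05_binary_character_weights.csv",
                           float_format="%.4g")
    metric.ranked().to_csv(RESULTS / "05_morphometric_weights.csv",
                           float_format="%.4g")
    top = binary.ranked().head(10)
    print("top binary characters by median bootstrap rho:")
    print(top.round(3).to_string())
    print("\nmorphometric traits by median bootstrap rho:")
    print(metric.ranked().round(3).to_string())

    rows = []
    for trait in ("TAPROOT", "GAP"):
        states = bundle.morphometrics[trait].map({0.0: "absent",
                                                  1.0: "present"})
        res = ppl.association_test(bundle.sections, states)
        rows.append({"trait": trait, "chi2": res.chi2, "df": res.df,
                     "p_value": res.p_value,
                     "cramers_v_corrected": res.cramers_v_corrected})
        print(f"\n{trait} x section: chi2 = {res.chi2:.2f}, "
              f"p = {res.p_value:.4f}, corrected V = "
              f"{res.cramers_v_corrected:.2f}")
    pd.DataFrame(rows).to_csv(RESULTS / "05_associations.csv", index=False)


if __name__ == "__main__":
    main()
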