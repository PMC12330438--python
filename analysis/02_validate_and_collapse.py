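#!/usr/bin/env python
"""Callerset validation and inter-sample collapse.

Each sample's assembly-based calls are validated by requiring support from
at least one alignment-based caller, then all validated calls are
collapsed across samples into a nonredundant genotype matrix; Mendelian
concordance is computed per trio.  Writes results/validation_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from svsieve.pipeline import RunConfig, run_pipeline
from svsieve.sim import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    result = run_pipeline(RunConfig(simulation=SimulationConfig(seed=SEED)))
    m = result.manifest
    rows = [{
        "sample": s,
        "assembly_calls": len(result.cohort.callsets[s]["assembly"]),
        "validated": len(result.validated[s]),
        "concordance": result.concordance.get(s, float("nan")),
    } for s in result.cohort.pedigree.samples]
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "validation_summary.tsv", sep="\t",
                              index=False, float_format="%.4f")
    print(f"validated fraction: {m['validated_fraction']:.1%} "
          f"(expected 1-(1-s_a)(1-s_b) for aligner sensitivities s)")
    print(f"nonredundant loci after collapse: {m['n_nonredundant_loci']}")
    print(f"mean Mendelian concordance across children: "
          f"{m['mean_mendelian_concordance']:.1%}")


if __name__ == "__main__":
    main()
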