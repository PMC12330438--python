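#!/usr/bin/env python
"""Control-panel scaling: cumulative SV discovery and rare-pool shrinkage.

Computes the cumulative nonredundant SV count as controls are added
(stratified by superpopulation) and the mean rare-SV pool per child as a
function of control-panel size -- the two curves that motivate growing the
pangenome panel.  Writes results/discovery_curve.tsv and
results/rare_pool_curve.tsv.
"""

from pathlib import Path

import pandas as pd

from svsieve.burden import discovery_curve, rare_pool_curve
from svsieve.pipeline import RunConfig, run_pipeline
from svsieve.sim import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    cfg = SimulationConfig(seed=SEED, n_controls=200)
    result = run_pipeline(RunConfig(simulation=cfg))
    co = result.cohort
    panel = co.panel

    curve_all = discovery_curve(panel)
    afr = [s for s in panel.samples if co.control_superpops[s] == "AFR"]
    non = [s for s in panel.samples if co.control_superpops[s] != "AFR"]
    rows = [{"k": k + 1, "stratum": "all", "cumulative": v}
            for k, v in enumerate(curve_all)]
    rows += [{"k": k + 1, "stratum": "AFR", "cumulative": v}
             for k, v in enumerate(discovery_curve(panel, afr))]
    rows += [{"k": k + 1, "stratum": "non-AFR", "cumulative": v}
             for k, v in enumerate(discovery_curve(panel, non))]
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "discovery_curve.tsv", sep="\t", index=False)

    child_sexes = {c.sample_id: c.sex for c in co.pedigree.children}
    carried = {
        cid: [l for l in result.matrix.loci
              if (g := result.matrix.genotype(l.id, cid)) is not None and g.has_alt]
        for cid in child_sexes
    }
    pool = rare_pool_curve(carried, panel, child_sexes, cfg.params,
                           control_sexes=co.control_sexes,
                           panel_sizes=[0, 25, 50, 100, 200])
    pool.to_csv(RESULTS / "rare_pool_curve.tsv", sep="\t", index=False)
    means = pool.groupby("panel_size")["n_rare"].mean()
    print(f"nonredundant loci: {curve_all[24]} at 25 controls -> "
          f"{curve_all[99]} at 100 -> {curve_all[-1]} at {len(panel.samples)}")
    print("mean rare SVs per child by panel size:")
    for k, v in means.items():
        print(f"  {k:4d} controls: {v:6.1f}")


if __name__ == "__main__":
    main()
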