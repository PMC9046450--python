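#!/usr/bin/env python
"""Generate the synthetic study data everything downstream consumes.

Writes, under results/synthetic/:
  * the canonical fixture set (control cohort, shifted cohort, one rendered
    image bundle, hash manifest);
  * the full two-genotype mitochondrial intensity cohort (4 mice/group,
    50 islets/mouse) with the mutant group carrying a 2.5-SEE complex-I
    deficit and a 0.5-SEE complex-IV deficit;
  * the two-genotype composition cohort (4 mice/group, 25 islets/mouse)
    with an expanded alpha-cell compartment in the mutant group.
"""

import argparse
from pathlib import Path

from isletquant.config import PipelineConfig
from isletquant.synthetic import (
    CohortConfig,
    CompositionSpec,
    IntensityModelParams,
    gen_composition_table,
    gen_intensity_table,
    write_fixture_set,
)

RESULTS = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    manifest = write_fixture_set(RESULTS / "fixtures", seed=args.seed)
    print(f"fixture set: {len(manifest)} files under {RESULTS / 'fixtures'}")

    cfg = PipelineConfig(seed=args.seed)
    cohort = CohortConfig(
        n_mice_per_group=cfg.n_mice_per_group,
        islets_per_mouse=cfg.islets_per_mouse,
        groups=tuple((g, cfg.age) for g in cfg.groups),
        seed=args.seed,
    )
    params = {
        (name, cfg.age): IntensityModelParams(
            deficiency_shift_N=g.deficiency_shift_N,
            deficiency_shift_M=g.deficiency_shift_M,
        )
        for name, g in cfg.groups.items()
    }
    intensity = gen_intensity_table(cohort, params)
    intensity.to_csv(RESULTS / "intensity_cohort.csv", index=False)
    print(f"intensity cohort: {len(intensity)} islet ROIs "
          f"({cfg.n_mice_per_group} mice/group x {cfg.islets_per_mouse} islets)")

    comp_frames = []
    for name, g in cfg.groups.items():
        spec = CompositionSpec(
            cells_per_islet=cfg.cells_per_islet,
            alpha_fraction=g.alpha_fraction,
            beta_fraction=g.beta_fraction,
            bihormonal_fraction=g.bihormonal_fraction,
            ki67_rate_alpha=g.ki67_rate_alpha,
            ki67_rate_beta=g.ki67_rate_beta,
            tunel_islet_rate=g.tunel_islet_rate,
        )
        one = CohortConfig(
            n_mice_per_group=cfg.n_mice_per_group,
            islets_per_mouse=cfg.islets_per_mouse_composition,
            groups=((name, cfg.age),),
            seed=args.seed + 1,
        )
        comp_frames.append(gen_composition_table(spec, one))
    import pandas as pd

    cells = pd.concat(comp_frames, ignore_index=True)
    cells.to_csv(RESULTS / "composition_cells.csv", index=False)
    print(f"composition cohort: {len(cells)} cells across "
          f"{cells.groupby(['mouse_id', 'islet_id']).ngroups} islets")


if __name__ == "__main__":
    main()
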