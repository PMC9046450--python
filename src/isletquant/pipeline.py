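"""End-to-end orchestration: simulate -> quantify -> Z-score -> compose -> compare.

Every stage is a pure function of (config, seed); two runs with the same
configuration produce byte-identical output files.  The run log records the
seed, a SHA-256 hash of the resolved configuration, and every exclusion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .composition import (
    beta_alpha_ratio,
    bihormonal_fraction,
    compute_composition,
    ki67_islet_metrics,
    tunel_count,
)
from .config import PipelineConfig
from .intensity import background_correct, log_transform
from .stats import compare_groups, summarize
from .synthetic import (
    MITO_CHANNELS,
    CohortConfig,
    CompositionSpec,
    IntensityModelParams,
    gen_composition_table,
    gen_intensity_table,
)
from .zscore import score_cohort

__all__ = ["run_end_to_end", "config_hash"]

log = logging.getLogger(__name__)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _intensity_params(cfg: PipelineConfig) -> dict[tuple[str, str], IntensityModelParams]:
    return {
        (name, cfg.age): IntensityModelParams(
            deficiency_shift_N=g.deficiency_shift_N,
            deficiency_shift_M=g.deficiency_shift_M,
        )
        for name, g in cfg.groups.items()
    }


def _comparison_payload(res) -> dict:
    return dataclasses.asdict(res)


def run_end_to_end(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full pipeline, returning the paths of the written artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    group_names = list(cfg.groups)
    if cfg.reference_group not in cfg.groups:
        raise ValueError(f"reference group {cfg.reference_group!r} not configured")

    # 1. simulate the mitochondrial intensity panel
    cohort = CohortConfig(
        n_mice_per_group=cfg.n_mice_per_group,
        islets_per_mouse=cfg.islets_per_mouse,
        groups=tuple((g, cfg.age) for g in group_names),
        seed=cfg.seed,
    )
    raw = gen_intensity_table(cohort, _intensity_params(cfg))

    # 2. background-correct and log-transform
    corrected = log_transform(background_correct(raw, MITO_CHANNELS), MITO_CHANNELS)
    artifacts["islets_raw"] = outdir / "islets_raw.csv"
    corrected.to_csv(artifacts["islets_raw"], index=False)

    # 3. conditional Z-scores against the reference group
    scored, model = score_cohort(
        corrected, cfg.reference_selector, seed=cfg.seed, thresholds=cfg.thresholds
    )
    artifacts["islets_z"] = outdir / "islets_z.csv"
    scored.to_csv(artifacts["islets_z"], index=False)
    artifacts["control_model"] = outdir / "control_model.yaml"
    model.to_yaml(artifacts["control_model"])

    # 4. composition panel (image-free path at cohort scale)
    comp_cohort = CohortConfig(
        n_mice_per_group=cfg.n_mice_per_group,
        islets_per_mouse=cfg.islets_per_mouse_composition,
        groups=tuple((g, cfg.age) for g in group_names),
        seed=cfg.seed + 1,
    )
    cell_frames = []
    for gname in group_names:
        g = cfg.groups[gname]
        spec = CompositionSpec(
            cells_per_islet=cfg.cells_per_islet,
            alpha_fraction=g.alpha_fraction,
            beta_fraction=g.beta_fraction,
            bihormonal_fraction=g.bihormonal_fraction,
            ki67_rate_alpha=g.ki67_rate_alpha,
            ki67_rate_beta=g.ki67_rate_beta,
            tunel_islet_rate=g.tunel_islet_rate,
        )
        one_group = dataclasses.replace(comp_cohort, groups=((gname, cfg.age),))
        cell_frames.append(gen_composition_table(spec, one_group))
    cells = pd.concat(cell_frames, ignore_index=True)
    artifacts["cells"] = outdir / "cells.csv"
    cells.to_csv(artifacts["cells"], index=False)

    comp = compute_composition(
        cells,
        group_cols=("genotype", "mouse_id"),
        class_col="true_class",
    )
    artifacts["composition"] = outdir / "composition.csv"
    comp.to_csv(artifacts["composition"], index=False)

    # 5. group comparisons
    ref = cfg.reference_group
    others = [g for g in group_names if g != ref] or [ref]
    test_grp = others[0]
    comparisons: dict[str, object] = {}
    z_ref = scored[scored["genotype"] == ref]
    z_test = scored[scored["genotype"] == test_grp]
    for metric in ("tomm20_z", "ndufb8_z", "mtco1_z", "insulin_z"):
        res = compare_groups(
            z_test[metric].to_numpy(),
            z_ref[metric].to_numpy(),
            metric=metric,
            groups=(test_grp, ref),
        )
        comparisons[metric] = _comparison_payload(res)

    comp_ref = comp[comp["genotype"] == ref]
    comp_test = comp[comp["genotype"] == test_grp]
    comparisons["beta_alpha_ratio"] = {
        ref: beta_alpha_ratio(comp_ref),
        test_grp: beta_alpha_ratio(comp_test),
    }
    comparisons["bihormonal_pct"] = {
        ref: summarize(bihormonal_fraction(comp_ref).to_numpy(), "mean_sem"),
        test_grp: summarize(bihormonal_fraction(comp_test).to_numpy(), "mean_sem"),
    }
    ki67 = ki67_islet_metrics(comp.assign(genotype=comp["genotype"]))
    ki67 = ki67.merge(comp[["mouse_id", "genotype"]].drop_duplicates(), on="mouse_id")
    ki_test = ki67.loc[ki67["genotype"] == test_grp, "pct_islets_ki67_alpha"].to_numpy()
    ki_ref = ki67.loc[ki67["genotype"] == ref, "pct_islets_ki67_alpha"].to_numpy()
    if min(len(ki_test), len(ki_ref)) >= 3:
        comparisons["pct_islets_ki67_alpha"] = _comparison_payload(
            compare_groups(
                ki_test, ki_ref, metric="pct_islets_ki67_alpha", groups=(test_grp, ref)
            )
        )
    else:  # too few mice for the normality gate: report summaries only
        log.warning("fewer than 3 mice per group; Ki67 comparison reports means only")
        comparisons["pct_islets_ki67_alpha"] = {
            test_grp: {"mean": float(ki_test.mean()), "n": len(ki_test)},
            ref: {"mean": float(ki_ref.mean()), "n": len(ki_ref)},
        }
    comparisons["tunel"] = {
        row["genotype"]: {
            "n_islets": int(row["n_islets"]),
            "n_tunel_islets": int(row["n_tunel_islets"]),
            "pct_tunel_islets": float(row["pct_tunel_islets"]),
        }
        for _, row in tunel_count(comp, group_cols=("genotype",)).iterrows()
    }

    artifacts["comparisons"] = outdir / "comparisons.json"
    artifacts["comparisons"].write_text(
        json.dumps(comparisons, indent=2, sort_keys=True, default=str)
    )

    artifacts["run_log"] = outdir / "run_log.txt"
    n_excluded = int(sum(corrected[f"{ch}_excluded"].sum() for ch in MITO_CHANNELS))
    artifacts["run_log"].write_text(
        "\n".join(
            [
                f"seed: {cfg.seed}",
                f"config_sha256: {config_hash(cfg)}",
                f"reference_selector: {cfg.reference_selector}",
                f"n_islet_rois: {len(scored)}",
                f"n_excluded_channel_values: {n_excluded}",
                f"control_pool_n: {model.n_ref}",
            ]
        )
        + "\n"
    )
    return artifacts
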