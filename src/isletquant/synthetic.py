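"""Synthetic islet data with known ground truth.

Two panels are emulated:

* the *mitochondrial* panel — per-islet mean intensities of TOMM20
  (mitochondrial mass), NDUFB8 (complex I), MTCO1 (complex IV) and insulin,
  generated on the log scale with a linear dependence of each subunit on
  TOMM20 plus Gaussian residuals, then exponentiated and offset by a
  no-primary-control (NPC) background level.  OXPHOS deficiency is a downward
  shift of the conditional mean in units of the residual SD (the standard
  error of estimate, SEE), so the conditional Z-score pipeline has an exact
  recovery oracle: a stratum generated at shift ``k`` must score a mean
  subunit Z of ``-k``.

* the *composition* panel — rendered multi-channel islet images
  (DAPI / Ki67 / glucagon / insulin) with a β-cell core and α-cell mantle,
  bihormonal cells, Ki67-positive nuclei, TUNEL-flagged islets and a
  per-islet acquisition gain, together with an exact per-cell ground-truth
  table.  Gain and background alter the pixels only, never the ground truth.

All generators are pure functions of (configuration, seed); child RNG
streams are derived per operation by fixed labels.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from ._rng import child_rng
from .errors import ConfigurationError, DataError

__all__ = [
    "CohortConfig",
    "IntensityModelParams",
    "CompositionSpec",
    "SyntheticImageBundle",
    "MITO_CHANNELS",
    "COMPOSITION_CHANNELS",
    "gen_intensity_table",
    "gen_deficient_cohort",
    "gen_composition_table",
    "gen_islet_image",
    "find_tunel_seed",
    "write_fixture_set",
]

#: channel order of the mitochondrial (intensity) panel
MITO_CHANNELS = ("tomm20", "ndufb8", "mtco1", "insulin")
#: channel order of the composition (imaging) panel
COMPOSITION_CHANNELS = ("dapi", "ki67", "glucagon", "insulin")

CELL_CLASSES = ("alpha", "beta", "bihormonal", "other")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study layout: groups, mice per group, islets (ROIs) per mouse."""

    n_mice_per_group: int = 4
    islets_per_mouse: int = 50
    groups: tuple[tuple[str, str], ...] = (("WT", "12w"), ("MUT", "12w"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group < 1:
            raise ConfigurationError("n_mice_per_group must be >= 1")
        if self.islets_per_mouse < 1:
            raise ConfigurationError("islets_per_mouse must be >= 1")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")


@dataclass(frozen=True)
class IntensityModelParams:
    """Generative parameters of the mitochondrial panel for one group.

    Log-TOMM20 is Normal(mu_T, sigma_T); log-subunit ``s`` is
    ``beta0_s + beta1_s * logT - deficiency_shift_s * see_s + N(0, see_s)``;
    log-insulin is Normal(mu_ins, sigma_ins).  Raw intensity is
    ``exp(log value) + npc_mean[channel]``, so subtract-then-log inverts the
    generator exactly.
    """

    mu_T: float = 6.0
    sigma_T: float = 0.35
    beta0_N: float = 0.4
    beta1_N: float = 0.9
    see_N: float = 0.25
    beta0_M: float = 0.7
    beta1_M: float = 0.85
    see_M: float = 0.25
    mu_ins: float = 6.5
    sigma_ins: float = 0.4
    npc_mean: Mapping[str, float] = field(
        default_factory=lambda: {"tomm20": 30.0, "ndufb8": 20.0, "mtco1": 25.0, "insulin": 35.0}
    )
    deficiency_shift_N: float = 0.0
    deficiency_shift_M: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_T", "see_N", "see_M", "sigma_ins"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for ch, v in self.npc_mean.items():
            if v < 0:
                raise ConfigurationError(f"npc_mean[{ch}] must be >= 0")
        missing = set(MITO_CHANNELS) - set(self.npc_mean)
        if missing:
            raise ConfigurationError(f"npc_mean missing channels: {sorted(missing)}")


@dataclass(frozen=True)
class CompositionSpec:
    """Cell-population parameters of the composition panel."""

    cells_per_islet: float = 120.0
    alpha_fraction: float = 0.07
    beta_fraction: float = 0.88
    bihormonal_fraction: float = 0.005
    ki67_rate_alpha: float = 0.002
    ki67_rate_beta: float = 0.002
    tunel_islet_rate: float = 0.02
    mantle_placement: bool = True

    def __post_init__(self) -> None:
        fracs = (self.alpha_fraction, self.beta_fraction, self.bihormonal_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigurationError("alpha + beta + bihormonal fractions must be <= 1")
        for name in ("ki67_rate_alpha", "ki67_rate_beta", "tunel_islet_rate"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.cells_per_islet < 1:
            raise ConfigurationError("cells_per_islet must be >= 1")

    @property
    def class_probs(self) -> np.ndarray:
        p = np.array(
            [self.alpha_fraction, self.beta_fraction, self.bihormonal_fraction], dtype=float
        )
        return np.append(p, max(0.0, 1.0 - p.sum()))


@dataclass
class SyntheticImageBundle:
    """A rendered composition-panel field of view with exact ground truth."""

    image: np.ndarray  # (4, H, W) float
    islet_mask: np.ndarray  # (H, W) uint16 labels, 0 = background
    nucleus_mask: np.ndarray  # (H, W) uint32 per-cell nuclear labels
    cell_table: pd.DataFrame  # islet_id, cell_id, row, col, true_class, ki67, tunel
    npc_image: np.ndarray  # (4, H, W) background-only
    gain: dict[int, float]  # per-islet multiplicative acquisition factor
    channels: tuple[str, ...] = COMPOSITION_CHANNELS

    def __post_init__(self) -> None:
        if self.image.shape[1:] != self.islet_mask.shape:
            raise DataError("image and islet_mask dimensions differ")
        if any(g <= 0 for g in self.gain.values()):
            raise DataError("per-islet gain must be > 0")


# ---------------------------------------------------------------------------
# intensity panel
# ---------------------------------------------------------------------------


def _draw_islet_logs(
    rng: np.random.Generator, params: IntensityModelParams, n: int
) -> dict[str, np.ndarray]:
    x = rng.normal(params.mu_T, params.sigma_T, size=n)
    y_n = (
        params.beta0_N
        + params.beta1_N * x
        - params.deficiency_shift_N * params.see_N
        + rng.normal(0.0, params.see_N, size=n)
    )
    y_m = (
        params.beta0_M
        + params.beta1_M * x
        - params.deficiency_shift_M * params.see_M
        + rng.normal(0.0, params.see_M, size=n)
    )
    y_i = rng.normal(params.mu_ins, params.sigma_ins, size=n)
    return {"tomm20": x, "ndufb8": y_n, "mtco1": y_m, "insulin": y_i}


def gen_intensity_table(
    cohort: CohortConfig,
    params_per_group: Mapping[tuple[str, str], IntensityModelParams],
) -> pd.DataFrame:
    """Simulate the per-islet mitochondrial intensity panel for a cohort.

    Returns one row per islet ROI with raw (background-offset) channel means,
    the matched NPC means, and the latent log-intensities as ground-truth
    columns (``*_log_true``).
    """
    for grp in cohort.groups:
        if tuple(grp) not in params_per_group:
            raise ConfigurationError(f"missing IntensityModelParams for group {grp}")

    frames = []
    for genotype, age in cohort.groups:
        params = params_per_group[(genotype, age)]
        for m in range(cohort.n_mice_per_group):
            mouse_id = f"{genotype}_{age}_m{m + 1}"
            rng = child_rng(cohort.seed, f"intensity/{mouse_id}")
            logs = _draw_islet_logs(rng, params, cohort.islets_per_mouse)
            n = cohort.islets_per_mouse
            rec: dict[str, object] = {
                "mouse_id": mouse_id,
                "genotype": genotype,
                "age": age,
                "group": f"{genotype}:{age}",
                "roi_id": [f"{mouse_id}_islet{i + 1}" for i in range(n)],
                "roi_kind": "islet",
                "cell_population": "all",
                "roi_area": rng.integers(500, 3000, size=n),
            }
            for ch in MITO_CHANNELS:
                rec[f"{ch}_raw"] = np.exp(logs[ch]) + params.npc_mean[ch]
                rec[f"{ch}_npc"] = params.npc_mean[ch]
                rec[f"{ch}_log_true"] = logs[ch]
            frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def gen_deficient_cohort(
    base: IntensityModelParams,
    shift_grid: Sequence[float],
    n_per_shift: int,
    seed: int,
) -> pd.DataFrame:
    """Strata of islets at graded complex-I deficiency shifts (in SEE units).

    One stratum per shift ``k`` with the NDUFB8 conditional mean lowered by
    ``k * see_N``; the stratum label is retained in the ``shift`` column.
    """
    if len(shift_grid) == 0:
        raise ConfigurationError("shift_grid must be non-empty")
    if any(k < 0 for k in shift_grid):
        raise ConfigurationError("shifts must be >= 0")
    if n_per_shift < 1:
        raise ConfigurationError("n_per_shift must be >= 1")

    frames = []
    for k in shift_grid:
        params = replace(base, deficiency_shift_N=float(k))
        cohort = CohortConfig(
            n_mice_per_group=1,
            islets_per_mouse=n_per_shift,
            groups=((f"shift{k:g}", "na"),),
            seed=seed,
        )
        tbl = gen_intensity_table(cohort, {(f"shift{k:g}", "na"): params})
        tbl["shift"] = float(k)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# composition panel: per-cell table (image-free fast path)
# ---------------------------------------------------------------------------


def _draw_islet_cells(
    rng: np.random.Generator, spec: CompositionSpec, n_cells: int
) -> pd.DataFrame:
    classes = rng.choice(len(CELL_CLASSES), size=n_cells, p=spec.class_probs)
    class_labels = np.array(CELL_CLASSES)[classes]
    ki67_p = np.zeros(n_cells)
    ki67_p[class_labels == "alpha"] = spec.ki67_rate_alpha
    ki67_p[class_labels == "beta"] = spec.ki67_rate_beta
    ki67 = rng.random(n_cells) < ki67_p
    tunel = np.zeros(n_cells, dtype=bool)
    if rng.random() < spec.tunel_islet_rate:
        tunel[rng.integers(n_cells)] = True  # a flagged islet holds >=1 apoptotic cell
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "true_class": class_labels,
            "ki67": ki67,
            "tunel": tunel,
        }
    )


def gen_composition_table(spec: CompositionSpec, cohort: CohortConfig) -> pd.DataFrame:
    """Per-cell ground-truth records for a cohort, without rendering images.

    Cell counts per islet are Poisson around ``spec.cells_per_islet`` (min 1);
    classes are multinomial; Ki67 flags are Bernoulli per class rate; TUNEL
    islet flags are Bernoulli per islet.
    """
    frames = []
    for genotype, age in cohort.groups:
        for m in range(cohort.n_mice_per_group):
            mouse_id = f"{genotype}_{age}_m{m + 1}"
            rng = child_rng(cohort.seed, f"composition/{mouse_id}")
            for islet in range(1, cohort.islets_per_mouse + 1):
                n_cells = max(1, int(rng.poisson(spec.cells_per_islet)))
                cells = _draw_islet_cells(rng, spec, n_cells)
                cells.insert(0, "islet_id", islet)
                cells.insert(0, "group", f"{genotype}:{age}")
                cells.insert(0, "age", age)
                cells.insert(0, "genotype", genotype)
                cells.insert(0, "mouse_id", mouse_id)
                frames.append(cells)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# composition panel: rendered images
# ---------------------------------------------------------------------------

_CELL_RADIUS = 4  # px: cytoplasm disk
_NUCLEUS_RADIUS = 2  # px: nuclear disk
_SIGNAL_AMP = 3000.0  # fluorophore amplitude above background
_BACKGROUND = {"dapi": 110.0, "ki67": 90.0, "glucagon": 100.0, "insulin": 105.0}


def _ellipse_params(rng: np.random.Generator) -> tuple[float, float, float]:
    a = rng.uniform(28.0, 44.0)
    b = rng.uniform(22.0, a)
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta


def _place_islets(
    rng: np.random.Generator, n_islets: int, shape: tuple[int, int], max_tries: int = 2000
) -> list[tuple[float, float, float, float, float]]:
    placed: list[tuple[float, float, float, float, float]] = []
    tries = 0
    while len(placed) < n_islets:
        if tries >= max_tries:
            raise DataError(
                f"could not place {n_islets} non-overlapping islets on canvas {shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        a, b, theta = _ellipse_params(rng)
        margin = a + 3
        if 2 * margin >= min(shape):
            raise DataError(f"canvas {shape} too small for islet radius {a:.0f}")
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 > (a + a0 + 4) ** 2 for r0, c0, a0, _, _ in placed):
            placed.append((r, c, a, b, theta))
    return placed


def _ellipse_interior(
    shape: tuple[int, int], r0: float, c0: float, a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel coordinates inside the ellipse and their normalised radius."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    q = (u / a) ** 2 + (v / b) ** 2
    inside = q <= 1.0
    return rr[inside], cc[inside], np.sqrt(q[inside])


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = rr**2 + cc**2 <= radius**2
    return rr[keep], cc[keep]


def gen_islet_image(
    spec: CompositionSpec,
    n_islets: int,
    canvas: tuple[int, int] = (512, 512),
    seed: int = 0,
    *,
    noise_sd: float = 0.0,
    gain_range: tuple[float, float] = (0.7, 1.4),
) -> SyntheticImageBundle:
    """Render a composition-panel field of view.

    Islets are non-overlapping ellipses; each cell is a cytoplasmic disk with
    a nuclear centre.  DAPI marks every nucleus, Ki67 marks flagged nuclei,
    glucagon marks α and bihormonal cytoplasm, insulin marks β and bihormonal
    cytoplasm.  With ``mantle_placement`` α-cells occupy the outermost radial
    quantiles.  A per-islet gain multiplies all four channels over the islet
    mask; the cell table is unaffected by gain, background or noise.
    """
    if n_islets < 1:
        raise ConfigurationError("n_islets must be >= 1")
    rng = child_rng(seed, "islet_image")
    H, W = canvas
    islet_mask = np.zeros((H, W), dtype=np.uint16)
    nucleus_mask = np.zeros((H, W), dtype=np.uint32)
    image = np.empty((4, H, W), dtype=np.float64)
    for ci, ch in enumerate(COMPOSITION_CHANNELS):
        image[ci] = _BACKGROUND[ch]
    npc_image = image.copy()

    cell_rows = []
    gains: dict[int, float] = {}
    nuc_label = 0
    d_rr, d_cc = _disk_offsets(_CELL_RADIUS)
    n_rr, n_cc = _disk_offsets(_NUCLEUS_RADIUS)
    cyto_keep = d_rr**2 + d_cc**2 > _NUCLEUS_RADIUS**2  # cytoplasm = disk minus nucleus

    for islet_id, (r0, c0, a, b, theta) in enumerate(
        _place_islets(rng, n_islets, (H, W)), start=1
    ):
        rr, cc, q = _ellipse_interior((H, W), r0, c0, a, b, theta)
        islet_mask[rr, cc] = islet_id
        gains[islet_id] = float(rng.uniform(*gain_range))

        # candidate cell centres: jittered grid inside the eroded ellipse
        step = 2 * _CELL_RADIUS + 1
        interior = q <= 1.0 - (_CELL_RADIUS + 1) / min(a, b)
        cand_r, cand_c, cand_q = rr[interior], cc[interior], q[interior]
        on_grid = (cand_r % step == step // 2) & (cand_c % step == step // 2)
        cand_r, cand_c, cand_q = cand_r[on_grid], cand_c[on_grid], cand_q[on_grid]

        n_cells = min(max(1, int(rng.poisson(spec.cells_per_islet))), len(cand_r))
        if n_cells == 0:
            continue
        pick = rng.choice(len(cand_r), size=n_cells, replace=False)
        cells = _draw_islet_cells(rng, spec, n_cells)

        if spec.mantle_placement:
            # outermost positions go to alpha cells, the rest are shuffled
            order_pos = np.argsort(cand_q[pick])[::-1]  # descending radius
            is_alpha = (cells["true_class"] == "alpha").to_numpy()
            cell_order = np.concatenate(
                [np.flatnonzero(is_alpha), rng.permutation(np.flatnonzero(~is_alpha))]
            )
        else:
            order_pos = rng.permutation(n_cells)
            cell_order = np.arange(n_cells)

        for pos_idx, cell_idx in zip(order_pos, cell_order):
            cy, cx = int(cand_r[pick[pos_idx]]), int(cand_c[pick[pos_idx]])
            cls = cells.at[cell_idx, "true_class"]
            nuc_label += 1
            nucleus_mask[cy + n_rr, cx + n_cc] = nuc_label
            image[0, cy + n_rr, cx + n_cc] += _SIGNAL_AMP  # DAPI
            if cells.at[cell_idx, "ki67"]:
                image[1, cy + n_rr, cx + n_cc] += _SIGNAL_AMP
            cyt_r, cyt_c = cy + d_rr[cyto_keep], cx + d_cc[cyto_keep]
            if cls in ("alpha", "bihormonal"):
                image[2, cyt_r, cyt_c] += _SIGNAL_AMP
            if cls in ("beta", "bihormonal"):
                image[3, cyt_r, cyt_c] += _SIGNAL_AMP
            cell_rows.append(
                {
                    "islet_id": islet_id,
                    "cell_id": int(cells.at[cell_idx, "cell_id"]),
                    "nucleus_label": nuc_label,
                    "row": cy,
                    "col": cx,
                    "true_class": cls,
                    "ki67": bool(cells.at[cell_idx, "ki67"]),
                    "tunel": bool(cells.at[cell_idx, "tunel"]),
                }
            )

        image[:, rr, cc] *= gains[islet_id]

    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)

    cell_table = pd.DataFrame(cell_rows)
    return SyntheticImageBundle(
        image=image,
        islet_mask=islet_mask,
        nucleus_mask=nucleus_mask,
        cell_table=cell_table,
        npc_image=npc_image,
        gain=gains,
    )


def find_tunel_seed(
    spec: CompositionSpec,
    cohort: CohortConfig,
    target_flagged_islets: int,
    max_tries: int = 500,
) -> int:
    """Smallest seed >= cohort.seed whose composition table flags exactly
    ``target_flagged_islets`` islets with >=1 TUNEL-positive cell."""
    for seed in range(cohort.seed, cohort.seed + max_tries):
        tbl = gen_composition_table(spec, replace(cohort, seed=seed))
        flagged = tbl.groupby(["mouse_id", "islet_id"])["tunel"].any().sum()
        if flagged == target_flagged_islets:
            return seed
    raise DataError(
        f"no seed in [{cohort.seed}, {cohort.seed + max_tries}) yields "
        f"{target_flagged_islets} flagged islets"
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(outdir: str | Path, seed: int = 0) -> pd.DataFrame:
    """Write the canonical small fixture set (CSV + TIFF) and a hash manifest.

    Fixtures: a control-only intensity cohort, a deficiency-shifted cohort,
    and one rendered image bundle.  Deterministic under ``seed``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory not writable: {outdir}") from exc

    params = IntensityModelParams()
    control = gen_intensity_table(
        CohortConfig(n_mice_per_group=3, islets_per_mouse=20, groups=(("WT", "12w"),), seed=seed),
        {("WT", "12w"): params},
    )
    shifted = gen_deficient_cohort(params, [0.0, 2.0, 3.0], n_per_shift=50, seed=seed)
    bundle = gen_islet_image(
        CompositionSpec(cells_per_islet=25.0), n_islets=4, canvas=(256, 256), seed=seed
    )

    files: dict[str, Path] = {}
    files["control_cohort.csv"] = outdir / "control_cohort.csv"
    control.to_csv(files["control_cohort.csv"], index=False)
    files["shifted_cohort.csv"] = outdir / "shifted_cohort.csv"
    shifted.to_csv(files["shifted_cohort.csv"], index=False)

    img16 = np.clip(np.rint(bundle.image), 0, 65535).astype(np.uint16)
    npc16 = np.clip(np.rint(bundle.npc_image), 0, 65535).astype(np.uint16)
    files["bundle_image.tif"] = outdir / "bundle_image.tif"
    tifffile.imwrite(files["bundle_image.tif"], img16, photometric="minisblack")
    files["bundle_npc.tif"] = outdir / "bundle_npc.tif"
    tifffile.imwrite(files["bundle_npc.tif"], npc16, photometric="minisblack")
    files["bundle_islet_mask.tif"] = outdir / "bundle_islet_mask.tif"
    tifffile.imwrite(files["bundle_islet_mask.tif"], bundle.islet_mask)
    files["bundle_nucleus_mask.tif"] = outdir / "bundle_nucleus_mask.tif"
    tifffile.imwrite(files["bundle_nucleus_mask.tif"], bundle.nucleus_mask.astype(np.uint16))
    files["bundle_cells.csv"] = outdir / "bundle_cells.csv"
    bundle.cell_table.to_csv(files["bundle_cells.csv"], index=False)

    manifest = pd.DataFrame(
        {"file": list(files), "sha256": [_sha256(p) for p in files.values()]}
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
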