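"""Cell classification by marker co-localisation and islet composition metrics.

Cells are identified on the composition panel (DAPI / Ki67 / glucagon /
insulin): a nucleus co-localised with glucagon is an α-cell, with insulin a
β-cell, with both a bihormonal cell, with neither "other".  Because the real
acquisition sets laser power per islet, every positivity decision here is
made *within* an islet against that islet's own background, so the
classification is invariant to any per-islet gain:

* hormone positivity — the mean signal in a perinuclear annulus (the
  cytoplasm) is compared with a multiple of the islet's stromal background
  (pixels of the islet away from any nucleus);
* Ki67 positivity — the nuclear mean is compared the same way (Ki67 is a
  nuclear antigen).

Composition metrics follow the counting scheme of the assay: per-islet class
counts, islet pixel/µm² area, β:α ratio over pooled counts, per-mouse
percentages of islets with ≥1 Ki67-positive cell (any / α / β), bihormonal
cells as a percentage of islet cells, glucagon-positive cells inside the
eroded "β-cell core", and TUNEL-positive islet counts.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion

from .errors import ConfigurationError, DataError

__all__ = [
    "classify_cells",
    "compute_composition",
    "beta_alpha_ratio",
    "ki67_islet_metrics",
    "bihormonal_fraction",
    "core_glucagon_fraction",
    "tunel_count",
]

log = logging.getLogger(__name__)

_ANNULUS_WIDTH = 2  # px: cytoplasm band outside the nucleus
_STROMA_CLEARANCE = 5  # px: dilation that keeps stromal background clear of cells
_BACKGROUND_FACTOR = 2.0  # positive if mean signal > factor * islet background


def _annulus_mean(channel: np.ndarray, nucleus: np.ndarray) -> float:
    ring = dilation(nucleus, disk(_ANNULUS_WIDTH)) & ~nucleus
    return float(channel[ring].mean())


def classify_cells(
    nucleus_mask: np.ndarray,
    glucagon: np.ndarray,
    insulin: np.ndarray,
    ki67: np.ndarray,
    islet_mask: np.ndarray,
    thresholds_mode: Literal["background", "otsu"] = "background",
) -> pd.DataFrame:
    """Classify each labelled nucleus as alpha / beta / bihormonal / other.

    Returns one row per nucleus: islet_id, nucleus_label, row, col, class,
    ki67 flag.  ``thresholds_mode='background'`` (default) calls a marker
    positive when its per-cell mean exceeds ``2x`` the islet's nucleus-free
    background; ``'otsu'`` instead splits the per-cell means bimodally within
    each islet.  Both rules are per-islet, hence gain-invariant.
    """
    for img in (glucagon, insulin, ki67):
        if img.shape != nucleus_mask.shape or img.shape != islet_mask.shape:
            raise DataError("channel/mask shapes are not congruent")

    labels = np.unique(nucleus_mask)
    labels = labels[labels != 0]
    rows: list[dict[str, object]] = []
    if labels.size == 0:
        log.warning("no nuclei labelled; empty classification")
        return pd.DataFrame(
            columns=["islet_id", "nucleus_label", "row", "col", "class", "ki67"]
        )

    centroids = ndimage.center_of_mass(
        np.ones_like(nucleus_mask), nucleus_mask, labels
    )
    any_nucleus = dilation(nucleus_mask > 0, disk(_STROMA_CLEARANCE))

    for islet_id in np.unique(islet_mask[islet_mask != 0]):
        in_islet = islet_mask == islet_id
        islet_labels = [
            (lab, rc)
            for lab, rc in zip(labels, centroids)
            if in_islet[int(round(rc[0])), int(round(rc[1]))]
        ]
        if not islet_labels:
            log.warning("islet %d contains no nuclei", islet_id)
            continue
        stroma = in_islet & ~any_nucleus
        per_cell = {
            lab: {
                "glucagon": _annulus_mean(glucagon, nucleus_mask == lab),
                "insulin": _annulus_mean(insulin, nucleus_mask == lab),
                "ki67": float(ki67[nucleus_mask == lab].mean()),
            }
            for lab, _ in islet_labels
        }
        if thresholds_mode == "background":
            if not stroma.any():
                raise DataError(f"islet {islet_id} has no nucleus-free background pixels")
            thr = {
                ch: _BACKGROUND_FACTOR * float(np.median(img[stroma]))
                for ch, img in (("glucagon", glucagon), ("insulin", insulin), ("ki67", ki67))
            }
        elif thresholds_mode == "otsu":
            thr = {}
            for ch in ("glucagon", "insulin", "ki67"):
                vals = np.array([v[ch] for v in per_cell.values()])
                if vals.max() <= 2 * vals.min():  # no bimodal separation: all negative
                    thr[ch] = np.inf
                else:
                    thr[ch] = float(threshold_otsu(vals))
        else:
            raise ConfigurationError(f"unknown thresholds_mode {thresholds_mode!r}")

        for lab, (r, c) in islet_labels:
            g_pos = per_cell[lab]["glucagon"] > thr["glucagon"]
            i_pos = per_cell[lab]["insulin"] > thr["insulin"]
            cls = (
                "bihormonal"
                if g_pos and i_pos
                else "alpha" if g_pos else "beta" if i_pos else "other"
            )
            rows.append(
                {
                    "islet_id": int(islet_id),
                    "nucleus_label": int(lab),
                    "row": float(r),
                    "col": float(c),
                    "class": cls,
                    "ki67": bool(per_cell[lab]["ki67"] > thr["ki67"]),
                }
            )
    return pd.DataFrame(rows)


def compute_composition(
    cells: pd.DataFrame,
    islet_mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
    *,
    group_cols: tuple[str, ...] = (),
    class_col: str = "class",
) -> pd.DataFrame:
    """Aggregate per-cell records into per-islet composition rows.

    Counts every class plus Ki67 tallies (total and per hormone class) and
    TUNEL-positive cells; with an ``islet_mask``, adds the islet pixel area
    and, given ``pixel_size_um``, the area in µm².
    """
    if cells.empty:
        return pd.DataFrame()
    keys = [*group_cols, "islet_id"]
    rows = []
    for key, grp in cells.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        islet_id = rec["islet_id"]
        rec["n_total"] = len(grp)
        for cls in ("alpha", "beta", "bihormonal", "other"):
            rec[f"n_{cls}"] = int((grp[class_col] == cls).sum())
        if "ki67" in grp:
            rec["n_ki67_total"] = int(grp["ki67"].sum())
            rec["n_ki67_alpha"] = int((grp["ki67"] & (grp[class_col] == "alpha")).sum())
            rec["n_ki67_beta"] = int((grp["ki67"] & (grp[class_col] == "beta")).sum())
        if "tunel" in grp:
            rec["n_tunel"] = int(grp["tunel"].sum())
        if islet_mask is not None:
            area = int((islet_mask == islet_id).sum())
            if area == 0:
                raise DataError(f"cells reference islet {islet_id} absent from mask")
            rec["area_px"] = area
            if pixel_size_um is not None:
                rec["area_um2"] = area * pixel_size_um**2
        rows.append(rec)
    return pd.DataFrame(rows)


def beta_alpha_ratio(composition: pd.DataFrame) -> float:
    """β:α cell ratio over the pooled composition rows.

    ``sum(n_beta) / sum(n_alpha)``; e.g. pooled counts 53:4 give 13.25.
    A zero α pool leaves the ratio undefined and raises.
    """
    n_alpha = int(composition["n_alpha"].sum())
    n_beta = int(composition["n_beta"].sum())
    if n_alpha == 0:
        raise DataError("pooled alpha count is zero; beta:alpha ratio undefined")
    return n_beta / n_alpha


def ki67_islet_metrics(
    composition: pd.DataFrame, mouse_col: str = "mouse_id"
) -> pd.DataFrame:
    """Per-mouse Ki67 proliferation metrics.

    For each mouse: the percentage of its islets containing ≥1 Ki67-positive
    cell (any class, α-restricted, β-restricted), and the mean number of
    Ki67-positive cells per islet by class.
    """
    rows = []
    for mouse, grp in composition.groupby(mouse_col, sort=True):
        n_islets = len(grp)
        rows.append(
            {
                mouse_col: mouse,
                "n_islets": n_islets,
                "pct_islets_ki67_any": 100.0 * (grp["n_ki67_total"] >= 1).mean(),
                "pct_islets_ki67_alpha": 100.0 * (grp["n_ki67_alpha"] >= 1).mean(),
                "pct_islets_ki67_beta": 100.0 * (grp["n_ki67_beta"] >= 1).mean(),
                "mean_ki67_cells_per_islet": float(grp["n_ki67_total"].mean()),
                "mean_ki67_alpha_per_islet": float(grp["n_ki67_alpha"].mean()),
                "mean_ki67_beta_per_islet": float(grp["n_ki67_beta"].mean()),
            }
        )
    return pd.DataFrame(rows)


def bihormonal_fraction(composition: pd.DataFrame) -> pd.Series:
    """Bihormonal cells as a percentage of all cells, per islet.

    Empty islets (n_total = 0) are excluded with a warning; summarise the
    returned per-islet percentages with group_stats.summarize.
    """
    empty = composition["n_total"] == 0
    if empty.any():
        log.warning("%d empty islet(s) excluded from bihormonal fraction", empty.sum())
    rows = composition[~empty]
    return 100.0 * rows["n_bihormonal"] / rows["n_total"]


def core_glucagon_fraction(
    cells: pd.DataFrame,
    islet_mask: np.ndarray,
    erosion_fraction: float = 0.3,
    class_col: str = "class",
) -> pd.DataFrame:
    """Percentage of cells inside the β-cell core that are glucagon-positive.

    The core of each islet is its mask eroded by ``erosion_fraction`` of the
    equivalent-circle radius; a cell is in the core if its centroid falls in
    the eroded mask.  Glucagon-positive means class alpha or bihormonal.
    Islets whose core erodes to nothing are skipped with a warning.
    """
    if not 0 <= erosion_fraction < 1:
        raise ConfigurationError("erosion_fraction must lie in [0, 1)")
    rows = []
    for islet_id, grp in cells.groupby("islet_id", sort=True):
        region = islet_mask == islet_id
        if not region.any():
            raise DataError(f"islet {islet_id} absent from mask")
        r_eq = np.sqrt(region.sum() / np.pi)
        r_erode = int(round(erosion_fraction * r_eq))
        core = erosion(region, disk(r_erode)) if r_erode > 0 else region
        if not core.any():
            log.warning("islet %d core empty after erosion; skipped", islet_id)
            continue
        rr = grp["row"].round().astype(int).to_numpy()
        cc = grp["col"].round().astype(int).to_numpy()
        in_core = core[rr, cc]
        n_core = int(in_core.sum())
        gluc = grp[class_col].isin(["alpha", "bihormonal"]).to_numpy()
        rows.append(
            {
                "islet_id": islet_id,
                "n_core_cells": n_core,
                "n_core_glucagon": int((in_core & gluc).sum()),
                "pct_core_glucagon": (
                    100.0 * (in_core & gluc).sum() / n_core if n_core else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def tunel_count(
    composition: pd.DataFrame, group_cols: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Number and percentage of islets with ≥1 TUNEL-positive (apoptotic) cell."""
    def _one(grp: pd.DataFrame) -> pd.Series:
        flagged = int((grp["n_tunel"] >= 1).sum())
        return pd.Series(
            {
                "n_islets": len(grp),
                "n_tunel_islets": flagged,
                "pct_tunel_islets": 100.0 * flagged / len(grp),
            }
        )

    if not group_cols:
        return _one(composition).to_frame().T
    out = composition.groupby(list(group_cols), sort=True).apply(_one, include_groups=False)
    return out.reset_index()
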