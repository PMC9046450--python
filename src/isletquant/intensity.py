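"""Per-ROI intensity extraction, background correction and log transform.

The measurement model: each islet (or cell-population) ROI contributes the
arithmetic mean pixel intensity per channel; the mean intensity of a matched
no-primary-control (NPC) section estimates non-specific background and is
subtracted; the corrected value is natural-log transformed to normalise the
intensity distribution.  ROIs whose corrected value is non-positive in a
channel are flagged excluded for that channel — never silently dropped —
because a log of a non-positive background-corrected mean is undefined and
flooring it would fabricate extreme values.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "measure_roi_mean",
    "background_correct",
    "log_transform",
    "quantify_image_set",
]

log = logging.getLogger(__name__)


def measure_roi_mean(channel: np.ndarray, label_mask: np.ndarray, label: int) -> float:
    """Arithmetic mean of ``channel`` over pixels where ``label_mask == label``."""
    if channel.shape != label_mask.shape:
        raise DataError(
            f"channel shape {channel.shape} != mask shape {label_mask.shape}"
        )
    sel = label_mask == label
    if not sel.any():
        raise DataError(f"label {label} absent from mask")
    return float(channel[sel].mean())


def background_correct(
    records: pd.DataFrame, channels: Sequence[str]
) -> pd.DataFrame:
    """Subtract the matched NPC mean from each channel's ROI mean.

    Expects ``<ch>_raw`` and ``<ch>_npc`` columns; adds ``<ch>_corrected`` and
    ``<ch>_excluded``.  A channel is excluded (with a logged warning) when the
    corrected value is non-positive; the record itself is always retained.
    """
    out = records.copy()
    for ch in channels:
        raw_col, npc_col = f"{ch}_raw", f"{ch}_npc"
        if raw_col not in out.columns:
            raise DataError(f"missing column {raw_col}")
        if npc_col not in out.columns:
            raise DataError(f"missing NPC column {npc_col} for channel {ch}")
        corrected = out[raw_col] - out[npc_col]
        excluded = corrected <= 0
        out[f"{ch}_corrected"] = corrected.where(~excluded)
        out[f"{ch}_excluded"] = excluded
        if excluded.any():
            ids = out.loc[excluded, "roi_id"].tolist() if "roi_id" in out else list(
                out.index[excluded]
            )
            log.warning(
                "channel %s excluded for %d ROI(s) (non-positive after background "
                "correction): %s",
                ch,
                int(excluded.sum()),
                ids[:10],
            )
    return out


def log_transform(corrected: pd.DataFrame, channels: Sequence[str]) -> pd.DataFrame:
    """Natural log of the background-corrected channel means.

    Adds ``<ch>_log`` columns; excluded channels stay missing.  Calling this
    on a frame without the correction stage is an error.
    """
    out = corrected.copy()
    for ch in channels:
        col = f"{ch}_corrected"
        if col not in out.columns:
            raise DataError(f"missing column {col}; run background_correct first")
        vals = out[col]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            raise DataError(f"non-positive corrected values in channel {ch}")
        out[f"{ch}_log"] = np.log(vals)
    return out


def quantify_image_set(
    images: Mapping[str, np.ndarray],
    masks: Mapping[str, np.ndarray],
    npc_images: Mapping[str, np.ndarray],
    channel_map: Mapping[str, int],
    *,
    cell_tables: Mapping[str, pd.DataFrame] | None = None,
    nucleus_masks: Mapping[str, np.ndarray] | None = None,
    populations: Sequence[str] = ("alpha", "beta"),
) -> pd.DataFrame:
    """Extract RawIntensityRecord rows from a batch of multi-channel images.

    ``images`` maps an image id to a (C, H, W) array, ``masks`` to its integer
    islet label mask and ``npc_images`` to the matched background-only image;
    ``channel_map`` assigns channel names to page indices.  When a ground
    truth ``cell_tables``/``nucleus_masks`` pair is supplied, additional
    records with ``roi_kind='cell_population'`` are produced per islet for
    each requested population, with the ROI taken as the union of that
    population's nuclear masks.
    """
    rows = []
    for img_id, image in images.items():
        if img_id not in masks:
            raise DataError(f"missing mask for image {img_id}")
        if img_id not in npc_images:
            raise DataError(f"missing NPC image for image {img_id}")
        mask, npc = masks[img_id], npc_images[img_id]
        labels = np.unique(mask)
        labels = labels[labels != 0]
        if labels.size == 0:
            log.warning("empty mask for image %s; no records produced", img_id)
            continue
        npc_means = {ch: float(npc[ci].mean()) for ch, ci in channel_map.items()}
        for label in labels:
            row: dict[str, object] = {
                "image_id": img_id,
                "roi_id": f"{img_id}_islet{int(label)}",
                "islet_id": int(label),
                "roi_kind": "islet",
                "cell_population": "all",
                "roi_area": int((mask == label).sum()),
            }
            for ch, ci in channel_map.items():
                row[f"{ch}_raw"] = measure_roi_mean(image[ci], mask, label)
                row[f"{ch}_npc"] = npc_means[ch]
            rows.append(row)

        if cell_tables is not None and img_id in cell_tables:
            nmask = nucleus_masks[img_id] if nucleus_masks else None
            if nmask is None:
                raise DataError(f"cell table given without nucleus mask for {img_id}")
            cells = cell_tables[img_id]
            for label in labels:
                for pop in populations:
                    sel = cells[
                        (cells["islet_id"] == label) & (cells["true_class"] == pop)
                    ]
                    if sel.empty:
                        continue
                    pop_mask = np.isin(nmask, sel["nucleus_label"].to_numpy())
                    row = {
                        "image_id": img_id,
                        "roi_id": f"{img_id}_islet{int(label)}_{pop}",
                        "islet_id": int(label),
                        "roi_kind": "cell_population",
                        "cell_population": pop,
                        "roi_area": int(pop_mask.sum()),
                    }
                    for ch, ci in channel_map.items():
                        row[f"{ch}_raw"] = float(image[ci][pop_mask].mean())
                        row[f"{ch}_npc"] = npc_means[ch]
                    rows.append(row)
    return pd.DataFrame(rows)
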