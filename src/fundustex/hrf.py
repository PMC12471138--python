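"""Loader and validation runner for a local copy of the public
high-resolution fundus database (45 images, three groups of 15).

Expected layout under ``root``::

    images/   01_h.jpg .. 15_h.jpg, 01_g.jpg .., 01_dr.jpg ..
    manual1/  ground-truth vessel masks with matching stems (.tif/.png)
    mask/     optional FOV masks named <stem>_mask.*

The database is external and optional: nothing in the package downloads
it, and all validation entry points raise :class:`FileNotFoundError`
when the directory is absent.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .color_histogram import image_histograms, mahalanobis_separation
from .glcm_texture import FEATURE_NAMES, vessel_texture_profile
from .vessel_segmentation import MatchedFilterParams, dice_coefficient, segment_vessels

__all__ = ["discover", "run_validation"]

GROUP_SUFFIX = {"h": "healthy", "g": "glaucoma", "dr": "diabetic_retinopathy"}
IMAGE_SUFFIXES = (".jpg", ".jpeg", ".png", ".tif", ".tiff", ".bmp")


def _group_of(stem: str) -> str | None:
    parts = stem.lower().split("_")
    return GROUP_SUFFIX.get(parts[-1]) if parts else None


def discover(root: str | Path) -> pd.DataFrame:
    """Scan a database directory into a manifest frame.

    Returns columns ``file``, ``group``, ``mask_file`` (may be empty) and
    ``fov_file`` (may be empty), sorted by file name.
    """
    root = Path(root)
    images_dir = root / "images" if (root / "images").exists() else root
    if not images_dir.exists():
        raise FileNotFoundError(f"no image directory under {root}")
    gt_dirs = [root / "manual1", root / "gt", root / "masks"]
    fov_dirs = [root / "mask", root / "fov"]
    rows = []
    for path in sorted(images_dir.iterdir()):
        if path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        group = _group_of(path.stem)
        if group is None:
            continue
        mask_file = ""
        for d in gt_dirs:
            hits = list(d.glob(f"{path.stem}.*")) if d.exists() else []
            if hits:
                mask_file = str(hits[0])
                break
        fov_file = ""
        for d in fov_dirs:
            hits = list(d.glob(f"{path.stem}_mask.*")) if d.exists() else []
            if hits:
                fov_file = str(hits[0])
                break
        rows.append(
            {"file": str(path), "group": group, "mask_file": mask_file, "fov_file": fov_file}
        )
    if not rows:
        raise FileNotFoundError(f"no recognizable fundus images under {root}")
    return pd.DataFrame(rows)


def run_validation(
    root: str | Path,
    mf_params: MatchedFilterParams | None = None,
    limit_per_group: int | None = None,
) -> dict:
    """Segment, profile and compare every image in a local database copy.

    Returns a dictionary with per-group texture feature means, the mean
    Dice coefficient against the supplied ground truth, and per-channel
    Mahalanobis distances between group pairs.
    """
    manifest = discover(root)
    if limit_per_group:
        manifest = (
            manifest.groupby("group", group_keys=False)
            .head(limit_per_group)
            .reset_index(drop=True)
        )
    mf_params = mf_params or MatchedFilterParams()

    feature_rows = []
    dice_scores = []
    hists: dict[str, list[np.ndarray]] = {}
    for _, row in manifest.iterrows():
        pixels = np.asarray(iio.imread(row["file"]))[:, :, :3]
        fov = None
        if row["fov_file"]:
            fov = np.asarray(iio.imread(row["fov_file"]))
            fov = (fov[..., 0] if fov.ndim == 3 else fov) > 0
        mask = segment_vessels(pixels, mf_params=mf_params, fov=fov)
        if row["mask_file"]:
            gt = np.asarray(iio.imread(row["mask_file"]))
            gt = (gt[..., 0] if gt.ndim == 3 else gt) > 0
            dice_scores.append(dice_coefficient(mask, gt))
        profile = vessel_texture_profile(pixels, mask)
        feature_rows.append({"group": row["group"], **profile.as_dict()})
        hists.setdefault(row["group"], []).append(image_histograms(pixels))

    features = pd.DataFrame(feature_rows)
    by_group = {
        g: {name: float(sub[name].mean()) for name in FEATURE_NAMES}
        for g, sub in features.groupby("group")
    }
    mahalanobis = {}
    groups = sorted(hists)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            ha, hb = np.stack(hists[ga]), np.stack(hists[gb])
            mahalanobis[f"{ga}|{gb}"] = {
                ch: mahalanobis_separation(ha, hb, channels=(ch,))
                for ch in ("R", "G", "B")
            }
    return {
        "features": by_group,
        "mean_dice": float(np.mean(dice_scores)) if dice_scores else None,
        "n_dice": len(dice_scores),
        "mahalanobis": mahalanobis,
        "n_images": int(len(manifest)),
    }
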