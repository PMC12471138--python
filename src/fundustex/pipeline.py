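"""Study orchestration: manifest ingestion, segmentation -> texture ->
color -> statistics, and report emission.

A study is fully described by a :class:`StudyConfig`; running the same
config twice produces byte-identical JSON reports (no timestamps, all
randomness seeded).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, replace as dc_replace
from itertools import combinations
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color_histogram import (
    CHANNELS,
    average_histogram,
    image_histograms,
    mahalanobis_separation,
)
from .glcm_texture import FEATURE_NAMES, vessel_texture_profile
from .group_stats import lilliefors, rank_sum, summarize_groups
from .preprocess import FundusImage
from .synthetic_fundus import generate_cohort, load_preset, write_cohort
from .vessel_segmentation import (
    MatchedFilterParams,
    dice_coefficient,
    estimate_fov,
    segment_vessels,
)

__all__ = ["StudyConfig", "run_study", "run_synthetic_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce a study run."""

    manifest: str = ""
    out_dir: str = ""
    # preprocessing
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    median_k: int = 3
    # matched filter
    mf_sigma: float = 2.0
    mf_length: int = 9
    mf_orientations: int = 12
    min_component_px: int | None = None
    # texture
    levels: int = 16
    distance: int = 1
    log_base: float = 2.0
    # color
    fov_only_color: bool = False
    covariance: str = "pinv"
    shrinkage: float = 0.1
    # statistics
    wilcoxon_mode: str = "avg_histogram"  # or "per_image_mean"
    mc_replicates: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clahe_tiles", tuple(self.clahe_tiles))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clahe_tiles"] = list(self.clahe_tiles)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @property
    def mf_params(self) -> MatchedFilterParams:
        return MatchedFilterParams(
            sigma=self.mf_sigma,
            length=self.mf_length,
            n_orientations=self.mf_orientations,
        )


#: Matched-filter overrides suited to the 256x256 synthetic scale.
SYNTHETIC_SCALE = {"mf_sigma": 1.5, "mf_length": 7}


def _read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface a manifest-specific message
        raise ValueError(f"malformed manifest {path}: {exc}") from exc
    for col in ("file", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} is missing required column {col!r}")
    counts = df["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("manifest must list at least 2 groups")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with fewer than 2 images: {list(small.index)}")
    missing = [f for f in df["file"] if not Path(f).exists()]
    if missing:
        raise FileNotFoundError(f"missing image files: {missing[:5]}")
    return df


def _load_image(row: pd.Series) -> tuple[FundusImage, np.ndarray | None]:
    pixels = np.asarray(iio.imread(row["file"]))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    fov = None
    if "fov_file" in row and isinstance(row.get("fov_file"), str) and row["fov_file"]:
        fov = np.asarray(iio.imread(row["fov_file"])) > 0
    img = FundusImage(
        pixels=pixels,
        group=str(row["group"]),
        id=Path(str(row["file"])).stem,
        fov_mask=fov if fov is not None else estimate_fov(pixels),
    )
    gt = None
    if "mask_file" in row and isinstance(row.get("mask_file"), str) and row["mask_file"]:
        gt = (np.asarray(iio.imread(row["mask_file"])) > 0).astype(np.uint8)
    return img, gt


def _color_stats(
    hists_by_group: dict[str, np.ndarray],
    means_by_group: dict[str, np.ndarray],
    config: StudyConfig,
) -> dict:
    """Per-channel rank-sum tests, Lilliefors checks, Mahalanobis matrix."""
    groups = sorted(hists_by_group)
    out: dict = {"rank_sum": {}, "lilliefors": {}, "mahalanobis": {}}
    for g in groups:
        for ci, ch in enumerate(CHANNELS):
            vals = means_by_group[g][:, ci]
            key = f"{g}/{ch}"
            if vals.size < 4 or np.std(vals, ddof=1) == 0:
                out["lilliefors"][key] = {"statistic": None, "p_value": None}
                continue
            res = lilliefors(vals, n_mc=config.mc_replicates, seed=config.seed)
            out["lilliefors"][key] = {
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
    for ga, gb in combinations(groups, 2):
        pair = f"{ga}|{gb}"
        out["rank_sum"][pair] = {}
        for ci, ch in enumerate(CHANNELS):
            if config.wilcoxon_mode == "per_image_mean":
                xs = means_by_group[ga][:, ci]
                ys = means_by_group[gb][:, ci]
            else:
                xs = average_histogram(hists_by_group[ga][:, ci, :])
                ys = average_histogram(hists_by_group[gb][:, ci, :])
            res = rank_sum(xs, ys)
            out["rank_sum"][pair][ch] = {
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        dists = {}
        for ch in CHANNELS:
            dists[ch] = mahalanobis_separation(
                hists_by_group[ga],
                hists_by_group[gb],
                channels=(ch,),
                covariance=config.covariance,
                shrinkage=config.shrinkage,
            )
        dists["RGB"] = mahalanobis_separation(
            hists_by_group[ga],
            hists_by_group[gb],
            channels=CHANNELS,
            covariance=config.covariance,
            shrinkage=config.shrinkage,
        )
        out["mahalanobis"][pair] = dists
    return out


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Reads the manifest, segments every image, extracts the texture
    profile of the segmented vasculature, computes color histograms and
    group statistics, writes CSV/JSON artifacts to ``config.out_dir``,
    and returns the report dictionary.
    """
    manifest = _read_manifest(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    feature_rows = []
    dice_rows = []
    run_warnings: list[str] = []
    hists_by_group: dict[str, list[np.ndarray]] = {}
    means_by_group: dict[str, list[np.ndarray]] = {}

    for _, row in manifest.iterrows():
        img, gt = _load_image(row)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mask = segment_vessels(
                img,
                mf_params=config.mf_params,
                min_component_px=config.min_component_px,
                clahe_tiles=config.clahe_tiles,
                clahe_clip=config.clahe_clip,
                median_k=config.median_k,
            )
            profile = vessel_texture_profile(
                img,
                mask,
                n_levels=config.levels,
                distance=config.distance,
                log_base=config.log_base,
            )
        run_warnings.extend(f"{img.id}: {w.message}" for w in caught)
        feature_rows.append({"id": img.id, "group": img.group, **profile.as_dict()})
        if gt is not None:
            dice_rows.append(
                {"id": img.id, "group": img.group, "dice": dice_coefficient(mask, gt)}
            )
        hists = image_histograms(
            img, fov_only=config.fov_only_color, fov=img.fov_mask
        )
        hists_by_group.setdefault(img.group, []).append(hists)
        means_by_group.setdefault(img.group, []).append(
            img.pixels.reshape(-1, 3).mean(axis=0)
        )

    features = pd.DataFrame(feature_rows)
    features.to_csv(out_dir / "features.csv", index=False)
    summary, tests = summarize_groups(features, feature_cols=list(FEATURE_NAMES))
    summary.to_csv(out_dir / "texture_summary.csv", index=False)
    tests.to_csv(out_dir / "texture_tests.csv", index=False)

    dice_table = pd.DataFrame(dice_rows)
    if not dice_table.empty:
        dice_table.to_csv(out_dir / "dice.csv", index=False)

    color = _color_stats(
        {g: np.stack(v) for g, v in hists_by_group.items()},
        {g: np.stack(v) for g, v in means_by_group.items()},
        config,
    )

    report = {
        "provenance": {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": config.seed,
        },
        "n_images": int(len(manifest)),
        "groups": sorted(hists_by_group),
        "texture_summary": summary.to_dict(orient="records"),
        "texture_tests": tests.to_dict(orient="records"),
        "color": color,
        "dice": dice_table.to_dict(orient="records"),
        "warnings": run_warnings,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_synthetic_study(
    presets: list[str],
    seed: int = 0,
    out_dir: str | Path = "report",
    config: StudyConfig | None = None,
    n_images: int | None = None,
) -> dict:
    """Generate preset cohorts and run the full study on them.

    Cohort seeds are derived from ``seed`` (one sub-seed per preset), so
    the whole run is reproducible from the master seed alone.  Matched
    filter parameters default to the synthetic 256x256 scale.
    """
    if len(presets) < 2:
        raise ValueError("need at least 2 presets to compare groups")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(presets))
    frames = []
    for name, sub in zip(presets, sub_seeds):
        overrides = {"seed": int(sub)}
        if n_images is not None:
            overrides["n_images"] = n_images
        spec = load_preset(name, **overrides)
        samples = generate_cohort(spec)
        manifest = write_cohort(samples, out_dir / "cohorts" / name)
        frames.append(pd.read_csv(manifest))
    combined = pd.concat(frames, ignore_index=True)
    manifest_path = out_dir / "manifest.csv"
    combined.to_csv(manifest_path, index=False)

    if config is None:
        config = StudyConfig(**SYNTHETIC_SCALE, seed=seed)
    config = dc_replace(config, manifest=str(manifest_path), out_dir=str(out_dir))
    return run_study(config)
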