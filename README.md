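# fundustex

Retinal fundus image analysis combining two complementary views of the
retina:

- **Vascular texture** — the vessel tree is segmented by oriented
  matched filtering plus iterative (isodata) thresholding; the masked
  grayscale vasculature is quantized to 16 levels and profiled with
  eight co-occurrence (Haralick) texture features (energy, contrast,
  correlation, variance, sum average, sum variance, sum entropy,
  entropy), averaged over the 0/45/90/135-degree orientations.
- **Global color distribution** — per-channel 256-bin RGB histograms,
  group-average histograms, bivariate channel histograms, and
  Mahalanobis separability between groups per channel and for all
  channels combined.

Group comparisons use the two-sample Kolmogorov–Smirnov test (texture
features), the Wilcoxon–Mann–Whitney rank-sum test (color histograms),
and a Monte-Carlo Lilliefors normality check.

Because the reference image collection is external, the package ships a
seeded **synthetic fundus cohort generator**: branching vessel trees on
a reddish circular field with group-dependent density, width, branching
and green/blue chromatic shifts, plus pixel-exact ground-truth masks.
Every pipeline stage is testable offline against these cohorts.

## Quick start

```python
from fundustex import (
    load_preset, generate_cohort, segment_vessels,
    MatchedFilterParams, vessel_texture_profile, dice_coefficient,
)

cohort = generate_cohort(load_preset("healthy", n_images=5, seed=7))
sample = cohort[0]
mask = segment_vessels(sample.image, mf_params=MatchedFilterParams(1.5, 7, 12))
print(dice_coefficient(mask, sample.mask))
print(vessel_texture_profile(sample.image, mask).as_dict())
```

## Command line

```bash
# synthetic end-to-end study (two groups, full report)
fundustex simulate --preset healthy --preset pathological --seed 42 --out report/

# individual stages on a directory of images
fundustex segment --in images/ --out masks/
fundustex texture --images images/ --masks masks/ --out features.csv
fundustex color   --images images/ --groups manifest.csv --out color/

# full study from a manifest CSV (columns: file, group[, mask_file, fov_file])
fundustex run --manifest manifest.csv --config cfg.yaml --out report/

# write one cohort to disk (images, masks, manifest)
fundustex make-cohort --preset pathological --out cohort/
```

Reports are deterministic for a fixed config and seed: `report.json`
contains the texture summary (per-group mean ± SD and pairwise KS
p-values), per-channel rank-sum and Lilliefors results, the Mahalanobis
distance matrix, the Dice table when ground-truth masks are supplied,
and a provenance block (config, hash, seed, version).

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracles (exhaustive pair enumeration for
co-occurrence matrices, direct-summation feature references, exact
permutation enumeration for the rank-sum test) and property tests for
the documented invariants. `tests/test_acceptance.py` holds the
acceptance criteria; the external-validation test is skipped unless a
local copy of the public high-resolution fundus database is placed
under `data/hrf` (`images/`, `manual1/`, optional `mask/`).

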