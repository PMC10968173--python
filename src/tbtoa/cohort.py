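"""Synthetic knee-osteoarthritis cohort generation.

The real study population this module emulates is a nested case-control
sample of ~600 knees (one per patient, baseline KL grade 1-3) followed at
months 0, 24 and 48, partitioned into radio-symptomatic progressors,
radiographic-only progressors, symptomatic-only progressors and
non-progressors. Because those data are access-restricted, every downstream
stage of the package is exercised on cohorts drawn here, whose

* group proportions, KL-grade distribution and sex ratio match the published
  cohort marginals (groups 192/102/103/200 of 597; KL 1/2/3 at
  12.6/51.1/36.3%; 59.0% female);
* outcome trajectories are constructed to straddle the progression rules
  with margin — first-period medial JSW losses are drawn from [0, 0.6] mm
  (below the 0.7 mm rule) and, for radiographic progressors, second-period
  losses from [0.7, 1.6] mm; pain changes analogously from [-5, 8] vs
  [9, 30] points around the 9-point rule — so that re-labelling generated
  trajectories recovers the intended group exactly;
* trabecular texture is coupled to structural progression: radiographic
  progressors carry a small baseline roughness offset and a knee-level
  24-month decline in per-ROI Hurst exponents, the generative analogue of
  the subchondral remodelling signal the texture models are meant to detect.

Per-ROI ground-truth Hurst exponents at both visits are stored with each
record, so texture descriptors can be produced either directly ("tabular"
fidelity: ground truth plus estimator-like noise) or by rendering fractional
Brownian patches per ROI and running the full variogram estimator on the
images ("imaging" fidelity, :func:`render_knee_images`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, StructuralError
from .fbm import FbmSpec, generate_fbm_surface
from .texture import ROILayout, TextureImage, descriptor_names

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "render_knee_images",
    "cohort_columns",
    "DEFAULT_GROUP_PROBS",
    "DEFAULT_KL_PROBS",
]

#: Group proportions of the emulated cohort: 192/102/103/200 knees of 597.
DEFAULT_GROUP_PROBS = (192 / 597, 102 / 597, 103 / 597, 200 / 597)
#: Baseline KL-grade distribution over grades 1, 2, 3.
DEFAULT_KL_PROBS = (0.126, 0.511, 0.363)

_DEFAULT_EFFECTS = {
    # baseline per-ROI Hurst shift for radiographic progressors (groups 1, 2)
    "tbt_baseline": -0.02,
    # knee-level 24-month Hurst change for radiographic progressors
    "tbt_delta": -0.05,
    # biomarker log-mean shifts
    "bio_rad": 0.25,
    "bio_symp": 0.10,
}

_DEFAULT_NOISE = {
    "h_knee": 0.04,      # between-knee SD of the baseline Hurst level
    "h_roi": 0.02,       # ROI-level SD around the knee mean
    "dh_knee": 0.04,     # between-knee SD of the 24-month Hurst change
    "dh_roi": 0.02,      # ROI-level SD of the change
    "descriptor": 0.02,  # estimator-like noise per descriptor (tabular mode)
}

#: log-scale location and SD of the three biomarkers in controls
_BIO_BASE = {"uctx2": (np.log(250.0), 0.45), "sntx1": (np.log(15.0), 0.35), "sha": (np.log(40.0), 0.50)}

_H_BASE = 0.70          # population mean baseline Hurst exponent per ROI
_H_CLIP = (0.05, 0.95)  # generated ground truth stays inside the open unit interval


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    Probability vectors must sum to one; ``effect_sizes`` and ``noise_sd``
    override individual entries of the documented defaults.
    """

    n_knees: int = 597
    group_probs: tuple[float, float, float, float] = DEFAULT_GROUP_PROBS
    kl_probs: tuple[float, float, float] = DEFAULT_KL_PROBS
    female_prob: float = 0.590
    effect_sizes: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    pixel_spacing_mm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_knees < 0:
            raise ParameterError("n_knees must be non-negative")
        for name, probs in (("group_probs", self.group_probs), ("kl_probs", self.kl_probs)):
            if abs(sum(probs) - 1.0) > 1e-12 or any(p < 0 for p in probs):
                raise ParameterError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ParameterError("female_prob must lie in [0, 1]")
        for key in self.effect_sizes:
            if key not in _DEFAULT_EFFECTS:
                raise ParameterError(f"unknown effect_sizes key {key!r}")
        for key, sd in self.noise_sd.items():
            if key not in _DEFAULT_NOISE:
                raise ParameterError(f"unknown noise_sd key {key!r}")
            if not sd > 0:
                raise ParameterError(f"noise_sd[{key!r}] must be positive")

    @property
    def effects(self) -> dict:
        return {**_DEFAULT_EFFECTS, **self.effect_sizes}

    @property
    def noise(self) -> dict:
        return {**_DEFAULT_NOISE, **self.noise_sd}


def cohort_columns() -> list[str]:
    """Column order of the cohort table / CSV schema."""
    cols = ["knee_id", "group", "age", "sex", "bmi", "kl", "jsnm", "uctx2", "sntx1", "sha"]
    for prefix in ("jsw_med", "jsw_lat", "pain_idx", "pain_con"):
        cols += [f"{prefix}_{m}" for m in (0, 24, 48)]
    cols += [f"h0_r{r:02d}" for r in range(16)]
    cols += [f"h24_r{r:02d}" for r in range(16)]
    cols += descriptor_names("tbt0") + descriptor_names("tbt24")
    return cols


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table of ``spec.n_knees`` knees.

    Each row carries clinical covariates, radiological grades, biomarkers,
    outcome trajectories at months 0/24/48, per-ROI ground-truth Hurst
    exponents at both visits, and the 2 x 64 texture descriptors (tabular
    fidelity). The ``group`` column records the intended group; re-applying
    the labelling rules to the generated trajectories reproduces it exactly
    by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_knees
    eff, noise = spec.effects, spec.noise

    group = rng.choice([1, 2, 3, 4], size=n, p=spec.group_probs)
    is_rad = np.isin(group, [1, 2])     # radiographic progression of the index knee
    is_symp = np.isin(group, [1, 3])    # symptomatic progression of the index knee

    age = np.clip(rng.normal(61.5, 8.9, n), 45.0, 85.0)
    sex = (rng.random(n) < spec.female_prob).astype(int)  # 1 = female
    bmi = np.clip(rng.normal(30.7, 4.8, n), 18.0, 45.0)
    kl = rng.choice([1, 2, 3], size=n, p=spec.kl_probs)
    jsnm = np.clip(kl - 1 + rng.integers(0, 2, n), 0, 3)

    bio = {}
    for name, (mu, sd) in _BIO_BASE.items():
        shift = eff["bio_rad"] * is_rad + eff["bio_symp"] * is_symp
        bio[name] = np.exp(rng.normal(mu + shift, sd))

    # Trajectories: draws straddle the 0.7 mm / 9-point rules with margin.
    def _jsw(progressing: np.ndarray, lo: float, hi: float) -> np.ndarray:
        base = rng.uniform(lo, hi, n)
        loss1 = rng.uniform(0.0, 0.6, n)
        loss2 = np.where(progressing, rng.uniform(0.7, 1.6, n), rng.uniform(0.0, 0.6, n))
        return np.stack([base, base - loss1, base - loss1 - loss2], axis=1)

    def _pain(progressing: np.ndarray) -> np.ndarray:
        base = rng.uniform(10.0, 40.0, n)
        d1 = rng.uniform(-5.0, 8.0, n)
        d2 = np.where(progressing, rng.uniform(9.0, 30.0, n), rng.uniform(-5.0, 8.0, n))
        return np.stack([base, base + d1, base + d1 + d2], axis=1)

    jsw_med = _jsw(is_rad, 3.5, 5.0)
    jsw_lat = _jsw(np.zeros(n, dtype=bool), 4.0, 5.5)
    pain_idx = _pain(is_symp)
    pain_con = _pain(np.zeros(n, dtype=bool))

    # Per-ROI ground-truth Hurst exponents; radiographic progressors carry a
    # baseline offset and a knee-level 24-month decline.
    h_knee = _H_BASE + eff["tbt_baseline"] * is_rad + rng.normal(0, noise["h_knee"], n)
    h0 = np.clip(h_knee[:, None] + rng.normal(0, noise["h_roi"], (n, 16)), *_H_CLIP)
    dh_knee = eff["tbt_delta"] * is_rad + rng.normal(0, noise["dh_knee"], n)
    h24 = np.clip(h0 + dh_knee[:, None] + rng.normal(0, noise["dh_roi"], (n, 16)), *_H_CLIP)

    # Tabular-fidelity descriptors: ground truth plus estimator-like noise,
    # independently per (roi, band, direction).
    tbt0 = np.repeat(h0, 4, axis=1) + rng.normal(0, noise["descriptor"], (n, 64))
    tbt24 = np.repeat(h24, 4, axis=1) + rng.normal(0, noise["descriptor"], (n, 64))

    data: dict[str, np.ndarray] = {
        "knee_id": np.array([f"K{i:05d}" for i in range(n)]),
        "group": group, "age": age, "sex": sex, "bmi": bmi, "kl": kl, "jsnm": jsnm,
        **bio,
    }
    for prefix, arr in (("jsw_med", jsw_med), ("jsw_lat", jsw_lat),
                        ("pain_idx", pain_idx), ("pain_con", pain_con)):
        for j, m in enumerate((0, 24, 48)):
            data[f"{prefix}_{m}"] = arr[:, j]
    for r in range(16):
        data[f"h0_r{r:02d}"] = h0[:, r]
        data[f"h24_r{r:02d}"] = h24[:, r]
    for j, name in enumerate(descriptor_names("tbt0")):
        data[name] = tbt0[:, j]
    for j, name in enumerate(descriptor_names("tbt24")):
        data[name] = tbt24[:, j]

    table = pd.DataFrame(data, columns=cohort_columns())
    table.attrs["cohort_spec"] = spec
    return table


def render_knee_images(
    record: pd.Series,
    layout: ROILayout,
    seed: int,
    pixel_spacing_mm: float = 0.1,
) -> tuple[TextureImage, TextureImage]:
    """Render baseline and 24-month images for one knee record.

    Each ROI of the layout is filled with a fractional Brownian patch drawn
    at the record's ground-truth per-ROI Hurst exponent (columns ``h0_r*``
    and ``h24_r*``); pixels outside the ROIs are a constant mid-grey. Patch
    seeds derive deterministically from ``(seed, visit, roi)``, so the same
    record and seed reproduce the identical image pair.
    """
    for r in range(16):
        for col in (f"h0_r{r:02d}", f"h24_r{r:02d}"):
            if col not in record.index:
                raise StructuralError(f"record lacks ground-truth column {col!r}")
    if len(layout.rois) != 16:  # unreachable for a valid ROILayout; guards duck types
        raise StructuralError("layout must carry 16 ROIs")

    height = max(r + h for r, _, h, _ in layout.rois)
    width = max(c + w for _, c, _, w in layout.rois)
    images = []
    for visit, prefix in ((0, "h0"), (1, "h24")):
        canvas = np.full((max(height, 16), max(width, 16)), 32768.0)
        for roi_id, (r, c, h, w) in enumerate(layout.rois):
            patch_seed = int(
                np.random.SeedSequence((seed, visit, roi_id)).generate_state(1)[0]
            )
            side = max(h, w)
            patch = generate_fbm_surface(
                FbmSpec(
                    hurst=float(record[f"{prefix}_r{roi_id:02d}"]),
                    size_px=side,
                    pixel_spacing_mm=pixel_spacing_mm,
                    seed=patch_seed,
                )
            )
            canvas[r : r + h, c : c + w] = patch.pixels[:h, :w]
        images.append(TextureImage(pixels=canvas, pixel_spacing_mm=pixel_spacing_mm))
    return images[0], images[1]
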