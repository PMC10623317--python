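"""Synthetic variety panels with known ground truth.

Every downstream stage of the pipeline (classification, morphometrics,
spectral QC, ordination, ordinal regression) is testable against this
module: it generates a panel of quinoa-like varieties with known dormancy
classes and mechanisms, binomial germination assays driven by a closed-form
dose-response model, class-conditional trait tables, low-rank-plus-noise
NIR spectra with injected outliers, and rendered seed-scan images with
analytic per-seed shape ground truth.

The germination model gives each variety a baseline germinability ``g0``,
Hill-type ABA inhibition with half-inhibition concentration ``aba_ic50``
and slope ``hill``, a multiplicative GA boost, and release terms for dry
after-ripening (per-month fraction, compounding over months) and seed-coat
scarification:

    g    = g0 + release * (1 - g0)
    p_GA = g + ga_boost * (1 - g)
    p_ABA = g / (1 + (C / ic50)^hill)

Strongly dormant (SD) varieties are constructed so that every in-assay
expectation stays below 0.25, non-dormant (ND) varieties so that every
expectation stays above 0.75; SD varieties with embryo-imposed dormancy
release through after-ripening while seed-coat-imposed SD varieties release
only through scarification.  Trait distributions are class-conditional:
strongly dormant varieties draw thicker seed coats and a narrower, lower
range of eccentricities than non-dormant ones by construction.

All generators are pure functions of (config, seed).  Per-variety random
substreams are derived from the panel seed and the variety index, so
extending a panel does not reshuffle existing varieties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage.draw import ellipse as _draw_ellipse

from .classifier import Category
from .germination import (
    INITIAL_TREATMENTS,
    REFINED_TREATMENTS,
    GerminationAssay,
    TreatmentSpec,
)
from .morphometrics import SeedShape

__all__ = [
    "PanelConfig",
    "VarietyTruth",
    "generate_panel",
    "simulate_germination",
    "simulate_panel_assays",
    "germination_probability",
    "generate_spectra",
    "render_seed_image",
    "NIR_WAVELENGTHS",
]

#: Default panel composition: 189 varieties split 141 ND / 27 WD / 9 MD / 12 SD.
DEFAULT_COMPOSITION = {"ND": 141, "WD": 27, "MD": 9, "SD": 12}

#: NIR wavelength grid: 950-1650 nm at 5 nm steps (141 points).
NIR_WAVELENGTHS = np.arange(950, 1655, 5, dtype=float)

VIABILITY_TREATMENTS = tuple(
    TreatmentSpec.parse(c)
    for c in (
        "AR1-NT", "AR1-ABA10", "AR1-GA10", "AR1-SCR",
        "LAR3-NT", "LAR3-ABA10", "LAR3-GA10", "LAR3-SCR",
    )
)

# Seed-coat color frequencies per dormancy category, from the observed
# 181-variety color panel, smoothed toward the pooled marginal so that no
# color is exclusive to a single category by construction.
_COLOR_COUNTS = {
    "SD": {"beige": 6, "black": 1, "brown": 1, "cream": 2, "grey": 1,
           "warm cream": 1},
    "MD": {"beige": 5, "brown": 1, "cream": 1, "grey": 2},
    "WD": {"beige": 13, "black": 3, "brown": 7, "cream": 2, "red": 1},
    "ND": {"beige": 79, "black": 7, "brown": 17, "cream": 24, "grey": 4,
           "red brown": 3, "warm cream": 5, "yellow": 1},
}
_COLOR_SMOOTHING = 0.15
COLORS = sorted({c for d in _COLOR_COUNTS.values() for c in d})


def _color_probs() -> dict:
    pooled = {c: sum(d.get(c, 0) for d in _COLOR_COUNTS.values()) for c in COLORS}
    pooled_total = sum(pooled.values())
    out = {}
    for cat, counts in _COLOR_COUNTS.items():
        total = sum(counts.values())
        probs = np.array([
            (1 - _COLOR_SMOOTHING) * counts.get(c, 0) / total
            + _COLOR_SMOOTHING * pooled[c] / pooled_total
            for c in COLORS
        ])
        out[cat] = probs / probs.sum()
    return out


_COLOR_PROBS = _color_probs()


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions of a synthetic panel.

    Defaults reproduce the reference screen: 189 varieties in proportions
    141/27/9/12 (ND/WD/MD/SD), a quarter of SD varieties with seed-coat-
    imposed dormancy, 3 biological x 3 technical replicates of 10 seeds.
    """

    n_varieties: int = 189
    class_proportions: dict = field(
        default_factory=lambda: {k: v / 189 for k, v in DEFAULT_COMPOSITION.items()}
    )
    sd_mechanism_split: float = 0.25  # fraction of SD with seed-coat dormancy
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    seeds_per_rep: int = 10
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_varieties < 1:
            raise ValueError("n_varieties must be positive")
        keys = set(self.class_proportions)
        if keys != {"ND", "WD", "MD", "SD"}:
            raise ValueError("class_proportions must have keys ND, WD, MD, SD")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        if not 0 <= self.sd_mechanism_split <= 1:
            raise ValueError("sd_mechanism_split must lie in [0, 1]")
        for name in ("n_bio_reps", "n_tech_reps", "seeds_per_rep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class VarietyTruth:
    """Ground-truth parameters for one synthetic variety."""

    variety_id: str
    index: int
    true_class: Category
    true_mechanism: str  # embryo | seedcoat | none
    g0: float
    aba_ic50: float
    hill: float
    ga_boost: float
    ar_release: float    # release fraction per month of after-ripening
    scar_release: float
    thickness: float
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    eccentricity: float
    solidity: float
    protein: float
    moisture: float
    coat_color: str


def largest_remainder_counts(n: int, proportions: dict) -> dict:
    """Apportion ``n`` items to classes so counts sum exactly to ``n``."""
    order = list(proportions)
    quotas = np.array([proportions[k] * n for k in order])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # Largest fractional parts get the leftover units; ties broken by the
    # fixed class order, which keeps the apportionment deterministic.
    frac_order = np.argsort(-(quotas - counts), kind="stable")
    for idx in frac_order[:remainder]:
        counts[idx] += 1
    return dict(zip(order, counts))


def _variety_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _truncnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _truncexpon(rng, lo, scale, hi):
    # Inverse-CDF draw from an exponential truncated to [lo, hi].
    u = rng.random()
    span = 1.0 - math.exp(-(hi - lo) / scale)
    return lo - scale * math.log1p(-u * span)


_DOSE_RESPONSE_RANGES = {
    # (g0, ic50, hill, ga_boost, ar_release, scar_release) as (lo, hi) pairs
    "ND": ((0.88, 0.98), (100, 500), (1.0, 1.0), (0.3, 0.6), (0.3, 0.6), (0.0, 0.2)),
    "WD": ((0.62, 0.90), (1.0, 5.0), (0.9, 1.4), (0.4, 0.7), (0.5, 0.9), (0.2, 0.5)),
    "MD": ((0.25, 0.42), (0.5, 3.0), (0.9, 1.4), (0.65, 0.9), (0.7, 0.95), (0.3, 0.6)),
    "SD-embryo": ((0.02, 0.12), (0.3, 2.0), (1.0, 1.0), (0.0, 0.10), (0.80, 0.95), (0.0, 0.15)),
    "SD-seedcoat": ((0.02, 0.12), (0.3, 2.0), (1.0, 1.0), (0.0, 0.10), (0.0, 0.05), (0.80, 0.95)),
}

_THICKNESS = {  # mean, sd, lo, hi (mm)
    "ND": (0.040, 0.012, 0.02, 0.08),
    "WD": (0.050, 0.006, 0.04, 0.06),
    "MD": (0.055, 0.015, 0.03, 0.10),
    "SD": (0.065, 0.020, 0.02, 0.12),
}

_ECCENTRICITY = {  # lo, scale, hi for a truncated-exponential draw
    "ND": (0.34, 0.060, 0.84),
    "WD": (0.34, 0.090, 0.85),
    "MD": (0.34, 0.060, 0.68),
    "SD": (0.36, 0.045, 0.49),
}

_AREA = {  # mean, sd, lo, hi (mm^2)
    "ND": (2.35, 0.45, 0.43, 3.24),
    "WD": (2.03, 0.50, 0.31, 3.16),
    "MD": (1.93, 0.25, 1.20, 2.30),
    "SD": (2.28, 0.25, 1.87, 2.86),
}


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's ellipse-perimeter approximation for semi-axes a, b."""
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def _draw_truth(label: str, mechanism: str, index: int,
                config: PanelConfig) -> VarietyTruth:
    rng = _variety_rng(config.rng_seed, index, 0)
    key = f"SD-{mechanism}" if label == "SD" else label
    ranges = _DOSE_RESPONSE_RANGES[key]
    g0, ic50, hill, ga, ar, scar = (rng.uniform(lo, hi) for lo, hi in ranges)

    thickness = _truncnorm(rng, *_THICKNESS[label])
    ecc = _truncexpon(rng, *_ECCENTRICITY[label])
    area = _truncnorm(rng, *_AREA[label])
    ratio = math.sqrt(1 - ecc**2)          # minor/major
    a = math.sqrt(area / (math.pi * ratio))  # semi-major (mm)
    b = a * ratio
    roughness = rng.uniform(1.05, 1.18)    # real seeds are rougher than ellipses
    perimeter = ramanujan_perimeter(a, b) * roughness
    solidity = rng.uniform(0.96, 0.995)
    protein = _truncnorm(rng, 15.6, 1.6, 8.3, 20.1)
    moisture = _truncnorm(rng, 8.1, 0.3, 7.3, 9.1)
    color = COLORS[rng.choice(len(COLORS), p=_COLOR_PROBS[label])]

    truth = VarietyTruth(
        variety_id=f"SYN-{index + 1:04d}",
        index=index,
        true_class=Category[label],
        true_mechanism=mechanism,
        g0=g0, aba_ic50=ic50, hill=hill, ga_boost=ga,
        ar_release=ar, scar_release=scar,
        thickness=thickness, area=area, perimeter=perimeter,
        major_axis=2 * a, minor_axis=2 * b, eccentricity=ecc,
        solidity=solidity, protein=protein, moisture=moisture,
        coat_color=color,
    )
    _check_truth_invariants(truth)
    return truth


def _check_truth_invariants(truth: VarietyTruth) -> None:
    in_assay = list(INITIAL_TREATMENTS) + list(REFINED_TREATMENTS)
    probs = [germination_probability(truth, t) for t in in_assay]
    if truth.true_class == Category.SD and max(probs) >= 0.25:
        raise AssertionError("SD truth exceeds 0.25 expected germination in-assay")
    if truth.true_class == Category.ND and min(probs) <= 0.75:
        raise AssertionError("ND truth falls below 0.75 expected germination")


def generate_panel(config: PanelConfig | None = None) -> tuple[list[VarietyTruth], pd.DataFrame]:
    """Generate variety truths and the per-variety trait table.

    Class counts follow largest-remainder rounding of the configured
    proportions, so the default 189-variety panel has exactly 141 ND, 27 WD,
    9 MD and 12 SD varieties.  Identical config and seed give identical
    output.
    """
    config = config or PanelConfig()
    counts = largest_remainder_counts(config.n_varieties, config.class_proportions)
    n_sd = counts["SD"]
    n_seedcoat = int(round(config.sd_mechanism_split * n_sd))
    labels: list[tuple[str, str]] = []
    for label in ("ND", "WD", "MD"):
        mech = "embryo" if label == "MD" else "none"
        labels += [(label, mech)] * counts[label]
    labels += [("SD", "seedcoat")] * n_seedcoat
    labels += [("SD", "embryo")] * (n_sd - n_seedcoat)

    truths = [_draw_truth(lbl, mech, i, config)
              for i, (lbl, mech) in enumerate(labels)]
    traits = pd.DataFrame(
        {
            "variety_id": [t.variety_id for t in truths],
            "true_class": [t.true_class.label for t in truths],
            "true_mechanism": [t.true_mechanism for t in truths],
            "coat_color": [t.coat_color for t in truths],
            "thickness": [t.thickness for t in truths],
            "area": [t.area for t in truths],
            "perimeter": [t.perimeter for t in truths],
            "major_axis": [t.major_axis for t in truths],
            "minor_axis": [t.minor_axis for t in truths],
            "eccentricity": [t.eccentricity for t in truths],
            "solidity": [t.solidity for t in truths],
            "protein": [t.protein for t in truths],
            "moisture": [t.moisture for t in truths],
        }
    ).set_index("variety_id")
    return truths, traits


def germination_probability(truth: VarietyTruth, treatment: TreatmentSpec) -> float:
    """Closed-form expected germination fraction under one treatment."""
    release = 0.0
    if treatment.scarified:
        release = truth.scar_release
    elif treatment.after_ripened_months > 0:
        release = 1.0 - (1.0 - truth.ar_release) ** treatment.after_ripened_months
    g = truth.g0 + release * (1.0 - truth.g0)
    if treatment.hormone == "GA":
        g = g + truth.ga_boost * (1.0 - g)
    elif treatment.hormone == "ABA":
        g = g / (1.0 + (treatment.concentration_uM / truth.aba_ic50) ** truth.hill)
    return float(np.clip(g, 0.0, 1.0))


def simulate_germination(
    truth: VarietyTruth,
    treatments: list[TreatmentSpec],
    config: PanelConfig,
    n_replicates: int | None = None,
    stream: int = 1,
) -> list[GerminationAssay]:
    """Draw binomial germination counts for each treatment arm.

    Each replicate draws Binomial(seeds_per_rep, p) at the closed-form
    expectation for (truth, treatment).  The random substream depends only
    on the panel seed, the variety index and ``stream``, so assays are
    reproducible per variety.
    """
    rng = _variety_rng(config.rng_seed, truth.index, stream)
    n_reps = n_replicates or (config.n_bio_reps * config.n_tech_reps)
    out = []
    for t in treatments:
        if not isinstance(t, TreatmentSpec):
            t = TreatmentSpec.parse(str(t))
        p = germination_probability(truth, t)
        counts = rng.binomial(config.seeds_per_rep, p, size=n_reps)
        reps = [(config.seeds_per_rep, int(c)) for c in counts]
        out.append(GerminationAssay(truth.variety_id, t, reps))
    return out


def simulate_panel_assays(
    truths: list[VarietyTruth], config: PanelConfig
) -> pd.DataFrame:
    """Simulate the full screening campaign as a long-format table.

    Every variety gets the initial ABA dose-response round (technical
    replicates only); varieties that are truly dormant to any degree get the
    refined ABA+GA round (bio x tech replicates); truly SD/MD varieties
    additionally get the after-ripening, scarification and long
    after-ripening arms.  Columns: variety_id, round, treatment, bio_rep,
    tech_rep, sown, germinated.
    """
    records = []

    def _emit(truth, assays, round_name, n_tech):
        for assay in assays:
            for i, (sown, germ) in enumerate(assay.replicates):
                records.append({
                    "variety_id": truth.variety_id,
                    "round": round_name,
                    "treatment": assay.treatment.code,
                    "bio_rep": i // n_tech + 1,
                    "tech_rep": i % n_tech + 1,
                    "sown": sown,
                    "germinated": germ,
                })

    for truth in truths:
        initial = simulate_germination(
            truth, list(INITIAL_TREATMENTS), config,
            n_replicates=config.n_tech_reps, stream=1,
        )
        _emit(truth, initial, "initial", config.n_tech_reps)
        if truth.true_class == Category.ND:
            continue
        refined = simulate_germination(
            truth, list(REFINED_TREATMENTS), config, stream=2
        )
        _emit(truth, refined, "refined", config.n_tech_reps)
        if truth.true_class in (Category.SD, Category.MD):
            viability = simulate_germination(
                truth, list(VIABILITY_TREATMENTS), config, stream=3
            )
            _emit(truth, viability, "viability", config.n_tech_reps)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# NIR spectra
# ---------------------------------------------------------------------------

def generate_spectra(
    n_experimental: int,
    n_calibration: int,
    outlier_fraction: float = 0.0,
    rank: int = 5,
    noise_sd: float = 0.01,
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Low-rank-plus-noise absorbance spectra with injected outliers.

    Spectra live on the 950-1650 nm grid (141 wavelengths at 5 nm).  Inlier
    rows are mean + smooth low-rank factors + isotropic noise; outlier rows
    (a recorded subset of the experimental matrix) draw inflated factor
    scores and noise.  ``rank=0`` with ``noise_sd=1`` yields pure
    identity-covariance noise around the mean spectrum.

    Returns (experimental frame, calibration frame, outlier row indices).
    """
    if n_experimental < 0 or n_calibration < 0:
        raise ValueError("sample counts must be nonnegative")
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    rng = np.random.default_rng([seed, 9])
    wl = NIR_WAVELENGTHS
    p = wl.size
    x = (wl - wl.min()) / (wl.max() - wl.min())
    mean = 0.45 + 0.25 * np.sin(2 * math.pi * (x + 0.1)) + 0.3 * x

    if rank > 0:
        phases = rng.uniform(0, 2 * math.pi, size=rank)
        freqs = rng.uniform(1.0, 4.0, size=rank)
        weights = 0.15 * 0.6 ** np.arange(rank)
        loadings = np.array(
            [w * np.sin(2 * math.pi * f * x + ph)
             for w, f, ph in zip(weights, freqs, phases)]
        )
    else:
        loadings = np.zeros((0, p))

    def _draw(n, score_scale=1.0, noise_scale=1.0):
        scores = rng.standard_normal((n, rank)) * score_scale if rank else np.zeros((n, 0))
        noise = rng.standard_normal((n, p)) * noise_sd * noise_scale
        return mean + scores @ loadings + noise

    experimental = _draw(n_experimental)
    calibration = _draw(n_calibration)
    n_out = int(round(outlier_fraction * n_experimental))
    if n_out > 0:
        outlier_idx = np.sort(rng.choice(n_experimental, size=n_out, replace=False))
        experimental[outlier_idx] = _draw(n_out, score_scale=3.0, noise_scale=5.0)
    else:
        outlier_idx = np.array([], dtype=int)

    cols = [f"{w:g}" for w in wl]
    exp_df = pd.DataFrame(experimental, columns=cols,
                          index=[f"EXP-{i + 1:04d}" for i in range(n_experimental)])
    cal_df = pd.DataFrame(calibration, columns=cols,
                          index=[f"CAL-{i + 1:04d}" for i in range(n_calibration)])
    return exp_df, cal_df, outlier_idx


# ---------------------------------------------------------------------------
# Rendered seed scans
# ---------------------------------------------------------------------------

def render_seed_image(
    seed_params: list[tuple],
    image_size: tuple[int, int] = (1024, 1024),
    background_level: int = 230,
    foreground_level: int = 60,
    dpi: int = 1200,
) -> tuple[np.ndarray, list[SeedShape]]:
    """Render dark ellipses on a light background, with analytic truth.

    ``seed_params`` is a list of ((row, col) centre in px, (a, b) semi-axes
    in px, orientation in radians).  Touching ellipses are allowed; every
    ellipse must lie fully inside the canvas.  Ground truth uses the
    analytic area pi*a*b, Ramanujan's perimeter, full axes 2a/2b,
    eccentricity sqrt(1 - (b/a)^2) and solidity 1, converted to mm at
    25.4/dpi mm per pixel.
    """
    h, w = image_size
    img = np.full((h, w), background_level, dtype=np.uint8)
    truths = []
    scale = 25.4 / dpi
    for i, (center, axes, theta) in enumerate(seed_params, start=1):
        r0, c0 = center
        a, b = max(axes), min(axes)
        # Axis-aligned extent of the rotated ellipse.
        half_h = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        half_w = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
        if (r0 - half_h < 0 or r0 + half_h >= h
                or c0 - half_w < 0 or c0 + half_w >= w):
            raise ValueError(f"ellipse {i} extends outside the canvas")
        # skimage measures orientation against the row axis; rotation here is
        # of the (r_radius, c_radius)=(a, b) ellipse about the centre.
        rr, cc = _draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = foreground_level
        ecc = math.sqrt(1 - (b / a) ** 2) if a > 0 else 0.0
        truths.append(SeedShape(
            label=i,
            area=math.pi * a * b * scale**2,
            perimeter=ramanujan_perimeter(a, b) * scale,
            major_axis=2 * a * scale,
            minor_axis=2 * b * scale,
            eccentricity=ecc,
            solidity=1.0,
        ))
    rgb = np.stack([img] * 3, axis=-1)
    return rgb, truths


def random_seed_layout(
    n_seeds: int,
    mean_major_mm: float,
    mean_minor_mm: float,
    image_size: tuple[int, int],
    dpi: int = 1200,
    seed: int = 0,
    jitter: float = 0.06,
    max_tries: int = 2000,
) -> list[tuple]:
    """Place ``n_seeds`` non-overlapping ellipses at scan scale.

    Axis lengths jitter around the supplied means (coefficient of variation
    ``jitter``); placement is rejection-sampled to keep ellipses disjoint.
    """
    rng = np.random.default_rng([seed, 17])
    px_per_mm = dpi / 25.4
    params, centers, radii = [], [], []
    tries = 0
    while len(params) < n_seeds:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place seeds without overlap; "
                               "increase image_size or reduce n_seeds")
        a = 0.5 * mean_major_mm * px_per_mm * rng.normal(1.0, jitter)
        b = 0.5 * mean_minor_mm * px_per_mm * rng.normal(1.0, jitter)
        a, b = max(a, b), min(a, b)
        if b < 2:
            continue
        margin = a + 3
        r0 = rng.uniform(margin, image_size[0] - margin)
        c0 = rng.uniform(margin, image_size[1] - margin)
        if any((r0 - rc) ** 2 + (c0 - cc) ** 2 < (a + rr + 3) ** 2
               for (rc, cc), rr in zip(centers, radii)):
            continue
        theta = rng.uniform(0, math.pi)
        params.append(((r0, c0), (a, b), theta))
        centers.append((r0, c0))
        radii.append(a)
    return params
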