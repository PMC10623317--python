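"""NIR spectral quality control.

Near-infrared predictions of seed constituents (crude protein, moisture)
are only trusted inside the instrument's calibration space.  Two exclusion
filters run in order:

1. **Calibration-range filter** — a sample is excluded when a predicted
   constituent falls outside the calibration range (inclusive bounds).
2. **Mahalanobis filter** — a sample is excluded when its spectrum is too
   far from the calibration centroid.  The centroid uses calibration
   spectra only; the covariance is the sample covariance of the pooled
   (experimental + calibration) spectra.  The squared distance d^2 is
   compared against the chi-square quantile at 1 - alpha (alpha = 0.001)
   with degrees of freedom equal to the number of wavelengths (141).

Surviving predictions are then adjusted to a dry-matter basis:
value * 100 / (100 - moisture).

The covariance can be near-singular when the pooled sample count is small
relative to the 141-dimensional spectra; a small ridge (1e-8 * trace/p on
the diagonal) is added whenever the condition number exceeds 1e12.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "range_filter",
    "mahalanobis_d2",
    "mahalanobis_filter",
    "dry_matter_adjust",
    "apply_qc",
]


def mahalanobis_d2(X, mu, sigma) -> np.ndarray:
    """Squared Mahalanobis distances of rows of ``X`` from centroid ``mu``.

    With ``sigma`` the identity this is the squared Euclidean distance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = X - np.asarray(mu, dtype=float)
    solved = np.linalg.solve(np.atleast_2d(sigma), diff.T).T
    return np.maximum(np.einsum("ij,ij->i", diff, solved), 0.0)


def range_filter(value: float, lo: float, hi: float) -> bool:
    """Keep iff ``lo <= value <= hi`` (boundaries inclusive)."""
    if lo > hi:
        raise ValueError(f"invalid calibration range [{lo}, {hi}]")
    return lo <= value <= hi


def mahalanobis_filter(
    experimental,
    calibration,
    alpha: float = 0.001,
    df: int | None = None,
    cond_threshold: float = 1e12,
    ridge_scale: float = 1e-8,
    distance_measure: str = "squared",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Flag spectra far from the calibration centroid.

    Returns ``(keep_mask, d2, threshold)`` where ``d2`` holds squared
    Mahalanobis distances of the experimental rows and ``threshold`` is the
    chi-square quantile at ``1 - alpha`` with ``df`` degrees of freedom
    (defaulting to the number of wavelength columns).  With
    ``distance_measure='root'`` the unsquared distance is compared against
    the square root of the quantile; the exclusion decisions are identical,
    only the reported threshold scale changes.
    """
    X = np.asarray(experimental, dtype=float)
    C = np.asarray(calibration, dtype=float)
    if X.ndim != 2 or C.ndim != 2:
        raise ValueError("matrices must be 2-dimensional")
    if X.shape[1] != C.shape[1]:
        raise ValueError(
            f"column mismatch: experimental has {X.shape[1]} wavelengths, "
            f"calibration has {C.shape[1]}"
        )
    if C.shape[0] < 1:
        raise ValueError("calibration matrix must be non-empty")
    pooled = np.vstack([X, C])
    if pooled.shape[0] < 2:
        raise ValueError("need at least two pooled rows to estimate covariance")
    p = X.shape[1]
    mu = C.mean(axis=0)
    sigma = np.cov(pooled, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    if np.linalg.cond(sigma) > cond_threshold:
        sigma = sigma + np.eye(p) * (ridge_scale * np.trace(sigma) / p)
    d2 = mahalanobis_d2(X, mu, sigma)
    dof = p if df is None else df
    q = float(stats.chi2.ppf(1 - alpha, dof))
    if distance_measure == "squared":
        keep = d2 <= q
        threshold = q
    elif distance_measure == "root":
        threshold = float(np.sqrt(q))
        keep = np.sqrt(d2) <= threshold
    else:
        raise ValueError("distance_measure must be 'squared' or 'root'")
    return keep, d2, threshold


def dry_matter_adjust(value: float, moisture: float):
    """Convert an as-is constituent (g/100 g) to a dry-matter basis."""
    moisture_arr = np.asarray(moisture, dtype=float)
    if np.any((moisture_arr < 0) | (moisture_arr >= 100)):
        raise ValueError("moisture must lie in [0, 100)")
    out = np.asarray(value, dtype=float) * 100.0 / (100.0 - moisture_arr)
    return float(out) if out.ndim == 0 else out


def apply_qc(
    spectra: pd.DataFrame,
    calibration: pd.DataFrame,
    predicted: pd.DataFrame,
    calibration_ranges: dict,
    alpha: float = 0.001,
    **mahalanobis_kwargs,
) -> pd.DataFrame:
    """Run the full QC chain: range filter, Mahalanobis filter, adjustment.

    ``predicted`` holds per-sample constituent predictions (g/100 g, as-is
    basis) aligned with ``spectra``; ``calibration_ranges`` maps each
    constituent to its (lo, hi) calibration range.  Returns a frame indexed
    like ``spectra`` with ``qc_status`` (kept / excluded_range /
    excluded_mahalanobis), ``mahalanobis_d2`` and, for kept samples,
    ``<constituent>_dry`` columns.  Filters run in order; the Mahalanobis
    distance is still reported for range-excluded samples but cannot
    overturn their exclusion.
    """
    if not spectra.index.equals(predicted.index):
        raise ValueError("spectra and predictions must share an index")
    for constituent in predicted.columns:
        if constituent not in calibration_ranges:
            raise KeyError(f"no calibration range configured for {constituent!r}")

    status = pd.Series("kept", index=spectra.index, dtype=object)
    for constituent, (lo, hi) in calibration_ranges.items():
        if constituent not in predicted.columns:
            continue
        bad = ~predicted[constituent].apply(lambda v: range_filter(v, lo, hi))
        status[bad] = "excluded_range"

    keep, d2, _ = mahalanobis_filter(
        spectra.to_numpy(), calibration.to_numpy(), alpha=alpha,
        **mahalanobis_kwargs,
    )
    maha_bad = pd.Series(~keep, index=spectra.index)
    status[maha_bad & (status == "kept")] = "excluded_mahalanobis"

    out = predicted.copy()
    out["qc_status"] = status
    out["mahalanobis_d2"] = d2
    kept = status == "kept"
    if "moisture" in predicted.columns:
        for constituent in predicted.columns:
            if constituent == "moisture":
                continue
            adjusted = np.full(len(out), np.nan)
            adjusted[kept.to_numpy()] = dry_matter_adjust(
                predicted.loc[kept, constituent].to_numpy(),
                predicted.loc[kept, "moisture"].to_numpy(),
            )
            out[f"{constituent}_dry"] = adjusted
    return out
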