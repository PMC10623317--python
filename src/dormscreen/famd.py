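"""Factor analysis of mixed data (FAMD).

FAMD ordinates observations described by a mixture of quantitative and
categorical variables with a single SVD.  Quantitative columns are
standardised to unit population variance (PCA convention); each categorical
level contributes an indicator column divided by the square root of its
frequency proportion and then centred (MCA convention).  The total inertia
is therefore K_quant + sum_q (levels_q - 1): with only quantitative columns
the analysis reduces exactly to correlation-matrix PCA, with a single
categorical variable it reduces to the correspondence analysis of its
indicator matrix.

A dimension-support rule accompanies the ordination: a factor map over the
first d dimensions is considered supported only when their cumulative
inertia reaches a threshold (50% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMDResult",
    "encode_mixed",
    "famd_fit",
    "famd",
    "support_check",
    "plot_factor_map",
]


@dataclass
class FAMDResult:
    eigenvalues: np.ndarray          # all nonzero dimensions, non-increasing
    percent_inertia: np.ndarray      # sums to 100
    cumulative_inertia: np.ndarray   # cumulative percents
    row_coords: pd.DataFrame         # n x n_dims principal coordinates
    loadings: pd.DataFrame           # encoded-column weights per dimension
    contributions: pd.DataFrame      # percent contribution of each column
    n_dims: int
    total_inertia: float
    n_rows: int
    n_dropped: int = 0
    quantitative: list = field(default_factory=list)
    categorical: list = field(default_factory=list)


def encode_mixed(
    table: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Build the weighted, centred FAMD matrix.

    Quantitative columns become population z-scores; each level ``l`` of a
    categorical variable with frequency proportion ``p_l`` becomes
    ``indicator / sqrt(p_l)`` centred (i.e. minus ``sqrt(p_l)``).  Every
    column then has mean zero, and the per-column inertias are 1 for a
    quantitative column and ``1 - p_l`` for a level column.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty table")
    cols, names = [], []
    for c in quantitative:
        x = table[c].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"column {c!r} contains missing values")
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"quantitative column {c!r} has zero variance")
        cols.append((x - x.mean()) / sd)
        names.append(c)
    for c in categorical:
        levels = sorted(table[c].astype(str).unique())
        for level in levels:
            ind = (table[c].astype(str) == level).to_numpy(dtype=float)
            p = ind.mean()
            if p == 0:
                raise ValueError(f"empty level {level!r} in column {c!r}")
            cols.append(ind / np.sqrt(p) - np.sqrt(p))
            names.append(f"{c}={level}")
    return np.column_stack(cols), names


def famd_fit(
    encoded: np.ndarray,
    names: list[str],
    n_dims: int = 2,
    row_ids=None,
) -> FAMDResult:
    """Eigendecompose the encoded matrix with uniform row masses 1/n.

    Eigenvalues are the squared singular values of ``encoded / sqrt(n)``;
    row principal coordinates satisfy mean(coord_d^2) = lambda_d.  Each
    dimension's sign is fixed so that its largest-magnitude loading is
    positive, making output deterministic.
    """
    Z = np.asarray(encoded, dtype=float)
    n, k = Z.shape
    max_dims = min(n - 1, k)
    if not 1 <= n_dims <= max_dims:
        raise ValueError(f"n_dims must lie in [1, {max_dims}]")
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eigenvalues = s**2
    keep = eigenvalues > 1e-12 * max(eigenvalues[0], 1.0)
    U, s, Vt, eigenvalues = U[:, keep], s[keep], Vt[keep], eigenvalues[keep]
    # Deterministic sign: largest |loading| positive in every dimension.
    for d in range(len(s)):
        j = np.argmax(np.abs(Vt[d]))
        if Vt[d, j] < 0:
            Vt[d] *= -1
            U[:, d] *= -1
    total = float(eigenvalues.sum())
    percent = 100.0 * eigenvalues / total
    dims = [f"Dim{d + 1}" for d in range(len(s))]
    coords = np.sqrt(n) * U * s
    if row_ids is None:
        row_ids = pd.RangeIndex(n)
    row_coords = pd.DataFrame(coords[:, :n_dims], index=row_ids,
                              columns=dims[:n_dims])
    loadings = pd.DataFrame(Vt.T, index=names, columns=dims)
    contributions = pd.DataFrame(100.0 * Vt.T**2, index=names, columns=dims)
    return FAMDResult(
        eigenvalues=eigenvalues,
        percent_inertia=percent,
        cumulative_inertia=np.cumsum(percent),
        row_coords=row_coords,
        loadings=loadings,
        contributions=contributions,
        n_dims=n_dims,
        total_inertia=total,
        n_rows=n,
    )


def famd(
    table: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str],
    n_dims: int = 2,
) -> FAMDResult:
    """Encode and fit in one step, dropping rows with missing cells.

    Rows with any missing value in the analysed columns are dropped (and
    counted in ``n_dropped``) rather than imputed, mirroring the practice of
    restricting ordination to the complete-case subset of a panel.
    """
    use = list(quantitative) + list(categorical)
    missing_cols = [c for c in use if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns not in table: {missing_cols}")
    sub = table[use].dropna()
    n_dropped = len(table) - len(sub)
    encoded, names = encode_mixed(sub, quantitative, categorical)
    result = famd_fit(encoded, names, n_dims=n_dims, row_ids=sub.index)
    result.n_dropped = n_dropped
    result.quantitative = list(quantitative)
    result.categorical = list(categorical)
    return result


def support_check(
    result: FAMDResult, n_dims: int | None = None, threshold: float = 0.5
) -> tuple[bool, str]:
    """Do the retained dimensions carry enough inertia to be interpreted?

    TRUE iff the cumulative inertia over the first ``n_dims`` dimensions
    reaches ``threshold`` (fractional, default 0.5).  Returns the verdict
    and a one-line report.
    """
    d = n_dims or result.n_dims
    if d < 1:
        raise ValueError("n_dims must be >= 1")
    d = min(d, len(result.cumulative_inertia))
    cum = result.cumulative_inertia[d - 1]
    ok = bool(cum >= 100.0 * threshold)
    verdict = "supported" if ok else "not supported"
    line = (f"first {d} dimension(s) explain {cum:.1f}% of inertia "
            f"(threshold {100 * threshold:.0f}%): {verdict}")
    return ok, line


def plot_factor_map(result: FAMDResult, color_by: pd.Series | None = None,
                    path=None):
    """Scatter of the first two row-coordinate dimensions (factor map)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.row_coords
    if coords.shape[1] < 2:
        raise ValueError("need at least two retained dimensions to plot")
    fig, ax = plt.subplots(figsize=(6, 5))
    if color_by is not None:
        groups = color_by.reindex(coords.index)
        for name, idx in groups.groupby(groups).groups.items():
            sel = coords.loc[idx]
            ax.scatter(sel.iloc[:, 0], sel.iloc[:, 1], s=14, label=str(name))
        ax.legend(title=color_by.name or "group", fontsize=8)
    else:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=14)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"Dim 1 ({result.percent_inertia[0]:.1f}%)")
    ax.set_ylabel(f"Dim 2 ({result.percent_inertia[1]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
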