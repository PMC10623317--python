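"""Germination-assay statistics.

Dormancy screening assays score germination of replicate batches of seeds
(typically 10 per plate) after 7 days of imbibition, with or without hormone
(abscisic acid, ABA, inhibits germination; gibberellin, GA, promotes it).
This module holds the assay containers and the small statistical toolkit the
classifier builds on: percent germination, the arcsine square-root transform
used to stabilise proportion variance, one-way ANOVA with Tukey's HSD
all-pairwise comparison and a compact letter display, and the operational
test for whether a variety is still "responsive to ABA".
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "TreatmentSpec",
    "GerminationAssay",
    "TukeyResult",
    "percent_germination",
    "arcsine_transform",
    "anova_tukey",
    "is_aba_responsive",
]

_VALID_CONCENTRATIONS = (0.0, 0.1, 1.0, 10.0)
_VALID_MONTHS = (0, 1, 3)


@dataclass(frozen=True)
class TreatmentSpec:
    """One imbibition treatment arm.

    ``hormone`` is one of ``none``/``ABA``/``GA``; scarified seeds are always
    imbibed without hormone (scarification is a viability check, not a
    hormone assay).  ``after_ripened_months`` is 0 (fresh), 1 (AR) or 3 (LAR).
    """

    hormone: str = "none"
    concentration_uM: float = 0.0
    after_ripened_months: int = 0
    scarified: bool = False

    def __post_init__(self) -> None:
        if self.hormone not in ("none", "ABA", "GA"):
            raise ValueError(f"unknown hormone {self.hormone!r}")
        if (self.hormone == "none") != (self.concentration_uM == 0):
            raise ValueError("hormone 'none' if and only if concentration is 0")
        if self.concentration_uM not in _VALID_CONCENTRATIONS:
            raise ValueError(f"concentration must be one of {_VALID_CONCENTRATIONS}")
        if self.after_ripened_months not in _VALID_MONTHS:
            raise ValueError(f"after-ripening months must be one of {_VALID_MONTHS}")
        if self.scarified and self.hormone != "none":
            raise ValueError("scarified treatments carry no hormone")

    @property
    def code(self) -> str:
        if self.scarified:
            base = "SCR"
        elif self.hormone == "none":
            base = "NT"
        else:
            base = f"{self.hormone}{self.concentration_uM:g}"
        if self.after_ripened_months == 1:
            return f"AR1-{base}"
        if self.after_ripened_months == 3:
            return f"LAR3-{base}"
        return base

    @classmethod
    def parse(cls, code: str) -> "TreatmentSpec":
        months = 0
        base = code
        if code.startswith("AR1-"):
            months, base = 1, code[4:]
        elif code.startswith("LAR3-"):
            months, base = 3, code[5:]
        if base == "NT":
            return cls(after_ripened_months=months)
        if base == "SCR":
            return cls(after_ripened_months=months, scarified=True)
        for hormone in ("ABA", "GA"):
            if base.startswith(hormone):
                try:
                    conc = float(base[len(hormone):])
                except ValueError:
                    break
                return cls(hormone=hormone, concentration_uM=conc,
                           after_ripened_months=months)
        raise ValueError(f"unknown treatment code {code!r}")


# Canonical arms of the two screening rounds.
INITIAL_TREATMENTS = tuple(
    TreatmentSpec.parse(c) for c in ("NT", "ABA0.1", "ABA1", "ABA10")
)
REFINED_TREATMENTS = tuple(TreatmentSpec.parse(c) for c in ("NT", "ABA10", "GA10"))


@dataclass
class GerminationAssay:
    """Replicate germination counts for one variety under one treatment."""

    variety_id: str
    treatment: TreatmentSpec
    replicates: list  # list of (sown, germinated) int pairs
    scoring_day: int = 7

    def __post_init__(self) -> None:
        if self.scoring_day < 1:
            raise ValueError("scoring_day must be >= 1")
        for sown, germ in self.replicates:
            if sown < 1:
                raise ValueError("each replicate must sow at least one seed")
            if not 0 <= germ <= sown:
                raise ValueError("germinated count must lie in [0, sown]")

    def fractions(self) -> np.ndarray:
        return np.array([g / s for s, g in self.replicates], dtype=float)


def percent_germination(assay: GerminationAssay) -> tuple[np.ndarray, float]:
    """Per-replicate germination fractions and their unweighted mean."""
    if not assay.replicates:
        raise ValueError("assay has no replicates")
    fracs = assay.fractions()
    return fracs, float(fracs.mean())


def arcsine_transform(p):
    """Arcsine square-root transform arcsin(sqrt(p)), mapping [0, 1] to [0, pi/2]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class TukeyResult:
    """One-way ANOVA + Tukey HSD summary with compact letter display."""

    means: dict  # group -> mean on the (transformed) input scale
    pvalues: dict  # frozenset({g1, g2}) -> Tukey-adjusted p
    letters: dict  # group -> letter string
    alpha: float
    f_statistic: float
    f_pvalue: float
    df_residual: int
    mse: float
    zero_variance: bool = False

    def pvalue(self, g1, g2) -> float:
        return self.pvalues[frozenset((g1, g2))]


def _compact_letter_display(order: list, significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups best-first (descending mean, ties lexicographic);
    ``significant`` holds frozensets of group pairs with adjusted p < alpha.
    Groups sharing a letter are never a significant pair.
    """
    columns = [set(order)]
    for pair in significant:
        i, j = tuple(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for new in (col - {j}, col - {i}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    columns = [c for c in columns if c]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in order}
    names = string.ascii_lowercase
    for idx, col in enumerate(columns):
        mark = names[idx] if idx < 26 else f"z{idx - 25}"
        for g in col:
            letters[g] += mark
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_tukey(groups: dict, alpha: float = 0.05) -> TukeyResult:
    """One-way fixed-effects ANOVA with Tukey(-Kramer) HSD comparisons.

    ``groups`` maps a treatment label to its replicate values (already on the
    analysis scale, conventionally arcsine-transformed fractions).  Adjusted
    p-values come from the studentized-range distribution at the residual
    degrees of freedom.  When the residual variance is exactly zero the
    comparisons degenerate: groups with unequal means are reported as
    significant (p -> 0) with ``zero_variance`` flagged, identical groups
    share a single letter.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    k = len(data)
    ns = {g: v.size for g, v in data.items()}
    n_total = sum(ns.values())
    df_res = n_total - k
    if df_res < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    means = {g: float(v.mean()) for g, v in data.items()}
    grand = sum(v.sum() for v in data.values()) / n_total
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in data)
    mse = ss_within / df_res
    order = sorted(data, key=lambda g: (-means[g], str(g)))

    pvalues: dict = {}
    # Replicates identical within every group up to rounding noise.
    scale = max(float(np.max(np.abs(np.concatenate(list(data.values()))))), 1.0)
    zero_variance = mse <= 1e-14 * scale**2
    if zero_variance:
        f_stat = np.inf if ss_between > 0 else 0.0
        f_p = 0.0 if ss_between > 0 else 1.0
        for g1, g2 in combinations(data, 2):
            pvalues[frozenset((g1, g2))] = 0.0 if means[g1] != means[g2] else 1.0
    else:
        f_stat = (ss_between / (k - 1)) / mse
        f_p = float(stats.f.sf(f_stat, k - 1, df_res))
        for g1, g2 in combinations(data, 2):
            se = np.sqrt(mse / 2 * (1 / ns[g1] + 1 / ns[g2]))
            q = abs(means[g1] - means[g2]) / se
            pvalues[frozenset((g1, g2))] = float(
                stats.studentized_range.sf(q, k, df_res)
            )

    significant = {pair for pair, p in pvalues.items() if p < alpha}
    letters = _compact_letter_display(order, significant)
    return TukeyResult(
        means=means,
        pvalues=pvalues,
        letters=letters,
        alpha=alpha,
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        df_residual=df_res,
        mse=float(mse),
        zero_variance=zero_variance,
    )


def is_aba_responsive(
    nt: GerminationAssay,
    aba10: GerminationAssay,
    alpha: float = 0.05,
    fallback_drop: float = 0.20,
) -> bool:
    """Is germination significantly lower with 10 uM ABA than without hormone?

    The decision is TRUE iff the ABA mean falls below the no-treatment mean
    and either a pooled-variance t-test on the arcsine scale rejects at
    ``alpha``, or — when both groups have zero residual variance, so no test
    is possible — the raw mean drop reaches ``fallback_drop`` (20 percentage
    points by default).
    """
    if nt.variety_id != aba10.variety_id:
        raise ValueError(
            f"assays come from different varieties: {nt.variety_id!r} vs "
            f"{aba10.variety_id!r}"
        )
    nt_frac, nt_mean = percent_germination(nt)
    aba_frac, aba_mean = percent_germination(aba10)
    if not aba_mean < nt_mean:
        return False
    t_nt = arcsine_transform(nt_frac)
    t_aba = arcsine_transform(aba_frac)
    pooled_var = np.var(t_nt, ddof=1) + np.var(t_aba, ddof=1)
    if pooled_var == 0:
        return (nt_mean - aba_mean) >= fallback_drop
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t_nt, t_aba, equal_var=True)
    return bool(res.pvalue < alpha)
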