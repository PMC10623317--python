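"""Rule-based seed-dormancy classification.

Quinoa varieties are screened for primary (physiological) dormancy with
hormone germination assays and assigned an ordered dormancy category:

    ND (1, none) < WD (2, weak) < MD (3, moderate) < SD (4, strong)

Two screening rounds feed the rules.  The initial round imbibes seeds
without hormone (NT) and across an ABA gradient (0.1, 1, 10 uM); the refined
round re-tests everything not initially ND with NT, 10 uM ABA and 10 uM GA.
Varieties still scoring SD or MD then enter a viability decision tree:
one month of dry after-ripening (AR), scarification of the seed coat (SCR),
and a long three-month after-ripening (LAR) distinguish embryo-imposed from
seed-coat-imposed dormancy and flag viability concerns.

All category thresholds follow the screening protocol's wording literally:
"0-24%" means < 0.25, "50% or greater" means >= 0.50, "above 50%" and
"above 75%" are strict inequalities.  Rules are evaluated in a fixed,
most-restrictive-first order; inputs satisfying no rule are assigned the
nearest rule's category (smallest threshold violation in percentage points)
with an ``ambiguous`` flag instead of failing silently.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .germination import GerminationAssay, arcsine_transform, is_aba_responsive, percent_germination
from scipy import stats as _stats

__all__ = [
    "Category",
    "ClassifierConfig",
    "DormancyCall",
    "ViabilityTimeline",
    "classify_initial",
    "classify_refined",
    "viability_decision",
    "classify_panel",
    "summarize_panel",
]


class Category(enum.IntEnum):
    """Ordered dormancy strength categories (larger = more dormant)."""

    ND = 1
    WD = 2
    MD = 3
    SD = 4

    @property
    def label(self) -> str:
        return self.name


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the categorisation rules (germination fractions).

    ``strict_nd`` additionally requires > 95% no-treatment germination for
    ND, the stricter variant sometimes used when describing non-dormant
    check varieties; the default implements the screening-protocol rule
    (above 75% under every treatment).
    """

    sd_max: float = 0.25          # SD: all means below this
    nd_min: float = 0.75          # ND: all means above this
    mid: float = 0.50             # MD/WD split on no-treatment germination
    sd_ga_max: float = 0.30       # SD refined: GA arm below this
    md_min_drop: float = 0.05     # MD initial: total drop across ABA gradient
    strict_nd: bool = False
    strict_nd_nt: float = 0.95
    alpha: float = 0.05
    release_min: float = 0.75     # AR release: germination at/above this
    rescue_min: float = 0.50      # scarification/LAR rescue threshold
    fail_max: float = 0.50        # "failed to germinate" after AR
    # Penalty (percentage points) charged by the nearest-rule fallback when a
    # rule's boolean ABA-responsiveness requirement is not met.
    responsiveness_penalty: float = 100.0


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class DormancyCall:
    """One variety's dormancy categorisation and its provenance."""

    variety_id: str
    category: Category
    stage: str                     # initial | refined | post_AR | post_LAR
    mechanism: str = "undetermined"  # embryo | seedcoat | undetermined
    viable: str = "unknown"          # yes | concern | unknown
    rule_fired: str = ""
    ambiguous: bool = False


def _nearest(violations: dict) -> tuple[Category, float]:
    # Deterministic tie-break: the less dormant category wins, which keeps
    # calls monotone when every germination mean is raised.
    best = min(violations, key=lambda c: (violations[c], int(c)))
    return best, violations[best]


def classify_initial(
    variety_id: str,
    means: dict,
    responsive: bool,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> DormancyCall:
    """Initial categorisation from the ABA dose-response round.

    ``means`` maps the treatment codes NT, ABA0.1, ABA1, ABA10 to mean
    germination fractions.  Rules, in order: SD if every mean is below 25%;
    ND if every mean is above 75% and the variety is not ABA-responsive;
    MD if no-treatment germination is below 50% with a non-increasing ABA
    dose response dropping at least 5 points in total; WD if no-treatment
    germination is above 50% and the variety is ABA-responsive.
    """
    required = ("NT", "ABA0.1", "ABA1", "ABA10")
    missing = [t for t in required if t not in means]
    if missing:
        raise ValueError(f"missing treatment means: {missing}")
    seq = np.array([means[t] for t in required], dtype=float)
    if np.any((seq < 0) | (seq > 1)):
        raise ValueError("germination means must lie in [0, 1]")
    nt = seq[0]
    cfg = config

    if seq.max() < cfg.sd_max:
        return DormancyCall(variety_id, Category.SD, "initial",
                            rule_fired="initial:SD(all<25%)")
    nd_ok = seq.min() > cfg.nd_min and not responsive
    if cfg.strict_nd:
        nd_ok = nd_ok and nt > cfg.strict_nd_nt
    if nd_ok:
        return DormancyCall(variety_id, Category.ND, "initial",
                            rule_fired="initial:ND(all>75%,unresponsive)")
    increases = np.clip(np.diff(seq), 0, None).sum()
    drop = nt - seq[-1]
    if nt < cfg.mid and increases == 0 and drop >= cfg.md_min_drop:
        return DormancyCall(variety_id, Category.MD, "initial",
                            rule_fired="initial:MD(NT<50%,decreasing)")
    if nt > cfg.mid and responsive:
        return DormancyCall(variety_id, Category.WD, "initial",
                            rule_fired="initial:WD(NT>50%,responsive)")

    pen = cfg.responsiveness_penalty
    violations = {
        Category.SD: 100 * max(0.0, seq.max() - cfg.sd_max),
        Category.ND: 100 * max(0.0, cfg.nd_min - seq.min())
        + (pen if responsive else 0.0)
        + (100 * max(0.0, cfg.strict_nd_nt - nt) if cfg.strict_nd else 0.0),
        Category.MD: 100 * (max(0.0, nt - cfg.mid) + increases
                            + max(0.0, cfg.md_min_drop - drop)),
        Category.WD: 100 * max(0.0, cfg.mid - nt) + (0.0 if responsive else pen),
    }
    cat, _ = _nearest(violations)
    return DormancyCall(variety_id, cat, "initial", ambiguous=True,
                        rule_fired=f"initial:nearest({cat.label})")


def classify_refined(
    variety_id: str,
    means: dict,
    responsive: bool,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> DormancyCall:
    """Refined categorisation from the ABA + GA hormone screen.

    ``means`` maps NT, ABA10, GA10 to mean germination fractions.  Intended
    only for varieties not initially ND (those are not retested).  Rules in
    order: SD if NT and ABA are below 25% and GA below 30%; MD if GA reaches
    at least 50% while NT stays below 50% and the variety responds to ABA;
    WD if germination is above 50% without hormone or with GA and the
    variety responds to ABA.
    """
    required = ("NT", "ABA10", "GA10")
    missing = [t for t in required if t not in means]
    if missing:
        raise ValueError(f"missing treatment means: {missing}")
    nt, aba, ga = (float(means[t]) for t in required)
    for v in (nt, aba, ga):
        if not 0 <= v <= 1:
            raise ValueError("germination means must lie in [0, 1]")
    cfg = config

    if nt < cfg.sd_max and aba < cfg.sd_max and ga < cfg.sd_ga_max:
        return DormancyCall(variety_id, Category.SD, "refined",
                            rule_fired="refined:SD(NT,ABA<25%,GA<30%)")
    if ga >= cfg.mid and nt < cfg.mid and responsive:
        return DormancyCall(variety_id, Category.MD, "refined",
                            rule_fired="refined:MD(GA>=50%,NT<50%,responsive)")
    if (nt > cfg.mid or ga > cfg.mid) and responsive:
        return DormancyCall(variety_id, Category.WD, "refined",
                            rule_fired="refined:WD(NT or GA>50%,responsive)")

    pen = cfg.responsiveness_penalty
    violations = {
        Category.SD: 100 * (max(0.0, nt - cfg.sd_max) + max(0.0, aba - cfg.sd_max)
                            + max(0.0, ga - cfg.sd_ga_max)),
        Category.MD: 100 * (max(0.0, cfg.mid - ga) + max(0.0, nt - cfg.mid))
        + (0.0 if responsive else pen),
        # Distance to the no-hormone branch of the WD rule; the GA branch
        # overlaps the MD region, which takes precedence.
        Category.WD: 100 * max(0.0, cfg.mid - nt)
        + (0.0 if responsive else pen),
    }
    cat, _ = _nearest(violations)
    return DormancyCall(variety_id, cat, "refined", ambiguous=True,
                        rule_fired=f"refined:nearest({cat.label})")


@dataclass
class ViabilityTimeline:
    """Assay history consulted by the viability decision tree.

    ``refined_nt`` is the no-hormone assay from the refined round (the
    baseline the after-ripening and scarification gains are tested against);
    ``ar1`` maps NT/ABA10/GA10 to the one-month after-ripened assays;
    ``scr`` is the scarified no-hormone assay (optional) and ``lar3`` the
    three-month after-ripened arms (optional, may include SCR).
    """

    variety_id: str
    refined_call: DormancyCall
    refined_nt: GerminationAssay
    ar1: dict
    scr: GerminationAssay | None = None
    lar3: dict | None = None


def _mean(assay: GerminationAssay) -> float:
    return percent_germination(assay)[1]


def _significant_increase(base: GerminationAssay, test: GerminationAssay,
                          alpha: float) -> bool:
    """Two-sample t-test on the arcsine scale, requiring a mean increase."""
    b = arcsine_transform(base.fractions())
    t = arcsine_transform(test.fractions())
    if t.mean() <= b.mean():
        return False
    if np.var(b, ddof=1) + np.var(t, ddof=1) == 0:
        return True  # distinct constant levels: unambiguous increase
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _stats.ttest_ind(t, b, equal_var=True)
    return bool(res.pvalue < alpha)


def viability_decision(
    timeline: ViabilityTimeline,
    alpha: float = 0.05,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> DormancyCall:
    """Assign dormancy mechanism and viability from the AR/SCR/LAR history.

    Decision order: (1) after-ripening releases dormancy (NT or GA reaches
    75%) -> embryo-imposed, viable; (2) a significant but incomplete gain
    after AR (NT still below 50%) -> slow after-ripener, embryo-imposed,
    viable; (3) scarification rescues germination (>= 50% and significantly
    above the refined baseline) -> seed-coat-imposed, viable; (4) long
    after-ripening releases dormancy -> embryo-imposed (long AR), viable;
    (5) only scarification after long after-ripening rescues -> seed-coat-
    imposed, viable; (6) otherwise a viability concern.

    The category of the refined call is retained: the tree characterises the
    mechanism behind dormancy observed at maturity, it does not reclassify
    its strength.
    """
    if timeline.refined_call.category not in (Category.SD, Category.MD):
        raise ValueError("viability tree is only consulted for SD/MD varieties")
    if not timeline.ar1 or "NT" not in timeline.ar1:
        raise ValueError("viability tree requires one-month after-ripened data")
    cfg = config
    cat = timeline.refined_call.category
    vid = timeline.variety_id

    ar_nt = timeline.ar1["NT"]
    ar_ga = timeline.ar1.get("GA10")
    ar_nt_mean = _mean(ar_nt)
    ar_ga_mean = _mean(ar_ga) if ar_ga is not None else 0.0

    if max(ar_nt_mean, ar_ga_mean) >= cfg.release_min:
        return DormancyCall(vid, cat, "post_AR", mechanism="embryo",
                            viable="yes", rule_fired="viability:AR_release")
    if ar_nt_mean < cfg.mid and _significant_increase(
            timeline.refined_nt, ar_nt, alpha):
        return DormancyCall(vid, cat, "post_AR", mechanism="embryo",
                            viable="yes", rule_fired="viability:slow_AR")
    if timeline.scr is not None:
        scr_mean = _mean(timeline.scr)
        if scr_mean >= cfg.rescue_min and _significant_increase(
                timeline.refined_nt, timeline.scr, alpha):
            return DormancyCall(vid, cat, "post_AR", mechanism="seedcoat",
                                viable="yes", rule_fired="viability:SCR_rescue")
    if timeline.lar3:
        lar_nt = timeline.lar3.get("NT")
        lar_ga = timeline.lar3.get("GA10")
        lar_best = max(
            (_mean(a) for a in (lar_nt, lar_ga) if a is not None), default=0.0
        )
        if lar_best >= cfg.release_min:
            return DormancyCall(vid, cat, "post_LAR", mechanism="embryo",
                                viable="yes", rule_fired="viability:LAR_release")
        lar_scr = timeline.lar3.get("SCR")
        if lar_scr is not None:
            lscr_mean = _mean(lar_scr)
            if lscr_mean >= cfg.rescue_min and _significant_increase(
                    timeline.refined_nt, lar_scr, alpha):
                return DormancyCall(vid, cat, "post_LAR", mechanism="seedcoat",
                                    viable="yes",
                                    rule_fired="viability:LAR_SCR_rescue")
        return DormancyCall(vid, cat, "post_LAR", mechanism="undetermined",
                            viable="concern", rule_fired="viability:concern")
    return DormancyCall(vid, cat, "post_AR", mechanism="undetermined",
                        viable="concern", rule_fired="viability:concern")


# ---------------------------------------------------------------------------
# Panel-level driver over the long-format assay table
# ---------------------------------------------------------------------------

def _assays_by_treatment(sub: pd.DataFrame, variety_id: str) -> dict:
    out = {}
    for code, rows in sub.groupby("treatment", sort=False):
        reps = list(zip(rows["sown"].astype(int), rows["germinated"].astype(int)))
        from .germination import TreatmentSpec  # local to avoid cycle at import
        out[code] = GerminationAssay(variety_id, TreatmentSpec.parse(code), reps)
    return out


def classify_variety(
    variety_id: str,
    assays: pd.DataFrame,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> DormancyCall:
    """Run the full decision chain for one variety.

    ``assays`` is the variety's slice of the long table with columns
    ``round`` (initial/refined/viability), ``treatment``, ``sown``,
    ``germinated``.  Missing later rounds simply stop the chain at the last
    call that had data.
    """
    initial = _assays_by_treatment(assays[assays["round"] == "initial"], variety_id)
    missing = [t for t in ("NT", "ABA0.1", "ABA1", "ABA10") if t not in initial]
    if missing:
        raise ValueError(f"{variety_id}: missing initial arms {missing}")
    means0 = {c: percent_germination(a)[1] for c, a in initial.items()}
    resp0 = is_aba_responsive(initial["NT"], initial["ABA10"], config.alpha)
    call = classify_initial(variety_id, means0, resp0, config)
    if call.category == Category.ND:
        return call

    refined = _assays_by_treatment(assays[assays["round"] == "refined"], variety_id)
    if not all(t in refined for t in ("NT", "ABA10", "GA10")):
        return call
    means1 = {c: percent_germination(a)[1] for c, a in refined.items()}
    resp1 = is_aba_responsive(refined["NT"], refined["ABA10"], config.alpha)
    call = classify_refined(variety_id, means1, resp1, config)
    if call.category not in (Category.SD, Category.MD):
        return call

    viab = _assays_by_treatment(assays[assays["round"] == "viability"], variety_id)
    ar1 = {c.split("-", 1)[1]: a for c, a in viab.items() if c.startswith("AR1-")}
    if "NT" not in ar1:
        return call
    scr = ar1.pop("SCR", None)
    lar3 = {c.split("-", 1)[1]: a for c, a in viab.items() if c.startswith("LAR3-")}
    # Scarification is consulted only when AR seeds failed to germinate.
    ar_best = max(_mean(ar1["NT"]),
                  _mean(ar1["GA10"]) if "GA10" in ar1 else 0.0)
    if ar_best >= config.fail_max:
        scr = None
        lar3 = None
    timeline = ViabilityTimeline(
        variety_id=variety_id,
        refined_call=call,
        refined_nt=refined["NT"],
        ar1=ar1,
        scr=scr,
        lar3=lar3 or None,
    )
    return viability_decision(timeline, config.alpha, config)


def classify_panel(
    germination: pd.DataFrame,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Classify every variety in a long-format germination table.

    Returns one row per variety: ``variety_id``, ``category_code`` (1-4),
    ``category_label``, ``stage``, ``mechanism``, ``viable``, ``rule_fired``,
    ``ambiguous``.
    """
    required = {"variety_id", "round", "treatment", "sown", "germinated"}
    missing = required - set(germination.columns)
    if missing:
        raise ValueError(f"germination table lacks columns {sorted(missing)}")
    rows = []
    for vid, sub in germination.groupby("variety_id", sort=True):
        call = classify_variety(str(vid), sub, config)
        rows.append({
            "variety_id": call.variety_id,
            "category_code": int(call.category),
            "category_label": call.category.label,
            "stage": call.stage,
            "mechanism": call.mechanism,
            "viable": call.viable,
            "rule_fired": call.rule_fired,
            "ambiguous": call.ambiguous,
        })
    return pd.DataFrame(rows)


def summarize_panel(calls: pd.DataFrame, colors: pd.Series | None = None):
    """Category counts, optionally cross-tabulated with seed-coat color.

    ``calls`` is the frame produced by :func:`classify_panel` (or any frame
    with ``variety_id`` and ``category_label``).  Returns ``counts`` (Series
    over ND/WD/MD/SD, zero-filled) and, when ``colors`` is given (indexed by
    variety id), a color x category contingency table restricted to the
    varieties present in both inputs.
    """
    order = [c.label for c in Category]
    if calls.empty:
        counts = pd.Series(0, index=order, name="n_varieties")
        return (counts, None) if colors is not None else (counts, None)
    if calls["variety_id"].duplicated().any():
        dupes = calls.loc[calls["variety_id"].duplicated(), "variety_id"].tolist()
        raise ValueError(f"duplicate variety ids: {dupes}")
    counts = (
        calls["category_label"].value_counts().reindex(order).fillna(0).astype(int)
    )
    counts.name = "n_varieties"
    crosstab = None
    if colors is not None:
        merged = calls.set_index("variety_id").join(colors.rename("color"), how="inner")
        crosstab = pd.crosstab(merged["color"], merged["category_label"])
        crosstab = crosstab.reindex(columns=order, fill_value=0)
    return counts, crosstab
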