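"""Spine-density math and the group-statistics decision procedure.

Spine counts and sEPSC frequency/amplitude are treated as lognormally
distributed measures and log-transformed before parametric testing — a
global, per-measure-class rule rather than a per-dataset re-decision; the
``distribution_shape`` classifier remains available for new measure types.
Two-sample tests are pooled-variance Student t tests (df = n1 + n2 − 2),
two-tailed.  Many-to-one comparisons use one-way fixed-effects ANOVA with
Dunnett's multivariate-t correction against a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, StructuralError

LOGNORMAL_MEASURES = frozenset({"spine_count", "sepsc_freq", "sepsc_amp"})
MIN_DENDRITE_LENGTH_UM = 40.0
MAX_DENDRITES_PER_COMPARTMENT = 5


@dataclass(frozen=True)
class StatResult:
    test_name: str
    transform_applied: str  # "none" | "log"
    statistic: float
    df: float
    p_two_tailed: float
    group_summaries: list[dict] = field(default_factory=list)


def _summary(x: np.ndarray) -> dict:
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else float("nan")
    return {
        "mean": float(np.mean(x)),
        "sd": sd,
        "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
        "n": int(n),
    }


# ---------------------------------------------------------------------------
# spine density
# ---------------------------------------------------------------------------


def spine_density(counts: pd.DataFrame, per_um: float = 1.0) -> pd.DataFrame:
    """Per-dendrite spine densities with the study's inclusion rules.

    ``counts`` has one row per dendrite with columns ``neuron_id``,
    ``compartment`` ('apical'|'basal'), ``length_um``, ``spine_count``.
    Dendrites shorter than 40 µm are excluded; at most 5 dendrites per
    compartment per neuron are admitted, in the order supplied.  Density is
    count/length scaled to ``per_um`` (10.0 reports spines per 10 µm).
    """
    required = {"neuron_id", "compartment", "length_um", "spine_count"}
    missing = required - set(counts.columns)
    if missing:
        raise StructuralError(f"missing columns: {sorted(missing)}")
    if (counts["length_um"] <= 0).any():
        raise StructuralError("dendrite length must be > 0")
    if (counts["spine_count"] < 0).any():
        raise StructuralError("spine counts must be >= 0")
    kept = counts[counts["length_um"] >= MIN_DENDRITE_LENGTH_UM].copy()
    kept = (
        kept.groupby(["neuron_id", "compartment"], sort=False, group_keys=False)
        .head(MAX_DENDRITES_PER_COMPARTMENT)
        .copy()
    )
    kept["density"] = kept["spine_count"] / kept["length_um"] * per_um
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# distribution shape
# ---------------------------------------------------------------------------


def distribution_shape(sample: np.ndarray, alpha: float = 0.05) -> str:
    """Classify a sample as 'normal', 'lognormal', or 'other'.

    Shapiro–Wilk is run on the raw values and (when all are positive) on
    their logs; the classification is whichever scale passes at ``alpha``,
    the higher W statistic breaking the tie when both pass.  Non-positive
    values force a raw-only assessment.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise InsufficientDataError("distribution-shape test needs n >= 8")
    w_raw, p_raw = sps.shapiro(x)
    if np.all(x > 0):
        w_log, p_log = sps.shapiro(np.log(x))
    else:
        w_log, p_log = -np.inf, 0.0
    raw_ok, log_ok = p_raw > alpha, p_log > alpha
    if raw_ok and log_ok:
        return "normal" if w_raw >= w_log else "lognormal"
    if raw_ok:
        return "normal"
    if log_ok:
        return "lognormal"
    return "other"


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    design: str = "unpaired",
    measure_class: str = "other",
) -> StatResult:
    """Two-tailed Student t test with the measure-class transform rule.

    Measures in {'spine_count', 'sepsc_freq', 'sepsc_amp'} are
    log-transformed before testing; for 'other' measures the transform
    follows ``distribution_shape`` when both groups have n >= 8 (raw scale
    otherwise).  Group summaries are always reported on the untransformed
    scale.  Paired comparisons with zero-variance differences are guarded:
    identical groups give t = 0, p = 1, a constant nonzero shift gives
    t = ±inf, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if design not in ("paired", "unpaired"):
        raise StructuralError(f"unknown design {design!r}")
    if design == "paired" and a.size != b.size:
        raise StructuralError("paired design requires equal group sizes")

    transform = "none"
    if measure_class in LOGNORMAL_MEASURES:
        transform = "log"
    elif measure_class == "other" and a.size >= 8 and b.size >= 8:
        pooled = np.concatenate([a, b])
        if np.all(pooled > 0) and distribution_shape(pooled) == "lognormal":
            transform = "log"
    if transform == "log":
        if np.any(a <= 0) or np.any(b <= 0):
            raise StructuralError("log transform requires strictly positive values")
        ta, tb = np.log(a), np.log(b)
    else:
        ta, tb = a, b

    summaries = [_summary(a), _summary(b)]
    if design == "paired":
        diff = tb - ta
        sd = np.std(diff, ddof=1)
        n = diff.size
        df = n - 1
        mean_d = float(np.mean(diff))
        if sd <= abs(mean_d) * 1e-10 or sd == 0:  # constant shift up to rounding
            stat = 0.0 if mean_d == 0 else float(np.sign(mean_d)) * float("inf")
            p = 1.0 if mean_d == 0 else 0.0
        else:
            stat, p = sps.ttest_rel(tb, ta)
            stat, p = float(stat), float(p)
        name = "paired t test"
    else:
        df = a.size + b.size - 2
        res = sps.ttest_ind(ta, tb, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # both groups constant and equal
            stat, p = 0.0, 1.0
        name = "unpaired t test"
    return StatResult(
        test_name=name,
        transform_applied=transform,
        statistic=stat,
        df=float(df),
        p_two_tailed=p,
        group_summaries=summaries,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA with Dunnett many-to-one correction
# ---------------------------------------------------------------------------


def anova_dunnett(groups: list[np.ndarray], reference_index: int = 0) -> dict:
    """One-way fixed-effects ANOVA plus Dunnett-adjusted comparisons of every
    group against the reference group (multivariate-t evaluation).

    Returns F, degrees of freedom, the overall p, and for each non-reference
    group (in input order) the Dunnett-adjusted and unadjusted two-sided p
    of its comparison with the reference.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise InsufficientDataError("each group needs n >= 2")
    if not (0 <= reference_index < len(groups)):
        raise StructuralError("reference index out of range")
    if all(np.std(g) == 0 for g in groups):
        raise DegenerateDataError("zero within-group variance in every group")

    f_stat, p_overall = sps.f_oneway(*groups)
    n_total = sum(g.size for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)

    control = groups[reference_index]
    others = [g for i, g in enumerate(groups) if i != reference_index]
    res = sps.dunnett(*others, control=control)
    p_unadj = 2.0 * sps.t.sf(np.abs(res.statistic), df_within)
    comparisons = []
    j = 0
    for i in range(len(groups)):
        if i == reference_index:
            continue
        comparisons.append(
            {
                "group_index": i,
                "statistic": float(res.statistic[j]),
                "p_adjusted": float(res.pvalue[j]),
                "p_unadjusted": float(p_unadj[j]),
            }
        )
        j += 1
    return {
        "F": float(f_stat),
        "df_between": df_between,
        "df_within": df_within,
        "p_overall": float(p_overall),
        "comparisons": comparisons,
        "method": "dunnett multivariate-t",
    }
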