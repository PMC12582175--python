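"""Transcriptomic screening on annotated cell×gene tables.

Cells carry Allen-style cluster labels; clusters are grouped into putative
layers by exact-substring matching against the annotation tokens of each
layer list (the lists enumerate tokens verbatim, so substring matching —
not regex — is the faithful rule).  The retrosplenial-specific cluster
"133_L2 IT RSPv-POST-PRE", which corresponds to the low-rheobase (LR)
neurons of granular retrosplenial L2/3, maps to its own "L2/3 LR" group
with priority over the generic L2 rule.  Group contrasts delegate to the
statistics module and additionally report the fraction of cells with a
nonzero count ("detectable" fraction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, StructuralError
from .stats import anova_dunnett, compare_groups

L23_TOKENS = ("L2 IT", "L2/3 IT")
L5_TOKENS = ("L4 RSP-ACA", "L4 IT CTX", "L4/5 IT CTX", "L5 IT CTX",
             "L5 PT CTX", "L5 PPP", "L5/6 IT CTX", "L5/6 IT TPE-ENT")
L6_TOKENS = ("L6 IT CTX", "L6 IT ENTl", "L5/6 NP CTX", "L6 CT CTX",
             "L6b CTX", "Car3")
LR_CLUSTER = "133_L2 IT RSPv-POST-PRE"

GROUP_L23 = "L2/3"
GROUP_L5 = "L5"
GROUP_L6 = "L6"
GROUP_LR = "L2/3 LR"
GROUP_UNASSIGNED = "unassigned"


def layer_group_of(cluster_label: str) -> str:
    """Layer group of a single cluster label (deterministic, idempotent)."""
    if LR_CLUSTER in cluster_label:
        return GROUP_LR
    for tokens, group in ((L23_TOKENS, GROUP_L23), (L5_TOKENS, GROUP_L5),
                          (L6_TOKENS, GROUP_L6)):
        if any(tok in cluster_label for tok in tokens):
            return group
    return GROUP_UNASSIGNED


def assign_layer_groups(table: pd.DataFrame, cluster_col: str = "cluster_label") -> pd.DataFrame:
    """Return a copy of ``table`` with a ``layer_group`` column added."""
    if cluster_col not in table.columns:
        raise StructuralError(f"missing column {cluster_col!r}")
    out = table.copy()
    out["layer_group"] = out[cluster_col].map(layer_group_of)
    return out


def screen_contrast(
    table: pd.DataFrame,
    group_by: str = "layer_group",
    reference: str | None = None,
    pair: tuple[str, str] | None = None,
    count_col: str = "target_gene_count",
) -> dict:
    """Group contrast of per-cell counts (raw-count scale).

    With ``pair`` given, an unpaired two-group t test between the two named
    groups; with ``reference`` given, one-way ANOVA with Dunnett-corrected
    comparisons of every other group against the reference.  Per-group
    summaries include the fraction of cells with a nonzero count.
    """
    if group_by not in table.columns:
        raise StructuralError(f"missing column {group_by!r}")
    if (pair is None) == (reference is None):
        raise StructuralError("give exactly one of 'pair' or 'reference'")
    grouped = {name: sub[count_col].to_numpy(dtype=float)
               for name, sub in table.groupby(group_by, sort=False)}
    for name, values in grouped.items():
        if values.size == 0:
            raise InsufficientDataError(f"empty group {name!r}")
    group_stats = {
        name: {
            "n": int(v.size),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
            "detectable_fraction": float(np.mean(v > 0)),
        }
        for name, v in grouped.items()
    }
    if pair is not None:
        g1, g2 = pair
        for g in pair:
            if g not in grouped:
                raise StructuralError(f"group {g!r} not present")
        test = compare_groups(grouped[g1], grouped[g2], design="unpaired",
                              measure_class="other")
        return {"group_stats": group_stats, "test": test, "design": "pair"}
    if reference not in grouped:
        raise StructuralError(f"reference group {reference!r} not present")
    names = list(grouped)
    result = anova_dunnett([grouped[n] for n in names],
                           reference_index=names.index(reference))
    for comp in result["comparisons"]:
        comp["group"] = names[comp["group_index"]]
    return {"group_stats": group_stats, "test": result, "design": "many_to_one"}
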