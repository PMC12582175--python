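"""Recording-level quality-control gating.

Whole-cell recordings are excluded when the baseline resting membrane
potential is more depolarized than −55 mV (−45 mV for anterodorsal-thalamus
recordings, whose neurons rest more depolarized), when uncompensated series
resistance exceeds 35 MΩ, when series resistance changes by more than 25%
over the experiment, or when input resistance decreases by more than 25%.
Every violated rule is reported, so a report never hides a second failure
behind the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import StructuralError

CORTICAL = "cortical"
AD_THALAMUS = "AD_thalamus"

RMP_MAX_MV = {CORTICAL: -55.0, AD_THALAMUS: -45.0}
RS_MAX_MOHM = 35.0
RS_CHANGE_MAX_FRAC = 0.25
RIN_DECREASE_MAX_FRAC = 0.25

RULE_RMP = "rmp"
RULE_RS = "series_resistance"
RULE_RS_CHANGE = "rs_change"
RULE_RIN_CHANGE = "rin_change"


@dataclass(frozen=True)
class QCReport:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    measured: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise StructuralError("QCReport: passed must equal 'no reasons'")


def evaluate_qc(
    rmp_mV: float,
    rs_MOhm: float,
    rs_change_frac: float,
    rin_change_frac: float,
    region_profile: str = CORTICAL,
) -> QCReport:
    """Apply the four exclusion rules and report every violation.

    ``rs_change_frac`` and ``rin_change_frac`` are fractional changes
    ``(last − first)/first``; the Rs rule trips on a change in either
    direction, the Rin rule only on a decrease (``rin_change_frac < −0.25``).
    """
    if region_profile not in RMP_MAX_MV:
        raise StructuralError(f"unknown region profile {region_profile!r}")
    for name, v in (
        ("rmp_mV", rmp_mV),
        ("rs_MOhm", rs_MOhm),
        ("rs_change_frac", rs_change_frac),
        ("rin_change_frac", rin_change_frac),
    ):
        if not math.isfinite(v):
            raise StructuralError(f"{name} must be finite, got {v}")

    reasons = []
    if rmp_mV > RMP_MAX_MV[region_profile]:
        reasons.append(RULE_RMP)
    if rs_MOhm > RS_MAX_MOHM:
        reasons.append(RULE_RS)
    if abs(rs_change_frac) > RS_CHANGE_MAX_FRAC:
        reasons.append(RULE_RS_CHANGE)
    if rin_change_frac < -RIN_DECREASE_MAX_FRAC:
        reasons.append(RULE_RIN_CHANGE)
    measured = {
        RULE_RMP: rmp_mV,
        RULE_RS: rs_MOhm,
        RULE_RS_CHANGE: rs_change_frac,
        RULE_RIN_CHANGE: rin_change_frac,
    }
    return QCReport(passed=not reasons, reasons=reasons, measured=measured)
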