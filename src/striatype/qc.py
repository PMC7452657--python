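"""Recording-quality control.

A recording is excluded when its series resistance exceeds 25 MOhm, its
resting membrane potential is more depolarized than -50 mV, or its baseline
fluctuates by more than 10%.  "Fluctuation" is measured here as the
coefficient of variation of the per-sweep pre-stimulus baseline potential
across sweeps (the magnitude of the mean is used since baselines are
negative); a series-resistance drift check is available separately for users
who track Rs per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .recording import Recording

__all__ = ["QCRules", "QCReport", "apply_qc", "qc_table"]

#: Minimum usable pre-stimulus baseline (s).
MIN_BASELINE_S = 0.1


@dataclass(frozen=True)
class QCRules:
    """Exclusion thresholds for recording quality.

    ``rmp_ceiling`` is signed mV: a baseline mean above it (more depolarized)
    fails.  ``max_fluctuation`` is a fraction (0.10 = 10%).
    """

    max_series_resistance: float = 25.0  # MOhm
    rmp_ceiling: float = -50.0  # mV
    max_fluctuation: float = 0.10

    def __post_init__(self) -> None:
        if self.max_series_resistance <= 0:
            raise ValidationError("max_series_resistance must be positive")
        if not 0 < self.max_fluctuation < 1:
            raise ValidationError("max_fluctuation must be in (0, 1)")


@dataclass
class QCReport:
    cell_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    measured_rs: float | None = None  # MOhm
    measured_rmp: float = float("nan")  # mV
    rmp_cv: float = float("nan")  # fraction

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("QCReport.passed must match empty reasons")


def apply_qc(rec: Recording, rules: QCRules | None = None) -> QCReport:
    """Evaluate the exclusion criteria on one recording.

    All failing reasons are listed, not just the first.  A missing series
    resistance is recorded as ``rs_unknown`` while the other checks still run.
    """
    rules = rules or QCRules()
    if not rec.sweeps:
        raise ValidationError("recording has no sweeps")
    if rec.protocol.pre_stim < MIN_BASELINE_S:
        raise ValidationError(
            f"QC needs at least {MIN_BASELINE_S * 1e3:.0f} ms of pre-stimulus baseline"
        )

    b0, b1 = rec.baseline_window()
    per_sweep_baseline = np.array([float(np.mean(sw.samples[b0:b1])) for sw in rec.sweeps])
    rmp = float(np.mean(per_sweep_baseline))
    if len(per_sweep_baseline) > 1 and abs(rmp) > 0:
        cv = float(np.std(per_sweep_baseline, ddof=1) / abs(rmp))
    else:
        cv = 0.0

    reasons: list[str] = []
    if rec.series_resistance is None:
        reasons.append("rs_unknown")
    elif rec.series_resistance > rules.max_series_resistance:
        reasons.append(
            f"series_resistance {rec.series_resistance:.1f} MOhm > "
            f"{rules.max_series_resistance:.1f} MOhm"
        )
    if rmp > rules.rmp_ceiling:
        reasons.append(
            f"rmp {rmp:.1f} mV more depolarized than {rules.rmp_ceiling:.1f} mV"
        )
    if cv > rules.max_fluctuation:
        reasons.append(
            f"baseline fluctuation {cv:.1%} exceeds {rules.max_fluctuation:.0%}"
        )

    return QCReport(
        cell_id=rec.cell_id,
        passed=not reasons,
        reasons=reasons,
        measured_rs=rec.series_resistance,
        measured_rmp=rmp,
        rmp_cv=cv,
    )


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    """Tabulate QC reports for CSV export (one row per cell)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in reports],
            "passed": [r.passed for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
            "series_resistance_mohm": [r.measured_rs for r in reports],
            "rmp_mv": [r.measured_rmp for r in reports],
            "rmp_cv": [r.rmp_cv for r in reports],
        }
    )
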