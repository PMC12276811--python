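"""Run-level quality control.

A run (and all of its trajectories) is excluded when any of three
independent criteria fires: (1) strong responses to visual stimuli during
the clean-air-only periods, suggesting odor contamination; (2) generally
low visual responses throughout, suggesting a failed CO2 release or poor
animals; (3) much lower responses in one half of the stimulus series than
the other, suggesting the run fell outside the activity peak.  The
criteria are qualitative in origin; the numeric thresholds here are this
package's defaults and are recorded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import math

import pandas as pd

from .io import RunRecord
from .metrics import PeriodSummary


@dataclass(frozen=True)
class QCThresholds:
    """Numeric commitments for the three exclusion criteria.

    clean_air_max_recruitment: max tolerated recruited proportion during
        clean-air periods (criterion 1).
    min_recruited_total: minimum recruited trajectories summed over main
        periods (criterion 2).
    max_half_ratio: max tolerated ratio of recruited counts between the
        two halves of the main series (criterion 3).
    """

    clean_air_max_recruitment: float = 0.02
    min_recruited_total: int = 5
    max_half_ratio: float = 3.0


@dataclass(frozen=True)
class QCReport:
    run_id: str
    clean_air_response: bool | None  # None = not evaluable (no clean-air periods)
    low_response: bool
    half_imbalance: bool
    clean_air_recruitment: float
    total_recruited: int
    half_ratio: float
    excluded: bool
    clean_air_max_recruitment: float
    min_recruited_total: int
    max_half_ratio: float


def qc_run(
    run: RunRecord,
    summaries: Sequence[PeriodSummary],
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Evaluate the three exclusion criteria for one run.

    ``summaries`` must cover every scheduled period, including the pre/post
    clean-air phases.  When the schedule has no clean-air phases criterion 1
    is reported as not-evaluable (None) rather than as a pass.  QC is pure:
    identical inputs yield identical reports.
    """
    by_id = {s.period_id: s for s in summaries}
    missing = [p.period_id for p in run.schedule if p.period_id not in by_id]
    if missing:
        raise ValueError(f"run {run.run_id!r}: no summary for period(s) {missing}")

    clean = [by_id[p.period_id] for p in run.clean_air_periods]
    main = [by_id[p.period_id] for p in run.main_periods]

    # criterion 1: recruitment during clean-air-only periods
    if clean:
        n_act = sum(s.n_trajectories for s in clean)
        n_rec = sum(s.n_recruited for s in clean)
        clean_air_recruitment = n_rec / n_act if n_act else 0.0
        flag1: bool | None = clean_air_recruitment > thresholds.clean_air_max_recruitment
    else:
        clean_air_recruitment = math.nan
        flag1 = None

    # criterion 2: low visual response throughout
    total_recruited = sum(s.n_recruited for s in main)
    flag2 = total_recruited < thresholds.min_recruited_total

    # criterion 3: imbalance between series halves
    half = len(main) // 2
    first = sum(s.n_recruited for s in main[:half])
    second = sum(s.n_recruited for s in main[len(main) - half:])
    lo, hi = min(first, second), max(first, second)
    if hi == 0:
        half_ratio = 1.0  # no responses at all; imbalance is criterion 2's job
    elif lo == 0:
        half_ratio = math.inf
    else:
        half_ratio = hi / lo
    flag3 = half_ratio > thresholds.max_half_ratio

    excluded = bool(flag1) or flag2 or flag3
    return QCReport(
        run_id=run.run_id,
        clean_air_response=flag1,
        low_response=flag2,
        half_imbalance=flag3,
        clean_air_recruitment=clean_air_recruitment,
        total_recruited=total_recruited,
        half_ratio=half_ratio,
        excluded=excluded,
        **asdict(thresholds),
    )


def qc_table(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in reports])
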