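"""Cohort-level statistics: snapshot selection, rank-sum tests, report.

Per patient, only the first non-excluded snapshot enters testing.  Each
pathology group is compared against the Normal group for each of the three
structural parameters with a two-tailed Wilcoxon rank-sum test; p-values are
Bonferroni-corrected over the declared test count (a four-pathology-group,
three-parameter design gives 12 tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .image_io import GROUP_LABELS, PATHOLOGY_GROUPS, MetricsRow
from .metrics import StructureMetrics

logger = logging.getLogger(__name__)

#: Parameter name → StructureMetrics attribute.
PARAMETERS = {
    "T_med": "T_med_um",
    "sigma_T": "sigma_T_um",
    "C_s": "C_s_per_mm",
}

ALPHA = 0.05


@dataclass
class CohortRecord:
    """Per-snapshot metric row attributed to a patient and diagnosis group."""

    patient_id: str
    group: str
    snapshot_index: int
    metrics: Optional[StructureMetrics]
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValidationError(f"unknown group label {self.group!r}")

    def to_metrics_row(self) -> MetricsRow:
        if self.metrics is None:
            raise ValidationError("record has no metrics")
        m = self.metrics
        return MetricsRow(
            patient_id=self.patient_id,
            group=self.group,
            snapshot_index=self.snapshot_index,
            T_med_um=m.T_med_um,
            sigma_T_um=m.sigma_T_um,
            C_s_per_mm=m.C_s_per_mm,
            n_holes=m.n_holes,
            skeleton_length_um=m.skeleton_length_um,
        )


@dataclass(frozen=True)
class ComparisonResult:
    group: str
    parameter: str  # one of PARAMETERS
    group_median: float
    normal_median: float
    delta: float
    p_raw: float
    p_adjusted: float
    significant: bool
    method: str


def select_snapshots(records: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Per patient, the lowest-index non-excluded snapshot.

    Patients whose snapshots are all excluded are dropped (logged).  Output
    preserves the order of first patient appearance.
    """
    by_patient: dict[str, list[CohortRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.patient_id not in by_patient:
            order.append(rec.patient_id)
        by_patient.setdefault(rec.patient_id, []).append(rec)
    selected = []
    for pid in order:
        candidates = sorted(
            (r for r in by_patient[pid] if not r.excluded and r.metrics is not None),
            key=lambda r: r.snapshot_index,
        )
        if candidates:
            selected.append(candidates[0])
        else:
            logger.warning("patient %s dropped: all snapshots excluded", pid)
    return selected


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    method: str  # "exact" or "normal-approximation"


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], variant: str = "auto"
) -> WilcoxonResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    ``variant``: "auto" uses exact null enumeration when the combined sample
    size is at most 12 and there are no ties, otherwise the normal
    approximation with tie and continuity correction.  "exact" and "normal"
    force the respective method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    if variant == "auto":
        use_exact = tie_free and combined.size <= 12
    elif variant == "exact":
        if not tie_free:
            raise ValidationError("exact method requires tie-free samples")
        use_exact = True
    elif variant == "normal":
        use_exact = False
    else:
        raise ValidationError(f"unknown wilcoxon variant {variant!r}")
    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation"
    return WilcoxonResult(
        p_value=float(min(res.pvalue, 1.0)),
        statistic=float(res.statistic),
        method=method,
    )


def bonferroni(p_raw: Sequence[float], m: int = 12) -> list[float]:
    """Multiply each raw p by the declared test count m, capping at 1."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m < len(p_raw):
        raise ValidationError(
            f"m = {m} is smaller than the number of tests performed ({len(p_raw)})"
        )
    return [min(1.0, float(p) * m) for p in p_raw]


def compare_groups(
    records: Sequence[CohortRecord],
    m_tests: Optional[int] = None,
    alpha: float = ALPHA,
    wilcoxon_variant: str = "auto",
) -> list[ComparisonResult]:
    """Every pathology group vs Normal, for each structural parameter.

    ``records`` should already be one non-excluded snapshot per patient (see
    :func:`select_snapshots`).  The Bonferroni count defaults to
    (#pathology groups present) x (#parameters); pass ``m_tests`` (e.g. 12)
    to override for strict replication of a declared design.
    """
    usable = [r for r in records if not r.excluded and r.metrics is not None]
    groups: dict[str, list[CohortRecord]] = {}
    for rec in usable:
        groups.setdefault(rec.group, []).append(rec)
    if "Normal" not in groups:
        raise ValidationError("Normal group missing from cohort")
    pathology = [g for g in PATHOLOGY_GROUPS if g in groups]
    if not pathology:
        raise ValidationError("no pathology group present")
    m = m_tests if m_tests is not None else len(pathology) * len(PARAMETERS)

    raw: list[tuple[str, str, float, float, float, float, str]] = []
    for group in pathology:
        for param, attr in PARAMETERS.items():
            g_vals = [getattr(r.metrics, attr) for r in groups[group]]
            n_vals = [getattr(r.metrics, attr) for r in groups["Normal"]]
            g_med = float(np.median(g_vals))
            n_med = float(np.median(n_vals))
            test = wilcoxon_rank_sum(g_vals, n_vals, variant=wilcoxon_variant)
            raw.append(
                (group, param, g_med, n_med, g_med - n_med, test.p_value, test.method)
            )
    adjusted = bonferroni([r[5] for r in raw], m=m)
    return [
        ComparisonResult(
            group=g,
            parameter=param,
            group_median=g_med,
            normal_median=n_med,
            delta=delta,
            p_raw=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
            method=method,
        )
        for (g, param, g_med, n_med, delta, p, method), p_adj in zip(raw, adjusted)
    ]


def _stars(p_adjusted: float) -> str:
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return ""


def render_report(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabular report: one Normal row plus one row per pathology group.

    Columns per parameter: the group median, the delta vs Normal annotated
    with the adjusted p and significance stars (* p<0.05, ** p<0.01).  The
    Normal row renders "N/A" for delta columns.
    """
    if not results:
        raise ValidationError("no comparison results to render")
    normal_medians = {}
    by_group: dict[str, dict[str, ComparisonResult]] = {}
    for res in results:
        normal_medians[res.parameter] = res.normal_median
        by_group.setdefault(res.group, {})[res.parameter] = res
    columns = (
        [f"{p}_median" for p in PARAMETERS]
        + [f"delta_{p}" for p in PARAMETERS]
    )
    rows = {}
    rows["Normal"] = [f"{normal_medians[p]:.6g}" for p in PARAMETERS] + [
        "N/A" for _ in PARAMETERS
    ]
    for group in PATHOLOGY_GROUPS:
        if group not in by_group:
            continue
        cells = [f"{by_group[group][p].group_median:.6g}" for p in PARAMETERS]
        for p in PARAMETERS:
            res = by_group[group][p]
            cells.append(
                f"{res.delta:.6g} (p={res.p_adjusted:.3g}){_stars(res.p_adjusted)}"
            )
        rows[group] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
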