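"""Volume-time curve analysis and method-agreement statistics.

The phase-resolved appendage volumes V(t) over the cardiac cycle give the
ejection fraction

    EF = (max V - min V) / max V,

with the diastolic phase at the volume maximum and the systolic phase at
the minimum.  Agreement and reproducibility between observers or methods
are assessed by the within-subject coefficient of variation, Bland-Altman
bias with 95% limits of agreement, and the paired t-test.  Areas and
volumes can be normalised by body surface area (Mosteller formula).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

__all__ = [
    "PhaseSeries",
    "FunctionReport",
    "AgreementTable",
    "BodyMetrics",
    "ejection_fraction",
    "normalize_by_bsa",
    "coefficient_of_variation",
    "bland_altman",
    "paired_t_test",
]


@dataclass
class PhaseSeries:
    """Per-phase appendage measurements across the cardiac cycle."""

    phase_percents: np.ndarray
    volumes: np.ndarray  # cm^3
    ostium_areas: np.ndarray | None = None  # cm^2, optional

    def __post_init__(self) -> None:
        self.phase_percents = np.asarray(self.phase_percents, dtype=float).ravel()
        self.volumes = np.asarray(self.volumes, dtype=float).ravel()
        if len(self.phase_percents) != len(self.volumes):
            raise ValueError("phase_percents and volumes must have equal length")
        if np.any(self.phase_percents < 0) or np.any(self.phase_percents >= 100):
            raise ValueError("phase percentages must lie in [0, 100)")
        if np.any(np.diff(self.phase_percents) <= 0):
            raise ValueError("phase percentages must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("all phase volumes must be positive")
        if self.ostium_areas is not None:
            self.ostium_areas = np.asarray(self.ostium_areas, dtype=float).ravel()
            if len(self.ostium_areas) != len(self.volumes):
                raise ValueError("ostium_areas must match volumes in length")

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class FunctionReport:
    """Ejection fraction and the phases it derives from."""

    ef: float
    diastolic_index: int
    systolic_index: int
    diastolic_volume: float
    systolic_volume: float
    diastolic_phase_percent: float
    systolic_phase_percent: float

    @property
    def ef_percent(self) -> float:
        return 100.0 * self.ef


@dataclass
class AgreementTable:
    """Paired measurements of one parameter by two observers or methods."""

    m1: np.ndarray
    m2: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float).ravel()
        self.m2 = np.asarray(self.m2, dtype=float).ravel()
        if len(self.m1) != len(self.m2):
            raise ValueError("paired measurement lists must have equal length")
        if len(self.m1) < 2:
            raise ValueError("agreement statistics need at least 2 pairs")
        if not (np.all(np.isfinite(self.m1)) and np.all(np.isfinite(self.m2))):
            raise ValueError("measurements must be finite")
        if self.subject_ids is not None and len(self.subject_ids) != len(self.m1):
            raise ValueError("subject_ids must match the number of pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.m1 - self.m2


@dataclass
class BodyMetrics:
    """Height (cm), weight (kg) and the derived Mosteller body surface area."""

    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")

    @property
    def bsa_m2(self) -> float:
        """Mosteller BSA: sqrt(height_cm * weight_kg / 3600) in m^2."""
        return sqrt(self.height_cm * self.weight_kg / 3600.0)


def ejection_fraction(series: PhaseSeries) -> FunctionReport:
    """EF = (max V - min V) / max V with automatic phase detection.

    Diastole is the phase of maximal volume and systole the phase of
    minimal volume; ties resolve to the first occurrence.
    """
    if len(series) < 2:
        raise ValueError("ejection fraction needs at least 2 phases")
    v = series.volumes
    di = int(np.argmax(v))
    si = int(np.argmin(v))
    vmax, vmin = float(v[di]), float(v[si])
    return FunctionReport(
        ef=(vmax - vmin) / vmax,
        diastolic_index=di,
        systolic_index=si,
        diastolic_volume=vmax,
        systolic_volume=vmin,
        diastolic_phase_percent=float(series.phase_percents[di]),
        systolic_phase_percent=float(series.phase_percents[si]),
    )


def normalize_by_bsa(value: float, body: BodyMetrics) -> float:
    """Index a measurement to body surface area (cm^2/m^2 or cm^3/m^2)."""
    return float(value) / body.bsa_m2


def coefficient_of_variation(table: AgreementTable) -> float:
    """Within-subject two-rater coefficient of variation, in percent.

    CoV = 100 * sqrt(mean(d_i^2 / 2)) / grand mean, where d_i is the
    paired difference and the grand mean pools all 2n measurements.  This
    is the root-mean-square within-subject convention standard in
    reproducibility analyses.
    """
    d = table.differences
    grand_mean = float(np.mean(np.concatenate([table.m1, table.m2])))
    if grand_mean <= 0:
        raise ValueError("coefficient of variation requires a positive grand mean")
    return 100.0 * sqrt(float(np.mean(d**2 / 2.0))) / grand_mean


def bland_altman(table: AgreementTable) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement (bias -/+ 1.96 SD).

    SD is the sample standard deviation (n-1) of the paired differences.
    Returns (bias, lower_limit, upper_limit).
    """
    d = table.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_t_test(table: AgreementTable) -> tuple[float, float]:
    """Two-sided paired Student t-test on the paired differences.

    Returns (t, p) with df = n - 1.  When every difference is zero the
    statistic is defined as t = 0, p = 1 (perfect agreement).
    """
    d = table.differences
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.ttest_rel(table.m1, table.m2)
    return float(res.statistic), float(res.pvalue)
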