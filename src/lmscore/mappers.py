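"""Band mappers from raw clinical measurements to ordinal item points.

Each mapper is a monotone step function of its severity direction: a
lower weight-for-length Z, a deeper oximetry nadir, a higher pulmonary
pressure, a higher Penetration-Aspiration Scale (PAS) level or reflux
index, or more airway lesions can only raise (never lower) the point.
Band boundaries that the source grading schemes leave open are closed on
the milder side so that the mapping is total and gap-free.
"""

from __future__ import annotations

import math
from enum import Enum

from .errors import ValidationError

__all__ = [
    "FeesGrade",
    "map_growth_z",
    "map_collapse",
    "map_fees",
    "map_gmds",
    "map_anomalies",
    "map_echo",
    "map_o2_nadir",
    "map_sal",
    "map_pas",
    "map_reflux_index",
    "gerd_point",
]


class FeesGrade(str, Enum):
    """Outcome of the fiberoptic endoscopic evaluation of swallowing."""

    NORMAL = "normal"
    PENETRATION = "penetration"
    ASPIRATION = "aspiration"


def _finite(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: expected a number, got {value!r}") from None
    if not math.isfinite(value):
        raise ValidationError(f"{name}: value must be finite, got {value!r}")
    return value


def map_growth_z(z: float) -> int:
    """Weight-for-length Z score (WHO 0-2 y charts) -> growth-chart point.

    Normal growth is Z in [-2, +2] (0 points); moderate delay Z in
    [-3, -2) (1 point, failure to thrive); marked delay Z < -3
    (2 points).  Z above +2 maps to 0: the item measures growth
    faltering only.
    """
    z = _finite("growth z-score", z)
    if z >= -2:
        return 0
    if z >= -3:
        return 1
    return 2


def map_collapse(obscured_fraction: float) -> int:
    """Fraction of the vocal cords obscured by supraglottic collapse.

    Up to half obscured -> 0; more than half but not total -> 1
    (the "75%" band); complete obscuration -> 2.
    """
    f = _finite("collapse fraction", obscured_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"collapse fraction: {f} outside [0, 1]")
    if f <= 0.5:
        return 0
    if f < 1.0:
        return 1
    return 2


def map_fees(grade: FeesGrade | str) -> int:
    """FEES swallowing outcome: normal -> 0, penetration -> 1, aspiration -> 2."""
    try:
        grade = FeesGrade(grade.lower() if isinstance(grade, str) else grade)
    except (ValueError, AttributeError):
        raise ValidationError(f"unknown FEES grade {grade!r}") from None
    return {FeesGrade.NORMAL: 0, FeesGrade.PENETRATION: 1, FeesGrade.ASPIRATION: 2}[grade]


def map_gmds(domains_below_normal: int) -> int:
    """GMDS-III interpretation from the number of delayed domains (of 5).

    All domains in range -> 0 (normal); one below -> 1 (mild
    impairment); two or more -> 2 (global delay).
    """
    n = _int("GMDS domains below normal", domains_below_normal)
    if not 0 <= n <= 5:
        raise ValidationError(f"GMDS domains below normal: {n} outside 0-5")
    return min(n, 2)


def map_anomalies(anomaly_count: int) -> int:
    """Associated congenital anomalies: none -> 0, one -> 1, more -> 2."""
    n = _int("anomaly count", anomaly_count)
    if n < 0:
        raise ValidationError(f"anomaly count: {n} is negative")
    return min(n, 2)


def map_echo(
    cardiac_anomaly_present: bool,
    pulmonary_pressure_mmHg: float = 0.0,
    right_heart_failure: bool = False,
) -> int:
    """Echocardiography point from structural and pressure findings.

    Severe pulmonary hypertension (>= 45 mmHg) or right-sided heart
    failure scores 3; mild or moderate pulmonary hypertension
    (25-45 mmHg) scores 2; an associated cardiac anomaly without
    pulmonary hypertension scores 1; otherwise 0.
    """
    p = _finite("pulmonary pressure", pulmonary_pressure_mmHg)
    if p < 0:
        raise ValidationError(f"pulmonary pressure: {p} mmHg is negative")
    if right_heart_failure or p >= 45:
        return 3
    if p >= 25:
        return 2
    if cardiac_anomaly_present:
        return 1
    return 0


def map_o2_nadir(nadir_percent: float | None) -> int:
    """Overnight pulse-oximetry saturation nadir -> oximetry point.

    No nocturnal desaturation (no recorded nadir, or nadir >= 92%) -> 0;
    86-91% -> 1; 76-85% -> 2; <= 75% -> 3.
    """
    if nadir_percent is None:
        return 0
    n = _finite("O2 nadir", nadir_percent)
    if not 0 <= n <= 100:
        raise ValidationError(f"O2 nadir: {n}% outside [0, 100]")
    if n >= 92:
        return 0
    if n >= 86:
        return 1
    if n > 75:
        return 2
    return 3


def map_sal(sal_count: int) -> int:
    """Synchronous airway lesions: none -> 0, one -> 1, more -> 2."""
    n = _int("synchronous airway lesion count", sal_count)
    if n < 0:
        raise ValidationError(f"synchronous airway lesion count: {n} is negative")
    return min(n, 2)


def map_pas(pas: int) -> int:
    """Penetration-Aspiration Scale level (1-8) -> GERD modality point.

    PAS 1 is normal swallowing (0); PAS 2-5 laryngeal penetration (1);
    PAS 6-8 aspiration (2).
    """
    p = _int("PAS", pas)
    if not 1 <= p <= 8:
        raise ValidationError(f"PAS: {p} outside 1-8")
    if p == 1:
        return 0
    if p <= 5:
        return 1
    return 2


def map_reflux_index(ri_percent: float) -> int:
    """24-hour pH-metry reflux index (% time pH < 4) -> GERD modality point.

    RI < 3% -> 0; 3-7% -> 1; > 7% -> 2.
    """
    ri = _finite("reflux index", ri_percent)
    if ri < 0:
        raise ValidationError(f"reflux index: {ri}% is negative")
    if ri < 3:
        return 0
    if ri <= 7:
        return 1
    return 2


def gerd_point(pas: int | None = None, reflux_index: float | None = None) -> int:
    """Combined GERD point from the available modalities.

    The modified barium swallow contributes via PAS and 24-hour
    pH-metry via the reflux index; when both were performed the
    worse (maximum) point is kept, since pH-metry is invoked to
    escalate refractory cases.  At least one modality is required.
    """
    if pas is None and reflux_index is None:
        raise ValidationError("GERD point: neither PAS nor reflux index provided")
    points = []
    if pas is not None:
        points.append(map_pas(pas))
    if reflux_index is not None:
        points.append(map_reflux_index(reflux_index))
    return max(points)


def _int(name: str, value: object) -> int:
    try:
        i = int(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: expected an integer, got {value!r}") from None
    if isinstance(value, float) and value != i:
        raise ValidationError(f"{name}: expected an integer, got {value!r}")
    return i


#: mapper registry used by the CLI (`lmscore map --item o2_nadir --value 88`)
#: and by the cohort reader when raw columns are supplied.
RAW_MAPPERS = {
    "growth_z": map_growth_z,
    "collapse_fraction": map_collapse,
    "fees": map_fees,
    "gmds_domains_below_normal": map_gmds,
    "anomaly_count": map_anomalies,
    "o2_nadir": map_o2_nadir,
    "sal_count": map_sal,
    "pas": map_pas,
    "reflux_index": map_reflux_index,
}
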