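"""Instrument-level derived quantities for the vestibular test battery.

Implements the standard asymmetry formulas used in clinical
vestibulometry:

* canal paresis (CP%) and directional preponderance (DP%) from the
  bithermal caloric test, after Jongkees — relative asymmetry of the
  summed maximum slow-phase velocities per ear and per nystagmus
  direction respectively;
* the interaural amplitude asymmetry ratio (IAAR) of cervical/ocular
  vestibular-evoked myogenic potentials (VEMP);
* the video head-impulse-test (vHIT) VOR-gain asymmetry ratio;

plus binary abnormality flags at the conventional clinical cut-offs and
structural validation of the DHI, HADS and NPQ questionnaire scores.

Missing values are first-class: any field of a patient record may be
absent (``None`` or NaN), and derived flags propagate missingness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Optional

__all__ = [
    "CaloricRaw",
    "VempRaw",
    "VhitRaw",
    "AbnormalityFlags",
    "AbnormalityThresholds",
    "UndefinedInputError",
    "ScoreValidationError",
    "jongkees_cp",
    "directional_preponderance",
    "vemp_iaar",
    "vhit_asymmetry",
    "flag_abnormalities",
    "validate_scores",
    "is_missing",
]


class UndefinedInputError(ValueError):
    """An asymmetry ratio was requested for an all-zero response set."""


class ScoreValidationError(ValueError):
    """A questionnaire score violates its range or additivity structure."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def is_missing(value: Any) -> bool:
    """True for ``None`` or a float NaN (the two missing encodings used)."""
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class CaloricRaw:
    """Maximum slow-phase velocities (deg/s) of the four caloric irrigations."""

    right_warm: float
    right_cool: float
    left_warm: float
    left_cool: float

    def __post_init__(self) -> None:
        for name in ("right_warm", "right_cool", "left_warm", "left_cool"):
            v = getattr(self, name)
            if is_missing(v) or v < 0:
                raise ValueError(f"caloric response {name} must be >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.right_warm + self.right_cool + self.left_warm + self.left_cool


@dataclass(frozen=True)
class VempRaw:
    """Normalized peak-to-peak VEMP amplitudes (p13-n23 or n10-p15) per side."""

    amp_right: float
    amp_left: float

    def __post_init__(self) -> None:
        if self.amp_right < 0 or self.amp_left < 0:
            raise ValueError("VEMP amplitudes must be non-negative")


@dataclass(frozen=True)
class VhitRaw:
    """vHIT lateral-canal VOR gains at 60 ms and catch-up-saccade presence."""

    gain_right: float
    gain_left: float
    cus_present: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gain_right < 0 or self.gain_left < 0:
            raise ValueError("vHIT gains must be non-negative")


@dataclass(frozen=True)
class AbnormalityThresholds:
    """Clinical cut-offs for the binary abnormality flags.

    Comparisons are strict: a value exactly at the cut-off is normal.
    ``vhit_gain`` is the exception in direction — a worse-side gain
    strictly below it is flagged.
    """

    cp_percent: float = 20.0
    vemp_iaar: float = 33.3
    vor_dp_percent: float = 12.0
    vhit_gain: float = 0.6


@dataclass(frozen=True)
class AbnormalityFlags:
    """Per-test abnormality flags; ``None`` where the input was missing."""

    cp_abnormal: Optional[bool]
    cvemp_abnormal: Optional[bool]
    ovemp_abnormal: Optional[bool]
    vordp_abnormal: Optional[bool]
    vhit_low_gain: Optional[bool]


def jongkees_cp(raw: CaloricRaw) -> tuple[float, str]:
    """Canal paresis percentage and the weaker ear, after Jongkees.

    CP% = |(Rw + Rc) - (Lw + Lc)| / (Rw + Rc + Lw + Lc) x 100.

    Returns
    -------
    (cp_percent, weaker_side)
        ``cp_percent`` in [0, 100]; ``weaker_side`` is ``"left"`` or
        ``"right"`` (the ear with the smaller summed response), or
        ``"none"`` on an exact tie.

    Raises
    ------
    UndefinedInputError
        If all four responses are zero.
    """
    right = raw.right_warm + raw.right_cool
    left = raw.left_warm + raw.left_cool
    total = right + left
    if total == 0:
        raise UndefinedInputError("all four caloric responses are zero; CP% undefined")
    cp = abs(right - left) / total * 100.0
    if right < left:
        side = "right"
    elif left < right:
        side = "left"
    else:
        side = "none"
    return cp, side


def directional_preponderance(raw: CaloricRaw) -> float:
    """Directional preponderance percentage of caloric nystagmus.

    Right-beating responses (right warm + left cool) versus left-beating
    responses (left warm + right cool):

    DP% = |(Rw + Lc) - (Lw + Rc)| / (Rw + Rc + Lw + Lc) x 100.
    """
    total = raw.total
    if total == 0:
        raise UndefinedInputError("all four caloric responses are zero; DP% undefined")
    right_beating = raw.right_warm + raw.left_cool
    left_beating = raw.left_warm + raw.right_cool
    return abs(right_beating - left_beating) / total * 100.0


def vemp_iaar(raw: VempRaw) -> float:
    """Signed VEMP interaural amplitude asymmetry ratio.

    IAAR = (Ar - Al) / (Ar + Al) x 100; positive means the right-side
    amplitude is larger. |IAAR| > 33.3 is the conventional abnormality
    criterion (see :func:`flag_abnormalities`).
    """
    denom = raw.amp_right + raw.amp_left
    if denom == 0:
        raise UndefinedInputError("both VEMP amplitudes are zero; IAAR undefined")
    return (raw.amp_right - raw.amp_left) / denom * 100.0


def vhit_asymmetry(raw: VhitRaw) -> tuple[float, float, float]:
    """vHIT VOR-gain asymmetry ratio with better/worse-side gains.

    AR = |(RL - LL) / (RL + LL)| x 100.

    Returns ``(ar_percent, gain_better, gain_worse)``.
    """
    denom = raw.gain_right + raw.gain_left
    if denom == 0:
        raise UndefinedInputError("both vHIT gains are zero; AR undefined")
    ar = abs(raw.gain_right - raw.gain_left) / denom * 100.0
    return ar, max(raw.gain_right, raw.gain_left), min(raw.gain_right, raw.gain_left)


def _flag_greater(value: Any, cutoff: float, absolute: bool = False) -> Optional[bool]:
    if is_missing(value):
        return None
    v = abs(float(value)) if absolute else float(value)
    return v > cutoff


def flag_abnormalities(
    record: Mapping[str, Any],
    thresholds: AbnormalityThresholds = AbnormalityThresholds(),
) -> AbnormalityFlags:
    """Binary abnormality flags for one patient record.

    ``record`` is any mapping with (possibly missing) keys ``CP_percent``,
    ``cvemp_iaar``, ``ovemp_iaar``, ``vor_dp_percent`` and
    ``vhit_gain_worse``. All comparisons are strict; missing inputs yield
    ``None`` flags rather than errors.
    """
    worse = record.get("vhit_gain_worse")
    return AbnormalityFlags(
        cp_abnormal=_flag_greater(record.get("CP_percent"), thresholds.cp_percent),
        cvemp_abnormal=_flag_greater(record.get("cvemp_iaar"), thresholds.vemp_iaar, absolute=True),
        ovemp_abnormal=_flag_greater(record.get("ovemp_iaar"), thresholds.vemp_iaar, absolute=True),
        vordp_abnormal=_flag_greater(
            record.get("vor_dp_percent"), thresholds.vor_dp_percent, absolute=True
        ),
        vhit_low_gain=None if is_missing(worse) else float(worse) < thresholds.vhit_gain,
    )


# (field, low, high, must_be_integer, must_be_even)
_SCORE_RANGES: list[tuple[str, float, float, bool, bool]] = [
    ("age", 0, 130, True, False),
    ("HADS_anxiety", 0, 21, True, False),
    ("HADS_depression", 0, 21, True, False),
    ("HADS_total", 0, 42, True, False),
    ("DHI_physical", 0, 28, True, True),
    ("DHI_emotional", 0, 36, True, True),
    ("DHI_functional", 0, 36, True, True),
    ("DHI_total", 0, 100, True, True),
    ("NPQ_upright", 0, 24, True, False),
    ("NPQ_movement", 0, 24, True, False),
    ("NPQ_visual", 0, 24, True, False),
    ("NPQ_total", 0, 72, True, False),
    ("CP_percent", 0, 100, False, False),
    ("DP_percent", 0, 100, False, False),
    ("cvemp_iaar", -100, 100, False, False),
    ("ovemp_iaar", -100, 100, False, False),
    ("vor_dp_percent", -100, 100, False, False),
    ("vhit_ar", 0, 100, False, False),
]

# total = sum of its components (whenever all are present)
_ADDITIVE_BLOCKS: dict[str, tuple[str, ...]] = {
    "HADS_total": ("HADS_anxiety", "HADS_depression"),
    "DHI_total": ("DHI_physical", "DHI_emotional", "DHI_functional"),
    "NPQ_total": ("NPQ_upright", "NPQ_movement", "NPQ_visual"),
}

_POSITIVE_FIELDS = ("foam_ratio", "romberg_ratio_foam")


def validate_scores(record: Mapping[str, Any]) -> Mapping[str, Any]:
    """Check ranges, integrality and subscale/total additivity of a record.

    The DHI is the standard 25-item instrument (items scored 0/2/4;
    physical max 28, emotional/functional max 36 each, total 0-100); the
    HADS subscales range 0-21; the three NPQ factors range 0-24 (total
    0-72). Missing fields are skipped. Returns the record unchanged on
    success.

    Raises
    ------
    ScoreValidationError
        Naming the offending field, on any range or additivity violation.
    """
    for field, lo, hi, integer, even in _SCORE_RANGES:
        v = record.get(field)
        if is_missing(v):
            continue
        x = float(v)
        if not (lo <= x <= hi):
            raise ScoreValidationError(field, f"value {x} outside [{lo}, {hi}]")
        if integer and x != int(x):
            raise ScoreValidationError(field, f"value {x} is not an integer")
        if even and int(x) % 2 != 0:
            raise ScoreValidationError(field, f"value {x} is not an even integer")
    for field in _POSITIVE_FIELDS:
        v = record.get(field)
        if not is_missing(v) and float(v) <= 0:
            raise ScoreValidationError(field, f"value {v} is not > 0")
    for total, parts in _ADDITIVE_BLOCKS.items():
        values = [record.get(p) for p in parts] + [record.get(total)]
        if any(is_missing(v) for v in values):
            continue
        expected = sum(float(v) for v in values[:-1])
        if float(values[-1]) != expected:
            raise ScoreValidationError(
                total, f"total {values[-1]} != sum of components {expected}"
            )
    return record
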