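"""Mechanostat-based remodeling prediction and threshold calibration.

Mechanical stimulus is strain energy density divided by bone density
(J/kg).  A stimulus above the upper threshold predicts apposition, below
the lower threshold resorption, and the interval between them (the lazy
zone, thresholds inclusive) predicts no activity.  The upper threshold is
calibrated against observed zone labels by exhaustive grid search; the
lower threshold is the first quartile of stimuli in resorption-labelled
zones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import EmptyZoneError, InsufficientDataError, InvalidParameterError
from .meshing import Region

__all__ = [
    "RemodelingClass",
    "ThresholdPair",
    "ZoneSummary",
    "CalibrationResult",
    "mechanical_stimulus",
    "classify_stimulus",
    "zone_median_stimulus",
    "predict_zone_remodeling",
    "lower_threshold_from_iqr",
    "calibrate_upper_threshold",
    "classification_accuracy",
    "cortical_overload",
    "weighted_median",
]


class RemodelingClass(enum.Enum):
    RESORPTION = "resorption"
    NO_ACTIVITY = "no_activity"
    APPOSITION = "apposition"


@dataclass(frozen=True)
class ThresholdPair:
    """Mechanostat lower/upper stimulus thresholds in J/kg (defaults 2, 12)."""

    low: float = 2.0
    high: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low < self.high:
            raise InvalidParameterError("thresholds must satisfy 0 <= low < high")


@dataclass(frozen=True)
class ZoneSummary:
    zone_id: int
    median_stimulus: float  # J/kg
    predicted: RemodelingClass

    def __post_init__(self) -> None:
        if self.median_stimulus < 0.0:
            raise InvalidParameterError("median stimulus must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    t_high_star: float
    accuracy: float
    plateau: tuple[float, float]
    grid_step: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise InvalidParameterError("accuracy must lie in [0, 1]")
        lo, hi = self.plateau
        if not lo <= self.t_high_star <= hi:
            raise InvalidParameterError("plateau must contain t_high_star")


def mechanical_stimulus(sed_mpa, density: float):
    """Convert SED (MPa = 1e6 J/m^3) to stimulus in J/kg: S = sed * 1e6 / rho."""
    if density <= 0.0:
        raise InvalidParameterError("density must be > 0")
    sed_arr = np.asarray(sed_mpa, dtype=float)
    if np.any(sed_arr < 0.0):
        raise InvalidParameterError("SED must be >= 0")
    out = sed_arr * 1.0e6 / density
    return float(out) if np.isscalar(sed_mpa) else out


def classify_stimulus(stimulus: float, thresholds: ThresholdPair) -> RemodelingClass:
    """Three-way mechanostat rule; the thresholds belong to the lazy zone."""
    if stimulus < 0.0:
        raise InvalidParameterError("stimulus must be >= 0")
    if stimulus > thresholds.high:
        return RemodelingClass.APPOSITION
    if stimulus < thresholds.low:
        return RemodelingClass.RESORPTION
    return RemodelingClass.NO_ACTIVITY


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight exceeds half the total.

    With equal weights and odd n this is the classic sample median; ties at
    exactly half resolve upward.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("weighted median of an empty set")
    if np.any(w < 0.0):
        raise InvalidParameterError("weights must be >= 0")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half, side="right"))
    idx = min(idx, len(v) - 1)
    return float(v[idx])


def zone_median_stimulus(
    stimuli: np.ndarray,
    areas: np.ndarray,
    zone_ids: np.ndarray,
    *,
    weighted: bool = True,
) -> dict[int, float]:
    """Per-zone (area-weighted) median stimulus for zones 1..7.

    ``zone_ids`` assigns each element a zone in 1..7 (0 or negative =
    unzoned, ignored).  Raises EmptyZoneError if any zone has no element.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    areas = np.asarray(areas, dtype=float)
    zone_ids = np.asarray(zone_ids)
    medians: dict[int, float] = {}
    for zid in range(1, 8):
        mask = zone_ids == zid
        if not mask.any():
            raise EmptyZoneError(f"zone {zid} contains no interface-band elements")
        if weighted:
            medians[zid] = weighted_median(stimuli[mask], areas[mask])
        else:
            medians[zid] = float(np.median(stimuli[mask]))
    return medians


def predict_zone_remodeling(
    medians: dict[int, float], thresholds: ThresholdPair
) -> list[ZoneSummary]:
    return [
        ZoneSummary(zone_id=zid, median_stimulus=med, predicted=classify_stimulus(med, thresholds))
        for zid, med in sorted(medians.items())
    ]


def lower_threshold_from_iqr(resorption_zone_stimuli) -> float:
    """First quartile (sorted-order linear interpolation) of the stimuli
    observed in resorption-labelled zones.

    Q1 is interpolated at 1-based position 1 + 0.25 (n - 1).
    """
    x = np.sort(np.asarray(resorption_zone_stimuli, dtype=float))
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 stimuli for a quartile, got {n}")
    pos = 0.25 * (n - 1)  # 0-based
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo + 1 < n:
        return float(x[lo] * (1.0 - frac) + x[lo + 1] * frac)
    return float(x[lo])


def classification_accuracy(predicted, observed) -> float:
    """Fraction of zones where prediction matches observation."""
    pred = list(predicted)
    obs = list(observed)
    if len(pred) != len(obs):
        raise InvalidParameterError("predicted and observed lengths differ")
    if not pred:
        raise InsufficientDataError("empty label vectors")
    return sum(p == o for p, o in zip(pred, obs)) / len(pred)


def calibrate_upper_threshold(
    zone_medians,
    observed,
    t_low: float = 2.0,
    grid: tuple[float, float, float] = (3.0, 25.0, 0.25),
) -> CalibrationResult:
    """Exhaustive grid search for the apposition threshold.

    Every grid value t is scored by the accuracy of ``classify_stimulus``
    with thresholds (t_low, t) against the observed labels.  The result is
    the midpoint of the longest contiguous run of accuracy-maximising grid
    values (lowest such run on ties).
    """
    lo, hi, step = grid
    if step <= 0.0 or hi < lo:
        raise InvalidParameterError("grid must satisfy lo <= hi and step > 0")
    if lo <= t_low:
        raise InvalidParameterError("grid.lo must exceed t_low")
    medians = np.asarray(list(zone_medians), dtype=float)
    obs = list(observed)
    if len(medians) != len(obs):
        raise InvalidParameterError("zone_medians and observed lengths differ")
    if len(medians) == 0:
        raise InsufficientDataError("no zones to calibrate on")

    n_pts = int(np.floor((hi - lo) / step + 1e-9)) + 1
    ts = lo + step * np.arange(n_pts)
    accs = np.empty(n_pts)
    for i, t in enumerate(ts):
        thr = ThresholdPair(low=t_low, high=float(t))
        pred = [classify_stimulus(m, thr) for m in medians]
        accs[i] = classification_accuracy(pred, obs)

    best = accs.max()
    is_best = np.isclose(accs, best, rtol=0.0, atol=1e-12)
    # longest contiguous run of maximisers; lowest run on ties
    runs = []
    start = None
    for i, flag in enumerate(is_best):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n_pts - 1))
    run = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    plateau = (float(ts[run[0]]), float(ts[run[1]]))
    return CalibrationResult(
        t_high_star=0.5 * (plateau[0] + plateau[1]),
        accuracy=float(best),
        plateau=plateau,
        grid_step=float(step),
    )


def cortical_overload(
    stimuli: np.ndarray,
    areas: np.ndarray,
    region: np.ndarray,
    band_mask: np.ndarray,
    t_high: float,
) -> tuple[float, float]:
    """(overloaded area fraction, max stimulus) over cortical band elements.

    The fraction is the share of cortical interface-band area whose stimulus
    exceeds ``t_high``; both are 0 when no cortical element is in the band.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    areas = np.asarray(areas, dtype=float)
    mask = band_mask & (region == Region.CORTICAL)
    if not mask.any():
        return 0.0, 0.0
    a = areas[mask]
    s = stimuli[mask]
    frac = float(a[s > t_high].sum() / a.sum())
    return frac, float(s.max())
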