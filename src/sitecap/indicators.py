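"""Capacity, utilization, productivity and cascade indicators.

The capacity model: each VMMC procedure takes 30 minutes, so one station
(a provider for *current* capacity, a surgical bed for *optimum* capacity)
handles 15 procedures per 450-minute operating day.

* current daily capacity  = providers x 15 (x task factors)
* optimum daily capacity  = beds x 15
* utilization rate U      = performed / current capacity
  (<1 under-used, =1 balanced, >1 over-used, at two-decimal display)
* productivity P          = performed - optimum capacity
  (negative = unrealized output given the beds available)

Undefined ratios (zero denominators) are flagged absent values — ``None``
with an ``undefined`` classification — never 0 or infinity, so a closed
site can't look perfectly efficient or infinitely over-used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Optional, Tuple

from sitecap.data_model import CapacityParams, MonthlyRecord

_DEFAULT_PARAMS = CapacityParams()


def round_half_up(x: Optional[float], ndigits: int = 2) -> Optional[float]:
    """Display rounding: half-up to ``ndigits`` decimals (10/15 -> 0.67)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Utilization:
    """A utilization rate with display rounding and classification.

    ``value`` is full precision; ``display`` is half-up at two decimals;
    ``classification`` is judged at display precision so the printed
    number and the label never disagree.
    """

    value: Optional[float]
    display: Optional[float]
    classification: str  # under-used | balanced | over-used | undefined

    @property
    def defined(self) -> bool:
        return self.value is not None


def current_capacity_daily(
    providers: int,
    params: Optional[CapacityParams] = None,
    task_shifting: bool = False,
    task_sharing: bool = False,
) -> int:
    """VMMCs a site can perform per day with its present providers.

    providers x slots-per-station (default 15), scaled by the task-shifting
    and/or task-sharing factor where the site operates under those
    arrangements (default factors of 1.0 reproduce the plain providers x 15
    spreadsheet formula).  Rounded down to whole procedures.
    """
    if providers < 0:
        raise ValueError("providers must be >= 0")
    p = params or _DEFAULT_PARAMS
    cap = providers * p.slots_per_station_per_day
    if task_shifting:
        cap *= p.task_shifting_factor
    if task_sharing:
        cap *= p.task_sharing_factor
    return math.floor(cap)


def optimum_capacity_daily(beds: int,
                           params: Optional[CapacityParams] = None) -> int:
    """VMMCs per day were staffing matched to the surgical beds: beds x 15."""
    if beds < 0:
        raise ValueError("beds must be >= 0")
    p = params or _DEFAULT_PARAMS
    return beds * p.slots_per_station_per_day


def capacity_over_period(daily_capacity: int, days_of_operation: int) -> int:
    """Scale a daily capacity to a period using reported days of operation."""
    if days_of_operation < 0:
        raise ValueError("days_of_operation must be >= 0")
    return daily_capacity * days_of_operation


def utilization_rate(performed: Optional[int],
                     current_capacity: Optional[int]) -> Utilization:
    """Ratio of VMMCs performed to current capacity, with classification."""
    if performed is None or current_capacity is None or current_capacity == 0:
        return Utilization(None, None, "undefined")
    value = performed / current_capacity
    display = round_half_up(value, 2)
    if display < 1:
        cls = "under-used"
    elif display > 1:
        cls = "over-used"
    else:
        cls = "balanced"
    return Utilization(value, display, cls)


def productivity(performed: Optional[int],
                 optimum_capacity: int) -> Optional[int]:
    """Performed minus optimum capacity; negative = productivity loss."""
    if performed is None:
        return None
    return performed - optimum_capacity


def avg_daily_vmmcs(performed: Optional[int],
                    days_of_operation: int) -> Optional[float]:
    """Average VMMCs per operating day; None when the site never opened."""
    if performed is None or days_of_operation == 0:
        return None
    return performed / days_of_operation


def target_achievement(performed: Optional[int],
                       target: int) -> Optional[float]:
    """Performed over target; None (undefined) when no target was set."""
    if performed is None or target == 0:
        return None
    return performed / target


def staffing_gap(beds: int, staff_counts: Dict[str, int],
                 params: Optional[CapacityParams] = None) -> Dict[str, float]:
    """Per-role shortfall against the normative per-bed staffing template.

    shortfall(role) = max(0, beds x template_ratio - current_count).
    Zero beds implies zero normative need, hence zero shortfall.
    """
    p = params or _DEFAULT_PARAMS
    gaps: Dict[str, float] = {}
    for role, ratio in p.staffing_template.items():
        need = beds * ratio
        have = staff_counts.get(role, 0)
        gap = max(0.0, need - have)
        gaps[role] = int(gap) if float(gap).is_integer() else gap
    return gaps


def additional_staff_needed(
    record: MonthlyRecord,
    params: Optional[CapacityParams] = None,
) -> Dict[str, float]:
    """Additional staff needed for the site to operate at optimum capacity."""
    counts = {
        "providers": record.providers,
        "trained_assistants": record.trained_assistants,
        "other_nurses": record.other_nurses,
        "counselors": record.counselors,
        "mobilizers": record.mobilizers,
    }
    return staffing_gap(record.beds, counts, params)


@dataclass(frozen=True)
class Cascade:
    """The VMMC cascade: reached -> seeking -> performed.

    Conversion ratios may exceed 1 — people routinely seek services without
    having been reached by demand creation.
    """

    reached: Optional[int]
    seeking: Optional[int]
    performed: Optional[int]
    seeking_per_reached: Optional[float]
    performed_per_seeking: Optional[float]


def _ratio(num: Optional[int], den: Optional[int]) -> Optional[float]:
    if num is None or den is None or den == 0:
        return None
    return num / den


def _opt_sum(values: Iterable[Optional[int]]) -> Optional[int]:
    vals = [v for v in values if v is not None]
    return sum(vals) if vals else None


def cascade(records: Iterable[MonthlyRecord]) -> Cascade:
    """Cascade totals (summed over age bands and records) plus conversions."""
    recs = list(records)
    reached = _opt_sum(r.reached for r in recs)
    seeking = _opt_sum(r.seeking for r in recs)
    performed = _opt_sum(r.performed for r in recs)
    return Cascade(reached, seeking, performed,
                   _ratio(seeking, reached), _ratio(performed, seeking))


@dataclass(frozen=True)
class IndicatorSet:
    """All derived indicators for one site (or aggregate) over one period."""

    performed: Optional[int]
    current_capacity: int
    optimum_capacity: int
    utilization: Utilization
    productivity: Optional[int]
    avg_daily_vmmcs: Optional[float]
    target_achievement: Optional[float]
    staffing_gap: Dict[str, float] = field(default_factory=dict)
    cascade: Optional[Cascade] = None
    followup_rate_48h: Optional[float] = None
    followup_rate_7d: Optional[float] = None
    followup_rate_6w: Optional[float] = None
    ae_rate_mild: Optional[float] = None
    ae_rate_moderate: Optional[float] = None
    ae_rate_severe: Optional[float] = None
    hiv_test_uptake: Optional[float] = None


def compute_indicator_set(
    performed: Optional[int],
    current_capacity: int,
    optimum_capacity: int,
    days_of_operation: int,
    target: int,
    staffing_gaps: Optional[Dict[str, float]] = None,
    cascade_counts: Optional[Tuple[Optional[int], Optional[int]]] = None,
    followups: Tuple[Optional[int], Optional[int], Optional[int]] = (None,) * 3,
    adverse_events: Tuple[Optional[int], Optional[int], Optional[int]] = (None,) * 3,
    hiv_tests: Optional[int] = None,
) -> IndicatorSet:
    """Assemble an :class:`IndicatorSet` from aggregated inputs.

    All ratio indicators are computed here from the aggregated numerators
    and denominators — never averaged across members of an aggregate.
    """
    reached, seeking = cascade_counts if cascade_counts else (None, None)
    casc = Cascade(reached, seeking, performed,
                   _ratio(seeking, reached), _ratio(performed, seeking))
    f48, f7d, f6w = followups
    mild, moderate, severe = adverse_events
    return IndicatorSet(
        performed=performed,
        current_capacity=current_capacity,
        optimum_capacity=optimum_capacity,
        utilization=utilization_rate(performed, current_capacity),
        productivity=productivity(performed, optimum_capacity),
        avg_daily_vmmcs=avg_daily_vmmcs(performed, days_of_operation),
        target_achievement=target_achievement(performed, target),
        staffing_gap=staffing_gaps or {},
        cascade=casc,
        followup_rate_48h=_ratio(f48, performed),
        followup_rate_7d=_ratio(f7d, performed),
        followup_rate_6w=_ratio(f6w, performed),
        ae_rate_mild=_ratio(mild, performed),
        ae_rate_moderate=_ratio(moderate, performed),
        ae_rate_severe=_ratio(severe, performed),
        hiv_test_uptake=_ratio(hiv_tests, performed),
    )
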