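"""Published reference values for the studied tertiary-hospital case.

The underlying daily visit data of the case hospital are not public, but
its reported composite-index table and monthly emergency belief values
are, and they anchor the package's worked examples and checks:

* :data:`REFERENCE_INDICATORS` — the eight service-quality indicators with
  their national comparison values and published comprehensive indices;
* :func:`reference_payoff_index` — the published aggregate payoffs
  ``H = 1.55`` and ``L = -0.72`` (note: the published H-column entries
  actually sum to 1.56; the published aggregate rounds to 1.55, and both
  are exposed);
* :data:`EMERGENCY_MONTHLY_MEAN_P` — the reported monthly mean emergency
  beliefs, whose annual average is about 0.897.
"""

from __future__ import annotations

import pandas as pd

from .payoff import IndicatorRecord, PayoffIndex, aggregate_payoffs

__all__ = [
    "REFERENCE_INDICATORS",
    "PUBLISHED_GAIN",
    "PUBLISHED_LOSS",
    "EMERGENCY_MONTHLY_MEAN_P",
    "reference_payoff_index",
    "reference_indicator_frame",
    "reference_metadata",
]

REFERENCE_INDICATORS: tuple[IndicatorRecord, ...] = (
    IndicatorRecord("Number of beds", "H", 1002, 1200, comprehensive_index=1.98),
    IndicatorRecord("Bed utilization rate", "H", 81.50, 64.63, comprehensive_index=2.07),
    IndicatorRecord(
        "Average number of consultations per day", "H", 6.3, 5.47,
        comprehensive_index=1.32,
    ),
    IndicatorRecord("Inpatient number per day", "H", 2.1, 2.9, comprehensive_index=-3.81),
    IndicatorRecord(
        "Total number of consultations", "L", 600801, 499438, comprehensive_index=1.69
    ),
    IndicatorRecord(
        "Number of hospital admissions", "L", 31285, 38775, comprehensive_index=-2.39
    ),
    IndicatorRecord(
        "Average disposable income", "L", 32189, 30949, comprehensive_index=-0.39
    ),
    IndicatorRecord(
        "Average hospitalization days of discharged patients", "L", 8.6, 8.28,
        comprehensive_index=0.37,
    ),
)

#: Published aggregate payoffs of the reference table.  The H-category
#: comprehensive indices sum to 1.56; the published aggregate is 1.55.
PUBLISHED_GAIN = 1.55
PUBLISHED_LOSS = -0.72

#: Reported monthly mean emergency belief values, January..December.
EMERGENCY_MONTHLY_MEAN_P = pd.Series(
    [0.968, 1.0, 0.994, 0.993, 0.9613, 0.82, 0.813, 0.806, 0.9, 0.845, 0.827, 0.845],
    index=pd.period_range("2020-01", periods=12, freq="M"),
    name="p",
)


def reference_payoff_index(published: bool = True) -> PayoffIndex:
    """The reference payoff pair.

    With ``published=True`` (default) returns the published aggregate
    (1.55, -0.72); otherwise re-sums the packaged comprehensive indices,
    which yields (1.56, -0.72).
    """
    if published:
        return PayoffIndex(gain=PUBLISHED_GAIN, loss=PUBLISHED_LOSS)
    return aggregate_payoffs(REFERENCE_INDICATORS)


def reference_indicator_frame() -> pd.DataFrame:
    """The reference indicator table as a DataFrame."""
    return pd.DataFrame(
        {
            "category": [r.category for r in REFERENCE_INDICATORS],
            "name": [r.name for r in REFERENCE_INDICATORS],
            "national": [r.national_value for r in REFERENCE_INDICATORS],
            "instance": [r.instance_value for r in REFERENCE_INDICATORS],
            "standard_value": [r.standard_value for r in REFERENCE_INDICATORS],
            "comprehensive_index": [r.comprehensive_index for r in REFERENCE_INDICATORS],
        }
    )


def reference_metadata() -> dict:
    """Provenance notes surfaced in report bundles."""
    raw = aggregate_payoffs(REFERENCE_INDICATORS)
    return {
        "published_gain": PUBLISHED_GAIN,
        "published_loss": PUBLISHED_LOSS,
        "column_sum_gain": round(raw.gain, 10),
        "column_sum_loss": round(raw.loss, 10),
        "note": (
            "published aggregate H (1.55) differs from the H-column sum (1.56); "
            "published values are used for expected-payoff results"
        ),
    }
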