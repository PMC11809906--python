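"""Calendar helpers shared across modules.

Months are ``pandas.Period`` objects with monthly frequency; nights are
``pandas.Timestamp`` dates. The simulator additionally uses integer day/month
indices relative to a start month, converted here.
"""

from __future__ import annotations

import pandas as pd

MONTH = "M"


def as_month(value) -> pd.Period:
    """Coerce a date, string, or Period to a monthly Period."""
    if isinstance(value, pd.Period):
        return value.asfreq(MONTH)
    return pd.Period(value, MONTH)


def month_index(month, start) -> int:
    """Integer offset of *month* from *start* (both coercible to Period)."""
    return (as_month(month) - as_month(start)).n


def index_to_month(idx: int, start) -> pd.Period:
    return as_month(start) + int(idx)


def day_to_date(day: int, start) -> pd.Timestamp:
    """Date of integer day index *day*, where day 0 is the first day of *start*."""
    return as_month(start).start_time + pd.Timedelta(days=int(day))


def date_to_day(date, start) -> int:
    return (pd.Timestamp(date).normalize() - as_month(start).start_time).days


def month_index_of_day(day: int, start) -> int:
    return month_index(pd.Period(day_to_date(day, start), MONTH), start)


def month_start_day(idx: int, start) -> int:
    """Day index of the first day of month *idx*."""
    return date_to_day(index_to_month(idx, start).start_time, start)
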