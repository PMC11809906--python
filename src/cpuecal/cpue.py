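"""Monthly effort-corrected capture-per-unit-effort (CPUE).

Visual CPUE is snakes per km walked; trap CPUE is snakes per corrected
trap-night. Monthly values are ratios of monthly totals (cumulative captures
over cumulative effort within the calendar month), which equals the
effort-weighted mean of nightly CPUEs. An unweighted mean of nightly CPUEs is
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import pandas as pd

METHODS = ("visual", "trap")

_EFFORT_COL = {"visual": "km", "trap": "trap_nights_corrected"}
_CPUE_COL = {"visual": "cpue_visual", "trap": "cpue_trap"}
_N_COL = {"visual": "n_capture_visual", "trap": "n_capture_trap"}
_EFFORT_OUT = {"visual": "km_surveyed", "trap": "trap_nights_corrected"}


def _month_of(dates) -> pd.PeriodIndex:
    return pd.PeriodIndex(pd.to_datetime(dates), freq="M")


def corrected_trap_nights(effort: pd.DataFrame, correction_policy=None) -> float:
    """Total corrected trap-nights across trap effort records.

    Default policy: use the ``trap_nights_corrected`` column when present,
    otherwise deployed minus ``trap_nights_inoperable``. A callable policy
    receives the trap effort frame and returns per-row corrected counts.
    Corrected counts must stay within [0, deployed].
    """
    trap = effort[effort["method"] == "trap"] if "method" in effort.columns else effort
    if correction_policy is not None:
        corrected = pd.Series(correction_policy(trap), index=trap.index, dtype=float)
    elif "trap_nights_corrected" in trap.columns and trap["trap_nights_corrected"].notna().all():
        corrected = trap["trap_nights_corrected"].astype(float)
    elif "trap_nights_inoperable" in trap.columns:
        corrected = trap["trap_nights_deployed"].astype(float) - trap[
            "trap_nights_inoperable"
        ].fillna(0).astype(float)
    else:
        corrected = trap["trap_nights_deployed"].astype(float)
    deployed = trap["trap_nights_deployed"].astype(float)
    if ((corrected < 0) | (corrected > deployed)).any():
        raise ValueError("corrected trap-nights must lie in [0, deployed] for every record")
    return float(corrected.sum())


def monthly_cpue(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    method: str,
    aggregate: str = "ratio-of-totals",
) -> pd.DataFrame:
    """Monthly CPUE for one method: month, captures, effort, cpue.

    A month with recorded captures but zero (or missing) effort is a
    bookkeeping inconsistency and raises. Months with effort but no captures
    get CPUE 0; months with zero recorded effort are dropped.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if aggregate not in ("ratio-of-totals", "mean-of-nights"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    eff_col = _EFFORT_COL[method]
    eff = effort[effort["method"] == method].copy()
    caps = captures[captures["method"] == method].copy()
    if eff.empty:
        if not caps.empty:
            raise ValueError(f"{method} captures recorded but no {method} effort at all")
        return pd.DataFrame(
            columns=["month", _N_COL[method], _EFFORT_OUT[method], _CPUE_COL[method]]
        )
    eff["month"] = _month_of(eff["date"])
    eff_by_month = eff.groupby("month")[eff_col].sum()
    if caps.empty:
        cap_by_month = pd.Series(0, index=eff_by_month.index, dtype=int)
    else:
        caps["month"] = _month_of(caps["date"])
        cap_by_month = caps.groupby("month").size()
    orphan = cap_by_month.index.difference(eff_by_month.index)
    if len(orphan):
        raise ValueError(
            f"{method} captures in months with no recorded effort: {[str(m) for m in orphan]}"
        )
    out = pd.DataFrame(
        {
            "month": eff_by_month.index,
            _N_COL[method]: cap_by_month.reindex(eff_by_month.index, fill_value=0).to_numpy(),
            _EFFORT_OUT[method]: eff_by_month.to_numpy(),
        }
    )
    zero_eff = out[_EFFORT_OUT[method]] <= 0
    if (zero_eff & (out[_N_COL[method]] > 0)).any():
        bad = out.loc[zero_eff & (out[_N_COL[method]] > 0), "month"].astype(str).tolist()
        raise ValueError(f"{method} captures recorded in months with zero effort: {bad}")
    out = out[~zero_eff].reset_index(drop=True)
    if aggregate == "ratio-of-totals":
        out[_CPUE_COL[method]] = out[_N_COL[method]] / out[_EFFORT_OUT[method]]
    else:
        # unweighted mean of nightly CPUEs (sensitivity analysis)
        nightly_eff = eff.groupby(["month", "date"])[eff_col].sum()
        if caps.empty:
            nightly_cap = pd.Series(0.0, index=nightly_eff.index)
        else:
            nightly_cap = (
                caps.groupby(["month", "date"]).size().reindex(nightly_eff.index, fill_value=0)
            )
        nightly = (nightly_cap / nightly_eff).groupby(level="month").mean()
        out[_CPUE_COL[method]] = nightly.reindex(out["month"]).to_numpy()
    return out


def build_panel(
    truth: pd.DataFrame,
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    aggregate: str = "ratio-of-totals",
) -> pd.DataFrame:
    """Join the monthly truth series with visual and trap CPUE columns.

    Rows exist only for truth months with at least one effort record of either
    method; method-specific columns are NaN in months that method did not
    sample (those rows are excluded from that method's fits downstream).
    """
    truth = truth.copy()
    truth["month"] = pd.PeriodIndex(truth["month"], freq="M")
    panel = truth
    any_effort = None
    for method in METHODS:
        mc = monthly_cpue(captures, effort, method, aggregate=aggregate)
        panel = panel.merge(mc, on="month", how="left")
        sampled = panel["month"].isin(mc["month"])
        any_effort = sampled if any_effort is None else (any_effort | sampled)
    return panel[any_effort].reset_index(drop=True)
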