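"""Real-world overall survival from insurance-claims event streams.

Vital status is not observed directly in claims data: death is inferred
for any patient whose claims stop more than 100 days before the data
cutoff (strictly more — a gap of exactly 100 days is censoring), with the
death date imputed as the last-claim date.  Overall survival runs from
treatment initiation to death or last contact.  Castration state is
assigned by the 90-day rule: systemic therapies starting within 90 days
of the first first-line ADT are hormone-sensitive, later starts are
castration-resistant.

Two-arm class-versus-WT contrasts are fitted with a Cox proportional
hazards model (single binary covariate, Efron tie handling) and the
log-rank test, via lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)

#: claim-gap (days) beyond which death is assumed; strictly greater-than.
DEFAULT_GAP_DAYS = 100
#: window (days) after first-line ADT separating hormone-sensitive from
#: castration-resistant treatment starts; strictly greater-than.
DEFAULT_CASTRATION_WINDOW_DAYS = 90

CLAIM_KINDS = ("claim", "treatment_start", "last_contact")

TREATMENT_CATEGORIES = (
    "first_line_ADT",
    "second_gen_ARSI",
    "taxane",
    "pembrolizumab",
    "other",
)

#: drug -> treatment category mapping for the drugs this cohort uses.
DEFAULT_DRUG_CATEGORIES = {
    "goserelin": "first_line_ADT",
    "leuprolide": "first_line_ADT",
    "triptorelin": "first_line_ADT",
    "degarelix": "first_line_ADT",
    "relugolix": "first_line_ADT",
    "apalutamide": "second_gen_ARSI",
    "abiraterone": "second_gen_ARSI",
    "darolutamide": "second_gen_ARSI",
    "enzalutamide": "second_gen_ARSI",
    "docetaxel": "taxane",
    "cabazitaxel": "taxane",
    "pembrolizumab": "pembrolizumab",
}


def _as_days(x) -> float:
    """Difference-to-days helper: supports numeric days and Timedelta."""
    if hasattr(x, "days"):
        return x / pd.Timedelta(days=1)
    return float(x)


def infer_vital_status(
    events: pd.DataFrame,
    data_cutoff_date,
    gap_days: float = DEFAULT_GAP_DAYS,
) -> tuple[int, object]:
    """Infer (event flag, terminal date) for one patient.

    ``events`` needs a ``date`` column (numeric day offsets or datetimes).
    If the gap between the last event and the cutoff strictly exceeds
    ``gap_days``, the patient is presumed dead at the last-event date;
    otherwise censored at last contact.
    """
    if len(events) == 0:
        raise ValueError("patient has no claim events; vital status undefined")
    last = events["date"].max()
    gap = _as_days(data_cutoff_date - last)
    if gap < 0:
        raise ValueError("data cutoff precedes the last claim event")
    return (1, last) if gap > gap_days else (0, last)


def annotate_castration_state(
    treatments: pd.DataFrame,
    window_days: float = DEFAULT_CASTRATION_WINDOW_DAYS,
) -> pd.DataFrame:
    """Label one patient's treatment starts by castration state.

    Adds a ``castration_state`` column: ``hormone_sensitive`` for starts
    at most ``window_days`` after the first first-line ADT start,
    ``castration_resistant`` for strictly later starts, ``unknown`` when
    the patient has no ADT start on record.
    """
    out = treatments.copy()
    adt = out.loc[out["drug_category"] == "first_line_ADT", "date"]
    if adt.empty:
        out["castration_state"] = "unknown"
        return out
    first_adt = adt.min()
    delta = (out["date"] - first_adt).map(_as_days)
    out["castration_state"] = np.where(
        delta > window_days, "castration_resistant", "hormone_sensitive"
    )
    return out


def build_survival_records(
    class_labels: pd.DataFrame,
    claims: pd.DataFrame,
    treatment_category: str = "any",
    *,
    data_cutoff_date=None,
    gap_days: float = DEFAULT_GAP_DAYS,
    castration_window_days: float = DEFAULT_CASTRATION_WINDOW_DAYS,
) -> pd.DataFrame:
    """Derive one survival record per patient for one treatment category.

    ``class_labels`` carries ``patient_id`` and ``class`` (plus any strata
    columns to keep, e.g. biopsy site).  ``claims`` is the long event
    table (``patient_id``, ``date``, ``kind``, optional ``drug`` and
    ``drug_category``).  The index date is the FIRST start of the given
    category (``"any"`` = earliest treatment start of any kind).  Patients
    never receiving the category contribute no record; records with
    non-positive follow-up are dropped with a warning.
    """
    if data_cutoff_date is None:
        data_cutoff_date = claims["date"].max() + (
            pd.Timedelta(days=1) if hasattr(claims["date"].iloc[0], "to_pydatetime")
            or isinstance(claims["date"].iloc[0], pd.Timestamp) else 1
        )
    if (claims["date"].max() - data_cutoff_date) > (
        pd.Timedelta(0) if hasattr(data_cutoff_date, "to_pydatetime") else 0
    ):
        raise ValueError("data cutoff precedes the last claim event")
    last_event = claims.groupby("patient_id")["date"].max()
    gap = (data_cutoff_date - last_event).map(_as_days)
    event = (gap > gap_days).astype(int).rename("event")

    starts = claims[claims["kind"] == "treatment_start"]
    sel = starts if treatment_category == "any" else starts[
        starts["drug_category"] == treatment_category
    ]
    if sel.empty:
        records = pd.DataFrame(
            columns=[
                "patient_id", "index_date", "time_days", "event",
                "treatment_category", "castration_state",
            ]
        )
        return records.merge(class_labels, on="patient_id", how="inner")
    index_date = sel.groupby("patient_id")["date"].min().rename("index_date")
    first_adt = (
        starts[starts["drug_category"] == "first_line_ADT"]
        .groupby("patient_id")["date"]
        .min()
        .reindex(index_date.index)
    )
    delta = (index_date - first_adt).map(_as_days)
    state = pd.Series(
        np.select(
            [delta.isna(), delta > castration_window_days],
            ["unknown", "castration_resistant"],
            default="hormone_sensitive",
        ),
        index=index_date.index,
        name="castration_state",
    )
    records = pd.concat([index_date, state], axis=1).join(
        pd.concat([last_event.rename("terminal"), event], axis=1), how="left"
    )
    records["time_days"] = (records["terminal"] - records["index_date"]).map(_as_days)
    n_dropped = int((records["time_days"] <= 0).sum())
    if n_dropped:
        logger.warning(
            "%d patient(s) dropped: index date on/after terminal date", n_dropped
        )
    records = records[records["time_days"] > 0].reset_index(names="patient_id")
    records["treatment_category"] = treatment_category
    records = records[
        ["patient_id", "index_date", "time_days", "event",
         "treatment_category", "castration_state"]
    ]
    return records.merge(class_labels, on="patient_id", how="inner")


@dataclass(frozen=True)
class HazardEstimate:
    """One class-vs-reference survival contrast."""

    comparison: str
    hr: float
    ci_low: float
    ci_high: float
    p_logrank: float
    n_class: int
    n_ref: int
    events_class: int
    events_ref: int
    converged: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def fit_class_vs_wt(
    records: pd.DataFrame,
    class_label: str,
    reference: str = "WT",
    *,
    class_column: str = "class",
) -> HazardEstimate:
    """Two-arm Cox fit (class vs reference) with a log-rank p value.

    The Cox model has the single binary covariate "is class"; the HR is
    exp(coef) with a 95% Wald CI on the log scale.  An arm with zero
    events yields a non-convergent estimate with missing HR.
    """
    sub = records[records[class_column].isin([class_label, reference])].copy()
    sub["arm"] = (sub[class_column] == class_label).astype(int)
    n1 = int(sub["arm"].sum())
    n0 = len(sub) - n1
    d1 = int(sub.loc[sub["arm"] == 1, "event"].sum())
    d0 = int(sub.loc[sub["arm"] == 0, "event"].sum())
    comparison = f"{class_label} vs {reference}"
    if n1 == 0 or n0 == 0 or d1 == 0 or d0 == 0:
        return HazardEstimate(
            comparison, np.nan, np.nan, np.nan, np.nan, n1, n0, d1, d0, converged=False
        )
    lr = logrank_test(
        sub.loc[sub["arm"] == 1, "time_days"],
        sub.loc[sub["arm"] == 0, "time_days"],
        event_observed_A=sub.loc[sub["arm"] == 1, "event"],
        event_observed_B=sub.loc[sub["arm"] == 0, "event"],
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                sub[["time_days", "event", "arm"]],
                duration_col="time_days",
                event_col="event",
            )
    except ConvergenceError:
        return HazardEstimate(
            comparison, np.nan, np.nan, np.nan, lr.p_value, n1, n0, d1, d0,
            converged=False,
        )
    coef = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    with np.errstate(over="ignore"):
        lo = float(np.exp(coef - 1.959963984540054 * se))
        hi = float(np.exp(coef + 1.959963984540054 * se))
    return HazardEstimate(
        comparison,
        float(np.exp(coef)),
        lo,
        hi,
        float(lr.p_value),
        n1,
        n0,
        d1,
        d0,
    )


def forest_table(
    records: pd.DataFrame,
    class_labels: Sequence[str],
    reference: str = "WT",
    *,
    class_column: str = "class",
) -> pd.DataFrame:
    """Fit every class-vs-reference contrast and stack into a tidy table."""
    rows = [
        fit_class_vs_wt(records, c, reference, class_column=class_column).as_dict()
        for c in class_labels
    ]
    return pd.DataFrame(rows)


def km_coordinates(
    records: pd.DataFrame, *, class_column: str = "class"
) -> pd.DataFrame:
    """Kaplan-Meier survival coordinates per class, tidy long format."""
    frames = []
    for label, grp in records.groupby(class_column, sort=False):
        km = KaplanMeierFitter()
        km.fit(grp["time_days"], grp["event"], label=str(label))
        sf = km.survival_function_.reset_index()
        sf.columns = ["time_days", "survival"]
        sf.insert(0, class_column, label)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
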