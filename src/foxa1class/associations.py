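"""Class-versus-WT categorical enrichment testing.

Each binary molecular or demographic feature (TMPRSS2-ERG fusion, TP53
mutation, MSI-high, TMB-high, race, ...) is compared between one
alteration class and the WT arm as a 2x2 contingency table: Fisher's
exact test when any expected cell count is below 5, otherwise the
chi-squared test (continuity correction configurable).  Within one class
comparison, p values across features are Benjamini-Hochberg adjusted and
q < 0.05 declares significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_TMB_HIGH_THRESHOLD = 10.0  # mutations per megabase

RACE_LEVELS = ("EA", "AF", "AP", "other")


def flag_tmb_high(tmb: float, threshold: float = DEFAULT_TMB_HIGH_THRESHOLD) -> bool:
    """TMB-high iff tumor mutational burden >= threshold (mut/Mb)."""
    if tmb < 0:
        raise ValueError(f"negative TMB value {tmb}")
    return tmb >= threshold


@dataclass(frozen=True)
class ContingencyResult:
    feature: str
    class_label: str
    a: int  # feature+ in class
    b: int  # feature- in class
    c: int  # feature+ in reference
    d: int  # feature- in reference
    test: str  # "fisher" | "chi2" | "untestable"
    odds_ratio: float
    p: float
    q: float = np.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio; Haldane-Anscombe 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def _test_2x2(a: int, b: int, c: int, d: int, *, continuity: bool = True) -> tuple[str, float]:
    """Two-sided 2x2 test: Fisher if any expected count < 5, else chi2."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0:
        return "untestable", np.nan
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if (expected < 5).any():
        return "fisher", float(stats.fisher_exact(table, alternative="two-sided")[1])
    chi2 = stats.chi2_contingency(table, correction=continuity)
    return "chi2", float(chi2[1])


def test_feature_enrichment(
    flags: pd.DataFrame,
    *,
    class_column: str = "class",
    feature_columns: Optional[Sequence[str]] = None,
    classes: Optional[Sequence[str]] = None,
    reference: str = "WT",
    continuity: bool = True,
) -> pd.DataFrame:
    """Per-(feature, class) 2x2 enrichment tests against the WT arm.

    ``flags`` holds one row per sample with a class-label column and
    boolean feature columns.  BH adjustment is applied across all features
    within one class comparison (one family per class, matching per-panel
    q values).  Empty class arms produce untestable rows.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in flags.columns
            if c != class_column and flags[c].dropna().isin([0, 1, True, False]).all()
        ]
    if classes is None:
        classes = [c for c in flags[class_column].unique() if c != reference]
    ref = flags[flags[class_column] == reference]
    results: list[ContingencyResult] = []
    for cls in classes:
        grp = flags[flags[class_column] == cls]
        fam: list[ContingencyResult] = []
        for feat in feature_columns:
            gf = grp[feat].dropna().astype(bool)
            rf = ref[feat].dropna().astype(bool)
            a, b = int(gf.sum()), int((~gf).sum())
            c, d = int(rf.sum()), int((~rf).sum())
            if a + b == 0 or c + d == 0:
                fam.append(ContingencyResult(feat, cls, a, b, c, d, "untestable", np.nan, np.nan))
                continue
            test, p = _test_2x2(a, b, c, d, continuity=continuity)
            fam.append(ContingencyResult(feat, cls, a, b, c, d, test, _odds_ratio(a, b, c, d), p))
        results.extend(_attach_q(fam))
    return pd.DataFrame([r.as_dict() for r in results])


def _attach_q(family: list[ContingencyResult]) -> list[ContingencyResult]:
    ps = np.array([r.p for r in family], dtype=float)
    ok = ~np.isnan(ps)
    qs = np.full(len(ps), np.nan)
    if ok.sum() > 0:
        qs[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    return [
        ContingencyResult(r.feature, r.class_label, r.a, r.b, r.c, r.d, r.test, r.odds_ratio, r.p, q)
        for r, q in zip(family, qs)
    ]


def race_distribution(
    samples: pd.DataFrame,
    *,
    class_column: str = "class",
    race_column: str = "race",
    reference_race: str = "EA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class frequencies by race plus per-class race-vs-EA 2x2 tests.

    Patients with unknown/uncharacterised race are excluded.  Returns the
    frequency table (race x class, proportions of that race's patients)
    and a tidy test table (one row per non-reference race per class).
    With a single race stratum only the table is returned (empty tests).
    """
    known = samples[samples[race_column].isin(RACE_LEVELS)].copy()
    freq = (
        known.groupby(race_column)[class_column]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    races = [r for r in known[race_column].unique() if r != reference_race]
    if not races or reference_race not in set(known[race_column]):
        return freq, pd.DataFrame(
            columns=["feature", "class_label", "a", "b", "c", "d", "test", "odds_ratio", "p", "q"]
        )
    tests = []
    classes = sorted(c for c in known[class_column].unique() if c != "WT")
    for race in races:
        flags = known[known[race_column].isin([race, reference_race])].copy()
        flags["arm"] = np.where(flags[race_column] == race, race, "WT")
        for cls in classes:
            flags[f"class_{cls}"] = flags[class_column] == cls
        res = test_feature_enrichment(
            flags,
            class_column="arm",
            feature_columns=[f"class_{c}" for c in classes],
            classes=[race],
        )
        tests.append(res)
    return freq, pd.concat(tests, ignore_index=True)
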