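"""Validation metrics for mating-system scores.

Three independent quantities are used to check that ordinal mating-system
scores track the strength of sexual selection:

* the opportunity for sexual selection ``I_S = var(m) / mean(m)**2``, the
  variance in mating success scaled by squared mean — an upper bound on
  standardized selection on any trait;
* the Bateman gradient ``beta_SS``, the least-squares slope of (relative)
  reproductive success on (relative) mating success;
* residual testes mass, the residual from a log10-log10 allometric
  regression of testes mass on body mass, a proxy for sperm competition.

Genetically monogamous species with a measured 0% extra-pair paternity rate
are assigned ``I_S = 0`` without per-individual data (the zero-EPP rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricEstimate",
    "opportunity_for_selection",
    "is_from_zero_epp",
    "bateman_gradient",
    "residual_testes_mass",
    "max_of_sexes",
    "metrics_table",
]


@dataclass
class MetricEstimate:
    species_id: str
    metric: str  # "I_S" | "bateman" | "residual_testes"
    value: float
    sex_used: str  # "male" | "female" | "max_of_sexes"
    source: str = "computed"  # or "zero_epp_rule"


def opportunity_for_selection(mating_success, ddof: int = 1) -> float:
    """I_S = var(m) / mean(m)**2 over individual mating successes.

    ``ddof=1`` (sample variance) by default; set ``ddof=0`` for the
    population convention.
    """
    m = np.asarray(mating_success, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 individuals to estimate I_S")
    if np.any(m < 0):
        raise ValueError("mating successes must be non-negative counts")
    mean = m.mean()
    if mean == 0:
        raise ValueError("I_S is undefined when mean mating success is 0")
    return float(m.var(ddof=ddof) / mean**2)


def is_from_zero_epp(epp_rate: float, socially_monogamous: bool = True) -> Optional[float]:
    """Zero-EPP rule: a genetically monogamous species has I_S = 0.

    Applies only at exactly 0% extra-pair paternity in a socially
    monogamous species; returns ``None`` otherwise.
    """
    if epp_rate == 0.0 and socially_monogamous:
        return 0.0
    return None


def bateman_gradient(mating, reproductive, relative: bool = True) -> float:
    """Least-squares slope of reproductive success on mating success.

    With ``relative=True`` (the classical definition) both variables are
    divided by their means first, making the slope invariant to separate
    rescaling of either variable.
    """
    m = np.asarray(mating, dtype=float)
    r = np.asarray(reproductive, dtype=float)
    if m.shape != r.shape or m.size < 2:
        raise ValueError("mating and reproductive success must be equal-length, n >= 2")
    if np.var(m) == 0:
        raise ValueError("Bateman gradient undefined: no variance in mating success")
    if relative:
        if m.mean() <= 0 or r.mean() <= 0:
            raise ValueError("relative Bateman gradient needs positive means")
        m = m / m.mean()
        r = r / r.mean()
    return float(stats.linregress(m, r).slope)


def residual_testes_mass(testes_mass, body_mass) -> np.ndarray:
    """Residuals of OLS log10(testes mass) ~ log10(body mass).

    Positive residuals indicate testes larger than the allometric
    expectation for the species' body size.
    """
    t = np.asarray(testes_mass, dtype=float)
    b = np.asarray(body_mass, dtype=float)
    if t.shape != b.shape or t.size < 3:
        raise ValueError("need equal-length mass vectors with n >= 3")
    if np.any(t <= 0) or np.any(b <= 0):
        raise ValueError("masses must be strictly positive")
    x = np.log10(b)
    y = np.log10(t)
    slope, intercept = np.polyfit(x, y, 1)
    return y - (intercept + slope * x)


def max_of_sexes(male_value: Optional[float], female_value: Optional[float]):
    """Largest of the sex-specific metric values, treating sexes equally.

    Returns ``(value, sex)``; ties go to the male value by fixed tie-break.
    """
    male_missing = male_value is None or (isinstance(male_value, float) and np.isnan(male_value))
    female_missing = female_value is None or (
        isinstance(female_value, float) and np.isnan(female_value)
    )
    if male_missing and female_missing:
        raise ValueError("both sex-specific values are missing")
    if female_missing or (not male_missing and male_value >= female_value):
        return float(male_value), "male"
    return float(female_value), "female"


def metrics_table(
    mating: pd.DataFrame,
    testes: Optional[pd.DataFrame] = None,
    relative: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-species metric estimates from per-individual mating records.

    ``mating`` columns: species_id, sex, individual_id, mating_success,
    reproductive_success.  I_S and the Bateman gradient are computed per
    species and sex, then combined with the largest-of-sexes rule.  If a
    ``testes`` table (species_id, testes_mass, body_mass) is given,
    residual testes mass is appended (one shared allometry across species).
    """
    rows = []
    for sp, sp_df in mating.groupby("species_id", sort=True):
        by_sex = {}
        for sex, sex_df in sp_df.groupby("sex"):
            m = sex_df["mating_success"].to_numpy(float)
            r = sex_df["reproductive_success"].to_numpy(float)
            entry = {}
            if m.size >= 2 and m.mean() > 0:
                entry["I_S"] = opportunity_for_selection(m, ddof=ddof)
                if np.var(m) > 0 and (not relative or r.mean() > 0):
                    entry["bateman"] = bateman_gradient(m, r, relative=relative)
            by_sex[sex] = entry
        for metric in ("I_S", "bateman"):
            vals = {s: e.get(metric) for s, e in by_sex.items()}
            if all(v is None for v in vals.values()):
                continue
            value, sex = max_of_sexes(vals.get("male"), vals.get("female"))
            rows.append((str(sp), metric, value, "max_of_sexes" if len(by_sex) > 1 else sex, "computed"))

    if testes is not None and len(testes) >= 3:
        resid = residual_testes_mass(
            testes["testes_mass"].to_numpy(float), testes["body_mass"].to_numpy(float)
        )
        for sp, val in zip(testes["species_id"], resid):
            rows.append((str(sp), "residual_testes", float(val), "male", "computed"))

    return pd.DataFrame(
        rows, columns=["species_id", "metric", "value", "sex_used", "source"]
    )
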