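"""Indirect standardization of admission counts.

For each sex, area-wide age-specific admission rates are applied to every
tract's stratified population, giving expected counts E_i; the
standardized admission ratio SAR_i = 100 * O_i / E_i compares each tract
with the study-area average.  With internally derived rates the method is
conservative by construction: sum(E) = sum(O) within each sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_KEY = ["sex", "age_group"]


def reference_rates(counts: pd.DataFrame, pop: pd.DataFrame) -> pd.DataFrame:
    """Area-wide stratum rates r_{g,s} = sum_i O_{i,g,s} / sum_i n_{i,g,s}.

    Rates are cumulative over the study period (the same period underlies
    counts and populations, so the time scale cancels in the SAR).
    Returns columns ``sex, age_group, rate``.
    """
    o = counts.groupby(_KEY, sort=True)["value"].sum()
    n = pop.groupby(_KEY, sort=True)["value"].sum()
    o, n = o.align(n, fill_value=0)
    bad = (o > 0) & (n == 0)
    if bad.any():
        strata = list(o.index[bad])
        raise ValueError(f"events observed in strata with zero population: {strata}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, o / n.replace(0, np.nan), 0.0)
    out = o.reset_index()[_KEY].copy()
    out["rate"] = np.nan_to_num(r, nan=0.0)
    return out


def expected_counts(pop: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    """Expected admissions per (tract, sex): E_{i,s} = sum_g n_{i,g,s} r_{g,s}."""
    merged = pop.merge(rates, on=_KEY, how="left", validate="many_to_one")
    if merged["rate"].isna().any():
        missing = merged.loc[merged["rate"].isna(), _KEY].drop_duplicates()
        raise ValueError(f"rates missing for strata: {missing.to_records(index=False).tolist()}")
    merged["E"] = merged["value"] * merged["rate"]
    out = merged.groupby(["tract_id", "sex"], sort=False, as_index=False)["E"].sum()
    return out


def sar(observed: pd.DataFrame, expected: pd.DataFrame) -> pd.DataFrame:
    """Standardized admission ratio per (tract, sex), percent scale.

    ``observed`` is a stratified count table (or already aggregated with an
    ``O`` column); ``expected`` has columns ``tract_id, sex, E``.  Tracts
    with E = 0 get SAR = NaN and ``sar_defined`` False — they are flagged
    and excluded from maps rather than imputed.
    """
    if "O" in observed.columns:
        o = observed[["tract_id", "sex", "O"]].copy()
    else:
        o = (observed.groupby(["tract_id", "sex"], sort=False, as_index=False)["value"]
             .sum().rename(columns={"value": "O"}))
    if (o["O"] < 0).any() or (expected["E"] < 0).any():
        raise ValueError("observed and expected counts must be non-negative")
    out = o.merge(expected, on=["tract_id", "sex"], how="outer")
    out["O"] = out["O"].fillna(0.0)
    out["E"] = out["E"].fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["SAR"] = np.where(out["E"] > 0, 100.0 * out["O"] / out["E"], np.nan)
    out["sar_defined"] = out["E"] > 0
    return out


def standardize(counts: pd.DataFrame, pop: pd.DataFrame) -> pd.DataFrame:
    """Full indirect standardization: internal rates -> E -> SAR.

    Returns one row per (tract_id, sex) with O, E, SAR, sar_defined.
    """
    rates = reference_rates(counts, pop)
    e = expected_counts(pop, rates)
    return sar(counts, e)
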