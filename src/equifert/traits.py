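"""Mare fertility traits derived from foaling histories.

Seven traits, all ages in months:

====  =======================================================
AFF   age at first foaling
ALF   age at last foaling
AIF   average interval between consecutive foalings (FN >= 2)
FN    total number of foalings
IF12  interval between first and second foaling (FN >= 2)
PL    productive life: culling age (or ALF if still active) minus AFF
RE    reproductive efficiency, %: 100 * FN / optimal foalings,
      where the optimum assumes one foaling per year from the
      first foaling over the productive window
====  =======================================================

The optimal foaling count is ``floor(PL/12) + 1`` by default (the foaling
that opens the window plus one per completed year); an exact yearly schedule
then scores RE = 100% and more frequent foaling can exceed 100%. The
alternative ``ceil`` convention (``max(ceil(PL/12), 1)``) is available via
``optimal_rule``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReproHistory", "derive_traits", "derive_trait_table", "describe",
           "TRAIT_NAMES", "TraitError"]

TRAIT_NAMES = ["AFF", "ALF", "AIF", "FN", "IF12", "PL", "RE"]


class TraitError(ValueError):
    """Raised for invalid foaling histories."""


@dataclass
class ReproHistory:
    """One mare's reproductive record.

    ``foaling_ages`` are ages at each foaling in months, strictly
    increasing; ``culling_age`` is the age at culling in months, or None if
    the mare is still reproductively active.
    """

    mare_id: int | str
    foaling_ages: list[float]
    culling_age: float | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.foaling_ages, dtype=float)
        if ages.size and np.any(np.diff(ages) <= 0):
            raise TraitError(f"mare {self.mare_id}: foaling ages not strictly increasing")
        if self.culling_age is not None and ages.size and self.culling_age < ages[-1]:
            raise TraitError(
                f"mare {self.mare_id}: culling age {self.culling_age} precedes last foaling"
            )


def optimal_foalings(pl_months: float, rule: str = "floor_plus_one") -> int:
    """Optimal number of foalings over a productive window of ``pl_months``."""
    if rule == "floor_plus_one":
        return int(math.floor(pl_months / 12.0)) + 1
    if rule == "ceil":
        return max(int(math.ceil(pl_months / 12.0)), 1)
    raise ValueError(f"unknown optimal-foalings rule {rule!r}")


def derive_traits(history: ReproHistory, optimal_rule: str = "floor_plus_one") -> dict:
    """Derive the seven fertility traits for one mare.

    Returns a dict with NaN for traits the history cannot define (all seven
    if there is no foaling; AIF and IF12 whenever FN < 2). A mare without a
    culling age uses her last foaling age as the end of the productive
    window for PL and RE.
    """
    ages = np.asarray(history.foaling_ages, dtype=float)
    out = {t: np.nan for t in TRAIT_NAMES}
    if ages.size == 0:
        return out
    fn = int(ages.size)
    aff = float(ages[0])
    alf = float(ages[-1])
    end = float(history.culling_age) if history.culling_age is not None else alf
    pl = end - aff
    out["AFF"] = aff
    out["ALF"] = alf
    out["FN"] = fn
    out["PL"] = pl
    out["RE"] = 100.0 * fn / optimal_foalings(pl, optimal_rule)
    if fn >= 2:
        out["IF12"] = float(ages[1] - ages[0])
        out["AIF"] = (alf - aff) / (fn - 1)
    return out


def derive_trait_table(
    histories: list[ReproHistory], optimal_rule: str = "floor_plus_one"
) -> pd.DataFrame:
    """Trait table for a set of mares, indexed by mare id."""
    rows = {h.mare_id: derive_traits(h, optimal_rule) for h in histories}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=TRAIT_NAMES)
    table.index.name = "mare_id"
    return table


def describe(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait descriptive statistics, missing values excluded per trait.

    Columns: n, mean, sd (denominator n-1), min, max, cv_pct = 100*sd/mean.
    An all-missing trait yields an empty (NaN) row rather than an error.
    """
    stats = []
    cols = [c for c in TRAIT_NAMES if c in table.columns]
    for trait in cols:
        x = table[trait].dropna().to_numpy(dtype=float)
        if x.size == 0:
            stats.append((0, *[np.nan] * 5))
            continue
        mean = x.mean()
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        stats.append((x.size, mean, sd, x.min(), x.max(), cv))
    return pd.DataFrame(
        stats, index=cols, columns=["n", "mean", "sd", "min", "max", "cv_pct"]
    )
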