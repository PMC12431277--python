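"""Combining-ability tables and mid-/best-parent heterosis.

Heterosis is computed on adjusted means (mu_hat + BLUP) from per-year
model-1 fits, parents and hybrids fitted separately.  For concentrations
(all positive) the best parent is the larger parent mean, so best-parent
heterosis never exceeds mid-parent heterosis when the parents differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import MatingDesign
from .errors import InsufficientDataError, ValidationError
from .reml import REMLResults, blup_ttest


def heterosis_pct(f1: float, reference: float) -> float:
    """Percent excess of the F1 over a reference mean: 100 (F1 - ref)/ref."""
    if reference <= 0:
        raise ValidationError(
            f"reference mean must be > 0 for percent heterosis, got {reference}"
        )
    return 100.0 * (f1 - reference) / reference


@dataclass
class HeterosisTable:
    """Per-cross F1/MP/BP adjusted means and MPH/BPH percentages."""

    frame: pd.DataFrame  # female, male, f1, mp, bp, mph, bph (+ trait/year)
    excluded: list = field(default_factory=list)


def build_heterosis_table(
    parent_means: Mapping[str, float],
    hybrid_means: Mapping[tuple[str, str], float],
    design: MatingDesign,
    trait: str | None = None,
    year: int | None = None,
) -> HeterosisTable:
    """Heterosis for every realized cross with both parent means available.

    Crosses whose parents lack an adjusted mean are skipped and listed in
    the exclusion report.
    """
    rows, excluded = [], []
    for f, m in sorted(design.crosses):
        if (f, m) not in hybrid_means:
            excluded.append({"female": f, "male": m, "reason": "missing F1 mean"})
            continue
        if f not in parent_means or m not in parent_means:
            excluded.append(
                {"female": f, "male": m, "reason": "missing parent mean"}
            )
            continue
        pf, pm = float(parent_means[f]), float(parent_means[m])
        f1 = float(hybrid_means[(f, m)])
        mp = 0.5 * (pf + pm)
        bp = max(pf, pm)
        rows.append(
            {
                "female": f,
                "male": m,
                "trait": trait,
                "year": year,
                "f1": f1,
                "mp": mp,
                "bp": bp,
                "mph": heterosis_pct(f1, mp),
                "bph": heterosis_pct(f1, bp),
            }
        )
    return HeterosisTable(frame=pd.DataFrame(rows), excluded=excluded)


def pooled_heterosis_range(
    tables: Iterable[HeterosisTable | pd.DataFrame],
) -> tuple[float, float]:
    """(min %, max %) over all MPH and BPH entries of all tables."""
    values = []
    for t in tables:
        df = t.frame if isinstance(t, HeterosisTable) else t
        values.append(df["mph"].to_numpy(float))
        values.append(df["bph"].to_numpy(float))
    if not values or sum(v.size for v in values) == 0:
        raise InsufficientDataError("no heterosis entries to pool")
    pooled = np.concatenate(values)
    return float(pooled.min()), float(pooled.max())


@dataclass
class CombiningAbilityTable:
    """GCA/SCA BLUPs with significance, ranked within parent sex."""

    females: pd.DataFrame
    males: pd.DataFrame
    crosses: pd.DataFrame
    trait: str | None = None
    year: int | None = None


def combining_ability_tables(
    fit: REMLResults, trait: str | None = None, year: int | None = None
) -> CombiningAbilityTable:
    """Assemble GCA/SCA effect tables from a combining-ability fit.

    Requires a fit containing ``gca_f``, ``gca_m`` and ``sca`` BLUPs
    (i.e. model 5 or 6); parents are ranked by GCA, largest first.
    """
    needed = ("gca_f", "gca_m", "sca")
    missing = [t for t in needed if t not in fit.blups]
    if missing:
        raise ValidationError(
            f"fit has no BLUPs for {missing}; a combining-ability model "
            "(model5/model6) with nonzero variances is required"
        )

    def _table(term: str) -> pd.DataFrame:
        df = fit.blup_tests(term)
        df = df.sort_values("blup", ascending=False)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    return CombiningAbilityTable(
        females=_table("gca_f"),
        males=_table("gca_m"),
        crosses=_table("sca"),
        trait=trait,
        year=year,
    )
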