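"""Spearman association panels.

Two families of panels: (i) per trait x year, rank correlations linking
parent per-se performance with GCA, and hybrid performance with SCA, summed
parental GCA (sGCA), and heterosis; (ii) trait x trait rank-correlation
matrices over parents, hybrids, SCA effects or heterosis values.

Ties get midranks and p-values use the t approximation on n - 2 degrees of
freedom; no multiplicity correction is applied across panel cells.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._util import stars
from .errors import InsufficientDataError, ValidationError

#: panel column vocabulary: output name -> (series x, series y)
PANEL_PAIRS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("r(per_se,GCA)", ("per_se", "gca")),
    ("r(F1,SCA)", ("f1", "sca")),
    ("r(F1,MPH)", ("f1", "mph")),
    ("r(F1,BPH)", ("f1", "bph")),
    ("r(SCA,MPH)", ("sca", "mph")),
    ("r(SCA,BPH)", ("sca", "bph")),
    ("r(F1,sGCA)", ("f1", "sgca")),
    ("r(sGCA,MPH)", ("sgca", "mph")),
    ("r(sGCA,BPH)", ("sgca", "bph")),
)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation with midranks for ties; p via the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"series must be 1-d and equal length, got {x.shape} vs {y.shape}"
        )
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sgca_series(
    gca_f: pd.Series,
    gca_m: pd.Series,
    crosses,
) -> pd.Series:
    """Summed parental GCA per cross: sGCA = GCA_f + GCA_m, keyed "f|m".

    Parents without a BLUP (variance at the boundary) contribute 0.
    """
    return pd.Series(
        {
            f"{f}|{m}": float(gca_f.get(f, 0.0)) + float(gca_m.get(m, 0.0))
            for f, m in crosses
        }
    )


def _aligned(a: pd.Series, b: pd.Series, label: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = set(a.index), set(b.index)
    if ia != ib:
        offending = sorted((ia ^ ib))[:10]
        raise ValidationError(
            f"misaligned keys for {label}: symmetric difference {offending}"
        )
    b = b.reindex(a.index)
    return a.to_numpy(float), b.to_numpy(float)


def correlation_panel(
    series: Mapping[str, pd.Series],
    trait: str | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """One trait x year row-set of the performance/CA/heterosis panel.

    ``series`` maps names from {per_se, gca, f1, sca, sgca, mph, bph} to
    aligned pandas Series: parent-keyed for (per_se, gca), cross-keyed for
    the rest.  Pairs whose inputs are absent are omitted; pairs whose
    inputs are present but misaligned raise.
    """
    rows = []
    for name, (kx, ky) in PANEL_PAIRS:
        if kx not in series or ky not in series:
            continue
        if len(series[kx]) < 3 or len(series[ky]) < 3:
            continue
        x, y = _aligned(series[kx], series[ky], name)
        if np.std(x) == 0 or np.std(y) == 0:
            rho, p = np.nan, np.nan  # undefined for a constant series
        else:
            rho, p = spearman(x, y)
        rows.append(
            {
                "trait": trait,
                "year": year,
                "pair": name,
                "rho": rho,
                "p": p,
                "stars": (stars(p) or "ns") if np.isfinite(p) else "",
                "n": len(x),
            }
        )
    return pd.DataFrame(rows)


def mineral_correlation_matrix(
    wide: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait x trait Spearman matrix (rho, p) over a wide table.

    Rows are genotypes/crosses, columns are traits.  A zero-variance column
    yields NaN in its row and column (undefined, not zero); the diagonal is
    exactly 1 for non-degenerate traits.
    """
    cols = list(wide.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        xi = wide[cols[i]].to_numpy(float)
        degenerate_i = np.nanstd(xi) == 0
        if degenerate_i:
            rho.iloc[i, i] = np.nan
            pmat.iloc[i, i] = np.nan
        for j in range(i + 1, k):
            xj = wide[cols[j]].to_numpy(float)
            if degenerate_i or np.nanstd(xj) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = spearman(xi, xj)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat
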