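"""Phenotype tables, mating designs, QC and descriptive statistics.

The central container is :class:`PhenotypeTable`, a validated long-format
table with one row per (genotype, year, replicate, trait) observation of a
leaf mineral concentration.  Two generations coexist in one table: selfed
``parent`` lines and F1 ``hybrid`` crosses; hybrids carry their female and
male parent tokens so the factorial mating design can be recovered with
:func:`validate_design`.

Quality control follows the standard plant-breeding recipe: a simple
screening model (genotype + replicate) is fitted per population x trait x
year, and externally studentized residuals are tested with the
Bonferroni-Holm step-down at a 5% family level.  Flagging and removal are
separated; callers decide what to drop.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import stars
from .errors import (
    DesignError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

#: The nine-trait vocabulary.  Macroelements are in g/kg DW, microelements
#: in mg/kg DW.
TRAITS: tuple[str, ...] = ("Ca", "K", "Mg", "Na", "P", "Fe", "Zn", "Cu", "Mn")
MACROELEMENTS: frozenset[str] = frozenset({"Ca", "K", "Mg", "Na", "P"})
MICROELEMENTS: frozenset[str] = frozenset({"Fe", "Zn", "Cu", "Mn"})

TRAIT_UNITS: dict[str, str] = {
    t: ("g kg-1 DW" if t in MACROELEMENTS else "mg kg-1 DW") for t in TRAITS
}

#: Canonical column order of the CSV dialect.
COLUMNS: tuple[str, ...] = (
    "genotype",
    "generation",
    "female",
    "male",
    "year",
    "rep",
    "trait",
    "value",
)

GENERATIONS = ("parent", "hybrid")

_TRAIT_ALIASES = {
    "calcium": "Ca",
    "potassium": "K",
    "magnesium": "Mg",
    "sodium": "Na",
    "phosphorus": "P",
    "iron": "Fe",
    "zinc": "Zn",
    "copper": "Cu",
    "manganese": "Mn",
}


def _normalize_trait(token: str) -> str:
    s = str(token).strip()
    for t in TRAITS:
        if s.lower() == t.lower():
            return t
    if s.lower() in _TRAIT_ALIASES:
        return _TRAIT_ALIASES[s.lower()]
    raise ValidationError(
        f"unknown trait {token!r}; expected one of {', '.join(TRAITS)}"
    )


@dataclass(frozen=True)
class MatingDesign:
    """Female/male parent sets and the realized subset of crosses."""

    females: tuple[str, ...]
    males: tuple[str, ...]
    crosses: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = set(self.females) & set(self.males)
        if overlap:
            raise DesignError(
                f"tokens used as both female and male: {sorted(overlap)}"
            )
        bad = [
            c
            for c in self.crosses
            if c[0] not in self.females or c[1] not in self.males
        ]
        if bad:
            raise DesignError(f"crosses outside the female x male grid: {bad[:5]}")

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(self.females) + tuple(self.males)

    def cross_counts(self) -> dict[str, int]:
        """Number of realized crosses each parent participates in."""
        counts = {p: 0 for p in self.parents}
        for f, m in self.crosses:
            counts[f] += 1
            counts[m] += 1
        return counts

    def is_connected(self) -> bool:
        """Every parent appears in at least one cross."""
        return all(c > 0 for c in self.cross_counts().values())


class PhenotypeTable:
    """Validated long-format phenotype observations.

    Parameters
    ----------
    frame:
        DataFrame with the canonical columns (:data:`COLUMNS`).  Copied and
        normalized on construction; invalid input raises
        :class:`~ncii.errors.ValidationError` / :class:`~ncii.errors.SchemaError`.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = self._validate(frame)

    # -- construction -------------------------------------------------
    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = frame.loc[:, list(COLUMNS)].copy().reset_index(drop=True)

        df["genotype"] = df["genotype"].astype(str)
        gen = df["generation"].astype(str).str.lower()
        bad_gen = sorted(set(gen) - set(GENERATIONS))
        if bad_gen:
            raise ValidationError(f"unknown generation labels: {bad_gen}")
        df["generation"] = gen

        values = pd.to_numeric(df["value"], errors="coerce")
        bad_rows = df.index[values.isna()].tolist()
        if bad_rows:
            raise ValidationError(
                f"non-numeric phenotype value at rows {bad_rows[:10]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite phenotype values")
        neg = df.index[values < 0].tolist()
        if neg:
            raise ValidationError(
                f"negative concentration at rows {neg[:10]} (values must be >= 0)"
            )
        df["value"] = values.astype(float)

        df["year"] = df["year"].astype(int)
        df["rep"] = df["rep"].astype(int)
        df["trait"] = df["trait"].map(_normalize_trait)

        # parent/hybrid parentage structure
        is_hyb = df["generation"] == "hybrid"
        for col in ("female", "male"):
            df[col] = df[col].where(df[col].notna(), None)
            df[col] = df[col].map(lambda x: None if x is None or str(x).strip() in ("", "nan", "None") else str(x))
        if is_hyb.any():
            null_parent = is_hyb & (df["female"].isna() | df["male"].isna())
            if null_parent.any():
                raise ValidationError(
                    f"hybrid rows without both parents: rows {df.index[null_parent].tolist()[:10]}"
                )
        nonnull_parent = (~is_hyb) & (df["female"].notna() | df["male"].notna())
        if nonnull_parent.any():
            raise ValidationError(
                f"parent rows must have null parent fields: rows {df.index[nonnull_parent].tolist()[:10]}"
            )

        parent_set = set(df.loc[~is_hyb, "genotype"])
        if parent_set and is_hyb.any():
            used = set(df.loc[is_hyb, "female"]) | set(df.loc[is_hyb, "male"])
            unknown = sorted(used - parent_set)
            if unknown:
                raise ValidationError(
                    f"hybrid parents absent from the parent set: {unknown[:10]}"
                )

        dup = df.duplicated(subset=["genotype", "year", "rep", "trait"])
        if dup.any():
            raise ValidationError(
                "duplicate (genotype, year, rep, trait) keys at rows "
                f"{df.index[dup].tolist()[:10]}"
            )
        return df

    # -- convenience accessors ----------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def traits(self) -> tuple[str, ...]:
        present = set(self.frame["trait"])
        return tuple(t for t in TRAITS if t in present)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @property
    def parents(self) -> pd.DataFrame:
        return self.frame[self.frame["generation"] == "parent"]

    @property
    def hybrids(self) -> pd.DataFrame:
        return self.frame[self.frame["generation"] == "hybrid"]

    def subset(
        self,
        generation: str | None = None,
        trait: str | None = None,
        year: int | None = None,
    ) -> pd.DataFrame:
        df = self.frame
        if generation is not None:
            df = df[df["generation"] == generation]
        if trait is not None:
            df = df[df["trait"] == _normalize_trait(trait)]
        if year is not None:
            df = df[df["year"] == int(year)]
        return df

    def drop_rows(self, index: Iterable[int]) -> "PhenotypeTable":
        """New table with the given (positional) rows removed."""
        return PhenotypeTable(self.frame.drop(index=list(index)))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.frame.to_csv(buf, index=False)
        return buf.getvalue()


def read_phenotype_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Read a phenotype table from CSV (or XLSX for supplementary layouts).

    Parameters
    ----------
    path:
        CSV path; ``.xlsx`` files are read through openpyxl.
    schema:
        Optional map from canonical column names (:data:`COLUMNS`) to the
        file's column names, for files with a different header vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"schema refers to absent columns: {missing}")
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    return PhenotypeTable(raw)


def validate_design(table: PhenotypeTable) -> MatingDesign:
    """Infer the mating design from hybrid parentage.

    Females/males are the tokens appearing in the respective parent slot of
    any hybrid; a token appearing on both sides raises
    :class:`~ncii.errors.DesignError`.
    """
    hyb = table.hybrids
    if hyb.empty:
        raise DesignError("table contains no hybrids; cannot infer a design")
    females = tuple(sorted(set(hyb["female"])))
    males = tuple(sorted(set(hyb["male"])))
    crosses = frozenset(zip(hyb["female"], hyb["male"]))
    return MatingDesign(females=females, males=males, crosses=crosses)


@dataclass
class QCReport:
    """Outliers flagged by the Holm test on studentized residuals."""

    flags: pd.DataFrame  # row, genotype, generation, year, rep, trait, student_resid, p_adj
    method: str = "bonferroni-holm on externally studentized residuals"
    alpha: float = 0.05

    @property
    def n_flagged(self) -> int:
        return len(self.flags)


def flag_outliers(table: PhenotypeTable, alpha: float = 0.05) -> QCReport:
    """Screen for gross errors per population x trait x year.

    The screening model regresses the value on genotype and replicate
    indicators; externally studentized residuals are tested two-sided and
    Holm-adjusted within each screening family at level ``alpha``.  With
    ``alpha = 0`` nothing is ever flagged.

    Raises
    ------
    InsufficientDataError
        if any screening family has fewer than 3 residual degrees of freedom.
    """
    import statsmodels.api as sm

    if not 0 <= alpha < 1:
        raise ValidationError(f"alpha must be in [0, 1), got {alpha}")
    records = []
    grouped = table.frame.groupby(["generation", "trait", "year"], sort=True)
    for (gen, trait, year), df in grouped:
        X = pd.get_dummies(df["genotype"], drop_first=True, dtype=float)
        reps = pd.get_dummies(df["rep"], drop_first=True, prefix="rep", dtype=float)
        X = pd.concat([X, reps], axis=1)
        X = sm.add_constant(X, has_constant="add")
        y = df["value"].to_numpy(float)
        res = sm.OLS(y, X.to_numpy(float)).fit()
        if res.df_resid < 3:
            raise InsufficientDataError(
                f"screening model for ({gen}, {trait}, {year}) has "
                f"{int(res.df_resid)} residual df; need >= 3"
            )
        test = np.asarray(res.outlier_test(method="holm"), float)
        student = test[:, 0]
        p_adj = test[:, 2]
        hit = p_adj < alpha
        for pos in np.flatnonzero(hit):
            row = df.iloc[pos]
            records.append(
                {
                    "row": int(df.index[pos]),
                    "genotype": row["genotype"],
                    "generation": gen,
                    "year": int(year),
                    "rep": int(row["rep"]),
                    "trait": trait,
                    "student_resid": float(student[pos]),
                    "p_adj": float(min(1.0, p_adj[pos])),
                }
            )
    flags = pd.DataFrame(
        records,
        columns=[
            "row",
            "genotype",
            "generation",
            "year",
            "rep",
            "trait",
            "student_resid",
            "p_adj",
        ],
    )
    return QCReport(flags=flags, alpha=alpha)


def descriptive_stats(table: PhenotypeTable) -> pd.DataFrame:
    """Mean / min / max / SE / CV% per (population, trait).

    Raw observations are pooled across years and replicates; CV is
    100*sd/mean and SE is sd/sqrt(n), both on the raw pooled sample.
    """
    rows = []
    for (gen, trait), df in table.frame.groupby(["generation", "trait"]):
        v = df["value"].to_numpy(float)
        if v.size < 2:
            raise InsufficientDataError(
                f"({gen}, {trait}): need >= 2 observations, got {v.size}"
            )
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        rows.append(
            {
                "population": gen,
                "trait": trait,
                "n": int(v.size),
                "mean": mean,
                "minimum": float(v.min()),
                "maximum": float(v.max()),
                "se": sd / np.sqrt(v.size),
                "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index(["population", "trait"]).sort_index()
    return out


@dataclass
class PopulationComparison:
    trait: str
    test: str  # "welch-t" or "wilcoxon-rank-sum"
    statistic: float
    p: float
    stars: str
    n_parent: int
    n_hybrid: int
    shapiro_p: tuple[float, float] = field(default=(np.nan, np.nan))


def compare_populations(
    table: PhenotypeTable,
    trait: str,
    year: int | None = None,
) -> PopulationComparison:
    """Parent vs hybrid location test for one trait.

    Welch's t-test when both samples pass Shapiro-Wilk normality at 0.05,
    otherwise the Wilcoxon rank-sum (Mann-Whitney) test.
    """
    trait = _normalize_trait(trait)
    p_vals = table.subset("parent", trait, year)["value"].to_numpy(float)
    h_vals = table.subset("hybrid", trait, year)["value"].to_numpy(float)
    if len(p_vals) < 3 or len(h_vals) < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per population for {trait}"
            f" (parents {len(p_vals)}, hybrids {len(h_vals)})"
        )
    sw_p = stats.shapiro(p_vals).pvalue if len(set(p_vals)) > 1 else 0.0
    sw_h = stats.shapiro(h_vals).pvalue if len(set(h_vals)) > 1 else 0.0
    if sw_p > 0.05 and sw_h > 0.05:
        res = stats.ttest_ind(h_vals, p_vals, equal_var=False)
        test = "welch-t"
    else:
        res = stats.mannwhitneyu(h_vals, p_vals, alternative="two-sided")
        test = "wilcoxon-rank-sum"
    stat, p = float(res.statistic), float(res.pvalue)
    return PopulationComparison(
        trait=trait,
        test=test,
        statistic=stat,
        p=p,
        stars=stars(p),
        n_parent=len(p_vals),
        n_hybrid=len(h_vals),
        shapiro_p=(float(sw_p), float(sw_h)),
    )
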