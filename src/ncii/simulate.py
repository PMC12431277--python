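"""Synthetic NC design II phenotypes with known genetic architecture.

The generator draws every random term of the across-year combining-ability
model — year, replicate-within-year, female GCA, male GCA, SCA, their year
interactions, and a per-year residual — as independent Gaussians with
configurable variances, and sums them into phenotypes.  Because the realized
effects are returned alongside the table, every downstream stage (REML,
BLUP, heterosis, correlations) can be tested against ground truth.

Parents are optionally emitted with genotypic value ``2 * (own GCA)`` plus
year/replicate/residual noise.  That is a simulation convention (it makes
mid-/best-parent heterosis well defined with a known structure), not a
genetic claim about selfed lines.

Default variance magnitudes mirror an across-year leaf-calcium analysis of
a 12-female x 14-male incomplete factorial with 118 crosses, two years and
two replicates; :meth:`SimulationConfig.single_year_ca2019` gives the
corresponding single-year configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MatingDesign, PhenotypeTable
from .errors import DesignError, ValidationError


@dataclass
class SimulationConfig:
    """Parameters of the generative model (variances in trait units squared)."""

    n_females: int = 12
    n_males: int = 14
    n_crosses: int = 118
    years: tuple[int, ...] = (2019, 2020)
    reps: int = 2
    mu: float = 23.45
    var_gca_f: float = 5.19
    var_gca_m: float = 2.38
    var_sca: float = 0.36
    var_year: float = 68.70
    var_rep_in_year: float = 0.1
    var_gca_f_by_year: float = 9.33
    var_gca_m_by_year: float = 1.79
    var_sca_by_year: float = 15.36
    resid_var_by_year: dict[int, float] = field(
        default_factory=lambda: {2019: 0.48, 2020: 0.84}
    )
    include_parents: bool = True
    trait: str = "Ca"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crosses > self.n_females * self.n_males:
            raise ValidationError(
                f"n_crosses={self.n_crosses} exceeds the "
                f"{self.n_females}x{self.n_males} factorial"
            )
        for name in (
            "var_gca_f",
            "var_gca_m",
            "var_sca",
            "var_year",
            "var_rep_in_year",
            "var_gca_f_by_year",
            "var_gca_m_by_year",
            "var_sca_by_year",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self.years = tuple(int(y) for y in self.years)
        self.resid_var_by_year = {
            int(y): float(v) for y, v in self.resid_var_by_year.items()
        }
        for y in self.years:
            if y not in self.resid_var_by_year:
                raise ValidationError(f"no residual variance for year {y}")
            if self.resid_var_by_year[y] <= 0:
                raise ValidationError("residual variances must be > 0")

    @classmethod
    def single_year_ca2019(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Single-year configuration at calcium-2019 combining-ability scale."""
        kwargs = dict(
            years=(2019,),
            mu=29.32,
            var_gca_f=27.75,
            var_gca_m=6.69,
            var_sca=25.68,
            var_year=0.0,
            var_gca_f_by_year=0.0,
            var_gca_m_by_year=0.0,
            var_sca_by_year=0.0,
            resid_var_by_year={2019: 0.48},
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)  # YAML/JSON friendly
        return d


@dataclass
class TrueEffects:
    """Realized values of every random term, keyed by level."""

    year: dict[int, float]
    rep_in_year: dict[tuple[int, int], float]
    gca_f: dict[str, float]
    gca_m: dict[str, float]
    sca: dict[tuple[str, str], float]
    gca_f_by_year: dict[tuple[str, int], float]
    gca_m_by_year: dict[tuple[str, int], float]
    sca_by_year: dict[tuple[str, str, int], float]

    def to_json(self) -> str:
        def _k(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                    for k, v in d.items()}

        return json.dumps({f: _k(getattr(self, f)) for f in self.__dataclass_fields__},
                          indent=1)


def make_incomplete_factorial(
    n_females: int,
    n_males: int,
    n_crosses: int,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> MatingDesign:
    """Uniform random subset of the female x male grid, connected.

    When ``n_crosses >= max(n_females, n_males)`` the subset is resampled
    until every parent appears in at least one cross.
    """
    if n_crosses > n_females * n_males:
        raise DesignError(
            f"cannot place {n_crosses} crosses in a {n_females}x{n_males} grid"
        )
    if n_crosses < 1:
        raise DesignError("n_crosses must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    females = tuple(f"F{i + 1:02d}" for i in range(n_females))
    males = tuple(f"M{i + 1:02d}" for i in range(n_males))
    grid = [(f, m) for f in females for m in males]
    require_connected = n_crosses >= max(n_females, n_males)
    for _ in range(max_tries):
        pick = rng.choice(len(grid), size=n_crosses, replace=False)
        design = MatingDesign(
            females=females, males=males, crosses=frozenset(grid[i] for i in pick)
        )
        if not require_connected or design.is_connected():
            return design
    raise DesignError(
        f"could not draw a connected design in {max_tries} tries"
    )


def _cross_token(f: str, m: str) -> str:
    return f"{f}x{m}"


def simulate_ncii(
    config: SimulationConfig,
    design: MatingDesign | None = None,
) -> tuple[PhenotypeTable, TrueEffects]:
    """Draw one NC II dataset under the across-year combining-ability model.

    Every effect is an independent zero-mean Gaussian with its configured
    variance; the phenotype is the sum of mu and all effect realizations.
    Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_eff = [np.random.default_rng(s) for s in ss.spawn(2)]
    if design is None:
        design = make_incomplete_factorial(
            config.n_females, config.n_males, config.n_crosses, rng_design
        )

    def draw(var: float, keys: Sequence) -> dict:
        sd = np.sqrt(var)
        vals = rng_eff.normal(0.0, sd, size=len(keys)) if sd > 0 else np.zeros(len(keys))
        return dict(zip(keys, vals))

    years = config.years
    crosses = sorted(design.crosses)
    eff = TrueEffects(
        year=draw(config.var_year, years),
        rep_in_year=draw(
            config.var_rep_in_year,
            [(y, k) for y in years for k in range(1, config.reps + 1)],
        ),
        gca_f=draw(config.var_gca_f, list(design.females)),
        gca_m=draw(config.var_gca_m, list(design.males)),
        sca=draw(config.var_sca, crosses),
        gca_f_by_year=draw(
            config.var_gca_f_by_year, [(f, y) for f in design.females for y in years]
        ),
        gca_m_by_year=draw(
            config.var_gca_m_by_year, [(m, y) for m in design.males for y in years]
        ),
        sca_by_year=draw(
            config.var_sca_by_year,
            [(f, m, y) for (f, m) in crosses for y in years],
        ),
    )

    rows = []
    for (f, m) in crosses:
        for y in years:
            sd_e = np.sqrt(config.resid_var_by_year[y])
            for k in range(1, config.reps + 1):
                value = (
                    config.mu
                    + eff.year[y]
                    + eff.rep_in_year[(y, k)]
                    + eff.gca_f[f]
                    + eff.gca_m[m]
                    + eff.sca[(f, m)]
                    + eff.gca_f_by_year[(f, y)]
                    + eff.gca_m_by_year[(m, y)]
                    + eff.sca_by_year[(f, m, y)]
                    + rng_eff.normal(0.0, sd_e)
                )
                rows.append(
                    (
                        _cross_token(f, m),
                        "hybrid",
                        f,
                        m,
                        y,
                        k,
                        config.trait,
                        max(value, 0.0),
                    )
                )
    if config.include_parents:
        # Convention: parental genotypic value is twice the line's own GCA.
        own_gca = {**eff.gca_f, **eff.gca_m}
        for p in design.parents:
            for y in years:
                sd_e = np.sqrt(config.resid_var_by_year[y])
                for k in range(1, config.reps + 1):
                    value = (
                        config.mu
                        + eff.year[y]
                        + eff.rep_in_year[(y, k)]
                        + 2.0 * own_gca[p]
                        + rng_eff.normal(0.0, sd_e)
                    )
                    rows.append(
                        (p, "parent", None, None, y, k, config.trait, max(value, 0.0))
                    )
    frame = pd.DataFrame(
        rows,
        columns=["genotype", "generation", "female", "male", "year", "rep", "trait", "value"],
    )
    return PhenotypeTable(frame), eff


def parameter_recovery(
    config: SimulationConfig,
    design: MatingDesign | None,
    n_sims: int,
    fitter: Callable | None = None,
    model: str = "model5",
) -> pd.DataFrame:
    """Monte-Carlo recovery of variance components.

    Simulates ``n_sims`` datasets from ``config``, fits the requested
    combining-ability model to each, and summarizes the estimates against
    the generating truth (mean estimate, bias, RMSE, convergence count).

    ``fitter(table, model_name, trait, year)`` must return an object with a
    ``variance_components`` mapping and a ``converged`` flag; by default the
    package's own REML engine is used.
    """
    from .reml import fit_reml

    if fitter is None:
        def fitter(table, model_name, trait, year):  # noqa: ANN001
            return fit_reml(table, model_name, trait=trait, year=year)

    truth = {
        "gca_f": config.var_gca_f,
        "gca_m": config.var_gca_m,
        "sca": config.var_sca,
    }
    if model == "model6":
        truth.update(
            {
                "gca_f_x_year": config.var_gca_f_by_year,
                "gca_m_x_year": config.var_gca_m_by_year,
                "sca_x_year": config.var_sca_by_year,
            }
        )
        year = None
    else:
        year = config.years[0]
    truth["residual"] = config.resid_var_by_year[config.years[0]]

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]
    estimates: dict[str, list[float]] = {k: [] for k in truth}
    n_converged = 0
    for s in child_seeds:
        cfg = SimulationConfig.from_dict({**config.to_dict(), "seed": s})
        table, _ = simulate_ncii(cfg, design)
        fit = fitter(table, model, cfg.trait, year)
        if getattr(fit, "converged", True):
            n_converged += 1
        comps = dict(fit.variance_components)
        if model == "model6":
            comps["residual"] = fit.residual_variances[config.years[0]]
        else:
            comps["residual"] = fit.residual_variances["pooled"]
        for k in truth:
            estimates[k].append(float(comps[k]))

    rows = []
    for k, t in truth.items():
        est = np.asarray(estimates[k])
        rows.append(
            {
                "component": k,
                "truth": t,
                "mean_estimate": est.mean(),
                "bias": est.mean() - t,
                "rmse": float(np.sqrt(np.mean((est - t) ** 2))),
                "n_sims": n_sims,
                "n_converged": n_converged,
            }
        )
    return pd.DataFrame(rows).set_index("component")
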