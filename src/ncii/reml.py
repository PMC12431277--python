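"""REML variance components and BLUPs for NC II mixed models.

The model is the standard Gaussian variance-components mixed model

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, sigma_i^2 I),
    e ~ N(0, R),  R = diag(sigma_e^2) or diag(sigma_{e,j}^2) per year,

with an intercept-only fixed part.  Four named specifications cover the
analyses of a two-year NC design II trial:

``model1``   replicate + genotype, single residual (one population, one year)
``model3``   year + rep-in-year + genotype + genotype x year, per-year residuals
``model5``   female GCA + male GCA + SCA + replicate, single residual (hybrids, one year)
``model6``   the across-year combining-ability model: rep-in-year + year +
             female GCA + male GCA + SCA + all three x-year interactions,
             per-year residuals.

Estimation maximizes the restricted likelihood with average-information
(AI) updates after a few expectation-maximization warm-up steps; variance
components are constrained to be nonnegative, and components driven to the
boundary are fixed at zero (they may re-enter if their score turns
positive).  The problem sizes of this design (n <= a few hundred) allow a
dense formulation of V = sum_i sigma_i^2 Z_i Z_i' + R, which keeps the
implementation short and transparent; the restricted log-likelihood is

    l_R = -1/2 [ (n - p) log 2 pi + log|V| + log|X'V^-1 X| + y'Py ],
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X' V^-1.

BLUPs and their prediction-error variances come from the same P matrix:
u_hat_i = sigma_i^2 Z_i' P y and PEV = sigma_i^2 - sigma_i^4 diag(Z_i'PZ_i),
which is Henderson's mixed-model-equation solution written in V-form.
Approximate standard errors of the components are square roots of the
diagonal of the inverse AI matrix at the optimum (one-sided at a boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from ._util import stars
from .data import PhenotypeTable
from .errors import FitError, InsufficientDataError, ValidationError

__all__ = [
    "ModelSpec",
    "NCIIModel",
    "REMLResults",
    "LRTResult",
    "fit_reml",
    "lrt_variance",
    "blup_ttest",
]

# factor definitions: term name -> columns of the phenotype frame whose
# tuple defines the grouping level
_TERM_FACTORS: dict[str, tuple[str, ...]] = {
    "replicate": ("rep",),
    "year": ("year",),
    "rep_in_year": ("year", "rep"),
    "genotype": ("genotype",),
    "genotype_x_year": ("genotype", "year"),
    "gca_f": ("female",),
    "gca_m": ("male",),
    "sca": ("female", "male"),
    "gca_f_x_year": ("female", "year"),
    "gca_m_x_year": ("male", "year"),
    "sca_x_year": ("female", "male", "year"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four named mixed-model specifications."""

    name: str
    random_terms: tuple[str, ...]
    per_year_residual: bool
    hybrids_only: bool
    single_year: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = name.lower().replace(" ", "")
        table = {
            "model1": cls(
                "model1", ("replicate", "genotype"), False, False, True
            ),
            "model3": cls(
                "model3",
                ("year", "rep_in_year", "genotype", "genotype_x_year"),
                True,
                False,
                False,
            ),
            "model5": cls(
                "model5", ("gca_f", "gca_m", "sca", "replicate"), False, True, True
            ),
            "model6": cls(
                "model6",
                (
                    "rep_in_year",
                    "year",
                    "gca_f",
                    "gca_m",
                    "sca",
                    "gca_f_x_year",
                    "gca_m_x_year",
                    "sca_x_year",
                ),
                True,
                True,
                False,
            ),
        }
        if name not in table:
            raise ValidationError(
                f"unknown model {name!r}; expected model1/model3/model5/model6"
            )
        return table[name]


def _indicator(df: pd.DataFrame, cols: tuple[str, ...]) -> tuple[np.ndarray, list]:
    """0/1 design matrix for the interaction of ``cols``, plus level labels."""
    key = list(zip(*(df[c] for c in cols))) if len(cols) > 1 else list(df[cols[0]])
    codes, levels = pd.factorize(pd.Series(key), sort=True)
    Z = np.zeros((len(df), len(levels)))
    Z[np.arange(len(df)), codes] = 1.0
    return Z, list(levels)


class NCIIModel:
    """Variance-components mixed model for one trait of an NC II trial.

    Build with :meth:`from_table` (the usual route) or directly from a
    response vector and named random-effect design matrices.  ``fit``
    returns a :class:`REMLResults`.
    """

    def __init__(
        self,
        y: np.ndarray,
        random_design: Mapping[str, np.ndarray],
        levels: Mapping[str, Sequence],
        residual_groups: np.ndarray | None = None,
        spec: ModelSpec | None = None,
    ):
        self.y = np.asarray(y, float)
        n = len(self.y)
        if n < 2:
            raise InsufficientDataError("need at least 2 observations")
        self.terms = list(random_design)
        self.Z = {t: np.asarray(random_design[t], float) for t in self.terms}
        for t, Z in self.Z.items():
            if Z.shape[0] != n:
                raise FitError(f"design matrix for {t!r} has wrong row count")
        self.levels = {t: list(levels[t]) for t in self.terms}
        if residual_groups is None:
            self.resid_labels = ["pooled"]
            self._resid_masks = [np.ones(n, bool)]
        else:
            rg = np.asarray(residual_groups)
            labs = sorted(pd.unique(rg).tolist())
            self.resid_labels = labs
            self._resid_masks = [rg == g for g in labs]
        self.spec = spec
        self.X = np.ones((n, 1))
        self.nobs = n

    # -- construction from a phenotype table --------------------------
    @classmethod
    def from_table(
        cls,
        table: PhenotypeTable,
        spec: ModelSpec | str,
        trait: str,
        year: int | None = None,
        generation: str | None = None,
    ) -> "NCIIModel":
        if isinstance(spec, str):
            spec = ModelSpec.from_name(spec)
        if spec.hybrids_only:
            generation = "hybrid"
        df = table.subset(generation=generation, trait=trait, year=year)
        if df.empty:
            raise InsufficientDataError(
                f"no observations for trait={trait!r}, year={year}, "
                f"generation={generation!r}"
            )
        if generation is None and df["generation"].nunique() > 1:
            raise FitError(
                "table mixes parents and hybrids; pass generation='parent' "
                "or 'hybrid'"
            )
        if spec.single_year and df["year"].nunique() > 1:
            raise FitError(f"{spec.name} is a single-year model; pass year=")
        if not spec.single_year and df["year"].nunique() < 2:
            raise FitError(f"{spec.name} is an across-year model; need >= 2 years")
        random_design, levels = {}, {}
        for term in spec.random_terms:
            Z, levs = _indicator(df, _TERM_FACTORS[term])
            random_design[term] = Z
            levels[term] = levs
        resid_groups = df["year"].to_numpy() if spec.per_year_residual else None
        return cls(
            df["value"].to_numpy(float),
            random_design,
            levels,
            residual_groups=resid_groups,
            spec=spec,
        )

    # -- restricted likelihood machinery ------------------------------
    def _build_V(self, comp: np.ndarray, res: np.ndarray) -> np.ndarray:
        n = self.nobs
        V = np.zeros((n, n))
        for theta, t in zip(comp, self.terms):
            if theta > 0:
                Z = self.Z[t]
                V += theta * (Z @ Z.T)
        d = np.zeros(n)
        for sig, mask in zip(res, self._resid_masks):
            d[mask] = sig
        V[np.diag_indices(n)] += d
        return V

    def _reml_quantities(self, comp: np.ndarray, res: np.ndarray):
        """Return (loglik, P, Py) for the given components."""
        V = self._build_V(comp, res)
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by floors
            raise FitError(f"V not positive definite: {exc}") from exc
        logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
        Vinv = cho_solve(c, np.eye(self.nobs))
        ViX = Vinv @ self.X
        XtViX = self.X.T @ ViX
        s = float(XtViX[0, 0])
        P = Vinv - np.outer(ViX[:, 0], ViX[:, 0]) / s
        P = 0.5 * (P + P.T)
        Py = P @ self.y
        yPy = float(self.y @ Py)
        n, p = self.nobs, 1
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + np.log(s) + yPy)
        return ll, P, Py

    def loglike(self, components: Mapping[str, float], residuals: Mapping) -> float:
        """Restricted log-likelihood at the given variance parameters."""
        comp = np.array([components[t] for t in self.terms], float)
        res = np.array([residuals[g] for g in self.resid_labels], float)
        return self._reml_quantities(comp, res)[0]

    def _score_ai(self, comp, res, P, Py):
        """Score vector and average-information matrix over all parameters.

        Parameter order: random-term variances followed by residual-group
        variances.  For A_i = dV/dtheta_i,
        score_i = -1/2 (tr(P A_i) - y'P A_i P y) and
        AI_ij = 1/2 y'P A_i P A_j P y.
        """
        k, g = len(self.terms), len(self.resid_labels)
        m = k + g
        score = np.zeros(m)
        vvecs = []  # A_i @ Py for the AI matrix
        for i, t in enumerate(self.terms):
            Z = self.Z[t]
            PZ = P @ Z
            tr = float(np.einsum("ij,ij->", PZ, Z))
            v = Z @ (Z.T @ Py)
            score[i] = -0.5 * (tr - float(Py @ v))
            vvecs.append(v)
        diagP = np.diag(P)
        for j, mask in enumerate(self._resid_masks):
            tr = float(diagP[mask].sum())
            v = np.where(mask, Py, 0.0)
            score[k + j] = -0.5 * (tr - float(Py @ v))
            vvecs.append(v)
        W = np.column_stack(vvecs)  # n x m
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        AI = 0.5 * (AI + AI.T)
        return score, AI

    # -- the fitter ----------------------------------------------------
    def fit(
        self,
        maxiter: int = 200,
        tol_loglik: float = 1e-8,
        tol_param: float = 1e-6,
        n_em: int = 3,
        start: Mapping[str, float] | None = None,
    ) -> "REMLResults":
        """AI-REML with EM warm-up, nonnegativity and boundary fixing."""
        n = self.nobs
        k, g = len(self.terms), len(self.resid_labels)
        m = k + g
        vary = float(np.var(self.y, ddof=1)) if n > 1 else 0.0

        if vary == 0.0:
            # Degenerate constant response: everything at the boundary.
            return self._degenerate_results()

        floor = 1e-10 * vary
        qsizes = np.array(
            [self.Z[t].shape[1] for t in self.terms]
            + [int(mask.sum()) for mask in self._resid_masks],
            float,
        )
        theta = np.full(m, vary / m)
        if start is not None:
            for i, t in enumerate(self.terms):
                if t in start:
                    theta[i] = max(float(start[t]), 0.0)
        free = np.ones(m, bool)

        def unpack(th):
            return th[:k], np.maximum(th[k:], floor)

        ll, P, Py = self._reml_quantities(*unpack(theta))
        converged = False
        n_iter = 0
        for it in range(1, maxiter + 1):
            n_iter = it
            score, AI = self._score_ai(*unpack(theta), P, Py)

            # revive boundary components whose score points inward
            for i in range(m):
                if not free[i] and score[i] > 0:
                    free[i] = True
                    theta[i] = max(theta[i], 1e-6 * vary)

            idx = np.flatnonzero(free)
            use_em = it <= n_em
            delta = np.zeros(m)
            if not use_em:
                A = AI[np.ix_(idx, idx)]
                try:
                    d = np.linalg.solve(A + 1e-12 * vary * np.eye(len(idx)), score[idx])
                    delta[idx] = d
                except np.linalg.LinAlgError:
                    use_em = True
            if use_em:
                # EM update written as a scaled-gradient step:
                # theta_new = theta + 2 theta^2 / q * score
                delta[idx] = 2.0 * theta[idx] ** 2 / qsizes[idx] * score[idx]

            # step halving onto the feasible region, requiring non-decrease
            accepted = False
            step = 1.0
            for _ in range(30):
                cand = theta.copy()
                cand[idx] = theta[idx] + step * delta[idx]
                cand = np.maximum(cand, 0.0)
                cand[k:] = np.maximum(cand[k:], floor)
                ll_new, P_new, Py_new = self._reml_quantities(*unpack(cand))
                if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # fall back to a damped EM step, which cannot decrease ll
                cand = theta.copy()
                cand[idx] = theta[idx] + 2.0 * theta[idx] ** 2 / qsizes[idx] * score[idx]
                cand = np.maximum(cand, 0.0)
                cand[k:] = np.maximum(cand[k:], floor)
                ll_new, P_new, Py_new = self._reml_quantities(*unpack(cand))

            dpar = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-3 * vary))
            dll = abs(ll_new - ll) / max(1.0, abs(ll))
            theta, ll, P, Py = cand, ll_new, P_new, Py_new

            # boundary fixing
            for i in range(k):  # random terms only; residuals stay floored
                if free[i] and theta[i] < 1e-8 * vary:
                    theta[i] = 0.0
                    free[i] = False

            if dll < tol_loglik and dpar < tol_param:
                converged = True
                break

        comp, res = unpack(theta)
        score, AI = self._score_ai(comp, res, P, Py)
        se = np.zeros(m)
        idx = np.flatnonzero(theta > 0)
        if idx.size:
            try:
                cov = np.linalg.inv(AI[np.ix_(idx, idx)])
                se[idx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
            except np.linalg.LinAlgError:
                se[idx] = np.nan

        return self._package(comp, res, se, ll, P, Py, converged, n_iter)

    # -- assembling results -------------------------------------------
    def _mu_hat(self, P_unused, comp, res):
        V = self._build_V(comp, res)
        c = cho_factor(V, lower=True)
        ViX = cho_solve(c, self.X)
        s = float((self.X.T @ ViX)[0, 0])
        Viy = cho_solve(c, self.y)
        mu = float(self.X[:, 0] @ Viy) / s
        return mu, np.sqrt(1.0 / s)

    def _package(self, comp, res, se, ll, P, Py, converged, n_iter):
        k = len(self.terms)
        mu, mu_se = self._mu_hat(P, comp, res)
        blups, pevs = {}, {}
        for i, t in enumerate(self.terms):
            if comp[i] <= 0:
                continue
            Z = self.Z[t]
            u = comp[i] * (Z.T @ Py)
            dZPZ = np.einsum("ij,ij->j", Z, P @ Z)
            pev = comp[i] - comp[i] ** 2 * dZPZ
            pev = np.maximum(pev, 1e-12 * comp[i])
            labels = [
                lv if not isinstance(lv, tuple) else "|".join(map(str, lv))
                for lv in self.levels[t]
            ]
            blups[t] = pd.Series(u, index=labels, name=t)
            pevs[t] = pd.Series(pev, index=labels, name=t)
        return REMLResults(
            model=self,
            mu=mu,
            mu_se=mu_se,
            variance_components=dict(zip(self.terms, comp.tolist())),
            component_se=dict(zip(self.terms, se[:k].tolist())),
            residual_variances=dict(zip(self.resid_labels, res.tolist())),
            residual_se=dict(zip(self.resid_labels, se[k:].tolist())),
            blups=blups,
            pev=pevs,
            llf=float(ll),
            converged=bool(converged),
            n_iter=int(n_iter),
        )

    def _degenerate_results(self) -> "REMLResults":
        k = len(self.terms)
        return REMLResults(
            model=self,
            mu=float(self.y[0]),
            mu_se=0.0,
            variance_components={t: 0.0 for t in self.terms},
            component_se={t: 0.0 for t in self.terms},
            residual_variances={g: 0.0 for g in self.resid_labels},
            residual_se={g: 0.0 for g in self.resid_labels},
            blups={},
            pev={},
            llf=np.inf,
            converged=True,
            n_iter=0,
        )


@dataclass(frozen=True)
class LRTResult:
    """Boundary likelihood-ratio test for one variance component."""

    term: str
    statistic: float
    p: float

    @property
    def stars(self) -> str:
        return stars(self.p)


@dataclass
class REMLResults:
    """Fitted variance components, BLUPs and diagnostics."""

    model: NCIIModel
    mu: float
    mu_se: float
    variance_components: dict[str, float]
    component_se: dict[str, float]
    residual_variances: dict
    residual_se: dict
    blups: dict[str, pd.Series]
    pev: dict[str, pd.Series]
    llf: float
    converged: bool
    n_iter: int

    @property
    def spec_name(self) -> str:
        return self.model.spec.name if self.model.spec else "custom"

    # -- derived quantities -------------------------------------------
    def adjusted_means(self, term: str) -> pd.Series:
        """Level means mu_hat + BLUP(level) for a genotype-like term."""
        if term not in self.blups:
            raise ValidationError(
                f"term {term!r} has no BLUPs in this fit "
                f"(available: {sorted(self.blups)})"
            )
        return self.mu + self.blups[term]

    def blup_tests(self, term: str) -> pd.DataFrame:
        """Two-tailed significance of every BLUP of ``term`` (t = u/sqrt(PEV))."""
        if term not in self.blups:
            raise ValidationError(f"term {term!r} has no BLUPs in this fit")
        rows = []
        for level in self.blups[term].index:
            u = float(self.blups[term][level])
            pev = float(self.pev[term][level])
            t, p, s = blup_ttest(u, pev)
            rows.append({"level": level, "blup": u, "pev": pev, "t": t, "p": p, "stars": s})
        return pd.DataFrame(rows).set_index("level")

    def lrt(self, reduced: "REMLResults") -> LRTResult:
        return lrt_variance(self, reduced)

    def components_frame(self) -> pd.DataFrame:
        """Tidy components table (estimate, approximate SE)."""
        rows = [
            {"term": t, "estimate": v, "se": self.component_se[t]}
            for t, v in self.variance_components.items()
        ]
        for gname, v in self.residual_variances.items():
            label = "residual" if gname == "pooled" else f"residual[{gname}]"
            rows.append({"term": label, "estimate": v, "se": self.residual_se[gname]})
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        lines = [
            f"REML fit: {self.spec_name}  (n = {self.model.nobs})",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            f"  REML log-likelihood: {self.llf:.6g}",
            f"  mu_hat = {self.mu:.6g} (SE {self.mu_se:.3g})",
            "  variance components (estimate +/- SE):",
        ]
        for _, row in self.components_frame().iterrows():
            lines.append(f"    {row.name:<18s} {row['estimate']:>12.5g} +/- {row['se']:.4g}")
        return "\n".join(lines)


def fit_reml(
    table: PhenotypeTable,
    spec: ModelSpec | str,
    trait: str,
    year: int | None = None,
    generation: str | None = None,
    **options,
) -> REMLResults:
    """Fit one of the named models to one trait; see :class:`NCIIModel`."""
    model = NCIIModel.from_table(table, spec, trait, year=year, generation=generation)
    return model.fit(**options)


def lrt_variance(full: REMLResults, reduced: REMLResults) -> LRTResult:
    """Likelihood-ratio test for the single component dropped in ``reduced``.

    The null distribution for one variance on the boundary is the mixture
    1/2 chi2_0 + 1/2 chi2_1, so p = 1/2 P(chi2_1 >= LR) for LR > 0 and 1
    when LR = 0.
    """
    t_full = set(full.variance_components)
    t_red = set(reduced.variance_components)
    dropped = t_full - t_red
    if len(dropped) != 1 or not t_red < t_full:
        raise ValidationError(
            "reduced model must nest the full model with exactly one fewer "
            f"variance component (full {sorted(t_full)}, reduced {sorted(t_red)})"
        )
    if full.model.nobs != reduced.model.nobs:
        raise ValidationError("LRT requires the same data in both fits")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return LRTResult(term=dropped.pop(), statistic=stat, p=p)


def blup_ttest(blup: float, pev: float) -> tuple[float, float, str]:
    """Two-tailed test of a BLUP against zero using its PEV.

    t = blup / sqrt(PEV); p from the standard normal reference (residual
    degrees of freedom in these trials are in the hundreds).
    """
    if pev <= 0:
        raise ValidationError(f"PEV must be > 0, got {pev}")
    t = blup / np.sqrt(pev)
    p = 2.0 * float(stats.norm.sf(abs(t)))
    return float(t), p, stars(p)
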