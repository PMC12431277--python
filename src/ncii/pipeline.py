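"""End-to-end orchestration: QC -> fits -> summaries -> reports.

The pipeline runs the full analysis of an NC II trial: outlier screening,
per-year model-1 (both populations) and model-5 (hybrids) fits, across-year
model-3 and model-6 fits, the derived quantitative-genetics summaries,
combining-ability and heterosis tables, and the Spearman association
panels.  Every product is written as CSV/JSON with a stable schema and the
run is recorded in a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .assoc import correlation_panel, mineral_correlation_matrix, sgca_series
from .data import (
    PhenotypeTable,
    compare_populations,
    descriptive_stats,
    flag_outliers,
    read_phenotype_table,
    validate_design,
)
from .errors import NCIIError, PipelineError, ValidationError
from .heterosis import (
    build_heterosis_table,
    combining_ability_tables,
    pooled_heterosis_range,
)
from .quantgen import summarize_hybrids, summarize_parents, summary_frame
from .reml import fit_reml
from .simulate import SimulationConfig, simulate_ncii

log = logging.getLogger("ncii")


@dataclass
class PipelineConfig:
    """Run configuration; either ``input`` (CSV path) or ``simulate``."""

    input: str | None = None
    schema: dict[str, str] | None = None
    simulate: SimulationConfig | None = None
    traits: list[str] | None = None
    qc: bool = True
    qc_alpha: float = 0.05
    fit_options: dict[str, Any] = field(default_factory=dict)
    outdir: str = "ncii-output"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise PipelineError("exactly one of input/simulate must be given")
        if not 0 < self.qc_alpha < 1:
            raise PipelineError(f"qc_alpha must be in (0,1), got {self.qc_alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        return cls(simulate=sim, **raw)


def _load(config: PipelineConfig) -> PhenotypeTable:
    if config.simulate is not None:
        sim = SimulationConfig.from_dict(
            {**config.simulate.to_dict(), "seed": config.seed}
        )
        table, _ = simulate_ncii(sim)
        return table
    return read_phenotype_table(config.input, schema=config.schema)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": [],
        "warnings": [],
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        manifest["stages"].append({"name": name, "t0": t0})
        return t0

    def done(t0):
        manifest["stages"][-1]["seconds"] = round(time.perf_counter() - t0, 3)

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, index=index)
        manifest["outputs"].append(name)

    try:
        t0 = stage("load")
        table = _load(config)
        traits = config.traits or list(table.traits)
        design = validate_design(table)
        done(t0)

        if config.qc:
            t0 = stage("qc")
            report = flag_outliers(table, alpha=config.qc_alpha)
            emit(report.flags, "qc_flags.csv", index=False)
            if report.n_flagged:
                try:
                    table = table.drop_rows(report.flags["row"])
                    manifest["warnings"].append(
                        f"dropped {report.n_flagged} flagged observations"
                    )
                except ValidationError as exc:
                    # e.g. every observation of a parent flagged on a tiny
                    # trial; keep the data rather than break referential
                    # structure
                    manifest["warnings"].append(
                        f"kept flagged observations ({exc})"
                    )
            done(t0)

        t0 = stage("describe")
        emit(descriptive_stats(table), "descriptive_stats.csv")
        comps = []
        for trait in traits:
            try:
                c = compare_populations(table, trait)
                comps.append(
                    {"trait": trait, "test": c.test, "statistic": c.statistic,
                     "p": c.p, "stars": c.stars}
                )
            except NCIIError as exc:
                manifest["warnings"].append(f"compare {trait}: {exc}")
        if comps:
            emit(pd.DataFrame(comps), "population_comparison.csv", index=False)
        done(t0)

        t0 = stage("fit")
        years = list(table.years)
        has_parents = not table.parents.empty
        fits: dict[tuple, Any] = {}
        for trait in traits:
            for year in years:
                fits[("m1h", trait, year)] = fit_reml(
                    table, "model1", trait, year=year, generation="hybrid",
                    **config.fit_options
                )
                if has_parents:
                    fits[("m1p", trait, year)] = fit_reml(
                        table, "model1", trait, year=year, generation="parent",
                        **config.fit_options
                    )
                fits[("m5", trait, year)] = fit_reml(
                    table, "model5", trait, year=year, **config.fit_options
                )
            if len(years) > 1:
                fits[("m3h", trait)] = fit_reml(
                    table, "model3", trait, generation="hybrid", **config.fit_options
                )
                if has_parents:
                    fits[("m3p", trait)] = fit_reml(
                        table, "model3", trait, generation="parent",
                        **config.fit_options
                    )
                fits[("m6", trait)] = fit_reml(
                    table, "model6", trait, **config.fit_options
                )
        comp_rows = []
        for key, fit in fits.items():
            if not fit.converged:
                manifest["warnings"].append(f"fit {key} did not converge")
            df = fit.components_frame().reset_index()
            df.insert(0, "fit", "/".join(map(str, key)))
            comp_rows.append(df)
        emit(pd.concat(comp_rows, ignore_index=True), "variance_components.csv",
             index=False)
        done(t0)

        t0 = stage("summarize")
        summaries = []
        for trait in traits:
            for year in years:
                m5 = fits[("m5", trait, year)]
                m1h = fits[("m1h", trait, year)]
                vc = m5.variance_components
                summaries.append(
                    summarize_hybrids(
                        trait,
                        year,
                        vc.get("gca_f", 0.0),
                        vc.get("gca_m", 0.0),
                        vc.get("sca", 0.0),
                        m5.residual_variances["pooled"],
                        m1h.variance_components.get("genotype", 0.0),
                        m1h.residual_variances["pooled"],
                        mean=float(
                            table.subset("hybrid", trait, year)["value"].mean()
                        ),
                        r=int(table.subset("hybrid", trait, year)["rep"].nunique()),
                    )
                )
                if has_parents:
                    m1p = fits[("m1p", trait, year)]
                    summaries.append(
                        summarize_parents(
                            trait,
                            year,
                            m1p.variance_components.get("genotype", 0.0),
                            m1p.residual_variances["pooled"],
                            mean=float(
                                table.subset("parent", trait, year)["value"].mean()
                            ),
                            r=int(table.subset("parent", trait, year)["rep"].nunique()),
                        )
                    )
        emit(summary_frame(summaries), "genetic_summary.csv")
        done(t0)

        t0 = stage("heterosis")
        het_tables = {}
        ca_rows = []
        panel_rows = []
        het_frames = []
        sca_wide: dict[tuple, dict] = {}
        mph_wide: dict[tuple, dict] = {}
        for trait in traits:
            for year in years:
                m5 = fits[("m5", trait, year)]
                try:
                    ca = combining_ability_tables(m5, trait=trait, year=year)
                    for sex, df in (("female", ca.females), ("male", ca.males)):
                        d = df.reset_index()
                        d.insert(0, "sex", sex)
                        d.insert(0, "year", year)
                        d.insert(0, "trait", trait)
                        ca_rows.append(d)
                except NCIIError as exc:
                    manifest["warnings"].append(f"CA {trait}/{year}: {exc}")

                if not has_parents:
                    continue
                m1h = fits[("m1h", trait, year)]
                m1p = fits[("m1p", trait, year)]
                if "genotype" not in m1h.blups or "genotype" not in m1p.blups:
                    manifest["warnings"].append(
                        f"heterosis {trait}/{year}: zero genotypic variance"
                    )
                    continue
                hyb_rows = table.subset("hybrid", trait, year)
                key_of = dict(
                    zip(hyb_rows["genotype"], zip(hyb_rows["female"], hyb_rows["male"]))
                )
                hyb_means = {
                    key_of[g]: v
                    for g, v in m1h.adjusted_means("genotype").items()
                    if g in key_of
                }
                par_means = dict(m1p.adjusted_means("genotype"))
                het = build_heterosis_table(
                    par_means, hyb_means, design, trait=trait, year=year
                )
                het_tables[(trait, year)] = het
                het_frames.append(het.frame)

                # association panel inputs
                gca_f = m5.blups.get("gca_f", pd.Series(dtype=float))
                gca_m = m5.blups.get("gca_m", pd.Series(dtype=float))
                gca_parent = pd.concat([gca_f, gca_m])
                per_se = pd.Series(par_means).reindex(gca_parent.index).dropna()
                crosses = list(zip(het.frame["female"], het.frame["male"]))
                ckeys = [f"{f}|{m}" for f, m in crosses]
                f1 = pd.Series(het.frame["f1"].to_numpy(), index=ckeys)
                mph = pd.Series(het.frame["mph"].to_numpy(), index=ckeys)
                bph = pd.Series(het.frame["bph"].to_numpy(), index=ckeys)
                sca = m5.blups.get("sca")
                series = {
                    "per_se": per_se,
                    "gca": gca_parent.reindex(per_se.index),
                    "f1": f1,
                    "mph": mph,
                    "bph": bph,
                }
                if sca is not None:
                    series["sca"] = sca.reindex(ckeys).dropna()
                    series["f1"] = f1.reindex(series["sca"].index)
                    series["mph"] = mph.reindex(series["sca"].index)
                    series["bph"] = bph.reindex(series["sca"].index)
                    for (f, m), s in zip(crosses, sca.reindex(ckeys)):
                        sca_wide.setdefault((f, m, year), {})[trait] = s
                series["sgca"] = sgca_series(gca_f, gca_m, crosses).reindex(
                    series["f1"].index
                )
                panel_rows.append(correlation_panel(series, trait=trait, year=year))
                for (f, m), v in zip(crosses, het.frame["mph"]):
                    mph_wide.setdefault((f, m, year), {})[trait] = v

        if ca_rows:
            emit(pd.concat(ca_rows, ignore_index=True), "combining_ability.csv",
                 index=False)
        if het_frames:
            all_het = pd.concat(het_frames, ignore_index=True)
            emit(all_het, "heterosis.csv", index=False)
            lo, hi = pooled_heterosis_range(het_tables.values())
            manifest["pooled_heterosis_range_pct"] = [lo, hi]
        done(t0)

        t0 = stage("correlate")
        if panel_rows:
            emit(pd.concat(panel_rows, ignore_index=True),
                 "correlation_panels.csv", index=False)
        # trait x trait matrices over per-se values, SCA effects and MPH
        for pop in ("parent", "hybrid"):
            sub = table.subset(pop)
            if sub.empty or sub["trait"].nunique() < 2:
                continue
            wide = sub.pivot_table(
                index="genotype", columns="trait", values="value", aggfunc="mean"
            )
            rho, _ = mineral_correlation_matrix(wide)
            emit(rho, f"mineral_correlations_{pop}.csv")
        for label, store in (("sca", sca_wide), ("mph", mph_wide)):
            if store and len({t for d in store.values() for t in d}) >= 2:
                wide = pd.DataFrame.from_dict(store, orient="index")
                rho, _ = mineral_correlation_matrix(wide)
                emit(rho, f"mineral_correlations_{label}.csv")
        done(t0)

        t0 = stage("report")
        write_report(
            {
                "fits": fits,
                "het_tables": het_tables,
                "traits": traits,
                "years": years,
            },
            outdir,
            manifest,
        )
        done(t0)
    except NCIIError as exc:
        manifest["failed_stage"] = manifest["stages"][-1]["name"] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise PipelineError(f"stage {manifest['failed_stage']} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def write_report(results: dict, outdir: str | Path, manifest: dict | None = None) -> list[str]:
    """Write the plain-text summary: top-5 GCA parents and SCA crosses per trait."""
    outdir = Path(outdir)
    if not results or not results.get("fits"):
        raise PipelineError("empty results; nothing to report")
    lines = ["NC II analysis summary", "======================", ""]
    fits = results["fits"]
    for trait in results["traits"]:
        for year in results["years"]:
            key = ("m5", trait, year)
            if key not in fits:
                continue
            fit = fits[key]
            lines.append(f"[{trait} {year}]")
            for term, label in (("gca_f", "top female GCA"),
                                ("gca_m", "top male GCA"),
                                ("sca", "top SCA crosses")):
                if term not in fit.blups:
                    continue
                top = fit.blups[term].sort_values(ascending=False).head(5)
                pretty = ", ".join(f"{i}={v:.3g}" for i, v in top.items())
                lines.append(f"  {label}: {pretty}")
            lines.append("")
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines))
    if manifest is not None:
        manifest["outputs"].append("summary.txt")
    return ["summary.txt"]
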