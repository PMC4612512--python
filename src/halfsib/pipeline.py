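"""End-to-end pipeline: simulate → prepare → fit → parameters → correlations.

Everything is driven by a single YAML config and a single seed, producing a
publication-shaped parameter table (one row per trait), a test-statistics
table, a genetic-correlation report and a machine-readable run manifest.
Given the same config and seed the numeric outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal import build_A_matrix, fit_bivariate_animal_model
from .params import GeneticParameterSet, estimate_genetic_parameters
from .prep import analysis_frame, derive_traits, filter_analysis_subset
from .reml import ModelSpec, TestResult, fit_nested_lmm, lrt_random_effect, select_minimal_model, wald_test
from .simulate import (
    SimulationConfig,
    read_pedigree,
    read_phenotypes,
    simulate_dataset,
    write_pedigree,
    write_phenotypes,
)

__all__ = ["PipelineConfig", "TraitConfig", "run_pipeline", "render_table1", "parse_table1"]

log = logging.getLogger("halfsib")

DEFAULT_TRAITS: dict[str, dict] = {
    "longevity": {
        "candidates": ["lifetime_matings", "start_date", "body_size"],
        "test_transform": "none",
    },
    "early_life_matings": {
        "candidates": ["longevity", "start_date", "body_size"],
        "test_transform": "log1p",
    },
}
DEFAULT_CORRELATIONS = [
    ["longevity", "early_life_matings"],
    ["early_life_matings", "later_life_matings"],
]


@dataclass
class TraitConfig:
    name: str
    candidates: tuple[str, ...]
    test_transform: str = "none"


@dataclass
class PipelineConfig:
    """Top-level run configuration (usually read from YAML)."""

    seed: int = 0
    out_dir: Path = Path("halfsib_out")
    simulation: SimulationConfig | None = None
    phenotypes_path: Path | None = None
    pedigree_path: Path | None = None
    traits: list[TraitConfig] = field(default_factory=list)
    correlations: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    jackknife: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        traits_cfg = d.get("traits") or DEFAULT_TRAITS
        traits = [
            TraitConfig(
                name=name,
                candidates=tuple(tc.get("candidates", [])),
                test_transform=tc.get("test_transform", "none"),
            )
            for name, tc in traits_cfg.items()
        ]
        sim = None
        if "input" not in d:
            sim_kwargs = dict(d.get("simulation", {}))
            if "G" in sim_kwargs:
                sim_kwargs["G"] = np.asarray(sim_kwargs["G"], dtype=float)
            for key in ("V_dam", "V_resid", "trait_means", "opportunity_schedule"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_kwargs.setdefault("seed", d.get("seed", 0))
            sim = SimulationConfig(**sim_kwargs)
        inp = d.get("input", {})
        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=Path(d.get("out_dir", "halfsib_out")),
            simulation=sim,
            phenotypes_path=Path(inp["phenotypes"]) if "phenotypes" in inp else None,
            pedigree_path=Path(inp["pedigree"]) if "pedigree" in inp else None,
            traits=traits,
            correlations=[tuple(c) for c in d.get("correlations", DEFAULT_CORRELATIONS)],
            alpha=float(d.get("alpha", 0.05)),
            jackknife=bool(d.get("jackknife", True)),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"pipeline config not found: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def _cell(value: float, se: float | None) -> str:
    if se is None or not np.isfinite(se):
        return _fmt(value)
    return f"{_fmt(value)} ({_fmt(se)})"


def _fmt_p(p: float | None) -> str:
    if p is None:
        return ""
    return "<0.001*" if p < 0.001 else _fmt(p)


TABLE1_COLUMNS = [
    "Trait", "N", "Mean (SE)", "n sires", "n dams",
    "V_Sire (SE)", "V_Dam (SE)", "V_A (SE)", "V_P (SE)", "V_R (SE)",
    "h2 (SE)", "CV_A (SE)", "CV_P (SE)", "CV_R (SE)", "I_A (SE)",
    "P_Sire", "P_Dam",
]


def render_table1(
    params: list[GeneticParameterSet],
    tests: dict[str, dict[str, TestResult]] | None = None,
) -> str:
    """Render parameter sets as a tab-separated table in the journal layout.

    One row per trait with "value (SE)" cells at 3 decimals, followed by
    the sire and dam random-effect p-values.
    """
    lines = ["\t".join(TABLE1_COLUMNS)]
    for ps in params:
        se = ps.se
        p_sire = ps.p_sire
        p_dam = ps.p_dam
        if tests and ps.trait in tests:
            p_sire = tests[ps.trait].get("sire", TestResult(0, 1, np.nan, "lrt")).p_value
            p_dam = tests[ps.trait].get("dam", TestResult(0, 1, np.nan, "lrt")).p_value
        row = [
            ps.trait,
            str(ps.n_obs),
            _cell(ps["mean"], se.get("mean")),
            str(ps.n_sires),
            str(ps.n_dams),
            _cell(ps["V_sire"], se.get("V_sire")),
            _cell(ps["V_dam"], se.get("V_dam")),
            _cell(ps["V_A"], se.get("V_A")),
            _cell(ps["V_P"], se.get("V_P")),
            _cell(ps["V_R"], se.get("V_R")),
            _cell(ps["h2"], se.get("h2")),
            _cell(ps["CV_A"], se.get("CV_A")),
            _cell(ps["CV_P"], se.get("CV_P")),
            _cell(ps["CV_R"], se.get("CV_R")),
            _cell(ps["I_A"], se.get("I_A")),
            _fmt_p(p_sire),
            _fmt_p(p_dam),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_table1(text: str) -> pd.DataFrame:
    """Parse a rendered table back into numeric columns (inverse of render at 3 dp)."""
    rows = [line.split("\t") for line in text.strip().splitlines()]
    header, body = rows[0], rows[1:]
    records = []
    for row in body:
        rec: dict[str, Any] = {}
        for col, cell in zip(header, row):
            if col == "Trait":
                rec[col] = cell
            elif col in ("N", "n sires", "n dams"):
                rec[col] = int(cell)
            elif col.startswith("P_"):
                rec[col] = cell
            else:
                base = cell.split(" (")[0]
                rec[col.replace(" (SE)", "")] = float(base)
                if " (" in cell:
                    rec[col.replace(" (SE)", "") + "_se"] = float(cell.split(" (")[1].rstrip(")"))
        records.append(rec)
    return pd.DataFrame(records)


def _config_hash(cfg: PipelineConfig) -> str:
    payload = dict(cfg.raw)
    payload["seed"] = cfg.seed
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (parameter sets, test
    results, bivariate estimates, paths).  Any stage failure raises with a
    stage-labelled message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {"out_dir": out}

    # --- stage: data -------------------------------------------------------
    truth = None
    try:
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            pedigree, records, manifest = simulate_dataset(sim_cfg)
            truth = manifest.to_dict()["truth"]
            write_phenotypes(records, out / "phenotypes.csv")
            write_pedigree(pedigree, out / "pedigree.csv")
            with open(out / "truth.yaml", "w") as fh:
                yaml.safe_dump(manifest.to_dict(), fh, sort_keys=True)
        else:
            if config.phenotypes_path is None or not config.phenotypes_path.exists():
                raise FileNotFoundError(f"phenotype table not found: {config.phenotypes_path}")
            if config.pedigree_path is None or not config.pedigree_path.exists():
                raise FileNotFoundError(f"pedigree table not found: {config.pedigree_path}")
            records = read_phenotypes(config.phenotypes_path)
            pedigree = read_pedigree(config.pedigree_path)
    except Exception as exc:
        raise RuntimeError(f"[stage: data] {exc}") from exc

    # --- stage: prepare ----------------------------------------------------
    try:
        kept = filter_analysis_subset(records)
        log.info("prepare: %d records -> %d analysed after subsetting", len(records), len(kept))
        data = analysis_frame(derive_traits(kept))
        data.to_csv(out / "analysis_records.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage: prepare] {exc}") from exc
    results["n_raw"], results["n_analysed"] = len(records), len(data)

    # --- stage: fit + parameters ------------------------------------------
    param_sets: list[GeneticParameterSet] = []
    wald_rows, lrt_rows = [], []
    tests_by_trait: dict[str, dict[str, TestResult]] = {}
    minimal_specs: dict[str, ModelSpec] = {}
    try:
        for tc in config.traits:
            full_spec = ModelSpec(tc.name, tuple(tc.candidates), transform=tc.test_transform)
            full_fit = fit_nested_lmm(full_spec, data)
            for term in tc.candidates:
                w = wald_test(full_fit, term)
                wald_rows.append(
                    {"trait": tc.name, "term": term, "chi2": w.statistic, "df": w.df, "p": w.p_value}
                )
            minimal = select_minimal_model(full_spec, data, config.alpha)
            # genetic parameters are extracted from the untransformed minimal fit
            minimal_untr = dataclasses.replace(minimal, transform="none")
            minimal_specs[tc.name] = minimal_untr
            ps = estimate_genetic_parameters(data, minimal_untr, jackknife=config.jackknife)
            fit_min = fit_nested_lmm(minimal_untr, data)
            t: dict[str, TestResult] = {}
            for dropped in ("sire", "dam"):
                reduced_struct = tuple(x for x in ("sire", "dam") if x != dropped)
                reduced = fit_nested_lmm(
                    dataclasses.replace(minimal_untr, random_structure=reduced_struct), data
                )
                t[dropped] = lrt_random_effect(fit_min, reduced)
                lrt_rows.append(
                    {
                        "trait": tc.name, "component": dropped,
                        "chi2": t[dropped].statistic, "df": 1, "p": t[dropped].p_value,
                    }
                )
            tests_by_trait[tc.name] = t
            ps.p_sire, ps.p_dam = t["sire"].p_value, t["dam"].p_value
            param_sets.append(ps)
            log.info("fit: %s minimal fixed terms = %s", tc.name, minimal.fixed_terms)
    except Exception as exc:
        raise RuntimeError(f"[stage: fit] {exc}") from exc

    table1 = render_table1(param_sets, tests_by_trait)
    (out / "table1.tsv").write_text(table1)
    pd.DataFrame(wald_rows).round(6).to_csv(out / "wald_tests.tsv", sep="\t", index=False)
    pd.DataFrame(lrt_rows).round(6).to_csv(out / "lrt_tests.tsv", sep="\t", index=False)
    results["parameters"] = param_sets
    results["wald_tests"] = wald_rows
    results["lrt_tests"] = lrt_rows
    results["table1"] = table1

    # --- stage: correlations ----------------------------------------------
    biv_rows = []
    try:
        A_full = build_A_matrix(pedigree)
        A = A_full.submatrix(list(data["female_id"]))
        for t1, t2 in config.correlations:
            X1 = _design_for(minimal_specs.get(t1), data, exclude=t2)
            X2 = _design_for(minimal_specs.get(t2), data, exclude=t1)
            est = fit_bivariate_animal_model(
                data[t1].to_numpy(float), data[t2].to_numpy(float), X1, X2, A.A
            )
            biv_rows.append(
                {
                    "trait1": t1, "trait2": t2, "r_g": est.r_g, "se_r_g": est.se_r_g,
                    "V_A1": est.V_A1, "V_A2": est.V_A2, "cov_A": est.cov_A,
                    "converged": est.converged,
                }
            )
            log.info("corr: r_g(%s, %s) = %.3f (SE %.3f)", t1, t2, est.r_g, est.se_r_g)
    except Exception as exc:
        raise RuntimeError(f"[stage: correlations] {exc}") from exc
    pd.DataFrame(biv_rows).round(6).to_csv(out / "genetic_correlations.tsv", sep="\t", index=False)
    results["correlations"] = biv_rows

    # --- stage: manifest ---------------------------------------------------
    manifest_out: dict[str, Any] = {
        "package": "halfsib",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_records_raw": len(records),
        "n_records_analysed": int(len(data)),
    }
    if truth is not None:
        comparison = {"truth": truth, "estimates": {}}
        for ps in param_sets:
            comparison["estimates"][ps.trait] = {"h2": ps["h2"], "V_A": ps["V_A"]}
        if biv_rows:
            comparison["estimates"]["r_g"] = biv_rows[0]["r_g"]
        manifest_out["truth_vs_estimate"] = comparison
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest_out
    return results


def _design_for(spec: ModelSpec | None, data: pd.DataFrame, exclude: str | None = None):
    """Fixed-effect design matrix for a trait's minimal model (intercept first).

    A covariate that is itself the partner trait of the bivariate pair is
    excluded so the genetic covariance is not partialled out twice.
    """
    cols = [np.ones(len(data))]
    if spec is not None:
        for term in spec.fixed_terms:
            if term == exclude:
                continue
            cols.append(data[term].to_numpy(float))
    return np.column_stack(cols)
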