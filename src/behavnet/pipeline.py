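"""End-to-end orchestration: configuration, stage sequencing, reporting.

The analysis sequence mirrors the survey workflow: exclude -> code ->
describe -> correlate -> regress -> O/E -> network -> stability ->
communities. Every stochastic stage draws its seed deterministically from
the master seed and the stage name, so the consolidated JSON report is a
pure function of (input bytes, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import coding, communities, oe, stability, stats, synthetic
from ._utils import BEHAVIOR_NAMES, derive_seed, json_roundable
from .exceptions import BehavnetError, InputValidationError
from .ising import clustering_coefficient, elasso_fit, network_density, node_strength

__all__ = ["PipelineConfig", "run_pipeline", "validate_input", "write_report"]

ALL_STAGES = (
    "describe",
    "correlate",
    "regress",
    "oe",
    "network",
    "stability",
    "communities",
)

REPORT_VERSION = "1.0"


def _checked_fields(cls, data: dict, where: str) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InputValidationError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return data


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    input_path: str | None = None  # CSV; mutually exclusive with synthetic
    synthetic: dict | None = None  # kwargs for SyntheticConfig (minus seed)
    column_mapping: dict | None = None
    stages: tuple = ALL_STAGES
    seed: int = 0
    output_dir: str | None = None
    # statistical settings
    oe_method: str = "bootstrap"
    oe_bootstrap_B: int = 1000
    oe_level: float = 0.95
    oe_top_k: int = 10
    strata_column: str = "gender"
    gamma: float = 0.25
    rule: str = "AND"
    n_lambda: int = 100
    stability_B: int = 1000
    drop_fractions: tuple = stability.DEFAULT_DROP_FRACTIONS
    case_drop_B: int = 100
    weight_transform: str = "abs"
    resolution: float = 1.0

    def __post_init__(self):
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise InputValidationError(f"unknown stage(s): {sorted(bad)}")
        if self.input_path is None and self.synthetic is None:
            self.synthetic = {"n_records": 2000}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        _checked_fields(cls, data, "pipeline config")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "drop_fractions" in data:
            data["drop_fractions"] = tuple(data["drop_fractions"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["drop_fractions"] = list(self.drop_fractions)
        return out


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

_FIELD_DOMAINS = {
    "gender": coding.GENDER_VOCAB,
    "residence": coding.RESIDENCE_VOCAB,
    "co_residence": coding.CO_RESIDENCE_VOCAB,
    "economic_status": coding.ECONOMIC_VOCAB,
    "fruit_freq": coding.FREQ_VOCAB,
    "veg_freq": coding.FREQ_VOCAB,
    "smoking_now": coding.YESNO_VOCAB,
    "drinking_now": coding.YESNO_VOCAB,
    "regular_exercise": coding.YESNO_VOCAB,
    "qol_rating": coding.RATING_VOCAB,
    "health_rating": coding.RATING_VOCAB,
}

_NUMERIC_RANGES = {
    "age": (0, 130),
    "education_years": (0, 30),
    "sleep_hours": (0, 24),
}

REQUIRED_COLUMNS = tuple(coding.DEMOGRAPHIC_REQUIRED) + coding.BEHAVIOR_FIELDS


def validate_input(path, column_mapping: dict | None = None) -> dict:
    """Structural validation of an input CSV; never mutates the data.

    Returns ``{"structural_errors": [...], "field_errors": {field: count},
    "n_records": int, "ok": bool}``.
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"input file not found: {path}")
    report = {"structural_errors": [], "field_errors": {}, "n_records": 0, "ok": True}
    try:
        df = coding.read_survey_csv(path, column_mapping)
    except Exception as exc:  # malformed/empty CSV is a finding, not a crash
        report["structural_errors"].append(f"unreadable as CSV: {exc}")
        report["ok"] = False
        return report
    report["n_records"] = len(df)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        report["structural_errors"].append(f"missing required columns: {missing_cols}")
        report["ok"] = False
    for col, vocab in _FIELD_DOMAINS.items():
        if col not in df.columns:
            continue
        present = df[col].dropna().astype(str)
        present = present[present.str.strip() != ""]
        bad = int((~present.isin(vocab)).sum())
        if bad:
            report["field_errors"][col] = bad
    for col, (lo, hi) in _NUMERIC_RANGES.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        present = df[col].notna()
        bad = int(((vals < lo) | (vals > hi) | (vals.isna() & present)).sum())
        if bad:
            report["field_errors"][col] = report["field_errors"].get(col, 0) + bad
    if report["field_errors"]:
        report["ok"] = False
    return report


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _load_table(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return coding.read_survey_csv(config.input_path, config.column_mapping)
    syn_kwargs = dict(config.synthetic or {})
    syn_kwargs.setdefault("seed", derive_seed(config.seed, "simulate"))
    return synthetic.generate_survey_table(synthetic.SyntheticConfig(**syn_kwargs))


def _logistic_payload(res) -> dict:
    return {
        "terms": res.table.to_dict(orient="records"),
        "intercept_odds": res.intercept_odds,
        "intercept_ci": list(res.intercept_ci),
        "n_used": res.n_used,
        "n_dropped": res.n_dropped,
        "converged": res.converged,
        "iterations": res.iterations,
        "log_likelihood": res.log_likelihood,
    }


def _oe_records(ranked: pd.DataFrame, names) -> list:
    cols = ["rank", "pair", "behavior_a", "behavior_b", "oe", "ci_low", "ci_high",
            "n_ij", "joint_percent", "N"]
    return ranked[cols].to_dict(orient="records")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the consolidated report."""
    report: dict = {
        "version": REPORT_VERSION,
        "config": config.as_dict(),
        "seeds": {},
        "behavior_columns": list(BEHAVIOR_NAMES),
    }
    table = _load_table(config)
    kept, log = coding.apply_exclusions(table)
    report["exclusions"] = log.as_dict()
    matrix = coding.code_behaviors(kept)
    count_info = coding.behavior_count(matrix)
    counts = count_info["counts"]

    stages = set(config.stages)
    if "describe" in stages:
        report["prevalence"] = stats.prevalence(matrix).to_dict(orient="records")
        report["behavior_count"] = {
            "distribution": count_info["distribution"],
            "proportion_ge2": count_info["proportion_ge2"],
        }

    if "correlate" in stages:
        scores, n_dropped = coding.score_outcomes(kept)
        aligned = counts[matrix.index.get_indexer(scores.index)]
        corr = {}
        for outcome in ("qol_score", "health_score"):
            rho, p = stats.spearman_correlation(aligned, scores[outcome])
            corr[outcome] = {"rho": rho, "p_value": p, "n": int(len(scores))}
        corr["n_dropped_missing_ratings"] = n_dropped
        report["spearman"] = corr

    failures: dict = {}
    if "regress" in stages:
        try:
            res = stats.fit_cooccurrence_logistic(kept, counts >= 2)
        except BehavnetError as exc:
            failures["regress"] = str(exc)
            res = None
        if res is not None:
            report["logistic"] = _logistic_payload(res)

    if "oe" in stages:
        seed = derive_seed(config.seed, "oe")
        report["seeds"]["oe"] = seed
        full = oe.oe_table(
            matrix, level=config.oe_level, method=config.oe_method,
            B=config.oe_bootstrap_B, seed=seed,
        )
        ranked = oe.rank_combinations(full, top_k=config.oe_top_k)
        report["oe"] = {
            "method": config.oe_method,
            "B": config.oe_bootstrap_B,
            "level": config.oe_level,
            "all_pairs": full.to_dict(orient="records"),
            "ranked": _oe_records(ranked, BEHAVIOR_NAMES),
        }
        if config.strata_column and config.strata_column in kept.columns:
            strata = kept[config.strata_column].to_numpy()
            per_stratum = oe.stratified_oe(
                matrix, strata, level=config.oe_level, method=config.oe_method,
                B=config.oe_bootstrap_B, seed=derive_seed(config.seed, "oe-strata"),
                top_k=config.oe_top_k,
            )
            report["oe"]["strata"] = {
                lab: _oe_records(tbl, BEHAVIOR_NAMES) for lab, tbl in per_stratum.items()
            }

    fit = None
    if stages & {"network", "stability", "communities"}:
        fit = elasso_fit(matrix, gamma=config.gamma, rule=config.rule, n_lambda=config.n_lambda)

    if "network" in stages:
        strengths, mean_strength = node_strength(fit.W_hat)
        report["network"] = {
            "nodes": list(fit.node_names),
            "tau_hat": fit.tau_hat.tolist(),
            "W_hat": fit.W_hat.tolist(),
            "gamma": fit.gamma,
            "rule": fit.rule,
            "selected_lambda": fit.selected_lambda.tolist(),
            "metrics": {
                "density": network_density(fit.W_hat),
                "mean_strength": mean_strength,
                "node_strengths": strengths.tolist(),
                "clustering_coefficient": clustering_coefficient(fit.W_hat),
                "clustering_coefficient_barrat": clustering_coefficient(fit.W_hat, "barrat"),
            },
        }

    if "stability" in stages:
        seed = derive_seed(config.seed, "stability")
        report["seeds"]["stability"] = seed
        try:
            ci = stability.bootstrap_edge_ci(
                matrix, B=config.stability_B, seed=seed, gamma=config.gamma,
                rule=config.rule, n_lambda=config.n_lambda,
            )
            cd = stability.case_dropping_stability(
                matrix, drop_fractions=config.drop_fractions,
                B_per_fraction=config.case_drop_B,
                seed=derive_seed(config.seed, "case-dropping"),
                gamma=config.gamma, rule=config.rule, n_lambda=config.n_lambda,
            )
        except BehavnetError as exc:
            failures["stability"] = str(exc)
        else:
            report["stability"] = {
                "edge_ci": ci.to_dict(orient="records"),
                "case_dropping": cd.summary().to_dict(orient="records"),
                "cs_coefficient": cd.cs_coefficient,
            }

    if "communities" in stages:
        seed = derive_seed(config.seed, "communities")
        report["seeds"]["communities"] = seed
        try:
            part = communities.louvain(
                fit.W_hat, weight_transform=config.weight_transform,
                resolution=config.resolution, seed=seed,
            )
        except BehavnetError as exc:
            failures["communities"] = str(exc)
        else:
            report["communities"] = {
                "assignment": {fit.node_names[i]: c for i, c in part.assignment.items()},
                "modularity_q": part.modularity_q,
                "n_communities": part.n_communities,
                "resolution": part.resolution,
                "weight_transform": part.weight_transform,
            }

    if failures:
        report["stage_failures"] = failures

    if config.output_dir:
        _write_artifacts(report, matrix, fit, Path(config.output_dir))
    return json_roundable(report)


def write_report(report: dict, path) -> None:
    """Serialize the report with stable float formatting (12 s.f.)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(json_roundable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def network_to_graphml(W, node_names, path, partition: dict | None = None) -> None:
    """Export the weighted network as GraphML (community id as attribute)."""
    G = nx.Graph()
    for i, name in enumerate(node_names):
        attrs = {"community": int(partition[name])} if partition else {}
        G.add_node(name, **attrs)
    W = np.asarray(W)
    for i in range(len(node_names)):
        for j in range(i + 1, len(node_names)):
            if W[i, j] != 0:
                G.add_edge(node_names[i], node_names[j], weight=float(W[i, j]))
    nx.write_graphml(G, path)


def _write_artifacts(report: dict, matrix: pd.DataFrame, fit, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir / "report.json")
    matrix.to_csv(outdir / "behavior_matrix.csv", index=False)
    if "prevalence" in report:
        pd.DataFrame(report["prevalence"]).to_csv(outdir / "prevalence.csv", index=False)
    if "logistic" in report:
        pd.DataFrame(report["logistic"]["terms"]).to_csv(outdir / "logistic.csv", index=False)
    if "oe" in report:
        pd.DataFrame(report["oe"]["all_pairs"]).to_csv(outdir / "oe_pairs.csv", index=False)
        for lab, rows in report["oe"].get("strata", {}).items():
            pd.DataFrame(rows).to_csv(outdir / f"oe_{lab}.csv", index=False)
    if "stability" in report:
        pd.DataFrame(report["stability"]["edge_ci"]).to_csv(outdir / "edge_ci.csv", index=False)
        pd.DataFrame(report["stability"]["case_dropping"]).to_csv(
            outdir / "case_dropping.csv", index=False
        )
    if fit is not None and "network" in report:
        names = report["network"]["nodes"]
        edges = []
        W = fit.W_hat
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if W[i, j] != 0:
                    edges.append({"node_i": names[i], "node_j": names[j], "weight": W[i, j]})
        pd.DataFrame(edges, columns=["node_i", "node_j", "weight"]).to_csv(
            outdir / "edges.csv", index=False
        )
        partition = report.get("communities", {}).get("assignment")
        network_to_graphml(W, names, outdir / "network.graphml", partition)
    if "communities" in report:
        pd.DataFrame(
            list(report["communities"]["assignment"].items()),
            columns=["node", "community"],
        ).to_csv(outdir / "communities.csv", index=False)
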