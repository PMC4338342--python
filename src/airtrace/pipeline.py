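"""End-to-end orchestration: generate → filter → route → expose → stats.

``RunConfig`` collects file paths, the synthetic-city configuration, and
analysis options; the ``cmd_*`` functions implement the pipeline stages and
the :func:`cli` click group exposes them as subcommands.  All randomness is
seeded, all outputs are plain text (CSV/JSON), and a manifest with a config
hash accompanies every generation run, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import diary as diary_mod
from . import disparity, exposure, routing, synthetic_city
from .concentration import read_field, write_field
from .diary import AT_RESIDENCE, IN_TRAVEL, NONRESIDENTIAL

__all__ = [
    "RunConfig",
    "load_run_config",
    "cmd_generate",
    "cmd_filter",
    "cmd_route",
    "cmd_expose",
    "cmd_stats",
    "cmd_run",
    "cli",
]

log = logging.getLogger("airtrace")

EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


@dataclass
class RunConfig:
    output_dir: str = "airtrace_out"
    network_nodes: str | None = None
    network_links: str | None = None
    diaries: str | None = None
    field: str | None = None
    seed: int = 0
    city: synthetic_city.CityConfig = dc_field(
        default_factory=synthetic_city.CityConfig
    )
    alpha: float = 0.05
    interval_m: float = 100.0
    no2_fraction: float = 0.8
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.interval_m <= 0:
            raise ValueError("interval_m must be positive")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    city_doc = doc.pop("city", {})
    cfg = RunConfig(**doc)
    if city_doc:
        cfg.city = synthetic_city.CityConfig(**city_doc)
    cfg.city = dataclasses.replace(cfg.city, seed=cfg.seed)
    return cfg


def _config_hash(config: synthetic_city.CityConfig) -> str:
    doc = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(doc.encode()).hexdigest()


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_generate(cfg: RunConfig) -> dict:
    """Generate the synthetic city files into the output directory."""
    out = _outdir(cfg)
    city = dataclasses.replace(cfg.city, seed=cfg.seed)
    net = synthetic_city.generate_network(city)
    field = synthetic_city.generate_field(city, net)
    population = synthetic_city.generate_population(city, net, field)
    routing.write_network(net, out / "nodes.csv", out / "links.csv")
    write_field(field, out / "field.json")
    diary_mod.write_diaries(population, out / "diaries.csv")
    manifest = {
        "config_hash": _config_hash(city),
        "seed": cfg.seed,
        "n_person_days": len(population),
        "n_nodes": net.graph.number_of_nodes(),
        "n_links": net.graph.number_of_edges(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    log.info("generate: %d person-days, %d nodes, %d links",
             len(population), manifest["n_nodes"], manifest["n_links"])
    return manifest


def _inputs(cfg: RunConfig):
    out = Path(cfg.output_dir)
    nodes = cfg.network_nodes or out / "nodes.csv"
    links = cfg.network_links or out / "links.csv"
    diaries = cfg.diaries or out / "diaries.csv"
    field_path = cfg.field or out / "field.json"
    for p in (nodes, links, diaries, field_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"required input {p} does not exist")
    return nodes, links, diaries, field_path


def _load_and_filter(cfg: RunConfig):
    nodes, links, diaries_path, field_path = _inputs(cfg)
    net = routing.read_network(nodes, links)
    field = read_field(field_path)
    records, rejections = diary_mod.read_diaries(diaries_path)
    kept, excluded = diary_mod.filter_person_days(records, field.grid.bbox)
    kept = [diary_mod.pare_to_24h(r) for r in kept]
    counts = {}
    for ex in excluded:
        counts[ex.reason] = counts.get(ex.reason, 0) + 1
    log.info("filter: %d read, %d rejected rows, %d kept, excluded by reason %s",
             len(records), len(rejections), len(kept), counts)
    return net, field, kept, excluded, rejections


def cmd_filter(cfg: RunConfig) -> tuple[int, int]:
    """Filter diaries; write kept records and an exclusion report."""
    out = _outdir(cfg)
    _, _, kept, excluded, rejections = _load_and_filter(cfg)
    diary_mod.write_diaries(kept, out / "diaries_kept.csv")
    report = pd.DataFrame(
        [{"person_id": e.person_day.person_id, "reason": e.reason}
         for e in excluded]
        + [{"person_id": f"line {r.line_number}", "reason": r.reason}
           for r in rejections]
    )
    report.to_csv(out / "exclusions.csv", index=False, lineterminator="\n")
    return len(kept), len(excluded)


def _traces(cfg, net, kept):
    cache: dict = {}
    for pd_ in kept:
        yield pd_, routing.build_trace(pd_, net, cfg.interval_m, _path_cache=cache)


def cmd_route(cfg: RunConfig) -> int:
    """Route all kept person-days; write traces as newline-delimited GeoJSON."""
    out = _outdir(cfg)
    net, _, kept, _, _ = _load_and_filter(cfg)
    n = 0
    with open(out / "traces.geojsonl", "w") as fh:
        for _, trace in _traces(cfg, net, kept):
            fh.write(routing.trace_to_geojson(trace))
            fh.write("\n")
            n += 1
    log.info("route: %d traces written", n)
    return n


def cmd_expose(cfg: RunConfig) -> pd.DataFrame:
    """Compute per-person-day exposures; write exposure.csv."""
    out = _outdir(cfg)
    net, field, kept, _, _ = _load_and_filter(cfg)
    rows = []
    for pd_, trace in _traces(cfg, net, kept):
        try:
            rec = exposure.activity_exposure(trace, field, clamp=cfg.clamp)
        except Exception as exc:
            raise RuntimeError(
                f"exposure stage failed for person-day {pd_.person_id}: {exc}"
            ) from exc
        rows.append(
            {
                "person_id": rec.person_id,
                "c_activity": rec.c_activity,
                "c_residence": rec.c_residence,
                "error_pct": rec.error_pct,
                "e_at_residence": rec.exposure_by_kind[AT_RESIDENCE],
                "e_nonresidential": rec.exposure_by_kind[NONRESIDENTIAL],
                "e_in_travel": rec.exposure_by_kind[IN_TRAVEL],
                "min_at_residence": rec.minutes_by_kind[AT_RESIDENCE],
                "min_nonresidential": rec.minutes_by_kind[NONRESIDENTIAL],
                "min_in_travel": rec.minutes_by_kind[IN_TRAVEL],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "exposure.csv", index=False, lineterminator="\n")
    log.info("expose: %d exposure records", len(df))
    return df


def _person_frame(kept) -> pd.DataFrame:
    rows = []
    for p in kept:
        rows.append(
            {
                "person_id": p.person_id,
                "age_group": p.age_group,
                "black": p.black,
                "hispanic": p.hispanic,
                "white": p.white,
                "asian": p.asian,
                "income_category": p.income_category,
                "gender": p.gender,
                "urbanicity": p.residence_urbanicity,
            }
        )
    return pd.DataFrame(rows)


def _travel_stratum(minutes: float) -> str:
    if minutes == 0:
        return "no_travel"
    return "up_to_60" if minutes <= 60 else "more_than_60"


def _strata(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Group labels per stratification used in the group-statistics report."""
    age_pooled = df["age_group"].replace({"19-45": "19-65", "46-65": "19-65"})
    return {
        "race": pd.Series(
            np.select(
                [df["black"], df["hispanic"], df["white"]],
                ["black", "hispanic", "white"],
                default="other",
            ),
            index=df.index,
        ),
        "income": df["income_category"],
        "age": age_pooled,
        "urbanicity": df["urbanicity"],
        "travel_time": df["min_in_travel"].map(_travel_stratum),
    }


def _group_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stratum, labels in _strata(df).items():
        for metric in ("c_activity", "error_pct"):
            for lab, s in disparity.group_summary(df[metric], labels).items():
                rows.append(
                    {
                        "stratum": stratum,
                        "group": lab,
                        "metric": metric,
                        "n": s.n,
                        "mean": s.mean,
                        "ci_lo": s.ci_lo,
                        "ci_hi": s.ci_hi,
                        "min": s.minimum,
                        "max": s.maximum,
                        "p5": s.percentiles[5],
                        "p95": s.percentiles[95],
                    }
                )
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame) -> tuple[pd.DataFrame, list[list[str]]]:
    """0/1 design matrix and entry blocks for the exposure regression.

    Reference profile: nonblack non-Hispanic non-Asian female over 65 with
    higher income living rural with no time away from the residence.
    """
    design = pd.DataFrame(index=df.index)
    design["male"] = (df["gender"] == "male").astype(float)
    for ag, name in [("5-18", "age_5_18"), ("19-45", "age_19_45"),
                     ("46-65", "age_46_65")]:
        design[name] = (df["age_group"] == ag).astype(float)
    for col in ("black", "hispanic", "asian"):
        design[col] = df[col].astype(float)
    design["below_poverty"] = (df["income_category"] == "below_poverty").astype(float)
    design["middle_income"] = (df["income_category"] == "middle").astype(float)
    for z in ("urban", "suburban", "second_city"):
        design[z] = (df["urbanicity"] == z).astype(float)
    design["hours_away"] = (1440.0 - df["min_at_residence"]) / 60.0
    blocks = [
        ["male", "age_5_18", "age_19_45", "age_46_65", "black", "hispanic", "asian"],
        ["below_poverty", "middle_income"],
        ["urban", "suburban", "second_city"],
        ["hours_away"],
    ]
    return design, blocks


def cmd_stats(cfg: RunConfig, df: pd.DataFrame | None = None) -> dict:
    """Group summaries, pairwise tests, regression, and the error summary."""
    out = _outdir(cfg)
    net, field, kept, excluded, rejections = _load_and_filter(cfg)
    if df is None:
        df = cmd_expose(cfg)
    df = df.merge(_person_frame(kept), on="person_id", validate="1:1")

    _group_table(df).to_csv(out / "group_stats.csv", index=False, lineterminator="\n")

    # pairwise Games-Howell per stratum (groups with n >= 2 and variance)
    pairwise_rows = []
    for stratum, labels in _strata(df).items():
        groups = {
            lab: df.loc[labels == lab, "c_activity"].to_numpy()
            for lab in labels.unique()
        }
        groups = {k: v for k, v in groups.items()
                  if v.size >= 2 and v.var(ddof=1) > 0}
        if len(groups) < 2:
            continue
        f, df1, df2, p_anova = disparity.one_way_anova(list(groups.values()))
        for cmp_ in disparity.games_howell(groups, alpha=cfg.alpha):
            pairwise_rows.append(
                {
                    "stratum": stratum,
                    "group_i": cmp_.group_i,
                    "group_j": cmp_.group_j,
                    "mean_difference": cmp_.mean_difference,
                    "q": cmp_.statistic,
                    "df": cmp_.df,
                    "p": cmp_.p_value,
                    "significant": cmp_.significant,
                    "anova_F": f,
                    "anova_p": p_anova,
                }
            )
    pd.DataFrame(pairwise_rows).to_csv(
        out / "pairwise_tests.csv", index=False, lineterminator="\n"
    )

    design, blocks = _design(df)
    reg = disparity.hierarchical_stepwise_ols(
        design, df["c_activity"], blocks, alpha=cfg.alpha
    )
    reg_table = reg.summary_frame()
    reg_table.index.name = "predictor"
    reg_table.to_csv(out / "regression.csv", lineterminator="\n")

    t_stat, t_df, t_p = disparity.paired_t(df["c_activity"], df["c_residence"])
    traveling = df[df["min_in_travel"] > 0]
    contributions = {
        k: float(
            np.mean(
                [
                    100.0 * row[f"e_{k}"]
                    / (row["e_at_residence"] + row["e_nonresidential"]
                       + row["e_in_travel"])
                    for _, row in df.iterrows()
                ]
            )
        )
        for k in ("at_residence", "nonresidential", "in_travel")
    }
    summary = {
        "n_person_days": int(len(df)),
        "n_excluded": int(len(excluded)),
        "n_rejected_rows": int(len(rejections)),
        "n_no_travel": int((df["min_in_travel"] == 0).sum()),
        "mean_c_activity": float(df["c_activity"].mean()),
        "min_c_activity": float(df["c_activity"].min()),
        "max_c_activity": float(df["c_activity"].max()),
        "mean_c_residence": float(df["c_residence"].mean()),
        "mean_error_pct": float(df["error_pct"].mean()),
        "min_error_pct": float(df["error_pct"].min()),
        "max_error_pct": float(df["error_pct"].max()),
        "share_error_positive": float((df["error_pct"] > 0).mean()),
        "paired_t": {"t": t_stat, "df": t_df, "p": t_p},
        "bias_factor_all": exposure.bias_factor(
            df[["c_residence", "c_activity"]].to_numpy()
        ),
        "bias_factor_traveling": exposure.bias_factor(
            traveling[["c_residence", "c_activity"]].to_numpy()
        )
        if len(traveling) >= 3
        else None,
        "mean_contribution_pct": contributions,
        "regression": {
            "r_squared": reg.r_squared,
            "r_squared_adj": reg.r_squared_adj,
            "n": reg.n,
            "retained": reg.retained,
            "dropped": reg.dropped,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    log.info(
        "stats: mean C_A %.2f, mean error %.2f%%, bias factor %.3f",
        summary["mean_c_activity"], summary["mean_error_pct"],
        summary["bias_factor_all"],
    )
    return summary


def cmd_report(cfg: RunConfig, summary: dict | None = None) -> str:
    """Plain-text model summary from the stats outputs."""
    out = _outdir(cfg)
    if summary is None:
        summary = cmd_stats(cfg)
    reg = summary["regression"]
    lines = [
        "airtrace run report",
        "===================",
        f"person-days analyzed: {summary['n_person_days']} "
        f"({summary['n_no_travel']} with no travel; "
        f"{summary['n_excluded']} excluded, {summary['n_rejected_rows']} rejected rows)",
        f"mean activity-based exposure C_A: {summary['mean_c_activity']:.2f} ug/m3 "
        f"(range {summary['min_c_activity']:.2f}-{summary['max_c_activity']:.2f})",
        f"mean residence-based exposure C_R: {summary['mean_c_residence']:.2f} ug/m3",
        f"mean exposure error: {summary['mean_error_pct']:.2f} % "
        f"(range {summary['min_error_pct']:.1f} to {summary['max_error_pct']:.1f}; "
        f"{100 * summary['share_error_positive']:.0f} % positive)",
        f"bias factor (all / traveling): {summary['bias_factor_all']:.3f} / "
        + (
            f"{summary['bias_factor_traveling']:.3f}"
            if summary["bias_factor_traveling"] is not None
            else "n/a"
        ),
        "mean contribution to daily exposure (%): "
        + ", ".join(
            f"{k} {v:.1f}" for k, v in summary["mean_contribution_pct"].items()
        ),
        f"regression: R2 {reg['r_squared']:.3f}, adj R2 {reg['r_squared_adj']:.3f}, "
        f"n {reg['n']}",
        f"  retained: {', '.join(reg['retained'])}",
        f"  dropped: {', '.join(reg['dropped']) or 'none'}",
    ]
    text = "\n".join(lines) + "\n"
    with open(out / "report.txt", "w") as fh:
        fh.write(text)
    return text


def cmd_run(cfg: RunConfig) -> dict:
    """All-in-one: expose and stats (inputs must already exist)."""
    df = cmd_expose(cfg)
    summary = cmd_stats(cfg, df)
    cmd_report(cfg, summary)
    return summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_cfg(config_path, seed, output_dir) -> RunConfig:
    cfg = load_run_config(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.city = dataclasses.replace(cfg.city, seed=seed)
    if output_dir is not None:
        cfg.output_dir = output_dir
    return cfg


def _invoke(stage, cfg) -> None:
    try:
        stage(cfg)
    except (ValueError, KeyError, FileNotFoundError) as exc:
        log.error("validation failure: %s", exc)
        sys.exit(EXIT_VALIDATION)
    except Exception as exc:  # noqa: BLE001 - boundary of the CLI
        log.error("runtime failure: %s", exc)
        sys.exit(EXIT_RUNTIME)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging to stderr.")
def cli(verbose: bool) -> None:
    """Activity-based air pollution exposure pipeline."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _stage_command(name, stage, help_text):
    @cli.command(name=name, help=help_text)
    @click.option("--config", "config_path", type=click.Path(exists=True),
                  default=None, help="YAML/JSON run configuration.")
    @click.option("--seed", type=int, default=None)
    @click.option("--output-dir", type=click.Path(), default=None)
    def _command(config_path, seed, output_dir):
        _invoke(stage, _load_cfg(config_path, seed, output_dir))


for _name, _stage, _help in [
    ("generate", cmd_generate, "Generate a synthetic city (network, field, diaries)."),
    ("filter", cmd_filter, "Filter diaries and write an exclusion report."),
    ("route", cmd_route, "Route kept diaries; write space-time traces."),
    ("expose", cmd_expose, "Compute per-person-day exposure records."),
    ("stats", cmd_stats, "Group summaries, tests, and the exposure regression."),
    ("report", cmd_report, "Write the plain-text run report."),
    ("run", cmd_run, "Full pipeline: expose, stats, report."),
]:
    _stage_command(_name, _stage, _help)
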