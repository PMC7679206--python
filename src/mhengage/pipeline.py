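"""End-to-end pipeline: simulate/load -> cohort -> metrics -> features ->
regression -> curves, with a reproducibility manifest.

Every stage writes its interface file into the output directory; the
manifest records the config, seed, package version and per-stage row
counts, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import build_cohort, write_cohort
from .curves import event_matrix, monthly_active, survival_curve
from .events import (MODULES, events_to_frame, filter_preconsent,
                     frame_to_events, read_events, read_profiles,
                     write_events, write_profiles)
from .features import build_features, descriptives
from .metrics import GapThreshold, derive_gap_threshold, metrics_table
from .regression import (LINKS, build_design, clamp_uar, marginal_effects,
                         select_link)
from .simulate import GeneratorConfig, ModuleParams, generate, paperlike_config

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``events_path`` / ``generator`` drives the run."""

    out_dir: str | Path = "out"
    events_path: str | Path | None = None
    profiles_path: str | Path | None = None
    medications_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    data_end: date | None = None        # required for file inputs
    anchor_policy: str = "initiation"
    window_length: int = 180
    gap_days: int | None = 28           # None -> derive from the 0.9 quantile
    gap_quantile: float = 0.9
    weekly: bool = False
    links: tuple[str, ...] = LINKS
    alpha: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.events_path is not None
        have_gen = self.generator is not None
        if have_files == have_gen:
            raise ValueError("provide exactly one of events_path or generator")
        if have_files and self.data_end is None:
            raise ValueError("data_end is required with file inputs")


def load_config(path: str | Path) -> PipelineConfig:
    """Pipeline config from a YAML file (generator block optional)."""
    raw = yaml.safe_load(Path(path).read_text())
    gen = None
    if "generator" in raw:
        graw = dict(raw.pop("generator"))
        if graw.pop("preset", None) == "paperlike":
            gen = paperlike_config(n_users=graw.pop("n_users", 500),
                                   seed=graw.pop("seed", 0))
            for k, v in graw.items():
                setattr(gen, k, v)
        else:
            if "module_params" in graw:
                graw["module_params"] = {
                    m: ModuleParams(**p) for m, p in graw["module_params"].items()
                }
            if "enrollment_start" in graw:
                graw["enrollment_start"] = date.fromisoformat(graw["enrollment_start"])
            gen = GeneratorConfig(**graw)
    if "data_end" in raw and raw["data_end"] is not None:
        raw["data_end"] = date.fromisoformat(raw["data_end"])
    if "links" in raw:
        raw["links"] = tuple(raw["links"])
    return PipelineConfig(generator=gen, **raw)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (date, Path)):
            return str(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, path: Path | None, n_rows: int, **extra) -> None:
        manifest["stages"][stage] = {"rows": n_rows, **extra}
        if path is not None:
            manifest["outputs"].append(path.name)
        log.info("stage %-10s rows=%d %s", stage, n_rows, extra or "")

    stage = "input"
    try:
        # ---- input: simulate or load --------------------------------------
        if config.generator is not None:
            gen = config.generator
            events_df, profiles, truth = generate(gen)
            data_end = gen.data_end
            write_events(frame_to_events(events_df), out / "events.csv")
            write_profiles(profiles, out / "profiles.csv", out / "medications.csv")
            record("input", out / "events.csv", len(events_df),
                   n_users=gen.n_users, simulated=True)
        else:
            events_records, report = read_events(config.events_path)
            events_df = events_to_frame(events_records)
            profiles, _ = read_profiles(config.profiles_path,
                                        config.medications_path)
            data_end = config.data_end
            record("input", None, len(events_df),
                   rejected=dict(report.rejected), simulated=False)
        events_df, n_preconsent = filter_preconsent(events_df, profiles)
        manifest["stages"]["input"]["preconsent_dropped"] = n_preconsent

        # ---- cohort -------------------------------------------------------
        stage = "cohort"
        members, creport = build_cohort(profiles, events_df, data_end,
                                        policy=config.anchor_policy,
                                        window_length=config.window_length)
        write_cohort(members, out / "cohort.csv")
        record("cohort", out / "cohort.csv", len(members),
               consented=creport.n_consented, initiated=creport.n_initiated,
               included=creport.n_included)

        # ---- metrics ------------------------------------------------------
        stage = "metrics"
        if config.gap_days is not None:
            gap = GapThreshold(value_days=config.gap_days,
                               quantile=config.gap_quantile)
        else:
            probe = metrics_table(events_df, members, GapThreshold(28))
            mean_gaps = probe.loc[(probe["module"] == "any")
                                  & probe["recency"].notna(), "recency"]
            gap = derive_gap_threshold(mean_gaps, config.gap_quantile)
        metrics_df = metrics_table(events_df, members, gap, weekly=config.weekly)
        metrics_df.to_csv(out / "metrics.csv", index=False, na_rep="NA")
        record("metrics", out / "metrics.csv", len(metrics_df),
               gap_days=gap.value_days, weekly=config.weekly)

        # ---- features -----------------------------------------------------
        stage = "features"
        features_df = build_features(profiles, events_df, metrics_df, members)
        features_df.to_csv(out / "features.csv", index=False)
        descriptives(features_df).to_csv(out / "descriptives.csv", index=False)
        record("features", out / "features.csv", len(features_df))

        # ---- regression ---------------------------------------------------
        stage = "regression"
        reg_rows = []
        feat_idx = features_df.set_index("user_id")
        for module in [m.value for m in MODULES] + ["any"]:
            sub = metrics_df[metrics_df["module"] == module]
            if len(sub) < 30:
                log.info("module %s: %d users, too few for regression; skipped",
                         module, len(sub))
                continue
            feats = feat_idx.loc[sub["user_id"]].reset_index()
            try:
                X, term_factors = build_design(feats, drop_collinear=True)
                y = clamp_uar(sub["uar_180"].to_numpy())
                fit = select_link(y, X, candidates=config.links, module=module,
                                  term_factors=term_factors)
                for me in marginal_effects(fit, X, alpha=config.alpha,
                                           window_days=config.window_length):
                    reg_rows.append({
                        "module": module, "term": me.term, "me": me.me,
                        "p_value": me.p_value, "days": me.days,
                        "significant": me.significant, "link": fit.link,
                        "aic": fit.aic, "bic": fit.bic, "n": fit.n,
                    })
            except (ValueError, RuntimeError) as exc:
                log.warning("module %s: regression skipped (%s)", module, exc)
        reg_df = pd.DataFrame(reg_rows)
        reg_df.to_csv(out / "regression_results.csv", index=False)
        record("regression", out / "regression_results.csv", len(reg_df))

        # ---- curves -------------------------------------------------------
        stage = "curves"
        surv = [survival_curve(metrics_df, m, window_len=(26 if config.weekly
                                                          else config.window_length))
                for m in metrics_df["module"].unique()
                if (metrics_df["module"] == m).any()]
        surv_df = (pd.concat(surv, ignore_index=True) if surv
                   else pd.DataFrame(columns=["module", "day", "fraction_active"]))
        surv_df.to_csv(out / "survival.csv", index=False)
        monthly_active(events_df).to_csv(out / "monthly.csv", index=False)
        sparse = [event_matrix(events_df, members, m.value) for m in MODULES]
        sparse_df = pd.concat(sparse, ignore_index=True)
        sparse_df.to_csv(out / "events_sparse.csv", index=False)
        record("curves", out / "survival.csv", len(surv_df))
        manifest["outputs"] += ["monthly.csv", "events_sparse.csv",
                                "descriptives.csv"]
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "manifest.json").write_text(json.dumps(
            manifest | {"failed_stage": stage}, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"].append("manifest.json")
    return manifest
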