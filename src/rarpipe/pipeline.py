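"""End-to-end orchestration: simulate/read -> clean -> fit -> localized ->
cluster -> associate, writing flat CSV/JSON artifacts plus a checksum
manifest so a rerun with the same config and seed is byte-identical."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, cosine, epoch_io, localized, profiles, simulate, wear
from .errors import CollinearityError, ConfigError, DataError, RarpipeError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "fit", "localized", "cluster", "associate")

#: prerequisite stages (transitive requirements handled by ordering)
_STAGE_DEPS = {
    "clean": (),
    "fit": ("clean",),
    "localized": ("clean",),
    "cluster": ("fit",),
    "associate": ("fit",),
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "epoch_seconds": 60,
    "truncate_days": 5,
    "stages": list(STAGES),
    "input": {"epochs": None, "participants": None},
    "simulate": {
        "n_participants": 20,
        "n_days": 7,
        "noise_sd": 0.5,
        "nonwear_rate_per_day": 0.3,
        "archetypes": False,
    },
    "choi": {"window_min": 90, "allowance_min": 2, "stream_min": 30},
    "valid_day_minutes": 600,
    "min_valid_days": 3,
    "bin_hours": 4,
    "rise_aligned": False,
    "clustering": {"k": 4, "n_restarts": 100, "log_beta": False},
    "assoc": {
        "tau": 0.5,
        "bootstrap_B": 200,
        "covariates": ["age", "sex", "race", "bmi", "cesd"],
    },
    "pfs": {"max_missing": 3, "cutpoint": 15},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(config: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    enabled = [s for s in STAGES if s in cfg["stages"]]
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise ConfigError(f"stage {stage!r} requires stage {dep!r}")
    cfg["stages"] = enabled
    return cfg


def _stage_seed(global_seed: int, stage: str) -> int:
    """Fan a single global seed out to a fixed per-stage seed."""
    ss = np.random.SeedSequence([int(global_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _covariate_design(participants: pd.DataFrame, covariates: list[str]):
    """Numeric covariate columns; sex/race become indicator columns."""
    cols, names = [], []
    for cov in covariates:
        if cov == "sex":
            cols.append((participants["sex"] == "male").astype(float).to_numpy())
            names.append("sex_male")
        elif cov == "race":
            cols.append((participants["race"] == "non-white").astype(float).to_numpy())
            names.append("race_nonwhite")
        else:
            cols.append(participants[cov].astype(float).to_numpy())
            names.append(cov)
    keep_cols, keep_names = [], []
    for col, name in zip(cols, names):
        if np.nanstd(col) == 0:
            logger.warning("dropping constant covariate column %r", name)
            continue
        keep_cols.append(col)
        keep_names.append(name)
    return keep_cols, keep_names


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Run the configured stages; returns the artifact manifest."""
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    artifacts: list[Path] = [out / "resolved_config.yaml"]
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        if "simulate" in cfg["stages"]:
            stage = "simulate"
            sim_cfg = dict(cfg["simulate"])
            use_arch = sim_cfg.pop("archetypes", False)
            sim = simulate.simulate_cohort(
                simulate.SimConfig(
                    epoch_seconds=cfg["epoch_seconds"],
                    seed=_stage_seed(cfg["seed"], "simulate"),
                    archetypes=simulate.DEFAULT_ARCHETYPES if use_arch else None,
                    **sim_cfg,
                )
            )
            series_list = sim.series
            participants = sim.participants
            epoch_io.write_epoch_csv(series_list, out / "epochs.csv")
            participants.to_csv(out / "participants.csv", index=False)
            sim.truth.to_csv(out / "truth.csv", index=False)
            artifacts += [out / "epochs.csv", out / "participants.csv", out / "truth.csv"]
        else:
            stage = "read"
            if not cfg["input"]["epochs"]:
                raise ConfigError("no input epochs path and simulate stage disabled")
            series_list = epoch_io.read_epoch_csv(
                cfg["input"]["epochs"], epoch_seconds=cfg["epoch_seconds"]
            )
            participants = (
                pd.read_csv(cfg["input"]["participants"], dtype={"participant_id": str})
                if cfg["input"]["participants"]
                else None
            )
        logger.info("input: %d participants with epoch data", len(series_list))

        # ------------------------------------------------------------- clean
        eligible = [s.participant_id for s in series_list]
        cleaned: dict[str, epoch_io.EpochSeries] = {}
        summaries: dict[str, wear.WearSummary] = {}
        if "clean" in cfg["stages"]:
            stage = "clean"
            rows = []
            for s in series_list:
                s = epoch_io.truncate_to_midnights(s, n_days=cfg["truncate_days"])
                s = epoch_io.log_transform(s)
                s = wear.detect_nonwear_choi(s, **cfg["choi"])
                summary = wear.daily_wear_summary(
                    s,
                    min_wear_minutes=cfg["valid_day_minutes"],
                    min_valid_days=cfg["min_valid_days"],
                )
                cleaned[s.participant_id] = s
                summaries[s.participant_id] = summary
                for day in summary.days:
                    rows.append(
                        {
                            "participant_id": s.participant_id,
                            "date": day.date.isoformat(),
                            "wear_minutes": day.wear_minutes,
                            "valid_day": day.valid_day,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "wear_summary.csv", index=False)
            artifacts.append(out / "wear_summary.csv")
            eligible = wear.filter_valid_participants(
                list(summaries.values()), min_valid_days=cfg["min_valid_days"]
            )
            logger.info(
                "clean: %d/%d participants eligible (>= %d valid days)",
                len(eligible), len(series_list), cfg["min_valid_days"],
            )

        # --------------------------------------------------------------- fit
        fits: dict[str, cosine.CosineFitResult] = {}
        if "fit" in cfg["stages"]:
            stage = "fit"
            for pid in eligible:
                fits[pid] = cosine.fit_extended_cosine(cleaned[pid])
            table = cosine.fit_results_to_frame(fits)
            table.to_csv(out / "fit_params.csv", index=False)
            artifacts.append(out / "fit_params.csv")
            logger.info(
                "fit: %d participants, %d converged",
                len(fits), int(table["converged"].sum()),
            )

        # --------------------------------------------------------- localized
        if "localized" in cfg["stages"]:
            stage = "localized"
            metrics = []
            for pid in eligible:
                s = cleaned[pid]
                valid_days = {
                    i
                    for i, day in enumerate(summaries[pid].days)
                    if day.valid_day
                }
                if cfg["rise_aligned"]:
                    fit = fits.get(pid)
                    if fit is None or not fit.converged:
                        logger.warning("skipping rise alignment for %s", pid)
                    else:
                        s = localized.align_to_rise_time(s, fit.up_mesor)
                        valid_days = None  # person-time days differ from clock days
                daily = localized.bin_daily_activity(
                    s, bin_hours=cfg["bin_hours"], valid_day_indices=valid_days
                )
                metrics.append(
                    localized.summarize_bins(daily, pid, bin_hours=cfg["bin_hours"])
                )
            localized.localized_metrics_to_frame(metrics).to_csv(
                out / "localized.csv", index=False
            )
            artifacts.append(out / "localized.csv")

        # ----------------------------------------------------------- cluster
        model = None
        if "cluster" in cfg["stages"]:
            stage = "cluster"
            feats = profiles.features_from_fits(
                fits, log_beta=cfg["clustering"]["log_beta"]
            )
            feats = profiles.standardize_features(feats)
            model = profiles.kmeans_fit(
                feats,
                k=cfg["clustering"]["k"],
                n_restarts=cfg["clustering"]["n_restarts"],
                seed=_stage_seed(cfg["seed"], "cluster"),
            )
            model = profiles.label_clusters(model)
            profiles.cluster_assignments_frame(model).to_csv(
                out / "clusters.csv", index=False
            )
            diag = profiles.cluster_diagnostics(
                feats, seed=_stage_seed(cfg["seed"], "cluster")
            )
            _write_json(diag, out / "diagnostics.json")
            artifacts += [out / "clusters.csv", out / "diagnostics.json"]
            logger.info("cluster: k=%d, within_ss=%.3f", model.k, model.within_ss)

        # --------------------------------------------------------- associate
        if "associate" in cfg["stages"]:
            stage = "associate"
            if participants is None:
                raise ConfigError("associate stage needs a participant table")
            report = _associate(cfg, fits, model, participants)
            _write_json(report, out / "associations.json")
            artifacts.append(out / "associations.json")
    except RarpipeError as exc:
        raise RarpipeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "artifacts": [
            {"name": p.name, "sha256": _sha256(p)} for p in sorted(artifacts)
        ]
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _associate(cfg, fits, model, participants: pd.DataFrame) -> dict:
    """Feature-wise quantile regressions, cluster group tests and LRT."""
    item_cols = [f"pfs_item_{j}" for j in range(1, 11)]
    if "pfs_score" not in participants.columns:
        if not set(item_cols) <= set(participants.columns):
            raise ConfigError("participant table needs pfs_score or pfs_item_1..10")
        scored = [
            assoc.score_pfs(row, max_missing=cfg["pfs"]["max_missing"])[0]
            for row in participants[item_cols].itertuples(index=False)
        ]
        participants = participants.assign(pfs_score=scored)
    table = cosine.fit_results_to_frame(fits)
    table = table[table["converged"]]
    merged = table.merge(participants, on="participant_id", how="inner")
    cov_cols, cov_names = _covariate_design(merged, cfg["assoc"]["covariates"])
    y = merged["pfs_score"].to_numpy(dtype=float)
    seed = _stage_seed(cfg["seed"], "associate")
    B = cfg["assoc"]["bootstrap_B"]
    tau = cfg["assoc"]["tau"]

    feature_cols = {
        "alpha": "alpha",
        "beta": "beta",
        "acrophase": "phi",
        "amplitude": "amp",
        "mesor": "mesor_log",
        "up_mesor": "up_mesor",
        "down_mesor": "down_mesor",
        "pseudo_f": "pseudo_f",
    }
    report: dict = {"n": int(len(merged)), "models": {}}
    intercept = np.ones(len(merged))
    for feat, col in feature_cols.items():
        X = np.column_stack([intercept, merged[col].to_numpy(dtype=float), *cov_cols])
        try:
            res = assoc.median_regression(
                y, X, names=["intercept", feat, *cov_names],
                tau=tau, bootstrap_B=B, seed=seed,
            )
        except (CollinearityError, DataError) as exc:
            logger.warning("median regression for %s skipped: %s", feat, exc)
            report["models"][feat] = {"error": str(exc)}
            continue
        j = res.names.index(feat)
        report["models"][feat] = {
            "estimate": float(res.estimates[j]),
            "ci_lower": float(res.ci_lower[j]),
            "ci_upper": float(res.ci_upper[j]),
            "p_value": float(res.pvalues[j]),
        }

    if model is not None:
        assign = pd.Series(model.assignments, name="cluster_id")
        merged = merged.join(assign, on="participant_id")
        merged = merged.dropna(subset=["cluster_id"])
        groups = {
            model.labels.get(int(cid), str(int(cid))): grp["pfs_score"].to_numpy()
            for cid, grp in merged.groupby("cluster_id")
        }
        if len(groups) >= 2 and all(len(v) for v in groups.values()):
            tests = assoc.group_comparison_tests(groups)
            report["cluster_tests"] = {
                "kruskal": tests["kruskal"],
                "pairwise": {
                    f"{a} vs {b}": v for (a, b), v in tests["pairwise"].items()
                },
            }
        cov_cols2, cov_names2 = _covariate_design(merged, cfg["assoc"]["covariates"])
        y2 = merged["pfs_score"].to_numpy(dtype=float)
        cids = sorted(merged["cluster_id"].astype(int).unique())
        dummies = [
            (merged["cluster_id"].astype(int) == cid).astype(float).to_numpy()
            for cid in cids[1:]
        ]
        if dummies and len(merged) > len(dummies) + len(cov_cols2) + 1:
            intercept2 = np.ones(len(merged))
            try:
                full = assoc.median_regression(
                    y2,
                    np.column_stack([intercept2, *dummies, *cov_cols2]),
                    names=["intercept", *[f"cluster_{c}" for c in cids[1:]], *cov_names2],
                    tau=tau, bootstrap_B=0, seed=seed,
                )
                reduced = assoc.median_regression(
                    y2,
                    np.column_stack([intercept2, *cov_cols2]),
                    names=["intercept", *cov_names2],
                    tau=tau, bootstrap_B=0, seed=seed,
                )
            except (CollinearityError, DataError) as exc:
                logger.warning("cluster LRT skipped: %s", exc)
                report["cluster_lrt"] = {"error": str(exc)}
            else:
                lrt = assoc.qr_likelihood_ratio_test(full, reduced)
                report["cluster_lrt"] = {
                    "statistic": lrt.statistic,
                    "df": lrt.df,
                    "p_value": lrt.p_value,
                }
    return report
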