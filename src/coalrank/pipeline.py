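"""End-to-end pipeline: simulate/validate -> elo -> metrics -> datasets ->
fits -> bootstrap -> report.

Each stage writes its outputs under the run directory and can be re-entered:
a stage first looks for its inputs in memory, then reloads them from the
files a previous invocation wrote. A ``run_info.json`` provenance record
(config hash, seeds, package version) accompanies every run; with a fixed
seed the numeric outputs are byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigError, DataError
from .bootstrap import bootstrap_predictions
from .coalition import configuration_share_table, event_metrics, events_from_roles
from .config import (AgonismConfig, CoalitionSimConfig, EloParams, FocalSimConfig,
                     PaternitySimConfig, PopulationConfig)
from .datasets import add_autocorrelation_term, build_paternity_dataset, build_rank_dataset
from .elo import compute_trajectories
from .glmm import fit_paternity_model, PaternityGLMM
from .io import validate_inputs
from .lmm import (FixedEffectsSpec, RankTrajectoryModel, likelihood_ratio_test,
                  make_prediction_grid, observed_feasibility_range)
from .synthetic import generate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "elo", "metrics", "dataset", "fit",
          "bootstrap", "report")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _dataclass_from(cfg: dict, key: str, cls):
    return cls(**cfg.get(key, {}))


class StageError(RuntimeError):
    """Wraps a failure with the name of the stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class PipelineRunner:
    """Orchestrates the analysis stages for one configuration.

    Parameters
    ----------
    config : dict
        Parsed YAML configuration. Must contain exactly one of ``synthetic``
        (generation block) or ``inputs`` (paths to the five CSVs).
    outdir : path
    seed : int, optional
        Overrides ``config['seed']``.
    """

    def __init__(self, config: dict, outdir, seed: int | None = None):
        self.config = dict(config)
        if ("synthetic" in self.config) == ("inputs" in self.config):
            raise ConfigError(
                "config must contain exactly one of 'synthetic' or 'inputs'")
        self.outdir = pathlib.Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config.get("seed", 0) if seed is None else seed)
        elo_cfg = {k: v for k, v in self.config.get("elo", {}).items()
                   if k in ("start_value", "k", "expected_score")}
        self.elo_params = EloParams(**elo_cfg)
        w = self.config.get("windows", {})
        self.windows = {"stability": int(w.get("stability", 30)),
                        "aggression": int(w.get("aggression", 30)),
                        "conception": int(w.get("conception", 11)),
                        "step": int(w.get("step", 10)),
                        "horizon": int(w.get("horizon", 120))}
        m = self.config.get("model", {})
        self.spec = FixedEffectsSpec(
            include_autocorr=bool(m.get("include_autocorr", False)))
        self.bootstrap_B = int(m.get("bootstrap_B", 1000))
        self._mem: dict = {}
        self._write_run_info()

    # -- provenance --------------------------------------------------------

    def _write_run_info(self) -> None:
        canonical = yaml.safe_dump(self.config, sort_keys=True)
        info = {
            "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
            "seed": self.seed,
            "coalrank_version": __version__,
        }
        (self.outdir / "run_info.json").write_text(json.dumps(info, indent=2))

    # -- stage plumbing ----------------------------------------------------

    def run(self, stages=("all",)) -> None:
        wanted = list(STAGES) if "all" in stages else list(stages)
        if "inputs" in self.config:
            wanted = [s for s in wanted if s != "simulate"]
        for stage in wanted:
            try:
                getattr(self, f"stage_{stage}")()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

    def _csv(self, name: str) -> pathlib.Path:
        return self.outdir / name

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        syn = self.config.get("synthetic", {})
        dataset = generate_all(
            pop_cfg=_dataclass_from(syn, "population", PopulationConfig),
            agonism_cfg=_dataclass_from(syn, "agonism", AgonismConfig),
            coalition_cfg=_dataclass_from(syn, "coalitions", CoalitionSimConfig),
            paternity_cfg=_dataclass_from(syn, "paternity", PaternitySimConfig),
            focal_cfg=_dataclass_from(syn, "focal", FocalSimConfig),
            elo_params=self.elo_params,
            seed=self.seed)
        datadir = self.outdir / "data"
        dataset.write_tables(datadir)
        self._mem["dataset"] = dataset
        logger.info("simulate: %d interactions, %d events, %d conceptions",
                    len(dataset.interactions), len(dataset.events),
                    dataset.conceptions["infant"].nunique())

    def _input_paths(self) -> dict:
        if "inputs" in self.config:
            return dict(self.config["inputs"])
        datadir = self.outdir / "data"
        return {name: datadir / f"{name}.csv"
                for name in ("interactions", "coalitions", "presence", "focal",
                             "conceptions")
                if (datadir / f"{name}.csv").exists()}

    def stage_validate(self) -> None:
        tables = validate_inputs(self._input_paths())
        self._mem["tables"] = tables

    def _tables(self) -> dict:
        if "tables" not in self._mem:
            self.stage_validate()
        return self._mem["tables"]

    def stage_elo(self) -> None:
        tables = self._tables()
        contests = tables["interactions"]
        if self.config.get("elo", {}).get("include_coalitions", False):
            # sensitivity analysis: coalitionary aggression as
            # participant-vs-target wins (default excludes it)
            from .coalition import events_from_roles, events_to_contests

            extra = events_to_contests(events_from_roles(tables["coalitions"]))
            contests = pd.concat([contests, extra], ignore_index=True)
            contests = contests.sort_values("date", kind="stable",
                                            ignore_index=True)
        traj = compute_trajectories(contests, tables["presence"],
                                    self.elo_params)
        traj.to_frame().to_csv(self._csv("trajectories.csv"), index=False)
        self._mem["trajectories"] = traj

    def _trajectories(self):
        if "trajectories" not in self._mem:
            self.stage_elo()
        return self._mem["trajectories"]

    def stage_metrics(self) -> None:
        tables = self._tables()
        if "coalitions" not in tables or tables["coalitions"].empty:
            raise DataError("no coalition events in the input: the metrics "
                            "stage has nothing to classify")
        events = events_from_roles(tables["coalitions"])
        metrics = event_metrics(events, self._trajectories(), tables["presence"])
        metrics.to_csv(self._csv("event_metrics.csv"), index=False)
        shares = configuration_share_table(metrics["configuration"])
        shares.to_csv(self._csv("configuration_shares.csv"), index=False)
        self._mem["events"] = events
        self._mem["metrics"] = metrics

    def _events_metrics(self):
        if "metrics" not in self._mem:
            self.stage_metrics()
        return self._mem["events"], self._mem["metrics"]

    def stage_dataset(self) -> None:
        tables = self._tables()
        events, metrics = self._events_metrics()
        traj = self._trajectories()
        rank = build_rank_dataset(
            events, metrics, traj, tables["presence"], tables.get("focal"),
            step=self.windows["step"], horizon=self.windows["horizon"],
            stability_window=self.windows["stability"],
            aggression_window=self.windows["aggression"])
        rank.to_csv(self._csv("rank_dataset.csv"), index=False)
        self._mem["rank"] = rank
        # covariate audit table: event-level and male-level values
        ev_cov = (rank[["event_id", "group", "stability", "competition"]]
                  .drop_duplicates("event_id"))
        male_cov = (rank[["event_id", "male", "age", "aggr_rate"]]
                    .drop_duplicates(["event_id", "male"]))
        ev_cov.merge(male_cov, on="event_id").to_csv(
            self._csv("covariates.csv"), index=False)
        if "conceptions" in tables and not tables["conceptions"].empty:
            pat = build_paternity_dataset(
                tables["conceptions"], traj, tables["presence"],
                window=self.windows["conception"],
                stability_window=self.windows["stability"])
            pat.to_csv(self._csv("paternity_dataset.csv"), index=False)
            self._mem["paternity"] = pat
        self._write_schema_manifest()

    def _write_schema_manifest(self) -> None:
        manifest = {
            "rank_dataset.csv": {
                "future_rating": "response: Elo rating at event date + days_since",
                "days_since": "future offset in days (10..horizon, step 10)",
                "feasibility": "sum of participants' standardized ratings minus target's",
                "day0_rating": "control: rating on the event day (never the response)",
                "_z columns": "z-scored copies (mean 0, SD 1 on the assembled table)",
            },
            "paternity_dataset.csv": {
                "rating": "window-mean standardized rating over days present",
                "sired": "1 if the male sired the infant",
            },
        }
        (self.outdir / "schema_manifest.json").write_text(
            json.dumps(manifest, indent=2))

    def _rank_table(self) -> pd.DataFrame:
        if "rank" not in self._mem:
            path = self._csv("rank_dataset.csv")
            if path.exists():
                self._mem["rank"] = pd.read_csv(path)
            else:
                self.stage_dataset()
        return self._mem["rank"]

    def stage_fit(self) -> None:
        rank = self._rank_table()
        spec = self.spec
        first_spec = dataclasses.replace(spec, include_autocorr=False)
        full = RankTrajectoryModel(rank, spec=first_spec).fit()
        if spec.include_autocorr:
            # two-pass residual construction for the autocorrelation control;
            # residuals are marginal (fixed effects only) and NaN on rows the
            # first pass had to drop
            resid = np.full(len(rank), np.nan)
            fitted_rows = full.model.data.index
            loc = rank.index.get_indexer(fitted_rows)
            resid[loc] = (rank.loc[fitted_rows, spec.response].to_numpy()
                          - full.predict(rank.loc[fitted_rows]))
            rank = add_autocorrelation_term(rank, resid)
            self._mem["rank"] = rank
            full = RankTrajectoryModel(rank, spec=spec).fit()
        null = RankTrajectoryModel(rank, spec=spec, null=True,
                                   random_structure=full.structure).fit()
        lrt = likelihood_ratio_test(full, null)
        self._mem.update(rank_full=full, rank_null=null, rank_lrt=lrt)
        fits = {"rank_full": full.to_dict(), "rank_null": null.to_dict(),
                "rank_lrt": dataclasses.asdict(lrt)}
        (self.outdir / "rank_fit_summary.txt").write_text(
            full.summary() + "\n\n" + lrt.summary() + "\n")
        if "paternity" in self._mem or self._csv("paternity_dataset.csv").exists():
            pat = self._mem.get("paternity")
            if pat is None:
                pat = pd.read_csv(self._csv("paternity_dataset.csv"))
                self._mem["paternity"] = pat
            pfull = fit_paternity_model(pat)
            pnull = PaternityGLMM.from_formula(
                _drop_rating(pfull), pat, groups="male").fit()
            plrt = likelihood_ratio_test(pfull, pnull)
            self._mem.update(pat_full=pfull, pat_lrt=plrt)
            fits.update(paternity_full=pfull.to_dict(),
                        paternity_lrt=dataclasses.asdict(plrt))
            (self.outdir / "paternity_fit_summary.txt").write_text(
                pfull.summary() + "\n\n" + plrt.summary() + "\n")
        (self.outdir / "fits.json").write_text(
            json.dumps(fits, indent=2, default=float))

    def _fits(self):
        if "rank_full" not in self._mem:
            self.stage_fit()
        return self._mem

    def stage_bootstrap(self) -> None:
        mem = self._fits()
        rank = self._rank_table()
        rng = np.random.default_rng(self.seed + 1)
        full = mem["rank_full"]
        # one combined grid -> one refit per bootstrap replicate
        grids = {}
        for cfg_label in sorted(rank["configuration"].unique()):
            feas = observed_feasibility_range(rank, cfg_label, n=15)
            grids[f"feasibility_{cfg_label}"] = make_prediction_grid(
                rank, configuration=[cfg_label], feas_z=feas, days_z=[0.0])
        days = np.linspace(rank["days_z"].min(), rank["days_z"].max(), 13)
        grids["time"] = make_prediction_grid(
            rank, configuration=sorted(rank["configuration"].unique())[:1],
            feas_z=[0.0], days_z=days)
        combined = pd.concat(grids.values(), keys=grids.keys(),
                             names=["curve_set", None]).reset_index(level=0)
        arr_all = bootstrap_predictions(full, combined, B=self.bootstrap_B,
                                        seed=int(rng.integers(2 ** 31)))
        curves = {}
        offset = 0
        for name, grid in grids.items():
            curves[name] = (grid.reset_index(drop=True),
                            arr_all[:, offset:offset + len(grid)])
            offset += len(grid)
        rows = []
        for name, (grid, arr) in curves.items():
            for b in range(arr.shape[0]):
                for i in range(arr.shape[1]):
                    rows.append((name, b, i, grid["role"].iloc[i],
                                 grid["configuration"].iloc[i],
                                 grid["feas_z"].iloc[i], grid["days_z"].iloc[i],
                                 arr[b, i]))
        pd.DataFrame(rows, columns=["curve_set", "replicate", "grid_index",
                                    "role", "configuration", "feas_z", "days_z",
                                    "prediction"]).to_csv(
            self._csv("bootstrap_rank.csv"), index=False)
        self._mem["bootstrap_curves"] = curves
        if "pat_full" in mem:
            pat_grid = pd.DataFrame({"rating": np.linspace(0, 1, 21),
                                     "age_z": 0.0, "stab_z": 0.0, "comp_z": 0.0})
            arr = bootstrap_predictions(mem["pat_full"], pat_grid,
                                        B=self.bootstrap_B,
                                        seed=int(rng.integers(2 ** 31)))
            out = pd.DataFrame(arr, columns=[f"s_{i}" for i in range(arr.shape[1])])
            out.insert(0, "replicate", np.arange(arr.shape[0]))
            out.to_csv(self._csv("bootstrap_paternity.csv"), index=False)
            self._mem["bootstrap_paternity"] = (pat_grid, arr)

    def stage_report(self) -> None:
        mem = self._fits()
        _, metrics = self._events_metrics()
        shares = configuration_share_table(metrics["configuration"])
        lines = [
            "# Coalition dynamics report",
            "",
            f"- package version: {__version__}",
            f"- seed: {self.seed}",
            "",
            "## Coalition descriptives",
            "",
            f"- events analysed: {len(metrics)}",
            f"- mean participants per event: "
            f"{metrics['n_participants'].mean():.1f} "
            f"(median {metrics['n_participants'].median():.0f}, "
            f"range {metrics['n_participants'].min()}-"
            f"{metrics['n_participants'].max()})",
            "",
            shares.to_markdown(index=False),
            "",
            "## Rank model",
            "",
            "```",
            mem["rank_full"].summary(),
            "```",
            "",
            f"Full vs null: {mem['rank_lrt'].summary()}",
        ]
        if "pat_full" in mem:
            lines += ["", "## Paternity model", "", "```",
                      mem["pat_full"].summary(), "```", "",
                      f"Full vs null: {mem['pat_lrt'].summary()}"]
        (self.outdir / "report.md").write_text("\n".join(lines) + "\n")
        self._figures()

    def _figures(self) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mem = self._mem
        if "bootstrap_curves" not in mem:
            return
        figdir = self.outdir / "figures"
        figdir.mkdir(exist_ok=True)
        curve_sets = mem["bootstrap_curves"]
        feas_sets = {k: v for k, v in curve_sets.items()
                     if k.startswith("feasibility_")}
        if feas_sets:
            fig, axes = plt.subplots(1, len(feas_sets), figsize=(4 * len(feas_sets), 3.5),
                                     sharey=True, squeeze=False)
            for ax, (name, (grid, arr)) in zip(axes[0], sorted(feas_sets.items())):
                for role, color in (("participant", "tab:blue"), ("target", "tab:red")):
                    sel = grid.index[grid["role"] == role]
                    x = grid.loc[sel, "feas_z"]
                    for b in range(min(100, arr.shape[0])):
                        ax.plot(x, arr[b, sel], color=color, alpha=0.05, lw=0.5)
                    ax.plot(x, arr[:, sel].mean(axis=0), color=color, lw=2, label=role)
                ax.axvline(0, ls=":", color="grey")
                ax.set_title(name.replace("feasibility_", ""))
                ax.set_xlabel("feasibility (z)")
            axes[0][0].set_ylabel("predicted future rating")
            axes[0][0].legend(frameon=False)
            fig.tight_layout()
            fig.savefig(figdir / "feasibility_by_configuration.png", dpi=120)
            plt.close(fig)
        if "time" in curve_sets:
            grid, arr = curve_sets["time"]
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for role, color in (("participant", "tab:blue"), ("target", "tab:red")):
                sel = grid.index[grid["role"] == role]
                x = grid.loc[sel, "days_z"]
                for b in range(min(100, arr.shape[0])):
                    ax.plot(x, arr[b, sel], color=color, alpha=0.05, lw=0.5)
                ax.plot(x, arr[:, sel].mean(axis=0), color=color, lw=2, label=role)
            ax.set_xlabel("time distance (z)")
            ax.set_ylabel("predicted future rating")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(figdir / "time_decay.png", dpi=120)
            plt.close(fig)
        if "bootstrap_paternity" in mem:
            grid, arr = mem["bootstrap_paternity"]
            fig, ax = plt.subplots(figsize=(5, 3.5))
            x = grid["rating"]
            for b in range(min(200, arr.shape[0])):
                ax.plot(x, arr[b], color="tab:green", alpha=0.05, lw=0.5)
            ax.plot(x, arr.mean(axis=0), color="tab:green", lw=2)
            ax.set_xlabel("standardized rating (conception window)")
            ax.set_ylabel("P(sire)")
            fig.tight_layout()
            fig.savefig(figdir / "paternity.png", dpi=120)
            plt.close(fig)


def _drop_rating(pfull) -> str:
    """Null paternity formula: drop only the rating term, keep the controls."""
    terms = [t for t in pfull.fixed_names if t not in ("Intercept", "rating")]
    return "sired ~ 1" + "".join(f" + {t}" for t in terms)


def run_pipeline(config: dict, outdir, seed: int | None = None,
                 stages=("all",)) -> PipelineRunner:
    """Convenience wrapper: build a runner and execute the requested stages."""
    runner = PipelineRunner(config, outdir, seed=seed)
    runner.run(stages)
    return runner
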