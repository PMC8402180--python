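"""End-to-end pipeline: weather → canopy → simulate → evaluate → fit → scenarios.

Each stage writes a delimited text table prefixed with comment lines
carrying the configuration digest, so a results directory is traceable
and re-runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import carbon_balance, gof, sugar_model, vine_state, weather as weather_mod
from .config import RunConfig, config_digest
from .errors import VitisimError

__all__ = ["run_pipeline", "write_table"]

log = logging.getLogger("vitisim")

_FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path: Path, digest: str) -> None:
    """Write a CSV with a digest header comment (deterministic formatting)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_digest: {digest}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_obs_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every configured stage in order and write all outputs.

    Requires ``weather_path`` and ``canopy_path``; the evaluation, sugar
    fit and scenarios run only when their observation files are supplied.
    Returns a dict of the in-memory stage results.
    """
    out = Path(out_dir)
    digest = config_digest(config)
    results: dict = {"digest": digest}

    def stage(name):
        log.info("stage %s", name)

    if not config.weather_path or not config.canopy_path:
        raise VitisimError("run_pipeline needs weather_path and canopy_path")

    stage("weather")
    series = weather_mod.load_weather(
        config.weather_path, latitude=config.latitude, sprouting=config.sprouting
    )
    stage("canopy")
    obs = vine_state.load_canopy(config.canopy_path)
    das_range = range(int(series.data["das"].iloc[0]), int(series.data["das"].iloc[-1]) + 1)
    canopy = vine_state.interpolate_canopy(obs, das_range)

    stage("simulate")
    sim = carbon_balance.simulate_season(series, canopy, config.params)
    results["simulation"] = sim
    write_table(sim, out / "simulation.csv", digest)

    if config.dm_obs_path:
        stage("evaluate")
        dm = _read_obs_table(config.dm_obs_path)
        merged = dm.merge(sim[["das", "dm_cumulative"]], on="das", how="inner")
        if len(merged) < 2:
            raise VitisimError("dry-matter observations do not overlap the simulation")
        report = gof.evaluate(merged["dm"], merged["dm_cumulative"])
        results["gof"] = report
        write_table(
            pd.DataFrame([report.__dict__]), out / "gof.csv", digest
        )

    fit = None
    if config.brix_obs_path:
        stage("fit-sugar")
        bx = _read_obs_table(config.brix_obs_path)
        brix_obs = [
            sugar_model.BrixObservation(das=int(r.das), brix=float(r.brix))
            for r in bx.itertuples(index=False)
        ]
        fit = sugar_model.fit_brix_dm(brix_obs, sim)
        results["fit"] = fit
        write_table(pd.DataFrame([fit.__dict__]), out / "sugar_fit.csv", digest)

        stage("scenario")
        scenarios = sugar_model.run_cluster_scenarios(
            series, canopy, config.params, fit, config.scenario_clusters
        )
        results["scenarios"] = scenarios
        frames = []
        baseline = pd.DataFrame(
            {
                "clusters": "baseline",
                "das": sim["das"],
                "dm_cumulative": sim["dm_cumulative"],
                "brix": sugar_model.predict_brix(fit, sim["dm_cumulative"]),
            }
        )
        frames.append(baseline)
        for count, traj in scenarios.items():
            traj = traj.copy()
            traj.insert(0, "clusters", count)
            frames.append(traj)
        write_table(pd.concat(frames, ignore_index=True), out / "scenarios.csv", digest)

    # echo the resolved configuration for provenance
    import yaml

    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(
        f"# config_digest: {digest}\n"
        + yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    return results
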