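"""End-to-end runner: config in, clouds / fits / potentials / rate tables out.

A single structured YAML config drives the stages

    sample -> fit (optional) -> rates -> oracle (optional)

and a run manifest records the config snapshot, package version, seeds,
output paths and per-stage status.  Deterministic stages reproduce
bit-identically from the manifest's config; stochastic stages reproduce
given the recorded seeds.  A failed stage is recorded in the manifest and
reflected in the process exit status — never silently downgraded.
"""

from __future__ import annotations

import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .params import (
    SCENARIOS,
    ConfinementParams,
    KineticParams,
    TargetGeometry,
    save_config,
)
from .kinetics import sweep_rates, szabo_mfpt
from .radial import effective_potential, radial_equilibrium_density, write_radial_csv
from .sampling import sample_free_end, write_point_cloud
from .fitting import fit_parameters
from .geometry import clipped_mass_fraction

__all__ = ["RunManifest", "run_pipeline", "ConfigError", "load_pipeline_config"]


class ConfigError(ValueError):
    """Config schema violation, reported with the offending key path."""


class PipelineError(RuntimeError):
    """One or more pipeline stages failed."""


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)

    @property
    def failed_stages(self) -> list[str]:
        return [k for k, v in self.stages.items()
                if not v["status"].startswith("ok")]

    def to_dict(self) -> dict:
        return {"config": self.config, "version": self.version,
                "seeds": self.seeds, "outputs": self.outputs,
                "stages": self.stages}

    def save(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                                     sort_keys=False))


def _need(cfg: dict, key: str, typ, path: str):
    if key not in cfg:
        raise ConfigError(f"{path}.{key}: missing required key")
    v = cfg[key]
    if typ is float and isinstance(v, int):
        v = float(v)
    if not isinstance(v, typ):
        raise ConfigError(
            f"{path}.{key}: expected {getattr(typ, '__name__', typ)}, "
            f"got {type(v).__name__}"
        )
    return v


def load_pipeline_config(path: str | pathlib.Path) -> dict:
    """Parse and validate a pipeline config, raising :class:`ConfigError`
    with the offending key path on schema violations."""
    raw = yaml.safe_load(pathlib.Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config: expected a mapping at top level")
    scenarios = _need(raw, "scenarios", list, "config")
    for i, s in enumerate(scenarios):
        if s not in SCENARIOS:
            raise ConfigError(
                f"config.scenarios[{i}]: unknown scenario tag {s!r}; "
                f"expected one of {SCENARIOS}"
            )
    pdict = _need(raw, "params", dict, "config")
    try:
        params = ConfinementParams.from_dict(pdict)
        for s in scenarios:
            params.require_for(s)
    except Exception as exc:
        raise ConfigError(f"config.params: {exc}") from None
    kdict = _need(raw, "kinetics", dict, "config")
    try:
        kin = KineticParams(D=float(_need(kdict, "D", (int, float),
                                          "config.kinetics")),
                            kappa=float(_need(kdict, "kappa", (int, float),
                                              "config.kinetics")))
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"config.kinetics: {exc}") from None
    sweep = _need(raw, "sweep", dict, "config")
    eps_list = _need(sweep, "epsilon", list, "config.sweep")
    for i, e in enumerate(eps_list):
        if not isinstance(e, (int, float)) or e <= 0:
            raise ConfigError(f"config.sweep.epsilon[{i}]: must be positive")
    for key in ("a_min", "a_max", "a_step"):
        _need(sweep, key, (int, float), "config.sweep")
    if sweep["a_max"] < sweep["a_min"] or sweep["a_step"] <= 0:
        raise ConfigError("config.sweep: need a_min <= a_max and a_step > 0")
    for opt in ("sample", "fit", "oracle"):
        if opt in raw and not isinstance(raw[opt], dict):
            raise ConfigError(f"config.{opt}: expected a mapping")
    if "fit" in raw and "sample" not in raw:
        raise ConfigError("config.fit: requires a sample stage")
    return {"scenarios": scenarios, "params": params, "kinetics": kin,
            "sweep": sweep, "sample": raw.get("sample"),
            "fit": raw.get("fit"), "oracle": raw.get("oracle"),
            "output_dir": raw.get("output_dir", "out"), "raw": raw}


def run_pipeline(config_path: str | pathlib.Path,
                 output_dir: str | pathlib.Path | None = None) -> RunManifest:
    """Execute the configured stages; write outputs and a manifest.

    Raises :class:`PipelineError` after writing the manifest if any stage
    failed, so callers (and the CLI) can propagate a non-zero exit status.
    """
    cfg = load_pipeline_config(config_path)
    out = pathlib.Path(output_dir if output_dir is not None
                       else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg["raw"], version=__version__)
    params: ConfinementParams = cfg["params"]
    kin: KineticParams = cfg["kinetics"]
    scenarios = cfg["scenarios"]
    clouds = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
            manifest.stages[name] = {
                "status": "ok", "elapsed_s": round(time.perf_counter() - t0, 3)
            }
        except Exception as exc:
            manifest.stages[name] = {
                "status": f"failed: {exc}",
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }

    if cfg["sample"]:
        def do_sample():
            n = int(cfg["sample"].get("n", 10_000))
            seed = int(cfg["sample"].get("seed", 0))
            manifest.seeds["sample"] = seed
            for scn in scenarios:
                cloud = sample_free_end(scn, params, n, seed)
                clouds[scn] = cloud
                path = out / f"cloud_{scn}.csv"
                write_point_cloud(cloud, path)
                manifest.outputs.append(str(path))
        stage("sample", do_sample)

    if cfg["fit"]:
        def do_fit():
            free = tuple(cfg["fit"].get("free", []))
            for scn, cloud in clouds.items():
                res = fit_parameters(cloud, scn, free, init=params)
                path = out / f"fit_{scn}.yaml"
                save_config(
                    {**res.params.to_dict(),
                     "objective": res.objective,
                     "n_points": res.n_points,
                     "converged": res.converged},
                    path,
                )
                manifest.outputs.append(str(path))
        stage("fit", do_fit)

    def do_rates():
        sw = cfg["sweep"]
        n_a = int(round((sw["a_max"] - sw["a_min"]) / sw["a_step"])) + 1
        a_grid = sw["a_min"] + sw["a_step"] * np.arange(n_a)
        table = sweep_rates(scenarios, params, kin, a_grid, sw["epsilon"])
        path = out / "rates.csv"
        table.to_csv(path, index=False)
        manifest.outputs.append(str(path))
        for scn in scenarios:
            frac = clipped_mass_fraction(scn, params)
            if frac:
                manifest.stages.setdefault("diagnostics", {"status": "ok"})
                manifest.stages["diagnostics"][f"clipped_mass_{scn}"] = frac
    stage("rates", do_rates)

    if cfg["oracle"]:
        def do_oracle():
            from .bd import simulate_fpt, summarize_fpt

            oc = cfg["oracle"]
            seed = int(oc.get("seed", 0))
            manifest.seeds["oracle"] = seed
            geom = TargetGeometry(a=float(oc.get("a", params.L)),
                                  epsilon=float(oc.get("epsilon",
                                                       cfg["sweep"]["epsilon"][0])))
            rows = ["scenario,mean_fpt_s,se_s,szabo_s,n"]
            for scn in scenarios:
                rp = effective_potential(
                    radial_equilibrium_density(scn, params, geom))
                path = out / f"potential_{scn}.csv"
                write_radial_csv(rp, path)
                manifest.outputs.append(str(path))
                n_traj = int(oc.get("n_traj", 1000))
                sample = simulate_fpt(rp, kin, n=n_traj,
                                      dt=oc.get("dt"), seed=seed,
                                      n_contacts_target=int(
                                          oc.get("n_contacts", 100_000)))
                mean, se = summarize_fpt(sample)
                rows.append(f"{scn},{mean!r},{se!r},"
                            f"{szabo_mfpt(rp, kin).tau!r},{n_traj}")
            path = out / "oracle.csv"
            path.write_text("\n".join(rows) + "\n")
            manifest.outputs.append(str(path))
        stage("oracle", do_oracle)

    missing = [p for p in manifest.outputs if not pathlib.Path(p).exists()]
    if missing:
        manifest.stages["outputs"] = {"status": f"failed: missing {missing}"}
    manifest.save(out / "manifest.yaml")
    manifest.outputs.append(str(out / "manifest.yaml"))
    if manifest.failed_stages:
        raise PipelineError(
            f"stages failed: {manifest.failed_stages} (see {out/'manifest.yaml'})"
        )
    return manifest
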