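"""End-to-end pipeline: simulate -> link (+PET) -> classify -> MCS ->
importance, with per-stage CSV outputs and a machine-readable manifest.

Every stage is a pure function of its inputs and the run configuration;
fixed seeds make the whole run byte-reproducible.  Dropped or unmatched
records are always counted in the manifest — no row disappears silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import crosstab
from .importance import NetworkSpec, build_dataset, garson_importance, train_network
from .linkage import link
from .mcs import DegenerateDistributionError, fit_pet_distribution, mcs_probabilities, mcs_table
from .reference import ACCIDENT_TYPES, SEVERITIES
from .simulate import GeneratorConfig, generate_accidents, generate_climate


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    linkage_policy: str = "strict"
    mcs_draws: int = 1_000_000
    mcs_seed: int = 0
    network: NetworkSpec = field(default_factory=NetworkSpec)
    params_file: str | None = None  # optional (type,severity,mean,std) CSV

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**{
            **raw.get("generator", {}),
            **(
                {"layout": {c: tuple(d) for c, d in
                            raw["generator"]["layout"].items()}}
                if "layout" in raw.get("generator", {}) else {}
            ),
        })
        net = NetworkSpec(**raw.get("network", {}))
        return cls(
            generator=gen,
            linkage_policy=raw.get("linkage_policy", "strict"),
            mcs_draws=int(raw.get("mcs_draws", 1_000_000)),
            mcs_seed=int(raw.get("mcs_seed", 0)),
            network=net,
            params_file=raw.get("params_file"),
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        return {
            "generator": enc(self.generator),
            "linkage_policy": self.linkage_policy,
            "mcs_draws": self.mcs_draws,
            "mcs_seed": self.mcs_seed,
            "network": enc(self.network),
            "params_file": self.params_file,
        }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, writing per-stage CSVs and ``manifest.json`` to
    ``outdir``; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def finish_stage(name: str, **info):
        manifest["stages"][name] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def fail(name: str, exc: Exception):
        manifest["failed_stage"] = name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"stage {name!r} failed: {exc}") from exc

    try:
        climate = generate_climate(config.generator)
        accidents = generate_accidents(climate, config.generator)
        climate.to_csv(out / "climate.csv", index=False)
        accidents.to_csv(out / "accidents.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail("simulate", exc)
    finish_stage("simulate", n_climate=len(climate), n_accidents=len(accidents))

    try:
        linked, report = link(accidents, climate, policy=config.linkage_policy,
                              person=config.generator.person,
                              pet_config=config.generator.pet_config)
        linked.to_csv(out / "linked.csv", index=False)
    except Exception as exc:
        fail("link", exc)
    finish_stage(
        "link", n_linked=report.n_linked, n_exact=report.n_exact,
        n_nearest=report.n_nearest, n_unmatched=report.n_unmatched,
    )

    try:
        monthly = crosstab(linked, ("month", "accident_type", "severity"))
        bands = crosstab(linked, ("comfort_band", "accident_type", "severity"))
        monthly.table.to_csv(out / "monthly_counts.csv", index=False)
        bands.table.to_csv(out / "band_counts.csv", index=False)
    except Exception as exc:
        fail("classify", exc)
    finish_stage("classify", monthly_total=monthly.total, band_total=bands.total)

    try:
        if config.params_file:
            params = pd.read_csv(config.params_file)
            mcs_df = mcs_table(params, n_draws=config.mcs_draws,
                               seed=config.mcs_seed)
        else:
            rows = []
            children = np.random.SeedSequence(config.mcs_seed).spawn(
                len(ACCIDENT_TYPES) * len(SEVERITIES))
            it = iter(children)
            for atype in ACCIDENT_TYPES:
                for severity in SEVERITIES:
                    child = next(it)
                    try:
                        dist = fit_pet_distribution(linked, atype, severity)
                    except DegenerateDistributionError:
                        continue
                    seed = int(child.generate_state(1)[0] % (2**31))
                    s = mcs_probabilities(dist, n_draws=config.mcs_draws,
                                          seed=seed)
                    rows.append({
                        "accident_type": atype, "severity": severity,
                        "mean": dist.mean, "std": dist.std,
                        "n_events": dist.n_events,
                        "p_cold_pct": 100 * s.p_cold,
                        "p_hot_pct": 100 * s.p_hot,
                        "p_outside_pct": 100 * s.p_outside,
                        "se_outside_pct": 100 * s.se_outside,
                        "n_draws": s.n_draws, "seed": s.seed,
                    })
            mcs_df = pd.DataFrame(rows)
        mcs_df.to_csv(out / "mcs_probabilities.csv", index=False)
    except Exception as exc:
        fail("mcs", exc)
    finish_stage("mcs", n_strata=len(mcs_df))

    try:
        table = build_dataset(linked, climate,
                              working_hours=config.generator.working_hours,
                              encoding=config.network.target_encoding)
        model = train_network(table, config.network)
        imp = garson_importance(model)
        imp_df = pd.DataFrame(
            {"variable": list(imp.importances),
             "importance": list(imp.importances.values())}
        )
        imp_df.to_csv(out / "importance.csv", index=False)
        (out / "network.json").write_text(json.dumps({
            "w_hidden": model.w_hidden.tolist(),
            "w_output": model.w_output.tolist(),
            "r2": model.r2, "epochs": model.epochs,
            "final_loss": model.final_loss, "converged": model.converged,
        }, indent=2))
    except Exception as exc:
        fail("importance", exc)
    finish_stage("importance", r2=imp.r2, epochs=imp.epochs,
                 n_rows=len(table))

    return manifest
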