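"""Configuration, run manifests and the end-to-end pipeline runner.

The YAML configuration mirrors the dataclass fields: a ``simulation``
section (SimulationParams), a ``connectivity`` section (ConnectivityParams),
a ``plan`` section (repetitions, duration, cell counts, base seed) and a
``cma`` section (burst-detector constants).  Absent keys take the
calibrated defaults; unknown keys are rejected with their key path.
Internally time is kept in integer steps; seconds appear only at the I/O
boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import yaml

from .features import CmaParams
from .network_builder import ConnectivityParams
from .simulate import SimulationParams
from .experiments import ExperimentPlan

logger = logging.getLogger(__name__)

__all__ = ["load_config", "save_config", "RunManifest", "reproduce"]

_SECTIONS = {
    "simulation": SimulationParams,
    "connectivity": ConnectivityParams,
    "cma": CmaParams,
}
_PLAN_KEYS = {"base_seed", "n_reps", "duration_s", "n_neurons", "n_astro"}


def _build(cls, section: str, mapping: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in mapping:
        if key not in valid:
            raise ValueError(f"unknown configuration key: {section}.{key}")
    if cls is CmaParams and "alpha_table" in mapping:
        mapping = dict(mapping)
        mapping["alpha_table"] = tuple(
            (float(b), float(a)) for b, a in mapping["alpha_table"]
        )
    return cls(**mapping)


def load_config(path) -> ExperimentPlan:
    """Parse a YAML config file into an ExperimentPlan (defaults applied)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    for key in raw:
        if key not in set(_SECTIONS) | {"plan"}:
            raise ValueError(f"unknown configuration key: {key}")
    plan_map = raw.get("plan", {})
    for key in plan_map:
        if key not in _PLAN_KEYS:
            raise ValueError(f"unknown configuration key: plan.{key}")
    sim = _build(SimulationParams, "simulation", raw.get("simulation", {}))
    conn = _build(ConnectivityParams, "connectivity", raw.get("connectivity", {}))
    cma = _build(CmaParams, "cma", raw.get("cma", {}))
    return ExperimentPlan(sim=sim, conn=conn, cma=cma, **plan_map)


def save_config(plan: ExperimentPlan, path) -> None:
    """Write a plan back to YAML (round-trips through load_config)."""
    cma = dataclasses.asdict(plan.cma)
    cma["alpha_table"] = [[float(b) if b != float("inf") else ".inf", a]
                          for b, a in plan.cma.alpha_table]
    # yaml handles inf natively; keep numbers as-is
    cma["alpha_table"] = [[float(b), float(a)] for b, a in plan.cma.alpha_table]
    doc = {
        "plan": {
            "base_seed": plan.base_seed,
            "n_reps": plan.n_reps,
            "duration_s": plan.duration_s,
            "n_neurons": plan.n_neurons,
            "n_astro": plan.n_astro,
        },
        "simulation": dataclasses.asdict(plan.sim),
        "connectivity": dataclasses.asdict(plan.conn),
        "cma": cma,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


class RunManifest:
    """File inventory with checksums; proves a pipeline re-run is identical."""

    def __init__(self, out_dir, config_snapshot: dict | None = None):
        self.out_dir = Path(out_dir)
        self.entries: dict[str, str] = {}
        self.config = config_snapshot or {}
        self.stages: list[str] = []

    @staticmethod
    def checksum(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()

    def record(self, path) -> None:
        rel = str(Path(path).relative_to(self.out_dir))
        self.entries[rel] = self.checksum(path)

    def complete_stage(self, name: str) -> None:
        self.stages.append(name)

    def save(self) -> Path:
        target = self.out_dir / "manifest.json"
        target.write_text(
            json.dumps(
                {"config": self.config, "stages": self.stages, "files": self.entries},
                indent=2, sort_keys=True, default=str,
            )
        )
        return target


_DESK_SCALE = {"n_reps": 2, "duration_s": 120.0}


def reproduce(out_dir, plan: ExperimentPlan | None = None, scale: str = "full") -> RunManifest:
    """Run the whole pipeline: suite -> H1..H4 -> mixed-model tables.

    ``scale="desk"`` reduces repetitions and simulated duration via the plan
    (schema unchanged); ``"full"`` runs the complete design.  Outputs CSVs
    under ``out_dir`` and a manifest with checksums.
    """
    from . import experiments as ex
    from . import lme

    if scale not in ("full", "desk"):
        raise ValueError(f"unknown scale: {scale!r}")
    plan = plan or ExperimentPlan()
    if scale == "desk":
        plan = replace(plan, **_DESK_SCALE)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out, {"scale": scale, "base_seed": plan.base_seed,
                                 "n_reps": plan.n_reps, "duration_s": plan.duration_s})

    suite = ex.build_network_suite(plan)
    ex.suite_metrics_table(suite).to_csv(out / "topology_metrics.csv", index=False)
    manifest.record(out / "topology_metrics.csv")
    manifest.complete_stage("suite")

    tables = {}
    h1, glu = ex.run_h1_removal(suite, plan, collect_glutamate=True)
    h1.to_csv(out / "responses_h1.csv", index=False)
    manifest.record(out / "responses_h1.csv")
    if glu is not None:
        glu.to_csv(out / "glutamate_h1.csv", index=False)
        manifest.record(out / "glutamate_h1.csv")
    tables["H1"] = h1
    manifest.complete_stage("h1")

    for name, runner in (("H2", ex.run_h2_atp), ("H3", ex.run_h3_glutamate),
                         ("H4", ex.run_h4_weights)):
        t = runner(suite, plan)
        t.to_csv(out / f"responses_{name.lower()}.csv", index=False)
        manifest.record(out / f"responses_{name.lower()}.csv")
        tables[name] = t
        manifest.complete_stage(name.lower())

    # analysis stage: removal contrasts + hypothesis fits
    rows = []
    for tag in ("astro_removed", "neuron_removed"):
        for resp in ("Z_spike", "Z_burst", "Z_astro"):
            sub = tables["H1"][tables["H1"]["condition"].isin(["default", tag])]
            if not (sub[resp] > 0).all():
                # zero responses cannot be log-transformed; flag instead of
                # fitting (occurs only in heavily scaled-down runs)
                logger.warning("skipping removal fit for %s/%s: non-positive "
                               "responses present", tag, resp)
                rows.append({"removal": tag, "response": resp,
                             "delta_rem_pct": float("nan"),
                             "ci_lo": float("nan"), "ci_hi": float("nan"),
                             "p_value": float("nan"),
                             "sigma_rem_norm_pct": float("nan"),
                             "sigma_norm_pct": float("nan"),
                             "flag": "nonpositive_response"})
                continue
            rc = lme.removal_contrast(tables["H1"], resp, reduced_tag=tag)
            rows.append({
                "removal": tag, "response": resp,
                "delta_rem_pct": rc.delta_rem_pct,
                "ci_lo": rc.delta_rem_ci[0], "ci_hi": rc.delta_rem_ci[1],
                "p_value": rc.p_value,
                "sigma_rem_norm_pct": rc.sigma_rem_norm_pct,
                "sigma_norm_pct": rc.sigma_norm_pct,
                "flag": "",
            })
    import pandas as pd
    pd.DataFrame(rows).to_csv(out / "table_removal.csv", index=False)
    manifest.record(out / "table_removal.csv")

    for name in ("H2", "H3", "H4"):
        fits = {}
        for resp in ("Z_spike", "Z_burst", "Z_astro"):
            try:
                fits[resp] = lme._H_FITTERS[name](tables[name], resp)
            except ValueError as err:
                logger.warning("skipping %s fit for %s: %s", name, resp, err)
        lme.fits_to_table(fits).to_csv(out / f"table_{name.lower()}.csv", index=False)
        manifest.record(out / f"table_{name.lower()}.csv")
    manifest.complete_stage("analysis")

    manifest.save()
    return manifest
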