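"""File-format adapters, run manifests, and the staged pipeline.

Event data moves either as FCS (3.0/3.1 read, 3.1 write) or as plain
tabular files (one row per event, one column per channel); per-sample
metadata (animal, timepoint, group, block, volumes) travels in a
sidecar CSV keyed by sample_id, because volume keywords inside FCS
files are vendor-specific.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fcs import read_fcs, write_fcs
from .gating import EventTable, gate_sample
from .panel_model import load_builtin, load_panel_config, BUILTIN_PANELS
from .quantify import quantify_study
from .synthetic import default_study_config, generate_study, generate_challenge_study
from .variance import decompose_study, detectable_change, required_n
from .groups import compare_groups

log = logging.getLogger("immunogate")

SIDECAR_FIELDS = (
    "sample_id",
    "animal_id",
    "timepoint",
    "group",
    "block",
    "acquired_volume",
    "blood_volume",
    "diluent_volume",
)


def write_events(
    table: EventTable, path: str | Path, format: str = "tabular"
) -> None:
    """Write one sample's events as CSV or FCS 3.1 (intensities only;
    pair with :func:`write_sidecar` for the metadata)."""
    path = Path(path)
    if format == "tabular":
        table.events.to_csv(path, index=False)
    elif format == "fcs":
        write_fcs(path, table.events, {"SAMPLEID": table.sample_id})
    else:
        raise ValueError(f"unknown format {format!r}")


def write_sidecar(tables: list[EventTable], path: str | Path) -> None:
    rows = [
        {
            "sample_id": t.sample_id,
            "animal_id": t.animal_id,
            "timepoint": t.timepoint,
            "group": t.group,
            "block": t.block,
            "acquired_volume": t.acquired_volume,
            "blood_volume": t.blood_volume,
            "diluent_volume": t.diluent_volume,
        }
        for t in tables
    ]
    pd.DataFrame(rows, columns=SIDECAR_FIELDS).to_csv(path, index=False)


def read_events(
    path: str | Path,
    format: str | None = None,
    sidecar: str | Path | None = None,
    **metadata,
) -> EventTable:
    """Read one sample from an FCS or tabular event file.

    ``format`` is sniffed from the extension when omitted.  Metadata
    comes from the sidecar CSV (matched on sample_id, defaulting to the
    file stem) and/or keyword overrides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() in (".fcs",) else "tabular"
    if format == "fcs":
        events, kw = read_fcs(path)
        sample_id = kw.get("SAMPLEID", path.stem)
    elif format == "tabular":
        events = pd.read_csv(path)
        sample_id = path.stem
    else:
        raise ValueError(f"unknown format {format!r}")

    meta: dict = {"sample_id": sample_id}
    if sidecar is not None:
        side = pd.read_csv(sidecar)
        hit = side[side["sample_id"] == sample_id]
        if len(hit) == 1:
            row = hit.iloc[0].to_dict()
            for k in SIDECAR_FIELDS[1:]:
                if k in row and not pd.isna(row[k]):
                    meta[k] = row[k]
    meta.update({k: v for k, v in metadata.items() if v is not None})
    return EventTable(events=events, **meta)


@dataclass
class RunManifest:
    """Reproducibility record emitted once per pipeline invocation."""

    command: str
    config_hash: str
    seed: int
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    software_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_panel(name_or_path: str):
    if name_or_path in BUILTIN_PANELS:
        return load_builtin(name_or_path)
    return load_panel_config(name_or_path)


STAGES = ("simulate", "gate", "quantify", "variance", "compare", "power")


def run_pipeline(config: dict, out_dir: str | Path) -> tuple[dict, RunManifest]:
    """Run the declared stages in order, persisting tidy CSV outputs.

    ``config`` keys: ``seed`` (single seed governing all stochastic
    stages), ``panel`` (built-in name or config path), ``stages`` (an
    ordered subset of simulate/gate/quantify/variance/compare/power),
    and per-stage option maps under the stage name.  Later stages
    consume earlier stages' in-memory outputs and fail fast when a
    dependency was not scheduled.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ()))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    seed = int(config.get("seed", 0))
    panel_name = config.get("panel", "myeloid")
    panel, hierarchy = _load_panel(panel_name)

    state: dict = {}
    outputs: dict = {}
    out_paths: list[str] = []

    def persist(df: pd.DataFrame, name: str):
        p = out_dir / name
        df.to_csv(p, index=False)
        out_paths.append(str(p))
        return p

    for stage in stages:
        t0 = time.perf_counter()
        opts = dict(config.get(stage, {}))
        if stage == "simulate":
            design = opts.pop("design", "longitudinal")
            cfg = default_study_config(panel.panel_name, seed=seed, **opts.pop("config", {}))
            if design == "challenge":
                study = generate_challenge_study(cfg, **opts)
            else:
                study = generate_study(cfg)
            state["study"] = study
            state["sim_config"] = cfg
            write_sidecar([ev for ev, _ in study], out_dir / "samples.csv")
            out_paths.append(str(out_dir / "samples.csv"))
            truth = pd.concat(
                [
                    t.table.assign(sample_id=t.sample_id, animal_id=t.animal_id, timepoint=t.timepoint)
                    for _, t in study
                ],
                ignore_index=True,
            )
            persist(truth, "ground_truth.csv")
            log.info("simulate: %d samples, %d events each (first sample)",
                     len(study), study[0][0].n_events)
        elif stage == "gate":
            if "study" not in state:
                raise ValueError("gate stage needs simulate outputs (or load events first)")
            gated = []
            for ev, _ in state["study"]:
                res = gate_sample(ev, hierarchy, seed=seed)
                gated.append((res, ev))
                fb = res.thresholds.fallbacks() if res.thresholds else []
                if fb:
                    log.info("gate %s: quantile fallback on %s", ev.sample_id, fb)
            state["gated"] = gated
            tidy = pd.concat(
                [r.table.assign(sample_id=e.sample_id) for r, e in gated],
                ignore_index=True,
            )
            persist(tidy, "gated_counts.csv")
            log.info("gate: %d samples x %d nodes", len(gated), len(hierarchy.nodes()))
        elif stage == "quantify":
            if "gated" not in state:
                raise ValueError("quantify stage needs gate outputs")
            act = quantify_study(state["gated"], **opts)
            state["counts"] = act.table
            persist(act.table, "absolute_counts.csv")
        elif stage == "variance":
            if "counts" not in state:
                raise ValueError("variance stage needs quantify outputs")
            eta = decompose_study(state["counts"], **{k: v for k, v in opts.items() if k != "cohens_d"})
            persist(eta, "eta_squared.csv")
            d = float(opts.get("cohens_d", 0.5))
            mdc_rows = []
            for var, sub in state["counts"].groupby("node", sort=False):
                vals = sub["cells_per_uL"].to_numpy()
                if len(vals) >= 2 and vals.std(ddof=1) > 0 and vals.mean() > 0:
                    m = detectable_change(vals, cohens_d=d, variable_name=var)
                    mdc_rows.append((var, m.mdc_cells, m.mdc_relative_pct))
            mdc = pd.DataFrame(mdc_rows, columns=["variable", "mdc_cells", "mdc_pct"])
            persist(mdc, "detectable_change.csv")
            outputs["eta_squared"] = eta
            outputs["detectable_change"] = mdc
        elif stage == "compare":
            if "counts" not in state:
                raise ValueError("compare stage needs quantify outputs")
            cmp_opts = {"baseline": "T1", "followup": "T2", **opts}
            res = compare_groups(state["counts"], **cmp_opts)
            persist(res.table, "group_comparison.csv")
            for note in res.notes:
                log.info("compare: %s", note)
            outputs["comparison"] = res
        elif stage == "power":
            d = float(opts.get("cohens_d", 0.5))
            power = float(opts.get("power", 0.80))
            alpha = float(opts.get("alpha", 0.05))
            n_exact, n_norm = required_n(d, power, alpha)
            ptab = pd.DataFrame(
                [{"cohens_d": d, "power": power, "alpha": alpha,
                  "n_per_group_exact": n_exact, "n_per_group_normal": n_norm}]
            )
            persist(ptab, "required_n.csv")
            outputs["required_n"] = (n_exact, n_norm)
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    outputs.setdefault("counts", state.get("counts"))
    manifest = RunManifest(
        command="run_pipeline",
        config_hash=_config_hash(config),
        seed=seed,
        inputs=[str(panel_name)],
        outputs=out_paths,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out_dir / "manifest.json")
    return outputs, manifest
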