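"""End-to-end reproducible runs: device -> flow -> fill -> scene ->
automation -> PALM -> localization -> rendering, with a provenance manifest.

`run_pipeline` is the library equivalent of a workbench command line: it
executes every stage on a (scaled-down by default) configuration, writes
each stage's artefacts to the output directory, and records a manifest
JSON listing outputs with SHA-256 checksums, the seeds used, and per-stage
wall time, so any run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import automation, device, flow, localize, palm, trapping

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs of a full workbench run.

    The default device is a small (1-region, 8-row) instance of the array
    and the default movie is short and 128 px wide, so a full pipeline run
    takes seconds; pass the full-size specs for a production run.
    """

    out_dir: str = "basintrap_run"
    seed: int = 1
    device_spec: device.DeviceSpec = field(default_factory=lambda: device.DeviceSpec(
        n_regions=1, rows_per_region=8))
    fluid: flow.FluidSpec = field(default_factory=flow.FluidSpec)
    bc: flow.BoundaryConditions = field(default_factory=flow.BoundaryConditions)
    n_cells: int = 40
    acquisition: palm.AcquisitionConfig = field(
        default_factory=lambda: palm.AcquisitionConfig(
            activation_pulses=40, max_frames=400, detector_shape=(128, 128)))
    n_emitters_per_cluster: int = 20
    render_px_nm: float = 10.0

    def validate(self) -> None:
        self.device_spec.validate()
        self.fluid.validate()
        self.acquisition.validate()
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the manifest.

    Any stage failure is recorded in the manifest with the stage name and
    error, and the partial outputs of earlier stages are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [],
                "config": {"device_spec": asdict(config.device_spec),
                           "n_cells": config.n_cells,
                           "acquisition": asdict(config.acquisition)}}
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        entry = {"name": name, "ok": True, "outputs": {}}
        try:
            outputs = fn() or {}
            for label, path in outputs.items():
                entry["outputs"][label] = {
                    "path": str(path), "sha256": _checksum(Path(path))}
        except Exception as exc:
            entry["ok"] = False
            entry["error"] = f"{type(exc).__name__}: {exc}"
        entry["wall_s"] = round(time.perf_counter() - t0, 4)
        manifest["stages"].append(entry)
        return entry["ok"]

    def s_device():
        state["net"] = device.build_device(config.device_spec)
        p = out / "netlist.json"
        state["net"].to_json(p)
        return {"netlist": p}

    def s_flow():
        state["flow"] = flow.solve_flow(state["net"], config.fluid, config.bc)
        p = out / "flow.csv"
        flow.flow_to_csv(state["net"], state["flow"], p)
        return {"flow": p}

    def s_fill():
        stream = trapping.CellStream(config.n_cells, seed=config.seed)
        occ, events, fill = trapping.simulate_fill(
            state["net"], config.fluid, config.bc, stream)
        state["occupancy"], state["events"] = occ, events
        pe = out / "events.csv"
        with open(pe, "w") as fh:
            fh.write("cell_index,outcome,basin,n_basins_passed\n")
            for ev in events:
                fh.write(f"{ev.cell_index},{ev.outcome},"
                         f"{ev.basin or ''},{len(ev.path)}\n")
        po = out / "occupancy.json"
        with open(po, "w") as fh:
            json.dump({"occupied": sorted(occ.occupied),
                       "residual": occ.residual,
                       "fill_curve": [int(v) for v in fill]}, fh, indent=1)
        return {"events": pe, "occupancy": po}

    def s_scene():
        img, truth = palm.simulate_brightfield_cell(
            length_um=10.0, orientation_deg=25.0, shape=(256, 256),
            seed=config.seed)
        state["scene_img"], state["scene_truth"] = img, truth
        p = out / "scene.tif"
        import tifffile
        tifffile.imwrite(p, img.astype("float32"))
        return {"scene": p}

    def s_automation():
        scene = automation.TrappedCellScene(
            length_um=10.0, offset_px=(30.0, -18.0), seed=config.seed)
        history = automation.run_automation(scene)
        state["decisions"] = history
        p = out / "decision.json"
        with open(p, "w") as fh:
            json.dump([asdict(d) for d in history], fh, indent=1)
        if not history or history[-1].action != "acquire":
            raise RuntimeError("automation did not reach acquire")
        return {"decision": p}

    def s_palm():
        h, w = config.acquisition.detector_shape
        px = config.acquisition.pixel_size_nm
        cx, cy = w * px / 2, h * px / 2
        emitters = palm.EmitterSet.two_clusters(
            [(cx - 500, cy), (cx + 500, cy)],
            n_per_cluster=config.n_emitters_per_cluster,
            seed=config.seed, activation_prob=0.05)
        state["stack"] = palm.simulate_movie(
            emitters, config.acquisition, seed=config.seed)
        pm = out / "movie.tif"
        state["stack"].to_tiff(pm)
        pg = out / "ground_truth.csv"
        state["stack"].ground_truth.to_csv(pg, index=False)
        return {"movie": pm, "ground_truth": pg}

    def s_localize():
        state["table"] = localize.localize_stack(state["stack"])
        p = out / "locs.csv"
        state["table"].to_csv(p)
        return {"locs": p}

    def s_render():
        sr = localize.render(state["table"], config.render_px_nm)
        p = out / "sr.tif"
        sr.to_tiff(p)
        return {"sr": p}

    for name, fn in [("device", s_device), ("flow", s_flow),
                     ("fill", s_fill), ("scene", s_scene),
                     ("automation", s_automation), ("palm", s_palm),
                     ("localize", s_localize), ("render", s_render)]:
        if not stage(name, fn):
            break

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
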