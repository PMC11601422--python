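"""File-based tool execution: settings file in, results directory out.

Each tool reads its XML settings, loads the model (and overlay), runs the
corresponding library tool, and writes its results and a structured JSON
log (final objective/term breakdown, diagnostics, wall time) into the
results directory.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import numpy as np

from . import settings as st
from .gcp import GcpTask, GroundContactPersonalizer, extract_foot
from .jmp import JmpTask, JointModelPersonalizer
from .kinematics import inverse_kinematics
from .model import read_model, write_model
from .mtp import MtpSettings, MtpTrial, MuscleTendonPersonalizer
from .ncp import NcpSettings, NeuralControlPersonalizer
from .overlay import OsimxOverlay, apply_overlay, read_osimx, write_osimx
from .tables import (read_marker_file, read_time_series, write_time_series,
                     TimeSeriesTable)
from .treatment import (DesignOptimization, OcpFormulation,
                        SynergyController, TrackingOptimization,
                        VerificationOptimization, solution_tables)
from .collocation import OcpSolution

__all__ = ["run_tool"]


def run_tool(tool: str, settings_path, results_override=None) -> Path:
    """Run one tool from its settings file; returns the results directory.

    Raises on any configuration or execution error (the CLI converts these
    to a nonzero exit status with a machine-readable error record).
    """
    tool = tool.upper()
    cfg = st.parse_settings(settings_path, tool)
    results = Path(results_override or cfg.resolve(cfg.results_directory))
    results.mkdir(parents=True, exist_ok=True)
    model = read_model(cfg.resolve(cfg.model))
    overlay = read_osimx(cfg.resolve(cfg.overlay)) if cfg.overlay else None
    if overlay is not None:
        model = apply_overlay(model, overlay)
    t0 = _time.time()
    runner = {"JMP": _run_jmp, "MTP": _run_mtp, "NCP": _run_ncp,
              "GCP": _run_gcp, "TO": _run_ocp, "VO": _run_ocp,
              "DO": _run_ocp}[tool]
    log = runner(tool, cfg, model, overlay, results)
    log["tool"] = tool
    log["wall_time_s"] = _time.time() - t0
    with open(results / "log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=_jsonable)
    return results


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------

def _run_jmp(tool, cfg, model, overlay, results):
    tasks = []
    for el in st.elements(cfg, "JMPTask"):
        markers = read_marker_file(cfg.resolve(el["attrs"]["marker_file"]))
        joint_params, scales, offsets, roms = [], [], [], []
        weights = {}
        for ch in el["children"]:
            if ch["tag"] == "joint_parameter":
                joint_params.append((ch["attrs"]["joint"],
                                     ch["attrs"]["frame"],
                                     ch["attrs"]["kind"]))
            elif ch["tag"] == "scale_segment":
                scales.append(ch["text"])
            elif ch["tag"] == "marker_offset":
                offsets.append(ch["text"])
            elif ch["tag"] == "rom_coordinate":
                roms.append(ch["text"])
            elif ch["tag"] == "marker_weight":
                name, val = ch["text"].split()
                weights[name] = float(val)
        tasks.append(JmpTask(markers, joint_params, scales, offsets,
                             rom_coordinates=roms,
                             marker_weights=weights or None))
    fit = JointModelPersonalizer(tasks).fit(model)
    write_model(fit.model_, results / "personalized_model.yaml")
    ik = inverse_kinematics(fit.model_, tasks[-1].markers)
    write_time_series(ik.coordinates, results / "ik_coordinates.sto")
    return {"diagnostics": fit.diagnostics_,
            "objective_breakdown": {
                f"task{d['task']}": d["post_cost"]
                for d in fit.diagnostics_}}


def _run_mtp(tool, cfg, model, overlay, results):
    muscles = st.text_of(cfg, "muscles").split()
    tracked = st.text_of(cfg, "tracked_coordinates").split()
    free = tuple(st.text_of(cfg, "free").split())
    synx_cfg = st.elements(cfg, "synx")
    synx_muscles, synx_method, synx_k = [], "nmf", None
    if synx_cfg:
        synx_method = synx_cfg[0]["attrs"].get("method", "nmf")
        k = synx_cfg[0]["attrs"].get("components")
        synx_k = int(k) if k else None
        synx_muscles = [ch["text"] for ch in synx_cfg[0]["children"]]
    settings = MtpSettings(
        muscles=muscles, tracked_coordinates=tracked, free=free,
        moment_allowable=float(st.text_of(cfg, "moment_allowable")),
        passive_allowable=float(st.text_of(cfg, "passive_allowable")),
        similarity_groups=[e["text"]
                           for e in st.elements(cfg, "similarity_group")],
        synx_method=synx_method, synx_components=synx_k,
        synx_muscles=synx_muscles,
        max_nfev=int(st.text_of(cfg, "max_nfev")))
    trials = []
    for el in st.elements(cfg, "trial"):
        trials.append(MtpTrial(
            coordinates=read_time_series(
                cfg.resolve(el["attrs"]["coordinates"])),
            loads=read_time_series(cfg.resolve(el["attrs"]["loads"])),
            emg=_with_pad(read_time_series(cfg.resolve(el["attrs"]["emg"]))),
            cycle_duration=float(el["attrs"]["cycle_duration"])))
    fit = MuscleTendonPersonalizer(settings).fit(model, trials)
    write_osimx(OsimxOverlay(muscles=fit.params_,
                             provenance={"generated_by": "MTP"}),
                results / "personalized.osimx.xml")
    for i, act in enumerate(fit.activations_):
        write_time_series(act, results / f"activations_trial{i}.sto")
    return {"diagnostics": fit.diagnostics_,
            "objective_breakdown": {"total": fit.diagnostics_["cost"]}}


def _with_pad(table):
    """Infer the pad length of an EMG table whose time starts before 0."""
    n_pad = int(np.sum(table.time < -1e-12))
    table.metadata["pad_points"] = n_pad
    return table


def _run_ncp(tool, cfg, model, overlay, results):
    groups = {e["attrs"]["name"]: int(e["attrs"]["n_synergies"])
              for e in st.elements(cfg, "group")}
    shared = [(e["attrs"]["first"], e["attrs"]["second"])
              for e in st.elements(cfg, "shared_vectors")]
    settings = NcpSettings(
        groups=groups,
        tracked_coordinates=st.text_of(cfg, "tracked_coordinates").split(),
        moment_allowable=float(st.text_of(cfg, "moment_allowable")),
        activation_allowable=float(st.text_of(cfg, "activation_allowable")),
        activation_min_allowable=float(
            st.text_of(cfg, "activation_min_allowable")),
        shared_vectors=shared)
    trial = st.elements(cfg, "trial")[0]
    coords = read_time_series(cfg.resolve(trial["attrs"]["coordinates"]))
    loads = read_time_series(cfg.resolve(trial["attrs"]["loads"]))
    acts = (read_time_series(cfg.resolve(trial["attrs"]["activations"]))
            if "activations" in trial["attrs"] else None)
    params = {m: model.muscles[m].params for g in groups
              for m in model.muscle_groups[g]}
    if any(p is None for p in params.values()):
        missing = [m for m, p in params.items() if p is None]
        raise st.SettingsError(
            f"muscles without personalized parameters: {missing} "
            "(supply an overlay)")
    fit = NeuralControlPersonalizer(settings).fit(
        model, coords.time, coords, loads, params, acts)
    write_osimx(OsimxOverlay(
        synergies={g: {"muscles": s.muscles, "W": s.W}
                   for g, s in fit.synergies_.items()},
        provenance={"generated_by": "NCP"}),
        results / "personalized.osimx.xml")
    for g, s in fit.synergies_.items():
        write_time_series(TimeSeriesTable(
            coords.time, {f"synergy_{k}": s.H[:, k]
                          for k in range(s.n_synergies)}),
            results / f"synergy_activations_{g}.sto")
        write_time_series(TimeSeriesTable(
            np.arange(s.n_synergies, dtype=float),
            {m: s.W[:, j] for j, m in enumerate(s.muscles)}),
            results / f"synergy_vectors_{g}.sto")
    return {"diagnostics": fit.diagnostics_,
            "objective_breakdown": fit.diagnostics_["moment_rmse"]}


def _run_gcp(tool, cfg, model, overlay, results):
    feet = st.elements(cfg, "foot")
    symmetric = st.text_of(cfg, "symmetric", "false") == "true"
    trial = st.elements(cfg, "trial")[0]
    coords = read_time_series(cfg.resolve(trial["attrs"]["coordinates"]))
    grf = read_time_series(cfg.resolve(trial["attrs"]["grf"]))
    windows = {e["attrs"]["side"]: (float(e["attrs"]["start"]),
                                    float(e["attrs"]["end"]))
               for e in st.elements(cfg, "window")}
    if not np.allclose(np.diff(coords.time), np.diff(coords.time)[0],
                       rtol=1e-6):
        raise st.SettingsError("kinematics must have uniform time steps")
    out_contact = {}
    diagnostics = {}
    tasks = _gcp_tasks(cfg)
    for foot_el in feet:
        side = foot_el["attrs"]["side"]
        if symmetric and out_contact:
            out_contact[side] = next(iter(out_contact.values()))
            continue
        fm, Qf = extract_foot(
            model, foot_el["attrs"]["hindfoot"], foot_el["attrs"]["toes"],
            coords.as_matrix(model.coordinate_names).T)
        time = coords.time
        if side in windows:
            lo, hi = windows[side]
            mask = (time >= lo) & (time <= hi)
        else:
            mask = np.ones(len(time), bool)
        contact0 = (model.contact.get(side, {}).get("model")
                    or (overlay.contact.get(side) if overlay else None))
        if contact0 is None:
            raise st.SettingsError(f"no initial contact model for foot "
                                   f"{side!r}")
        force = np.vstack([grf[f"{side}_force_x"], grf[f"{side}_force_y"]])
        moment = grf[f"{side}_moment_z"]
        point = np.vstack([grf[f"{side}_point_x"], grf[f"{side}_point_y"]])
        gcp = GroundContactPersonalizer(fm, contact0, tasks)
        gcp.fit(time[mask], Qf[:, mask], force[:, mask], moment[mask],
                point[:, mask])
        out_contact[side] = gcp.contact_
        diagnostics[side] = gcp.diagnostics_
    write_osimx(OsimxOverlay(contact=out_contact,
                             provenance={"generated_by": "GCP"}),
                results / "personalized.osimx.xml")
    return {"diagnostics": diagnostics,
            "objective_breakdown": {
                side: d[-1]["cost"] for side, d in diagnostics.items()}}


def _gcp_tasks(cfg):
    els = st.elements(cfg, "task")
    if not els:
        return None

    def flag(e, name, default="false"):
        return e["attrs"].get(name, default) == "true"

    return [GcpTask(track_vertical=flag(e, "track_vertical", "true"),
                    track_horizontal=flag(e, "track_horizontal"),
                    track_moment=flag(e, "track_moment"),
                    free_viscous_friction=flag(e, "free_viscous_friction"),
                    free_dynamic_friction=flag(e, "free_dynamic_friction"),
                    free_damping=flag(e, "free_damping"),
                    free_resting_length=flag(e, "free_resting_length",
                                             "true"),
                    free_deviations=flag(e, "free_deviations"))
            for e in els]


# -- treatment optimization --------------------------------------------------

def _read_dir_tables(path: Path) -> dict:
    out = {}
    for f in sorted(Path(path).glob("*.sto")):
        out[f.stem] = read_time_series(f)
    return out


def _formulation(cfg, model, overlay) -> OcpFormulation:
    controllers = {e["attrs"]["coordinate"]: e["attrs"]["type"]
                   for e in st.elements(cfg, "controller")}
    synergies = []
    params = {}
    if overlay is not None:
        for g, d in overlay.synergies.items():
            synergies.append(SynergyController(g, d["muscles"],
                                               np.asarray(d["W"])))
            for m in d["muscles"]:
                params[m] = model.muscles[m].params
    ft_bounds = st.elements(cfg, "final_time_bounds")
    final_time = ((float(ft_bounds[0]["attrs"]["lower"]),
                   float(ft_bounds[0]["attrs"]["upper"])) if ft_bounds
                  else float(st.text_of(cfg, "final_time")))
    static = [(e["attrs"]["name"], float(e["attrs"]["lower"]),
               float(e["attrs"]["upper"]),
               float(e["attrs"].get("initial",
                                    (float(e["attrs"]["lower"])
                                     + float(e["attrs"]["upper"])) / 2)))
              for e in st.elements(cfg, "static_parameter")]
    return OcpFormulation(
        model=model, controllers=controllers, muscle_params=params,
        synergies=synergies,
        mesh_intervals=int(st.text_of(cfg, "mesh_intervals")),
        final_time=final_time,
        periodic=st.text_of(cfg, "periodic") == "true",
        kinetic_bound=float(st.text_of(cfg, "kinetic_bound")),
        residual_force_bound=float(st.text_of(cfg, "residual_force_bound")),
        residual_moment_bound=float(
            st.text_of(cfg, "residual_moment_bound")),
        periodicity_bound=float(st.text_of(cfg, "periodicity_bound")),
        range_scale_factor=float(st.text_of(cfg, "range_scale_factor")),
        static_parameters=static)


def _guess_from_dir(form, path: Path):
    tables = _read_dir_tables(path)
    states = tables["states"]
    controls = tables["controls"]
    coords = form.model.coordinate_names
    nn = len(states.time)
    X = np.column_stack([states[c] for c in coords]
                        + [states[c + "_v"] for c in coords])
    ucols = [controls[f"accel_{c}"] for c in coords]
    for c in coords:
        if form.controllers.get(c) in ("torque", "both") \
                and f"torque_{c}" in controls.columns:
            ucols.append(controls[f"torque_{c}"])
    for sc in form.synergies:
        for k in range(sc.W.shape[0]):
            ucols.append(controls[f"cmd_{sc.group}_{k}"])
    U = np.column_stack(ucols)
    return X, U, states.time


def _write_solution(form, sol, results: Path):
    coords = form.model.coordinate_names
    b_n = len(coords)
    X, U = sol.states, sol.controls
    write_time_series(TimeSeriesTable(
        sol.time, {**{c: X[:, i] for i, c in enumerate(coords)},
                   **{c + "_v": X[:, b_n + i]
                      for i, c in enumerate(coords)}}),
        results / "states.sto")
    cols = {f"accel_{c}": U[:, i] for i, c in enumerate(coords)}
    off = b_n
    for c in coords:
        if form.controllers.get(c) in ("torque", "both"):
            cols[f"torque_{c}"] = U[:, off]
            off += 1
    for sc in form.synergies:
        for k in range(sc.W.shape[0]):
            cols[f"cmd_{sc.group}_{k}"] = U[:, off]
            off += 1
    write_time_series(TimeSeriesTable(sol.time, cols),
                      results / "controls.sto")
    for name, table in solution_tables(form, sol).items():
        write_time_series(table, results / f"{name}.sto")


def _run_ocp(tool, cfg, model, overlay, results):
    form = _formulation(cfg, model, overlay)
    maxiter = int(st.text_of(cfg, "max_iterations"))
    allowables = {e["attrs"]["name"]: float(e["attrs"]["value"])
                  for e in st.elements(cfg, "allowable")}
    guess_dir = cfg.resolve(st.text_of(cfg, "initial_guess_directory"))
    X0, U0, t0 = _guess_from_dir(form, guess_dir)
    if tool == "TO":
        tracked_dir = cfg.resolve(st.text_of(cfg, "tracked_directory"))
        tracked = {}
        tables = _read_dir_tables(tracked_dir)
        if "coordinates" in tables:
            tb = tables["coordinates"]
            tracked["coordinates"] = tb.as_matrix()
            tracked["coordinates_names"] = tb.names
        if "loads" in tables:
            tb = tables["loads"]
            tracked["loads"] = tb.as_matrix()
            tracked["loads_names"] = tb.names
        if "activations" in tables:
            tb = tables["activations"]
            tracked["activations"] = tb.as_matrix()
            tracked["activations_names"] = tb.names
        form.tracked = tracked
        sol = TrackingOptimization(form, maxiter=maxiter).solve(
            X0, U0, allowables=allowables or None)
    else:
        prev = OcpSolution(
            time=t0, states=X0, controls=U0, parameters=np.zeros(0),
            final_time=float(t0[-1] - t0[0]), objective=np.nan,
            term_values={}, constraint_report={}, n_iterations=0,
            success=True)
        if tool == "VO":
            sol = VerificationOptimization(form, maxiter=maxiter).solve(
                prev, allowables=allowables or None)
        else:
            goal = [{"type": e["attrs"]["type"],
                     "center": float(e["attrs"]["center"]),
                     "allowable": float(e["attrs"]["allowable"])}
                    for e in st.elements(cfg, "goal_term")]
            sol = DesignOptimization(form, maxiter=maxiter).solve(
                prev, goal_terms=goal, allowables=allowables or None)
    _write_solution(form, sol, results)
    return {"objective": sol.objective,
            "objective_breakdown": sol.term_values,
            "constraints": sol.constraint_report,
            "iterations": sol.n_iterations,
            "final_time": sol.final_time,
            "static_parameters": list(map(float, sol.parameters)),
            "success": sol.success}
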