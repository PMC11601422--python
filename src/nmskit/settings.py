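"""Tool settings files (XML).

Every tool runs from a single XML settings file, OpenSim-style: common
elements name the model, optional overlay and results directory; a
tool-specific body describes tasks, trials, terms and flags. Parsing is
strict — unknown elements are rejected with their path — and unset advanced
fields are filled with documented defaults, so writing the parsed settings
back produces an equivalent, fully explicit file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

__all__ = ["ToolSettings", "parse_settings", "write_settings",
           "SettingsError", "TOOLS"]

TOOLS = ("JMP", "MTP", "NCP", "GCP", "TO", "VO", "DO")


class SettingsError(ValueError):
    pass


@dataclass
class ToolSettings:
    tool: str
    model: str
    results_directory: str
    overlay: str | None = None
    body: dict = field(default_factory=dict)
    source: str | None = None

    def resolve(self, rel: str) -> Path:
        base = Path(self.source).parent if self.source else Path(".")
        return (base / rel).resolve()


_COMMON = {"model", "overlay", "results_directory"}

_SCHEMAS = {
    "JMP": {"JMPTask": {"attrs": {"marker_file"},
                        "children": {"joint_parameter", "scale_segment",
                                     "marker_offset", "rom_coordinate",
                                     "marker_weight"}}},
    "MTP": {"trial": {"attrs": {"coordinates", "loads", "emg",
                                "cycle_duration"}, "children": set()},
            "muscles": {}, "tracked_coordinates": {}, "free": {},
            "moment_allowable": {}, "passive_allowable": {},
            "similarity_group": {}, "synx": {"attrs": {"method",
                                                       "components"},
                                             "children": {"muscle"}},
            "max_nfev": {}},
    "NCP": {"trial": {"attrs": {"coordinates", "loads", "activations",
                                "cycle_duration"}, "children": set()},
            "group": {"attrs": {"name", "n_synergies"}, "children": set()},
            "tracked_coordinates": {}, "moment_allowable": {},
            "activation_allowable": {},
            "activation_min_allowable": {},
            "shared_vectors": {"attrs": {"first", "second"},
                               "children": set()}},
    "GCP": {"foot": {"attrs": {"side", "hindfoot", "toes"},
                     "children": set()},
            "trial": {"attrs": {"coordinates", "grf"}, "children": set()},
            "task": {"attrs": {"track_vertical", "track_horizontal",
                               "track_moment", "free_viscous_friction",
                               "free_dynamic_friction", "free_damping",
                               "free_resting_length", "free_deviations"},
                     "children": set()},
            "window": {"attrs": {"side", "start", "end"}, "children": set()},
            "symmetric": {}, "grid": {"attrs": {"rows", "cols"},
                                      "children": set()},
            "midfoot_marker": {"attrs": {"side", "name"},
                               "children": set()}},
}
for _t in ("TO", "VO", "DO"):
    _SCHEMAS[_t] = {
        "controller": {"attrs": {"coordinate", "type"}, "children": set()},
        "mesh_intervals": {}, "final_time": {},
        "final_time_bounds": {"attrs": {"lower", "upper"},
                              "children": set()},
        "tracked_directory": {}, "initial_guess_directory": {},
        "allowable": {"attrs": {"name", "value"}, "children": set()},
        "periodic": {}, "range_scale_factor": {},
        "kinetic_bound": {}, "residual_force_bound": {},
        "residual_moment_bound": {}, "periodicity_bound": {},
        "max_iterations": {},
    }
_SCHEMAS["DO"].update({
    "static_parameter": {"attrs": {"name", "lower", "upper", "initial"},
                         "children": set()},
    "goal_term": {"attrs": {"type", "center", "allowable"},
                  "children": set()},
})

_CHILD_ATTRS = {
    "joint_parameter": {"joint", "frame", "kind"},
    "scale_segment": set(), "marker_offset": set(),
    "rom_coordinate": set(), "marker_weight": set(),
    "muscle": set(),
}

_DEFAULTS = {
    "MTP": {"moment_allowable": "2.0", "passive_allowable": "0.02",
            "max_nfev": "400",
            "free": "delay time_constants nonlinearity scale lengths"},
    "NCP": {"moment_allowable": "2.0", "activation_allowable": "0.05",
            "activation_min_allowable": "0.05"},
    "GCP": {"symmetric": "false"},
    "TO": {"mesh_intervals": "25", "final_time": "1.0",
           "periodic": "true", "range_scale_factor": "0.8",
           "kinetic_bound": "0.01", "residual_force_bound": "1.0",
           "residual_moment_bound": "0.1", "periodicity_bound": "0.05",
           "max_iterations": "300"},
}
_DEFAULTS["VO"] = dict(_DEFAULTS["TO"])
_DEFAULTS["DO"] = dict(_DEFAULTS["TO"])
_DEFAULTS["JMP"] = {}


def _element_path(el) -> str:
    return el.getroottree().getpath(el)


def parse_settings(path, tool: str | None = None) -> ToolSettings:
    path = str(path)
    tree = etree.parse(path)
    root = tree.getroot()
    if root.tag != "NMSKitSettings":
        raise SettingsError(f"{path}: root element must be "
                            f"<NMSKitSettings>, found <{root.tag}>")
    file_tool = root.get("tool")
    if file_tool not in TOOLS:
        raise SettingsError(f"{path}: unknown tool {file_tool!r}")
    if tool is not None and tool.upper() != file_tool:
        raise SettingsError(f"{path}: settings are for {file_tool}, "
                            f"not {tool.upper()}")
    schema = _SCHEMAS[file_tool]
    body: dict = {"_elements": []}
    model = overlay = results = None
    for el in root:
        if isinstance(el, etree._Comment):
            continue
        tag = el.tag
        if tag in _COMMON:
            if tag == "model":
                model = el.text.strip()
            elif tag == "overlay":
                overlay = el.text.strip() if el.text else None
            else:
                results = el.text.strip()
            continue
        if tag not in schema:
            raise SettingsError(
                f"{path}: unknown element at {_element_path(el)}")
        spec = schema[tag] or {"attrs": set(), "children": set()}
        allowed_attrs = spec.get("attrs", set())
        for a in el.attrib:
            if a not in allowed_attrs:
                raise SettingsError(
                    f"{path}: unknown attribute {a!r} at "
                    f"{_element_path(el)}")
        allowed_children = spec.get("children", set())
        for ch in el:
            if isinstance(ch, etree._Comment):
                continue
            if ch.tag not in allowed_children:
                raise SettingsError(
                    f"{path}: unknown element at {_element_path(ch)}")
            for a in ch.attrib:
                if a not in _CHILD_ATTRS.get(ch.tag, set()):
                    raise SettingsError(
                        f"{path}: unknown attribute {a!r} at "
                        f"{_element_path(ch)}")
        body["_elements"].append(_el_to_dict(el))
    if model is None:
        raise SettingsError(f"{path}: missing required element <model>")
    if results is None:
        raise SettingsError(
            f"{path}: missing required element <results_directory>")
    # fill unset simple defaults
    present = {e["tag"] for e in body["_elements"]}
    for tag, text in _DEFAULTS.get(file_tool, {}).items():
        if tag not in present:
            body["_elements"].append({"tag": tag, "text": text,
                                      "attrs": {}, "children": []})
    return ToolSettings(file_tool, model, results, overlay, body, path)


def _el_to_dict(el) -> dict:
    return {"tag": el.tag,
            "text": (el.text or "").strip(),
            "attrs": dict(el.attrib),
            "children": [_el_to_dict(ch) for ch in el
                         if not isinstance(ch, etree._Comment)]}


def write_settings(settings: ToolSettings, path) -> None:
    root = etree.Element("NMSKitSettings", tool=settings.tool)
    etree.SubElement(root, "model").text = settings.model
    if settings.overlay:
        etree.SubElement(root, "overlay").text = settings.overlay
    etree.SubElement(root, "results_directory").text = \
        settings.results_directory

    def build(parent, d):
        el = etree.SubElement(parent, d["tag"], **d["attrs"])
        if d["text"]:
            el.text = d["text"]
        for ch in d["children"]:
            build(el, ch)

    for d in sorted(settings.body["_elements"], key=lambda e: e["tag"]):
        build(root, d)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# convenience accessors ------------------------------------------------------

def elements(settings: ToolSettings, tag: str) -> list[dict]:
    return [e for e in settings.body["_elements"] if e["tag"] == tag]


def text_of(settings: ToolSettings, tag: str, default=None) -> str | None:
    els = elements(settings, tag)
    return els[0]["text"] if els else default
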