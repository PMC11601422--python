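"""Personalization-overlay files (osimx-style XML).

Personalized properties that the base model format does not carry —
calibrated muscle-tendon parameters, synergy sets, contact-surface
parameters — are stored in a companion XML overlay with three independent
blocks: ``<MTPMuscleSet>``, ``<RCNLSynergySet>`` and
``<GCPContactSurfaceSet>``. Writing one block into an existing file
preserves the other blocks; name consistency against a model is checked
when the overlay is applied, not when it is parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .gcp import ContactModel
from .model import Model
from .muscle import MuscleTendonParams

__all__ = ["OsimxOverlay", "read_osimx", "write_osimx", "apply_overlay",
           "OverlayError"]

VERSION = "1"

_MUSCLE_FIELDS = [
    "optimal_fiber_length", "tendon_slack_length", "max_isometric_force",
    "pennation_at_optimal", "emg_scale", "electromechanical_delay",
    "activation_time_constant", "deactivation_time_constant",
    "activation_nonlinearity",
]


class OverlayError(ValueError):
    pass


@dataclass
class OsimxOverlay:
    version: str = VERSION
    muscles: dict[str, MuscleTendonParams] = field(default_factory=dict)
    synergies: dict[str, dict] = field(default_factory=dict)
    # group -> {"muscles": [...], "W": (K, M) array}
    contact: dict[str, ContactModel] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def write_osimx(overlay: OsimxOverlay, path, merge: bool = True) -> None:
    """Write the overlay; with ``merge`` and an existing file, blocks not
    present in ``overlay`` are preserved from the file."""
    import os
    base = OsimxOverlay()
    if merge and os.path.exists(path):
        base = read_osimx(path)
    if overlay.muscles:
        base.muscles = overlay.muscles
    if overlay.synergies:
        base.synergies = overlay.synergies
    if overlay.contact:
        base.contact = overlay.contact
    base.provenance = {**base.provenance, **overlay.provenance}

    root = etree.Element("NMSKitModel", version=VERSION)
    for k, v in base.provenance.items():
        root.set(k, str(v))
    if base.muscles:
        ms = etree.SubElement(root, "MTPMuscleSet")
        for name, p in base.muscles.items():
            mu = etree.SubElement(ms, "muscle", name=name)
            for f in _MUSCLE_FIELDS:
                etree.SubElement(mu, f).text = repr(float(getattr(p, f)))
    if base.synergies:
        ss = etree.SubElement(root, "RCNLSynergySet")
        for gname, d in base.synergies.items():
            g = etree.SubElement(ss, "group", name=gname)
            etree.SubElement(g, "muscles").text = " ".join(d["muscles"])
            W = np.asarray(d["W"], float)
            for row in W:
                etree.SubElement(g, "synergy_vector").text = " ".join(
                    repr(float(v)) for v in row)
    if base.contact:
        cs = etree.SubElement(root, "GCPContactSurfaceSet")
        for side, cm in base.contact.items():
            s = etree.SubElement(cs, "surface", side=side,
                                 rows=str(cm.rows), cols=str(cm.cols))
            etree.SubElement(s, "stiffness").text = " ".join(
                repr(float(v)) for v in cm.stiffness)
            for f in ("damping", "viscous_friction", "dynamic_friction",
                      "resting_length", "smoothing",
                      "transition_velocity"):
                etree.SubElement(s, f).text = repr(float(getattr(cm, f)))
            st = etree.SubElement(s, "stations")
            for seg, loc in cm.stations:
                etree.SubElement(st, "station", segment=seg).text = \
                    f"{float(loc[0])!r} {float(loc[1])!r}"
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


def read_osimx(path) -> OsimxOverlay:
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "NMSKitModel":
        raise OverlayError(f"{path}: not an overlay file "
                           f"(root <{root.tag}>)")
    version = root.get("version")
    if version != VERSION:
        raise OverlayError(f"{path}: overlay version {version!r} needs "
                           f"migration to {VERSION!r}")
    out = OsimxOverlay(version=version,
                       provenance={k: v for k, v in root.attrib.items()
                                   if k != "version"})
    ms = root.find("MTPMuscleSet")
    if ms is not None:
        for mu in ms.findall("muscle"):
            kw = {f: float(mu.findtext(f)) for f in _MUSCLE_FIELDS
                  if mu.findtext(f) is not None}
            out.muscles[mu.get("name")] = MuscleTendonParams(**kw)
    ss = root.find("RCNLSynergySet")
    if ss is not None:
        for g in ss.findall("group"):
            W = np.array([[float(v) for v in sv.text.split()]
                          for sv in g.findall("synergy_vector")])
            out.synergies[g.get("name")] = {
                "muscles": g.findtext("muscles").split(), "W": W}
    cs = root.find("GCPContactSurfaceSet")
    if cs is not None:
        for s in cs.findall("surface"):
            stations = [(st.get("segment"),
                         np.array([float(v) for v in st.text.split()]))
                        for st in s.find("stations").findall("station")]
            out.contact[s.get("side")] = ContactModel(
                rows=int(s.get("rows")), cols=int(s.get("cols")),
                stiffness=np.array(
                    [float(v) for v in s.findtext("stiffness").split()]),
                stations=stations,
                damping=float(s.findtext("damping")),
                viscous_friction=float(s.findtext("viscous_friction")),
                dynamic_friction=float(s.findtext("dynamic_friction")),
                resting_length=float(s.findtext("resting_length")),
                smoothing=float(s.findtext("smoothing")),
                transition_velocity=float(
                    s.findtext("transition_velocity")))
    return out


def apply_overlay(model: Model, overlay: OsimxOverlay) -> Model:
    """Return a copy of ``model`` with the overlay's muscle parameters
    attached; name mismatches are errors here (deferred validation)."""
    out = model.copy()
    for name, p in overlay.muscles.items():
        if name not in out.muscles:
            raise OverlayError(f"overlay names unknown muscle {name!r}")
        out.muscles[name].params = p
    for gname, d in overlay.synergies.items():
        for m in d["muscles"]:
            if m not in out.muscles:
                raise OverlayError(
                    f"synergy group {gname!r} names unknown muscle {m!r}")
    return out
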