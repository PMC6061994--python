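"""Model serialization to and from an XML dialect (``.mmx`` files).

The schema is this package's own (documented in the README); it is
deliberately small: a ``MuskelModel`` root with a schema-version attribute,
a gravity element, and a nested tree of ``component`` elements, each
carrying typed ``property``, ``socket``, and ``input`` children.  Output is
deterministic — fixed element order, fixed attribute order, and floats
printed with 17 significant digits — so serializing the same in-memory
model twice is byte-identical and serialize(deserialize(text)) is the
identity on canonical files.
"""

from __future__ import annotations

import warnings
from xml.etree import ElementTree as ET

import numpy as np

from .components import ComponentSpec, ModelSpec, ModelError, Property, validate_model

__all__ = ["serialize_model", "deserialize_model", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _fmt_seq(values) -> str:
    return " ".join(_fmt(v) for v in np.asarray(values, dtype=float).ravel())


def _value_type(value) -> str:
    if isinstance(value, bool):
        return "bool"
    if isinstance(value, (int, float, np.floating)):
        return "float"
    if isinstance(value, str):
        return "str"
    if isinstance(value, np.ndarray):
        if value.shape == (3,):
            return "vec3"
        if value.shape == (3, 3):
            return "mat33"
        if value.ndim == 1:
            return "floats"
        raise ModelError(f"unsupported property array shape {value.shape}")
    if isinstance(value, list):
        return "pathpoints"
    raise ModelError(f"unsupported property value type {type(value).__name__}")


def _write_component(lines, comp: ComponentSpec, indent: str) -> None:
    lines.append(f'{indent}<component kind="{comp.kind}" name="{comp.name}">')
    inner = indent + "  "
    for sname, target in comp.sockets.items():
        lines.append(f'{inner}<socket name="{sname}">{target}</socket>')
    for iname, src in comp.inputs.items():
        lines.append(f'{inner}<input name="{iname}">{src}</input>')
    for pname, prop in comp.properties.items():
        vtype = _value_type(prop.value)
        units = f' units="{prop.units}"' if prop.units else ""
        head = f'{inner}<property name="{pname}" type="{vtype}"{units}>'
        if vtype == "float":
            lines.append(head + _fmt(prop.value) + "</property>")
        elif vtype == "bool":
            lines.append(head + ("true" if prop.value else "false") + "</property>")
        elif vtype == "str":
            lines.append(head + str(prop.value) + "</property>")
        elif vtype in ("vec3", "mat33", "floats"):
            lines.append(head + _fmt_seq(prop.value) + "</property>")
        else:  # pathpoints
            lines.append(head)
            for body, loc in prop.value:
                lines.append(f'{inner}  <point body="{body}">{_fmt_seq(loc)}</point>')
            lines.append(f"{inner}</property>")
    for child in comp.children:
        _write_component(lines, child, inner)
    lines.append(f"{indent}</component>")


def serialize_model(model: ModelSpec) -> str:
    """Render a validated model as canonical XML text."""
    validate_model(model)
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append(f'<MuskelModel schema="{SCHEMA_VERSION}" name="{model.name}">')
    lines.append(f'  <gravity units="m/s^2">{_fmt_seq(model.gravity)}</gravity>')
    for comp in model.components:
        _write_component(lines, comp, "  ")
    lines.append("</MuskelModel>")
    return "\n".join(lines) + "\n"


def _parse_floats(text: str, n=None) -> np.ndarray:
    vals = np.array([float(t) for t in (text or "").split()])
    if n is not None and vals.size != n:
        raise ModelError(f"expected {n} numbers, found {vals.size}")
    return vals


def _complain(msg: str, strict: bool) -> None:
    if strict:
        raise ModelError(msg)
    warnings.warn(msg, stacklevel=3)


def _parse_property(el, strict: bool) -> tuple[str, Property]:
    name = el.get("name")
    if name is None:
        raise ModelError("property element is missing its name attribute")
    vtype = el.get("type", "float")
    units = el.get("units", "")
    for attr in el.keys():
        if attr not in ("name", "type", "units"):
            _complain(f"unknown attribute {attr!r} on property {name!r}", strict)
    text = (el.text or "").strip()
    if vtype == "float":
        value = float(text)
    elif vtype == "bool":
        if text not in ("true", "false"):
            raise ModelError(f"property {name!r}: bool must be 'true' or 'false'")
        value = text == "true"
    elif vtype == "str":
        value = text
    elif vtype == "vec3":
        value = _parse_floats(text, 3)
    elif vtype == "mat33":
        value = _parse_floats(text, 9).reshape(3, 3)
    elif vtype == "floats":
        value = _parse_floats(text)
    elif vtype == "pathpoints":
        value = []
        for pt in el:
            if pt.tag != "point":
                _complain(f"unknown element {pt.tag!r} inside property {name!r}", strict)
                continue
            value.append((pt.get("body"), _parse_floats(pt.text, 3)))
    else:
        raise ModelError(f"property {name!r} has unsupported type {vtype!r}")
    return name, Property(value, units)


def _parse_component(el, strict: bool) -> ComponentSpec:
    kind = el.get("kind")
    name = el.get("name")
    if kind is None or name is None:
        raise ModelError("component element requires kind and name attributes")
    comp = ComponentSpec(name=name, kind=kind)
    for child in el:
        if child.tag == "socket":
            comp.sockets[child.get("name")] = (child.text or "").strip()
        elif child.tag == "input":
            comp.inputs[child.get("name")] = (child.text or "").strip()
        elif child.tag == "property":
            pname, prop = _parse_property(child, strict)
            if pname in comp.properties:
                raise ModelError(f"component {name!r} repeats property {pname!r}")
            comp.properties[pname] = prop
        elif child.tag == "component":
            comp.children.append(_parse_component(child, strict))
        else:
            _complain(f"unknown element {child.tag!r} in component {name!r}", strict)
    return comp


_REQUIRED_PROPS = {
    "body": ("mass", "com", "inertia"),
    "joint": ("type", "axis"),
    "marker": ("location", "weight"),
    "muscle": ("path",),
    "contact": ("center", "radius", "plane_point", "plane_normal", "stiffness", "dissipation"),
    "coordinate_limit_force": ("lower", "upper", "stiffness", "damping"),
}


def _check_required(comp: ComponentSpec) -> None:
    for prop in _REQUIRED_PROPS.get(comp.kind, ()):
        if prop not in comp.properties:
            raise ModelError(
                f"component {comp.name!r} (kind {comp.kind!r}) is missing required "
                f"property {prop!r}"
            )
    for child in comp.children:
        _check_required(child)


def deserialize_model(xml_text: str, strict: bool = True) -> ModelSpec:
    """Parse model XML; strict mode rejects unknown elements and attributes,
    lenient mode downgrades them to warnings.  The parsed model is validated
    before it is returned."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise ModelError(f"malformed XML: {exc}") from exc
    if root.tag != "MuskelModel":
        raise ModelError(f"root element must be MuskelModel, found {root.tag!r}")
    version = root.get("schema")
    if version != SCHEMA_VERSION:
        raise ModelError(f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})")
    model = ModelSpec(name=root.get("name", "model"))
    for el in root:
        if el.tag == "gravity":
            model.gravity = _parse_floats(el.text, 3)
        elif el.tag == "component":
            model.components.append(_parse_component(el, strict))
        else:
            _complain(f"unknown element {el.tag!r} in MuskelModel", strict)
    for comp in model.components:
        _check_required(comp)
    validate_model(model)
    return model
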