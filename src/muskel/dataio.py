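"""Labeled time-series tables, motion-capture file dialects, and reporters.

:class:`DataTable` is the in-memory container backing all file I/O: a
strictly increasing time column, named data columns (scalars, or one
3-vector per marker), and a metadata map holding per-column units plus
arbitrary header entries.  TRC files carry marker trajectories; STO/MOT
files carry scalar time series (MOT is treated as the STO dialect with the
same ``inDegrees`` header handling).  Angle columns are stored internally
in radians; unit conversions are explicit operations, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .components import ModelError, resolve_output

__all__ = [
    "DataTable",
    "read_trc",
    "write_trc",
    "read_sto",
    "write_sto",
    "read_mot",
    "write_mot",
    "trc_to_meters",
    "degrees_to_radians",
    "report_outputs",
    "format_table",
]


@dataclass
class DataTable:
    """Time-indexed columns with units metadata."""

    time: np.ndarray
    columns: dict = field(default_factory=dict)  # name -> (n,) or (n, 3)
    units: dict = field(default_factory=dict)  # name -> units string
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ModelError("table time column must be strictly increasing")
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            self.columns[name] = col
            if col.shape[0] != n:
                raise ModelError(f"column {name!r} length {col.shape[0]} != {n} rows")
            if col.ndim not in (1, 2) or (col.ndim == 2 and col.shape[1] != 3):
                raise ModelError(f"column {name!r} must be scalar or 3-vector valued")
            if name not in self.units:
                raise ModelError(f"column {name!r} has no units metadata")

    @property
    def nrows(self) -> int:
        return int(self.time.size)

    def column(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise ModelError(f"no column {name!r}; available: {list(self.columns)}")
        return self.columns[name]


def _data_rate(table: DataTable) -> float:
    if "DataRate" in table.meta:
        return float(table.meta["DataRate"])
    if table.nrows < 2:
        return 0.0
    return float(round(1.0 / np.median(np.diff(table.time))))


# ---------------------------------------------------------------------------
# TRC (marker trajectories)


def read_trc(text: str, strict: bool = True) -> DataTable:
    """Parse the TRC marker dialect (tab-separated, typed header rows).

    Units are recorded as read (mm stays mm, flagged in metadata); use
    :func:`trc_to_meters` for explicit conversion.  Frames with missing
    coordinate cells are marked invalid (NaN) with a warning.
    """
    lines = text.splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise ModelError("not a TRC file: missing PathFileType header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    n_frames = int(header.get("NumFrames", 0))
    n_markers = int(header.get("NumMarkers", 0))
    units = header.get("Units", "m")
    marker_row = lines[3].split("\t")
    markers = [m for m in marker_row[2:] if m.strip()]
    if len(markers) != n_markers:
        raise ModelError(f"NumMarkers={n_markers} but {len(markers)} marker labels found")

    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise ModelError(f"NumFrames={n_frames} but {len(data_lines)} data rows found")
    time = np.zeros(n_frames)
    data = np.full((n_frames, n_markers, 3), np.nan)
    bad_frames = []
    for r, ln in enumerate(data_lines):
        cells = ln.split("\t")
        time[r] = float(cells[1])
        row_ok = True
        for m in range(n_markers):
            for k in range(3):
                idx = 2 + 3 * m + k
                cell = cells[idx].strip() if idx < len(cells) else ""
                if not cell:
                    row_ok = False
                    continue
                data[r, m, k] = float(cell)
        if not row_ok:
            bad_frames.append(r)
    if bad_frames:
        warnings.warn(f"TRC frames with missing cells marked invalid: {bad_frames}")
    columns = {name: data[:, m, :] for m, name in enumerate(markers)}
    col_units = {name: units for name in markers}
    meta = {
        "DataRate": float(header.get("DataRate", 0.0)),
        "CameraRate": float(header.get("CameraRate", header.get("DataRate", 0.0))),
        "Units": units,
        "invalid_frames": bad_frames,
    }
    return DataTable(time=time, columns=columns, units=col_units, meta=meta)


def write_trc(table: DataTable, name: str = "markers.trc", precision: int = 6) -> str:
    """Render a marker table in the TRC dialect with deterministic formatting
    (6 significant digits by default)."""
    markers = list(table.columns)
    for m in markers:
        if table.columns[m].ndim != 2:
            raise ModelError(f"TRC columns must be 3-vector markers; {m!r} is scalar")
    units = table.meta.get("Units") or next(iter(table.units.values()), "m")
    n = table.nrows
    rate = _data_rate(table)
    cam = float(table.meta.get("CameraRate", rate))

    def num(x):
        return format(x, f".{precision}g")

    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{num(rate)}\t{num(cam)}\t{n}\t{len(markers)}\t{units}\t{num(rate)}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(markers) + ("\t\t" if markers else ""),
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(markers) + 1)),
    ]
    for r in range(n):
        cells = [str(r + 1), num(table.time[r])]
        for m in markers:
            v = table.columns[m][r]
            cells.extend("" if np.isnan(x) else num(x) for x in v)
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def trc_to_meters(table: DataTable) -> DataTable:
    """Explicitly convert a marker table to meters (mm values divide by 1000)."""
    units = table.meta.get("Units", "m")
    factor = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(units)
    if factor is None:
        raise ModelError(f"unknown marker units {units!r}")
    columns = {k: v * factor for k, v in table.columns.items()}
    meta = dict(table.meta)
    meta["Units"] = "m"
    return DataTable(time=table.time.copy(), columns=columns,
                     units={k: "m" for k in columns}, meta=meta)


# ---------------------------------------------------------------------------
# STO / MOT (scalar time series)


def read_sto(text: str) -> DataTable:
    """Parse the STO dialect: ``key=value`` header lines, ``endheader``, a
    tab-separated label row, then data rows.  The ``inDegrees`` flag is
    recorded in metadata; no silent angle conversion is performed."""
    lines = text.splitlines()
    meta = {}
    name = ""
    i = 0
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s == "endheader":
            break
        if "=" in s:
            k, v = s.split("=", 1)
            meta[k.strip()] = v.strip()
        elif s:
            name = s
    else:
        raise ModelError("not an STO file: missing endheader")
    labels = lines[i + 1].rstrip("\n").split("\t")
    if labels[0] != "time":
        raise ModelError("STO label row must start with 'time'")
    if len(set(labels)) != len(labels):
        raise ModelError("duplicate column labels in STO file")
    rows = [ln.split("\t") for ln in lines[i + 2:] if ln.strip()]
    data = np.array([[float(c) for c in row] for row in rows]) if rows else np.zeros((0, len(labels)))
    if data.size and data.shape[1] != len(labels):
        raise ModelError("STO data row width does not match label row")
    if "nColumns" in meta and int(meta["nColumns"]) != len(labels):
        raise ModelError(f"nColumns={meta['nColumns']} but {len(labels)} columns found")
    if "nRows" in meta and int(meta["nRows"]) != len(rows):
        raise ModelError(f"nRows={meta['nRows']} but {len(rows)} rows found")
    in_degrees = meta.get("inDegrees", "no").lower() == "yes"
    angle_units = "deg" if in_degrees else "rad"
    columns = {lab: data[:, k + 1] for k, lab in enumerate(labels[1:])}
    out_meta = {"name": name, "inDegrees": in_degrees}
    for k, v in meta.items():
        if k not in ("nRows", "nColumns", "inDegrees"):
            out_meta[k] = v
    return DataTable(
        time=data[:, 0] if data.size else np.zeros(0),
        columns=columns,
        units={lab: angle_units for lab in labels[1:]},
        meta=out_meta,
    )


def write_sto(table: DataTable, name: str = None, precision: int = 8) -> str:
    """Render a scalar table in the STO dialect."""
    labels = list(table.columns)
    for lab in labels:
        if table.columns[lab].ndim != 1:
            raise ModelError(f"STO columns must be scalar; {lab!r} is vector-valued")
    in_degrees = bool(table.meta.get("inDegrees", False))
    lines = [
        name if name is not None else str(table.meta.get("name", "table")),
        f"nRows={table.nrows}",
        f"nColumns={len(labels) + 1}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(["time"] + labels),
    ]
    fmt = f".{precision}g"
    for r in range(table.nrows):
        cells = [format(table.time[r], fmt)]
        cells += [format(table.columns[lab][r], fmt) for lab in labels]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


read_mot = read_sto
write_mot = write_sto


def degrees_to_radians(table: DataTable, columns=None) -> DataTable:
    """Explicit degree -> radian conversion of the named (default: all
    degree-unit) columns; clears the inDegrees flag when all are converted."""
    if columns is None:
        columns = [c for c in table.columns if table.units.get(c) == "deg"]
    out_cols = dict(table.columns)
    out_units = dict(table.units)
    for c in columns:
        out_cols[c] = np.deg2rad(table.columns[c])
        out_units[c] = "rad"
    meta = dict(table.meta)
    if all(u != "deg" for u in out_units.values()):
        meta["inDegrees"] = False
    return DataTable(time=table.time.copy(), columns=out_cols, units=out_units, meta=meta)


# ---------------------------------------------------------------------------
# reporters


def report_outputs(model, system, trajectory, output_paths) -> DataTable:
    """Evaluate named component outputs along a states trajectory.

    ``output_paths`` are ``'component_path:output_name'`` references; one
    column per request, in request order, with units from the output
    definitions.  Unknown outputs raise an error listing the candidates.
    """
    from . import muscle as _mu
    from .controllers import ExcitationSignal
    from .system import State

    resolved = []
    for ref in output_paths:
        path, comp, out, sig_type, units = resolve_output(model, ref)
        resolved.append((ref, path, comp, out, sig_type, units))

    n = len(trajectory.times)
    columns = {ref: (np.zeros((n, 3)) if s == "vec3" else np.zeros(n))
               for ref, _, _, _, s, _ in resolved}
    units = {ref: u for ref, _, _, _, _, u in resolved}

    for i in range(n):
        st = trajectory.state(i)
        muscle_cache = {}
        for ref, path, comp, out, sig_type, _ in resolved:
            if comp.kind == "joint":
                ci = system.coordinate_index(comp.name)
                columns[ref][i] = st.q[ci] if out == "q" else st.u[ci]
            elif comp.kind == "marker":
                from .multibody import point_kinematics

                mk = next(m for m in system.mb.markers if m.name == comp.name)
                x, _ = point_kinematics(system, st, mk.body, mk.location)
                columns[ref][i] = x
            elif comp.kind == "muscle":
                if comp.name not in muscle_cache:
                    muscle_cache[comp.name] = _evaluate_muscle(system, comp.name, st)
                columns[ref][i] = _muscle_output_value(muscle_cache[comp.name], out, st, system, comp.name)
            elif comp.kind == "controller":
                if comp.get("type") != "prescribed":
                    raise ModelError(
                        f"output {ref!r}: only prescribed controller excitations can be "
                        "reported post hoc"
                    )
                sig = ExcitationSignal(comp.get("times"), comp.get("values"))
                columns[ref][i] = sig(st.t)
    return DataTable(time=np.asarray(trajectory.times, dtype=float),
                     columns=columns, units=units, meta={"name": "outputs"})


def _evaluate_muscle(system, name, state):
    from . import muscle as _mu

    m = system.muscles[system.muscle_index(name)]
    l_MT, v_MT = _mu.path_length_and_speed(m.path, system, state)
    a = float(np.clip(state.z[m.a_slot], m.params.a_min, 1.0))
    if m.rigid_tendon:
        out = _mu.rigid_tendon_force(m.params, a, l_MT, v_MT)
    else:
        _, _, out = _mu.fiber_equilibrium_and_derivative(m.params, a, state.z[m.lm_slot], l_MT, v_MT)
    return a, out, m


def _muscle_output_value(cached, out, state, system, name):
    from . import muscle as _mu

    a, o, m = cached
    if out == "activation":
        return a
    if out == "metabolic_rate":
        return _mu.metabolic_rate(m.params, o, a, _default_muscle_mass(m.params))
    return {
        "path_length": o.l_MT, "path_speed": o.v_MT, "fiber_length": o.fiber_length,
        "norm_fiber_length": o.norm_fiber_length, "fiber_velocity_norm": o.norm_fiber_velocity,
        "tendon_length": o.l_T, "pennation": o.pennation, "force": o.force,
        "f_L": o.f_L, "f_V": o.f_V, "f_PE": o.f_PE, "f_T": o.f_T,
    }[out]


def _default_muscle_mass(params, sigma=0.25e6, rho=1059.7) -> float:
    """Muscle mass from PCSA = F_max / sigma and density rho [kg/m^3]."""
    return params.F_max / sigma * params.l_opt * rho


def format_table(table: DataTable, precision: int = 6, width: int = 14) -> str:
    """Console reporter: aligned fixed-width columns."""
    headers = ["time"]
    getters = [lambda r: table.time[r]]
    for name, col in table.columns.items():
        if col.ndim == 1:
            headers.append(name)
            getters.append(lambda r, c=col: c[r])
        else:
            for k, ax in enumerate("xyz"):
                headers.append(f"{name}_{ax}")
                getters.append(lambda r, c=col, k=k: c[r, k])
    lines = ["".join(h.rjust(width) for h in headers)]
    for r in range(table.nrows):
        lines.append("".join(format(g(r), f"{width}.{precision}g") for g in getters))
    return "\n".join(lines) + "\n"
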