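"""Profile CSV dialect and dataset manifest I/O.

One profile per file.  Header lines carry geometry metadata as ``# key=value``
comments, followed by a ``position_mm,value`` column header and the data
rows::

    # field_cm=10
    # depth_cm=5.0
    # plane=in
    # kind=truth
    position_mm,value
    -170.0,0.009
    ...

``kind`` is ``truth`` or ``measurement`` and decides whether a
:class:`~profile_restore.simulate.Profile` (uniform grid) or a
:class:`~profile_restore.simulate.DiscreteMeasurement` is returned.  Unknown
header keys are preserved in a ``meta`` mapping on read and re-emitted on
write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import BeamGeometry, DiscreteMeasurement, Profile

__all__ = ["read_profile", "write_profile", "ProfileParseError"]

_REQUIRED_KEYS = ("field_cm", "depth_cm", "plane", "kind")


class ProfileParseError(ValueError):
    """Malformed profile file; carries the offending line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def write_profile(obj: Profile | DiscreteMeasurement, path: str | Path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    geo = obj.geometry
    if geo is None:
        raise ValueError("object has no geometry metadata to serialize")
    if isinstance(obj, Profile):
        kind = "truth"
        pos, vals = obj.positions_mm, obj.values
    else:
        kind = "measurement"
        pos, vals = obj.positions_mm, obj.readings
    lines = [
        f"# field_cm={geo.field_size_cm:g}",
        f"# depth_cm={geo.depth_cm:g}",
        f"# plane={geo.plane}",
        f"# kind={kind}",
        f"# ssd_cm={geo.ssd_cm:g}",
    ]
    if isinstance(obj, DiscreteMeasurement) and obj.noise_seed is not None:
        lines.append(f"# noise_seed={obj.noise_seed}")
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}={v}")
    lines.append("position_mm,value")
    for p, v in zip(pos, vals):
        lines.append(f"{p:.6g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> Profile | DiscreteMeasurement:
    path = Path(path)
    meta: dict[str, str] = {}
    pos: list[float] = []
    vals: list[float] = []
    saw_header = False
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ProfileParseError(path, line_no, f"metadata line without '=': {raw!r}")
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
        elif not saw_header:
            if line.replace(" ", "") != "position_mm,value":
                raise ProfileParseError(path, line_no, f"expected 'position_mm,value' header, got {raw!r}")
            saw_header = True
        else:
            parts = line.split(",")
            if len(parts) != 2:
                raise ProfileParseError(path, line_no, f"expected two comma-separated fields, got {raw!r}")
            try:
                pos.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError:
                raise ProfileParseError(path, line_no, f"non-numeric row: {raw!r}") from None
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ProfileParseError(path, 0, f"missing required metadata key '{key}'")
    p = np.asarray(pos)
    v = np.asarray(vals)
    if p.size < 2:
        raise ProfileParseError(path, 0, "fewer than 2 data rows")
    if np.any(np.diff(p) <= 0):
        raise ProfileParseError(path, 0, "positions are not strictly increasing")
    geo = BeamGeometry(
        float(meta["field_cm"]),
        float(meta["depth_cm"]),
        meta["plane"],
        float(meta.get("ssd_cm", 90.0)),
    )
    kind = meta["kind"]
    known = {"field_cm", "depth_cm", "plane", "kind", "ssd_cm", "noise_seed"}
    extra = {k: v for k, v in meta.items() if k not in known}
    if kind == "truth":
        obj = Profile(p, v, geometry=geo)
    elif kind == "measurement":
        seed = int(meta["noise_seed"]) if "noise_seed" in meta else None
        obj = DiscreteMeasurement(geo, p, v, noise_seed=seed)
    else:
        raise ProfileParseError(path, 0, f"unknown kind {kind!r} (expected truth|measurement)")
    object.__setattr__(obj, "meta", extra)
    return obj
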