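"""Shared file I/O: curve CSVs, image stacks (TIFF + JSON sidecar), reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fcs import FcsCurve
from .flow import FlowProfile
from .imaging import TrastImage, TrastImageStack
from .trast import TrastCurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_stack",
    "write_stack",
    "write_maps",
    "CurveParseError",
]

_HEADERS = {
    "trast": ("width_s", "value"),
    "fcs": ("lag_s", "g"),
    "flow": ("t_s", "f_norm"),
}


class CurveParseError(ValueError):
    """Malformed curve file; message names the offending line."""


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise CurveParseError(
            f"{path}:{lineno}: cannot parse {token!r} as a decimal number "
            "(period decimal separator required)"
        ) from None


def read_curve(path: str | Path, kind: str):
    """Read a TRAST / FCS / flow curve from its CSV representation.

    Expected headers: ``width_s,value[,sd]`` (trast), ``lag_s,g[,sd]``
    (fcs), ``t_s,f_norm`` (flow).  Any malformed header, token or
    non-monotone x grid raises :class:`CurveParseError` naming the line.
    """
    if kind not in _HEADERS:
        raise ValueError(f"kind must be one of {sorted(_HEADERS)}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CurveParseError(f"{path}:1: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    want = _HEADERS[kind]
    if tuple(header[: len(want)]) != want:
        raise CurveParseError(
            f"{path}:1: expected header starting {','.join(want)!r}, "
            f"got {lines[0]!r}"
        )
    has_sd = len(header) > len(want) and header[len(want)] == "sd"
    meta: dict = {}
    xs, ys, sds = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line.lstrip("#").partition("=")
                meta[k.strip()] = v.strip()
            continue
        tokens = [t.strip() for t in line.split(",")]
        n_cols = 2 + int(has_sd)
        if len(tokens) < 2 or len(tokens) > n_cols:
            raise CurveParseError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(tokens)} "
                "(note: comma decimal separators are not accepted)"
            )
        xs.append(_parse_float(tokens[0], path, lineno))
        ys.append(_parse_float(tokens[1], path, lineno))
        if has_sd and len(tokens) > 2 and tokens[2]:
            sds.append(_parse_float(tokens[2], path, lineno))
    x = np.array(xs)
    if np.any(np.diff(x) <= 0):
        bad = int(np.argmax(np.diff(x) <= 0)) + 3
        raise CurveParseError(f"{path}:{bad}: x grid must be strictly increasing")
    sd = np.array(sds) if len(sds) == len(xs) and sds else None
    if kind == "trast":
        w0 = float(meta["w0"]) if "w0" in meta else None
        return TrastCurve(widths=x, values=np.array(ys), sd=sd, w0=w0)
    if kind == "fcs":
        irr = float(meta["irradiance"]) if "irradiance" in meta else None
        return FcsCurve(lags=x, g=np.array(ys), sd=sd, irradiance=irr)
    vel = float(meta["velocity"]) if "velocity" in meta else None
    return FlowProfile(t=x, f_norm=np.array(ys), velocity=vel)


def write_curve(curve, path: str | Path) -> None:
    """Write a curve object as CSV; full float precision, lossless round trip."""
    path = Path(path)
    if isinstance(curve, TrastCurve):
        header, x, y, sd = "width_s,value", curve.widths, curve.values, curve.sd
        meta = {"w0": curve.w0}
    elif isinstance(curve, FcsCurve):
        header, x, y, sd = "lag_s,g", curve.lags, curve.g, curve.sd
        meta = {} if curve.irradiance is None else {"irradiance": curve.irradiance}
    elif isinstance(curve, FlowProfile):
        header, x, y, sd = "t_s,f_norm", curve.t, curve.f_norm, None
        meta = {} if curve.velocity is None else {"velocity": curve.velocity}
    else:
        raise TypeError(f"cannot serialize {type(curve)!r}")
    lines = [header + (",sd" if sd is not None else "")]
    lines += [f"# {k} = {v!r}" for k, v in meta.items()]
    for i in range(len(x)):
        row = f"{float(x[i])!r},{float(y[i])!r}"
        if sd is not None:
            row += f",{float(sd[i])!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def write_stack(stack: TrastImageStack, path: str | Path) -> None:
    """Multi-page TIFF of the frames plus a JSON sidecar with metadata.

    Optional background and w0 reference frames are appended as extra
    pages; the sidecar records the page layout.
    """
    import tifffile

    path = Path(path)
    pages = [stack.frames.astype(np.float32)]
    layout = {"frames": stack.frames.shape[0]}
    if stack.background is not None:
        pages.append(stack.background.astype(np.float32)[None])
        layout["background"] = 1
    if stack.w0_refs is not None:
        pages.append(np.stack(stack.w0_refs).astype(np.float32))
        layout["w0_refs"] = 2
    tifffile.imwrite(path, np.concatenate(pages, axis=0))
    sidecar = {
        "widths_s": stack.widths.tolist(),
        "w0_s": stack.w0,
        "duty_cycle": stack.duty_cycle,
        "t_ill_s": stack.t_ill,
        "layout": layout,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> TrastImageStack:
    """Read a stack written by :func:`write_stack`."""
    import tifffile

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = np.asarray(tifffile.imread(path), dtype=float)
    n = sidecar["layout"]["frames"]
    frames = pages[:n]
    cursor = n
    background = None
    if "background" in sidecar["layout"]:
        background = pages[cursor]
        cursor += 1
    refs = None
    if "w0_refs" in sidecar["layout"]:
        refs = (pages[cursor], pages[cursor + 1])
    return TrastImageStack(
        frames=frames,
        widths=np.array(sidecar["widths_s"]),
        w0=sidecar["w0_s"],
        duty_cycle=sidecar["duty_cycle"],
        t_ill=sidecar["t_ill_s"],
        background=background,
        w0_refs=refs,
    )


def write_maps(image: TrastImage, path: str | Path) -> None:
    """Write fitted per-pixel maps as a 4-page 32-bit float TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack(
            [image.a_map, image.tau_map, image.intensity_map, image.quality_map]
        ).astype(np.float32),
    )
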