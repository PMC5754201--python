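"""Multi-channel Z-stack containers and TIFF/OME-TIFF input/output.

The canonical in-memory layout is a 4D array indexed ``(z, y, x, c)``,
0-based, with half-open region-of-interest bounds in the X,Y plane.
Channel *roles* (``glia``, ``nsc``, ``neuron``, optionally further markers)
map biological meaning onto channel indices so that downstream analysis
never hard-codes channel order.

Metadata that TIFF cannot carry natively (channel roles, condition label,
Z spacing) travels in a YAML sidecar written next to the image file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "read_stack",
    "write_stack",
    "apply_roi",
    "sidecar_path",
]

#: Roles required by the chamber organisation chart.
CORE_ROLES = ("glia", "nsc", "neuron")

MIN_SLICES = 3  # three-point peak refinement needs a full stencil


@dataclass
class ImageStack:
    """A multi-channel confocal stack.

    Parameters
    ----------
    voxels:
        Non-negative intensities, shape ``(z, y, x, c)``. Integer input is
        promoted to ``float64`` on construction.
    channel_roles:
        Map from role name (``"glia"``, ``"nsc"``, ``"neuron"``, ...) to
        channel index. Roles must be unique and in range.
    z_spacing:
        Distance between consecutive slices in micrometres, if known.
        Depth positions are reported in slice units regardless; the
        spacing allows optional conversion.
    specimen_id, condition:
        Free-text provenance labels (e.g. condition ``"fed"``/``"starved"``).
    """

    voxels: np.ndarray
    channel_roles: dict[str, int]
    z_spacing: float | None = None
    specimen_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise ValueError(f"voxels must be 4D (z, y, x, c); got ndim={v.ndim}")
        if v.size == 0:
            raise ValueError("empty stack: every axis must have positive extent")
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")
        if v.min() < 0:
            raise ValueError("voxel intensities must be non-negative")
        if v.shape[0] < MIN_SLICES:
            raise ValueError(
                f"too few slices: {v.shape[0]} < {MIN_SLICES} "
                "(three-point peak refinement needs at least 3)"
            )
        self.voxels = v
        n_channels = v.shape[3]
        seen: dict[int, str] = {}
        for role, idx in self.channel_roles.items():
            if not (0 <= int(idx) < n_channels):
                raise ValueError(
                    f"invalid channel index {idx} for role {role!r}: "
                    f"stack has {n_channels} channels"
                )
            if idx in seen:
                raise ValueError(
                    f"roles {seen[idx]!r} and {role!r} both map to channel {idx}"
                )
            seen[int(idx)] = role
        if self.z_spacing is not None and self.z_spacing <= 0:
            raise ValueError("z_spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a named role."""
        if role not in self.channel_roles:
            raise KeyError(
                f"unknown role {role!r}; available: {sorted(self.channel_roles)}"
            )
        return self.voxels[..., self.channel_roles[role]]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open X,Y bounding box ``[y0, y1) x [x0, x1)`` applied to every slice.

    Mirrors drawing a bounding box in the X,Y plane to exclude off-target
    signal (e.g. tracheal GFP) while keeping the full Z extent.
    """

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (0 <= self.y0 < self.y1 and 0 <= self.x0 < self.x1):
            raise ValueError(
                f"invalid ROI bounds (need 0 <= y0 < y1 and 0 <= x0 < x1): {self}"
            )

    @classmethod
    def full(cls, stack: "ImageStack") -> "RegionOfInterest":
        """The ROI covering the whole X,Y plane of *stack*."""
        _, ny, nx, _ = stack.shape
        return cls(0, ny, 0, nx)

    def validate_for(self, stack: "ImageStack") -> None:
        _, ny, nx, _ = stack.shape
        if self.y1 > ny or self.x1 > nx:
            raise ValueError(
                f"ROI {self} exceeds stack X,Y extent ({ny}, {nx})"
            )

    @property
    def area(self) -> int:
        return (self.y1 - self.y0) * (self.x1 - self.x0)

    def as_dict(self) -> dict[str, int]:
        return {"y0": self.y0, "y1": self.y1, "x0": self.x0, "x1": self.x1}


def sidecar_path(path: str | Path) -> Path:
    """YAML metadata sidecar for an image file (``image.tif`` -> ``image.tif.yaml``)."""
    return Path(str(path) + ".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* to TIFF with a YAML metadata sidecar.

    Voxels are stored as ``float32`` planes with axes ``ZYXC``; roles,
    condition, specimen id and Z spacing go to the sidecar so that
    :func:`read_stack` round-trips the stack losslessly.
    """
    path = Path(path)
    data = stack.voxels.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "ZYXC"})
    meta = {
        "channel_roles": {k: int(v) for k, v in stack.channel_roles.items()},
        "z_spacing": None if stack.z_spacing is None else float(stack.z_spacing),
        "specimen_id": stack.specimen_id,
        "condition": stack.condition,
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def _normalize_axes(data: np.ndarray, axes: str | None) -> np.ndarray:
    """Bring a TIFF array to canonical ``(z, y, x, c)`` order."""
    if data.ndim == 3:
        # single-channel stack: add a trailing channel axis
        if axes in (None, "ZYX", "QYX", "IYX"):
            return data[..., np.newaxis]
        raise ValueError(f"cannot interpret 3D TIFF with axes {axes!r}")
    if data.ndim != 4:
        raise ValueError(f"expected 3D or 4D TIFF; got ndim={data.ndim}")
    if axes is None:
        return data  # assume canonical ZYXC
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if sorted(axes) != sorted("ZYXC"):
        raise ValueError(f"unsupported TIFF axes {axes!r} (need a permutation of ZYXC)")
    return np.transpose(data, [axes.index(a) for a in "ZYXC"])


def read_stack(
    path: str | Path,
    channel_roles: dict[str, int] | None = None,
    z_spacing: float | None = None,
    specimen_id: str | None = None,
    condition: str | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into canonical ``(z, y, x, c)`` order.

    Metadata resolution order: explicit arguments override the YAML
    sidecar, which overrides defaults. ``channel_roles`` must be known
    from one of those sources.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
    except (OSError, ValueError, IndexError) as exc:
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    data = _normalize_axes(np.asarray(data), axes)

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    roles = channel_roles if channel_roles is not None else meta.get("channel_roles")
    if roles is None:
        raise ValueError(
            f"channel roles for {path} not given and no sidecar found"
        )
    return ImageStack(
        voxels=data,
        channel_roles={str(k): int(v) for k, v in roles.items()},
        z_spacing=z_spacing if z_spacing is not None else meta.get("z_spacing"),
        specimen_id=specimen_id if specimen_id is not None else meta.get("specimen_id", ""),
        condition=condition if condition is not None else meta.get("condition", ""),
    )


def apply_roi(stack: ImageStack, roi: RegionOfInterest) -> ImageStack:
    """Restrict *stack* to the X,Y bounding box; Z extent and channels unchanged."""
    roi.validate_for(stack)
    cropped = stack.voxels[:, roi.y0 : roi.y1, roi.x0 : roi.x1, :].copy()
    return stack.with_voxels(cropped)
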