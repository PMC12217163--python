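"""Image and table input/output.

Every pixel container in the pipeline is an :class:`ImageStack` with a fixed
five-axis layout ``(channel, time, z, y, x)``; singleton axes are kept so that
downstream code never branches on dimensionality.  Stacks are stored as
multi-page 16-bit (or floating point) TIFF with a YAML sidecar holding the
acquisition metadata (pixel size, z-step, frame interval, channel names, axis
order).  The sidecar — not TIFF tags — is authoritative, which keeps the
format unambiguous across TIFF writer dialects.

Tabular data (vesicle traces, foci, ground truth) travels as plain CSV with a
comma separator, ``.`` decimal and a mandatory header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("lnptrace")

AXES = "CTZYX"

#: Canonical column order of the per-vesicle trace table.
TRACE_COLUMNS = [
    "vesicle_id", "cell_id", "frame", "time_s", "channel",
    "x_px", "y_px", "z_index",
    "raw_mean", "local_background", "corrected", "bleach_corrected",
    "normalized", "t0_frame",
]

#: Canonical column order of the foci table.
FOCI_COLUMNS = [
    "frame", "channel", "focus_id", "x_px", "y_px",
    "area_px", "total_intensity", "cell_id",
]


@dataclass
class ImageStack:
    """A multi-channel time-lapse z-stack with physical metadata.

    Parameters
    ----------
    data:
        Array ordered ``(c, t, z, y, x)``.  Integer or floating point;
        intensities must be non-negative.
    pixel_size_nm:
        Lateral pixel size in nanometres.
    z_step_nm:
        Axial plane spacing in nanometres.
    frame_interval_s:
        Time between consecutive frames in seconds.
    channel_names:
        One name per channel; defaults to ``ch0, ch1, ...``.
    """

    data: np.ndarray
    pixel_size_nm: float
    z_step_nm: float = 500.0
    frame_interval_s: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must have 5 axes (c,t,z,y,x); got {self.data.ndim}"
            )
        for name in ("pixel_size_nm", "z_step_nm", "frame_interval_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensity values must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    data = stack.data
    pages = data.reshape(-1, data.shape[-2], data.shape[-1])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axes": AXES,
        "shape": list(data.shape),
        "dtype": str(data.dtype),
        "pixel_size_nm": float(stack.pixel_size_nm),
        "z_step_nm": float(stack.z_step_nm),
        "frame_interval_s": float(stack.frame_interval_s),
        "channel_names": list(stack.channel_names),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


_REQUIRED_META = ("axes", "shape", "pixel_size_nm", "z_step_nm",
                  "frame_interval_s", "channel_names")


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack`.

    The YAML sidecar is required and authoritative; a plain 2-D TIFF with a
    sidecar declaring ``axes: YX`` is promoted to shape ``(1,1,1,H,W)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar.name} for {path.name}"
        )
    meta = yaml.safe_load(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"metadata sidecar {sidecar.name} is missing field {key!r}")
    data = tifffile.imread(path)
    axes = str(meta["axes"]).upper()
    # promote missing leading axes (e.g. "YX" -> "CTZYX") with singletons
    for ax in reversed(AXES[: 5 - len(axes)]):
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    shape = tuple(int(s) for s in meta["shape"])
    if int(np.prod(shape)) != data.size:
        raise ValueError(
            f"TIFF page data ({data.size} px) does not match sidecar shape {shape}"
        )
    data = data.reshape(shape)
    return ImageStack(
        data=data,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        z_step_nm=float(meta["z_step_nm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channel_names=list(meta["channel_names"]),
    )


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label image (0 = background) as TIFF."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must be integer-valued")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16 if labels.max() < 2**16 else np.int32))
    return path


def read_labels(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a label image and relabel it to contiguous ids.

    Returns ``(labels, count)`` where labels are contiguous ``0..count`` with
    0 reserved for background.
    """
    img = tifffile.imread(Path(path))
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"label image {path} is not integer-valued ({img.dtype})")
    return relabel(img)


def relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary positive labels to contiguous ``1..n``; keep 0 = background."""
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(values, start=1):
        out[labels == old] = new
    count = len(values)
    logger.info("relabel: %d objects", count)
    return out, count
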