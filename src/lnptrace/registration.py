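"""Bead-based channel alignment and chromatic-aberration correction.

Multichannel widefield data acquired through an image splitter (or with
sequential filter changes) shows two kinds of channel misalignment: a rigid
offset between channels, and a lateral chromatic aberration that grows
linearly with field position.  Both are calibrated from a reference field of
sub-diffraction microspheres imaged in every channel, and corrected at
1-pixel (lateral) / 1-z-interval (axial) accuracy by image translation:

1. weighted bead centroids are detected per channel;
2. the integer translation maximizing the number of matched bead pairs is
   fitted per channel;
3. the residual centroid displacements are regressed linearly against field
   position (x and y independently), giving a per-column/per-row correction
   rounded to the nearest integer pixel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ImageStack

logger = logging.getLogger("lnptrace")


@dataclass
class ChannelAlignment:
    """Rigid + chromatic alignment of one channel relative to the reference."""

    dx: int = 0
    dy: int = 0
    dz: int = 0
    slope_x: float = 0.0
    intercept_x: float = 0.0
    slope_y: float = 0.0
    intercept_y: float = 0.0


@dataclass
class AlignmentModel:
    """Per-channel alignment; the reference channel maps to identity."""

    reference_channel: int = 0
    channels: dict[int, ChannelAlignment] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_channel": self.reference_channel,
            "channels": {str(k): asdict(v) for k, v in self.channels.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignmentModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            reference_channel=int(payload["reference_channel"]),
            channels={int(k): ChannelAlignment(**v)
                      for k, v in payload["channels"].items()},
        )


def detect_beads(stack: ImageStack, channel: int, *,
                 threshold: float | None = None,
                 window_radius_px: int = 10,
                 min_separation_px: float | None = None) -> pd.DataFrame:
    """Detect beads in one channel and return sub-pixel weighted centroids.

    The first time-point is used.  Candidate beads are local maxima above
    *threshold* (default: background median + 10 robust SDs); each centroid is
    the background-subtracted intensity-weighted mean position inside a cubic
    window of ``window_radius_px`` laterally (full z range axially).  Beads
    whose lateral window would be clipped by the image border are excluded.

    Returns a table with columns ``bead_id, x_px, y_px, z``.
    """
    vol = np.asarray(stack.data[channel, 0], dtype=float)  # (z,y,x)
    nz, h, w = vol.shape
    proj = vol.max(axis=0)
    med = float(np.median(proj))
    mad = float(np.median(np.abs(proj - med))) * 1.4826
    if threshold is None:
        threshold = med + 10.0 * max(mad, 1e-12)
    if min_separation_px is None:
        min_separation_px = 2.0 * window_radius_px

    # peak pixels: local maxima of the projection above threshold
    footprint = np.ones((3, 3), dtype=bool)
    maxima = (proj == ndimage.maximum_filter(proj, footprint=footprint))
    maxima &= proj > threshold
    labels, n = ndimage.label(maxima)
    peaks = ndimage.center_of_mass(maxima, labels, range(1, n + 1))
    # greedy non-maximum suppression by peak intensity
    peaks = sorted(peaks, key=lambda p: -proj[int(round(p[0])), int(round(p[1]))])
    kept: list[tuple[float, float]] = []
    for py, px in peaks:
        if all((py - qy) ** 2 + (px - qx) ** 2 >= min_separation_px ** 2
               for qy, qx in kept):
            kept.append((py, px))

    r = window_radius_px
    rows = []
    background = med
    zz = np.arange(nz, dtype=float)
    for py, px in kept:
        iy, ix = int(round(py)), int(round(px))
        if iy - r < 0 or iy + r >= h or ix - r < 0 or ix + r >= w:
            logger.info("detect_beads: bead near (%.0f, %.0f) clipped by border; "
                        "excluded", px, py)
            continue
        win = vol[:, iy - r:iy + r + 1, ix - r:ix + r + 1] - background
        win = np.clip(win, 0.0, None)
        total = win.sum()
        if total <= 0:
            continue
        ys = np.arange(iy - r, iy + r + 1, dtype=float)
        xs = np.arange(ix - r, ix + r + 1, dtype=float)
        cy = float((win.sum(axis=(0, 2)) * ys).sum() / total)
        cx = float((win.sum(axis=(0, 1)) * xs).sum() / total)
        cz = float((win.sum(axis=(1, 2)) * zz).sum() / total)
        rows.append({"x_px": cx, "y_px": cy, "z": cz})
    if not rows:
        raise ValueError(f"no beads detected in channel {channel}")
    df = pd.DataFrame(rows)
    df.insert(0, "bead_id", np.arange(len(df)))
    return df


def fit_integer_shift(reference: pd.DataFrame, target: pd.DataFrame, *,
                      match_radius_px: float = 0.5) -> tuple[int, int, int]:
    """Integer translation ``(dx, dy, dz)`` moving *target* beads onto *reference*.

    Maximizes the number of bead pairs within ``match_radius_px`` after the
    translation; candidates are the rounded pairwise displacements.  Ties go
    to the smallest shift norm, then lexicographically on ``(dz, dy, dx)``.
    """
    if len(reference) < 3 or len(target) < 3:
        raise ValueError("need at least 3 beads in each channel")
    ref = reference[["x_px", "y_px", "z"]].to_numpy(float)
    tgt = target[["x_px", "y_px", "z"]].to_numpy(float)
    diffs = ref[:, None, :] - tgt[None, :, :]          # shift to ADD to target
    candidates = np.unique(np.rint(diffs.reshape(-1, 3)).astype(int), axis=0)
    tree = cKDTree(ref)
    best = None
    for cand in candidates:
        moved = tgt + cand
        d, _ = tree.query(moved, distance_upper_bound=match_radius_px)
        score = int(np.isfinite(d).sum())
        norm = float(np.dot(cand, cand))
        key = (-score, norm, int(cand[2]), int(cand[1]), int(cand[0]))
        if best is None or key < best[0]:
            best = (key, cand, score)
    if best is None or best[2] == 0:
        raise ValueError("no candidate shift matches any bead")
    _, cand, _ = best
    return int(cand[0]), int(cand[1]), int(cand[2])


def match_beads(reference: pd.DataFrame, target: pd.DataFrame,
                shift: tuple[int, int, int] = (0, 0, 0), *,
                radius_px: float = 5.0) -> pd.DataFrame:
    """Mutual-nearest-neighbor bead pairing after applying *shift* to target.

    Returns one row per matched pair with reference positions and the residual
    displacement (target + shift − reference).
    """
    ref = reference[["x_px", "y_px", "z"]].to_numpy(float)
    tgt = target[["x_px", "y_px", "z"]].to_numpy(float) + np.asarray(shift, float)
    tree_r, tree_t = cKDTree(ref), cKDTree(tgt)
    d_rt, j_rt = tree_t.query(ref, distance_upper_bound=radius_px)
    d_tr, j_tr = tree_r.query(tgt, distance_upper_bound=radius_px)
    rows = []
    for i, (d, j) in enumerate(zip(d_rt, j_rt)):
        if np.isfinite(d) and j < len(tgt) and j_tr[j] == i:
            rows.append({
                "ref_x": ref[i, 0], "ref_y": ref[i, 1], "ref_z": ref[i, 2],
                "res_x": tgt[j, 0] - ref[i, 0],
                "res_y": tgt[j, 1] - ref[i, 1],
                "res_z": tgt[j, 2] - ref[i, 2],
            })
    return pd.DataFrame(rows)


def fit_chromatic_model(matches: pd.DataFrame) -> tuple[float, float, float, float]:
    """Least-squares lines of residual dx vs x and residual dy vs y.

    Returns ``(slope_x, intercept_x, slope_y, intercept_y)``.  A degenerate
    position range fixes the slope at 0 with the mean residual as intercept.
    """
    if len(matches) < 5:
        raise ValueError("need at least 5 matched beads spanning the field")

    def fit_axis(pos: np.ndarray, res: np.ndarray) -> tuple[float, float]:
        if np.ptp(pos) < 1e-9:
            logger.warning("fit_chromatic_model: degenerate position range; "
                           "slope fixed at 0")
            return 0.0, float(res.mean())
        slope, intercept = np.polyfit(pos, res, 1)
        return float(slope), float(intercept)

    sx, ix = fit_axis(matches["ref_x"].to_numpy(), matches["res_x"].to_numpy())
    sy, iy = fit_axis(matches["ref_y"].to_numpy(), matches["res_y"].to_numpy())
    return sx, ix, sy, iy


def fit_alignment(beads: ImageStack, reference_channel: int = 0, *,
                  detect_kwargs: dict | None = None) -> AlignmentModel:
    """Full calibration: detect beads in every channel, fit integer shift and
    chromatic model per non-reference channel."""
    detect_kwargs = detect_kwargs or {}
    ref = detect_beads(beads, reference_channel, **detect_kwargs)
    model = AlignmentModel(reference_channel=reference_channel)
    for ch in range(beads.n_channels):
        if ch == reference_channel:
            continue
        tgt = detect_beads(beads, ch, **detect_kwargs)
        # shift that moves target ONTO reference = -(target - reference)
        sx, sy, sz = fit_integer_shift(ref, tgt)
        matches = match_beads(ref, tgt, (sx, sy, sz))
        slope_x, int_x, slope_y, int_y = fit_chromatic_model(matches)
        model.channels[ch] = ChannelAlignment(
            dx=sx, dy=sy, dz=sz,
            slope_x=slope_x, intercept_x=int_x,
            slope_y=slope_y, intercept_y=int_y,
        )
    return model


def _translate_volume(vol: np.ndarray, align: ChannelAlignment) -> np.ndarray:
    """Apply integer shift + rounded per-position chromatic correction.

    ``align`` describes the displacement of this channel relative to the
    reference (target + shift_to_add = reference, i.e. the stored dx/dy/dz are
    already the correction to apply); the chromatic residual at corrected
    position x is removed by an additional per-column integer shift.
    """
    nz, h, w = vol.shape
    out = np.zeros_like(vol)
    # source index = output index - total correction; total correction at
    # output position p is dx - round(slope*p + intercept) (the rigid part
    # moves the data by +dx; the chromatic residual slope*p+intercept is
    # subtracted with 1-px accuracy)
    xs = np.arange(w)
    ys = np.arange(h)
    src_x = xs - align.dx + np.rint(align.slope_x * xs + align.intercept_x).astype(int)
    src_y = ys - align.dy + np.rint(align.slope_y * ys + align.intercept_y).astype(int)
    src_z = np.arange(nz) - align.dz
    ok_x = (src_x >= 0) & (src_x < w)
    ok_y = (src_y >= 0) & (src_y < h)
    ok_z = (src_z >= 0) & (src_z < nz)
    zz = src_z[ok_z][:, None, None]
    yy = src_y[ok_y][None, :, None]
    xx = src_x[ok_x][None, None, :]
    sub = vol[zz, yy, xx]
    out[np.ix_(ok_z, ok_y, ok_x)] = sub
    return out


def apply_alignment(stack: ImageStack, model: AlignmentModel) -> ImageStack:
    """Translate every non-reference channel onto the reference grid.

    Out-of-field pixels are filled with 0; the reference channel is returned
    unchanged.
    """
    data = np.array(stack.data, copy=True)
    for ch, align in model.channels.items():
        if ch >= stack.n_channels:
            raise ValueError(f"model channel {ch} not present in stack")
        for t in range(stack.n_frames):
            # the stored model maps target beads to reference via
            # target + (dx,dy,dz) + chromatic = reference; to correct the image
            # we move intensity by that same displacement
            data[ch, t] = _translate_volume(np.asarray(stack.data[ch, t]), align)
    return ImageStack(data, pixel_size_nm=stack.pixel_size_nm,
                      z_step_nm=stack.z_step_nm,
                      frame_interval_s=stack.frame_interval_s,
                      channel_names=list(stack.channel_names))


def mean_residual_distance(beads: ImageStack, reference_channel: int = 0, *,
                           detect_kwargs: dict | None = None) -> float:
    """Mean lateral centroid distance between matched beads of all channel
    pairs (reference vs others); the calibration quality metric."""
    detect_kwargs = detect_kwargs or {}
    ref = detect_beads(beads, reference_channel, **detect_kwargs)
    dists = []
    for ch in range(beads.n_channels):
        if ch == reference_channel:
            continue
        tgt = detect_beads(beads, ch, **detect_kwargs)
        shift = fit_integer_shift(ref, tgt)
        matches = match_beads(ref, tgt, shift)
        # match_beads residuals include the search shift; remove it to get
        # the raw (as-imaged) displacement of each matched pair
        res_raw = (matches[["res_x", "res_y"]].to_numpy()
                   - np.asarray(shift[:2], float))
        dists.append(np.hypot(res_raw[:, 0], res_raw[:, 1]))
    if not dists:
        return 0.0
    return float(np.concatenate(dists).mean())
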