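"""Chromatic-aberration correction from multi-colour bead fields.

Multi-fluorophore fiducial beads are visible in every channel, so the
apparent displacement of the same bead between channels measures the
chromatic misalignment of the optical path.  Each non-reference channel is
modelled by an in-plane similarity transform (translation + rotation +
isotropic scale about the image centre); the transform is estimated in
closed form from matched sub-pixel bead centres and then applied to *spot
coordinates*, never by resampling voxel data, so no interpolation artefacts
enter the nanometre-scale distance analysis.

Axial (z) chromatic offsets are not modelled: with 1 um slice spacing the
axial localization is far too coarse to constrain them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import ImageStack, px_to_nm

__all__ = [
    "ChannelTransform",
    "localize_beads",
    "match_beads",
    "estimate_transform",
    "apply_transform",
    "apply_transform_to_spots",
    "save_transforms",
    "load_transforms",
]

logger = logging.getLogger(__name__)


@dataclass
class ChannelTransform:
    """In-plane similarity transform mapping one channel onto the reference.

    ``apply`` maps ``(x, y)`` pixel coordinates measured in this channel to
    the reference-channel frame:

    ``p_ref = center + scale * R(rotation) @ (p - center) + (dx, dy)``

    Rotation is counter-clockwise in radians about ``center`` (by convention
    the image centre; the parameterization is centre-invariant because the
    translation is co-estimated).
    """

    channel: str = ""
    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0
    scale: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    residual_nm: float = float("nan")
    n_beads: int = 0
    translation_only_fallback: bool = False

    def __post_init__(self) -> None:
        if not (0.9 < self.scale < 1.1):
            raise ValueError(f"scale {self.scale} outside plausible chromatic range (0.9, 1.1)")
        if abs(self.rotation) > np.deg2rad(5.0):
            raise ValueError("rotation beyond +-5 degrees is not a chromatic correction")

    @property
    def is_identity(self) -> bool:
        return self.dx == 0 and self.dy == 0 and self.rotation == 0 and self.scale == 1

    def _matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` pixel coordinates from this channel to the reference."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ctr = np.asarray(self.center, dtype=float)
        out = (xy - ctr) @ self._matrix().T + ctr + np.array([self.dx, self.dy])
        return out

    def inverse(self) -> "ChannelTransform":
        """Analytic inverse (reference frame back to this channel's frame)."""
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        # solve for translation so that inverse(apply(p)) == p about same center
        ctr = np.asarray(self.center, dtype=float)
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        R_inv = inv_scale * np.array([[c, -s], [s, c]])
        d = np.array([self.dx, self.dy])
        inv_d = -R_inv @ d
        return ChannelTransform(
            channel=self.channel,
            dx=float(inv_d[0]),
            dy=float(inv_d[1]),
            rotation=inv_rot,
            scale=inv_scale,
            center=tuple(ctr),
            residual_nm=self.residual_nm,
            n_beads=self.n_beads,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = list(self.center)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelTransform":
        d = dict(d)
        d["center"] = tuple(d.get("center", (0.0, 0.0)))
        return cls(**d)


def identity_transform(channel: str = "", center: tuple[float, float] = (0.0, 0.0)) -> ChannelTransform:
    return ChannelTransform(channel=channel, center=center)


# ---------------------------------------------------------------------------
# bead localization and matching


def localize_beads(bead_stack: ImageStack, detection_params=None,
                   channels: tuple[str, ...] | None = None) -> dict[str, pd.DataFrame]:
    """Fit a sub-pixel 3D Gaussian centre to every bead in every channel.

    Beads whose seed is closer than the fit window to another bead in the
    same channel are rejected (the fit would mix two emitters) and logged.
    Returns one accepted-spot table per channel.
    """
    from .detection import DetectionParams, detect_spots

    if detection_params is None:
        detection_params = DetectionParams()
    channels = channels if channels is not None else bead_stack.channels
    out: dict[str, pd.DataFrame] = {}
    min_sep = float(detection_params.fit_window_xy)
    for ch in channels:
        table = detect_spots(bead_stack, ch, detection_params)
        acc = table[table["accepted"]].reset_index(drop=True)
        if len(acc) > 1:
            xy = acc[["x_px", "y_px"]].to_numpy()
            tree = cKDTree(xy)
            close = tree.query_pairs(min_sep)
            drop = sorted({i for p in close for i in p})
            if drop:
                logger.info("channel %s: rejecting %d beads closer than the fit window",
                            ch, len(drop))
                acc = acc.drop(index=drop).reset_index(drop=True)
        out[ch] = acc
    return out


def match_beads(ref_table: pd.DataFrame, other_table: pd.DataFrame,
                pairing_radius_px: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Match beads across channels by mutual nearest neighbour in xy.

    Beads visible in only one channel fall out of the matched set.  Returns
    ``(ref_xy, other_xy)`` arrays of equal length, in pixel coordinates.
    """
    if ref_table.empty or other_table.empty:
        return np.empty((0, 2)), np.empty((0, 2))
    ref_xy = ref_table[["x_px", "y_px"]].to_numpy(dtype=float)
    oth_xy = other_table[["x_px", "y_px"]].to_numpy(dtype=float)
    tree_o = cKDTree(oth_xy)
    d, j = tree_o.query(ref_xy, distance_upper_bound=pairing_radius_px)
    tree_r = cKDTree(ref_xy)
    d2, i_back = tree_r.query(oth_xy, distance_upper_bound=pairing_radius_px)
    pairs = []
    for i, jj in enumerate(j):
        if jj < len(oth_xy) and i_back[jj] == i:
            pairs.append((i, jj))
    if not pairs:
        return np.empty((0, 2)), np.empty((0, 2))
    idx_r, idx_o = map(np.array, zip(*pairs))
    return ref_xy[idx_r], oth_xy[idx_o]


# ---------------------------------------------------------------------------
# transform estimation (closed-form 2D Procrustes with isotropic scale)


def estimate_transform(ref_xy: np.ndarray, other_xy: np.ndarray, *,
                       channel: str = "",
                       center: tuple[float, float] = (0.0, 0.0),
                       voxel_size_xy_nm: float = 1.0) -> ChannelTransform:
    """Least-squares similarity transform taking ``other_xy`` onto ``ref_xy``.

    Closed-form Umeyama solution; deterministic.  With a degenerate
    (collinear) bead configuration the rotation/scale part is unidentifiable
    and a translation-only fallback is recorded on the returned transform.
    Residual is the post-fit RMS distance in nm.
    """
    ref_xy = np.asarray(ref_xy, dtype=float)
    other_xy = np.asarray(other_xy, dtype=float)
    n = len(ref_xy)
    if n < 3 or len(other_xy) != n:
        raise ValueError(
            f"need >=3 matched bead pairs to identify a similarity transform, got {n}"
        )
    mu_r = ref_xy.mean(axis=0)
    mu_o = other_xy.mean(axis=0)
    X = ref_xy - mu_r
    Y = other_xy - mu_o
    cov = X.T @ Y / n
    var_o = (Y ** 2).sum() / n
    U, D, Vt = np.linalg.svd(cov)
    degenerate = D[1] < 1e-9 * max(D[0], 1e-12) or var_o < 1e-18
    if degenerate:
        warnings.warn(
            "collinear bead configuration: falling back to translation-only correction",
            stacklevel=2,
        )
        t = ChannelTransform(channel=channel, dx=float(mu_r[0] - mu_o[0]),
                             dy=float(mu_r[1] - mu_o[1]), center=center,
                             n_beads=n, translation_only_fallback=True)
    else:
        S = np.eye(2)
        if np.linalg.det(U @ Vt) < 0:
            S[1, 1] = -1
        R = U @ S @ Vt
        scale = float(np.trace(np.diag(D) @ S) / var_o)
        rotation = float(np.arctan2(R[1, 0], R[0, 0]))
        ctr = np.asarray(center, dtype=float)
        # full map: p -> scale*R(p - mu_o) + mu_r ; re-express about `center`
        M = scale * R
        shift = mu_r - M @ mu_o  # p -> M p + shift
        d = M @ ctr + shift - ctr
        t = ChannelTransform(channel=channel, dx=float(d[0]), dy=float(d[1]),
                             rotation=rotation, scale=scale, center=center, n_beads=n)
    resid = t.apply(other_xy) - ref_xy
    t.residual_nm = float(np.sqrt((resid ** 2).sum(axis=1).mean()) * voxel_size_xy_nm)
    return t


def apply_transform(coords_xy: np.ndarray, transform: ChannelTransform) -> np.ndarray:
    """Map ``(n, 2)`` pixel coordinates from the transform's channel frame to
    the reference frame."""
    return transform.apply(coords_xy)


def apply_transform_to_spots(spots: pd.DataFrame, transform: ChannelTransform,
                             stack: ImageStack | None = None, *,
                             voxel_size_xy: float | None = None,
                             voxel_size_z: float | None = None) -> pd.DataFrame:
    """Return a spot table with corrected pixel coordinates and nm positions.

    The raw fitted (x, y) pixel centres are mapped through the channel's
    transform; z is unchanged.  ``*_nm`` columns are then populated in the
    reference frame using the stack calibration.
    """
    out = spots.copy()
    if len(out):
        xy = out[["x_px", "y_px"]].to_numpy(dtype=float)
        corrected = transform.apply(xy)
        out["x_px"] = corrected[:, 0]
        out["y_px"] = corrected[:, 1]
    nm = px_to_nm(out[["z_px", "y_px", "x_px"]].to_numpy(dtype=float).reshape(-1, 3),
                  stack, voxel_size_xy=voxel_size_xy, voxel_size_z=voxel_size_z)
    out["z_nm"], out["y_nm"], out["x_nm"] = nm[:, 0], nm[:, 1], nm[:, 2]
    return out


# ---------------------------------------------------------------------------
# persistence


def save_transforms(transforms: Mapping[str, ChannelTransform], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: t.to_dict() for k, t in transforms.items()}, indent=1))


def load_transforms(path: str | Path) -> dict[str, ChannelTransform]:
    payload = json.loads(Path(path).read_text())
    return {k: ChannelTransform.from_dict(v) for k, v in payload.items()}


def register_bead_field(bead_stack: ImageStack, reference_channel: str,
                        detection_params=None,
                        pairing_radius_px: float = 5.0) -> dict[str, ChannelTransform]:
    """End-to-end bead registration: localize, match, estimate per channel."""
    tables = localize_beads(bead_stack, detection_params)
    ref = tables[reference_channel]
    ny, nx = bead_stack.shape_zyx[1:]
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    out: dict[str, ChannelTransform] = {
        reference_channel: identity_transform(reference_channel, center)
    }
    for ch, table in tables.items():
        if ch == reference_channel:
            continue
        ref_xy, oth_xy = match_beads(ref, table, pairing_radius_px)
        if len(ref_xy) < 3:
            raise ValueError(
                f"channel {ch}: only {len(ref_xy)} matched beads; transform unidentifiable"
            )
        out[ch] = estimate_transform(ref_xy, oth_xy, channel=ch, center=center,
                                     voxel_size_xy_nm=bead_stack.voxel_size_xy)
    return out
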