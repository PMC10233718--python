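"""Synthetic multi-channel 3D smFISH sections with complete ground truth.

The generator emulates the statistical structure of neural-tube tissue
sections probed for nascent transcription of up to three genes:

* densely packed, non-overlapping spherical nuclei (radius 3 um) stained in
  a DAPI channel of uniform per-nucleus intensity;
* per-cell burst states — each gene is actively transcribed ("bursting") in
  a cell with a marginal probability, and pairwise co-bursting can be tuned
  from mutual exclusion through independence to positive coupling;
* each active gene contributes 1 or 2 diffraction-limited nascent spots
  (allele count) rendered as anisotropic 3D Gaussians at sub-voxel centres
  inside the nucleus;
* optional fixed inter-locus geometry: genes placed at rigid nm offsets on a
  randomly oriented per-cell frame, giving a known true inter-promoter
  separation for distance-analysis tests;
* per-channel chromatic misalignment (in-plane similarity transform),
  autofluorescent cytoplasmic clutter, and Poisson shot noise followed by
  additive Gaussian camera read noise.

The default z geometry is a 20-slice stack at 1 um spacing.  Defaults are
chosen once to represent a realistic acquisition and are not tuned per
experiment; every parameter is explicit in :class:`SimulationParams`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ImageStack, nm_to_px, px_to_nm, write_stack
from .registration import ChannelTransform, identity_transform

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "sample_burst_states",
    "place_nuclei",
    "sample_spot_table",
    "render_section",
    "render_bead_field",
    "simulate_spot_fields",
]

DAPI = "dapi"
DEFAULT_PROBE_CHANNELS = ("farred", "red", "green")


class ParameterValidityError(ValueError):
    """A parameter set implies joint probabilities outside [0, 1]."""


@dataclass
class SimulationParams:
    """Complete description of one simulated tissue section.

    ``coupling[g, h]`` is the pairwise lift of co-bursting over independence:
    ``P(g and h active) = coupling[g, h] * p_g * p_h``, so 1 is independence,
    0 mutual exclusion, and >1 positive co-regulation.  Triple co-activation
    follows product closure over the pairwise lifts.
    """

    image_shape: tuple[int, int, int] = (20, 256, 256)  # (z, y, x)
    voxel_size_xy: float = 110.0  # nm
    voxel_size_z: float = 1000.0  # nm
    genes: tuple[str, ...] = ("geneA", "geneB", "geneC")
    burst_probs: tuple[float, ...] = (0.3, 0.3, 0.3)
    coupling: float | np.ndarray = 1.0
    n_cells: int = 15
    nuclear_radius: float = 3000.0  # nm
    spots_per_active_cell: int = 1  # allele count, 1 or 2
    psf_sigma_xy: float = 150.0  # nm
    psf_sigma_z: float = 700.0  # nm
    spot_amplitude: float = 400.0  # photons at peak
    amplitude_cv: float = 0.1
    background_level: float = 10.0  # photons per voxel (far-red-like, low background)
    autofluorescence_density: float = 0.5  # clutter objects per 1000 um^3
    autofluorescence_amplitude_fraction: float = 0.25
    camera_noise_sd: float = 2.0  # read-noise counts
    shot_noise: bool = True
    dapi_intensity: float = 50.0  # photons per nuclear voxel
    chromatic_transforms: Mapping[str, ChannelTransform] = field(default_factory=dict)
    locus_offsets: np.ndarray | None = None  # (n_genes, 3) nm, (z, y, x)
    placement: str = "pack"  # "pack" (non-overlapping random) or "grid"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def probe_channels(self) -> tuple[str, ...]:
        return DEFAULT_PROBE_CHANNELS[: self.n_genes]

    @property
    def channels(self) -> tuple[str, ...]:
        return self.probe_channels + (DAPI,)

    def coupling_matrix(self) -> np.ndarray:
        n = self.n_genes
        if np.isscalar(self.coupling):
            m = np.full((n, n), float(self.coupling))
            np.fill_diagonal(m, 1.0)
            return m
        m = np.asarray(self.coupling, dtype=float)
        if m.shape != (n, n):
            raise ParameterValidityError(f"coupling matrix must be {n}x{n}")
        return m

    def validate(self) -> None:
        if not 1 <= self.n_genes <= 3:
            raise ParameterValidityError("1 to 3 probe channels supported")
        if len(self.burst_probs) != self.n_genes:
            raise ParameterValidityError("one burst probability per gene")
        if any(not (0.0 <= p <= 1.0) for p in self.burst_probs):
            raise ParameterValidityError("burst probabilities must lie in [0, 1]")
        m = self.coupling_matrix()
        if not np.allclose(m, m.T):
            raise ParameterValidityError("coupling matrix must be symmetric")
        if np.any(m < 0):
            raise ParameterValidityError("coupling entries must be non-negative")
        if self.spots_per_active_cell not in (1, 2):
            raise ParameterValidityError("allele count must be 1 or 2")
        for name in ("voxel_size_xy", "voxel_size_z", "nuclear_radius",
                     "psf_sigma_xy", "psf_sigma_z", "spot_amplitude"):
            if not getattr(self, name) > 0:
                raise ParameterValidityError(f"{name} must be positive")
        if self.background_level < 0 or self.camera_noise_sd < 0:
            raise ParameterValidityError("noise levels must be non-negative")
        if self.locus_offsets is not None:
            off = np.asarray(self.locus_offsets, dtype=float)
            if off.shape != (self.n_genes, 3):
                raise ParameterValidityError("locus_offsets must be (n_genes, 3) in nm")
        # cell-state distribution must be a valid probability table
        _state_probabilities(np.asarray(self.burst_probs, dtype=float), m)


@dataclass
class GroundTruth:
    """What the simulator actually drew: full answer key for one section."""

    cells: pd.DataFrame  # cell_id, z_nm, y_nm, x_nm, radius_nm
    spots: pd.DataFrame  # cell_id, gene, channel, z_nm, y_nm, x_nm (reference frame), amplitude
    burst_states: pd.DataFrame  # cells x genes, 0/1
    transforms: dict[str, ChannelTransform]

    def write(self, directory: str | Path, prefix: str = "truth") -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(d / f"{prefix}_cells.csv", index=False)
        self.spots.to_csv(d / f"{prefix}_spots.csv", index=False)
        self.burst_states.to_csv(d / f"{prefix}_burst_states.csv", index=False)
        from .registration import save_transforms

        save_transforms(self.transforms, d / f"{prefix}_transforms.json")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "truth") -> "GroundTruth":
        d = Path(directory)
        from .registration import load_transforms

        return cls(
            cells=pd.read_csv(d / f"{prefix}_cells.csv"),
            spots=pd.read_csv(d / f"{prefix}_spots.csv"),
            burst_states=pd.read_csv(d / f"{prefix}_burst_states.csv"),
            transforms=load_transforms(d / f"{prefix}_transforms.json"),
        )


# ---------------------------------------------------------------------------
# burst states


def _state_probabilities(p: np.ndarray, coupling: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability of each of the 2^n joint burst states.

    Moments are specified as ``E[X_g] = p_g``, ``E[X_g X_h] = c_gh p_g p_h``
    and (three genes) ``E[X_1 X_2 X_3] = p_1 p_2 p_3 c_12 c_13 c_23``
    (product closure).  The joint table follows by Moebius inversion; any
    negative cell probability means the requested moments are infeasible.
    """
    n = len(p)
    genes = list(range(n))

    def moment(subset: tuple[int, ...]) -> float:
        if not subset:
            return 1.0
        m = float(np.prod([p[g] for g in subset]))
        for g, h in itertools.combinations(subset, 2):
            m *= coupling[g, h]
        return m

    states = list(itertools.product([0, 1], repeat=n))
    probs = np.zeros(len(states))
    for i, state in enumerate(states):
        ones = tuple(g for g in genes if state[g])
        zeros = tuple(g for g in genes if not state[g])
        total = 0.0
        for k in range(len(zeros) + 1):
            for extra in itertools.combinations(zeros, k):
                total += (-1) ** k * moment(tuple(sorted(ones + extra)))
        probs[i] = total
    if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
        raise ParameterValidityError(
            "burst probabilities and coupling imply joint probabilities outside [0, 1]"
        )
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    return np.array(states), probs


def sample_burst_states(n_cells: int, burst_probs: Sequence[float],
                        coupling: float | np.ndarray = 1.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a ``(n_cells, n_genes)`` 0/1 burst-state matrix.

    Marginal activation frequencies converge to ``burst_probs`` and pairwise
    co-activation to ``coupling[g, h] * p_g * p_h``; deterministic given the
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(burst_probs, dtype=float)
    n = len(p)
    if np.isscalar(coupling):
        m = np.full((n, n), float(coupling))
        np.fill_diagonal(m, 1.0)
    else:
        m = np.asarray(coupling, dtype=float)
    states, probs = _state_probabilities(p, m)
    idx = rng.choice(len(states), size=n_cells, p=probs)
    return states[idx].astype(np.int8)


# ---------------------------------------------------------------------------
# geometry


def _field_extent_nm(params: SimulationParams) -> np.ndarray:
    nz, ny, nx = params.image_shape
    return np.array([nz * params.voxel_size_z, ny * params.voxel_size_xy,
                     nx * params.voxel_size_xy])


def place_nuclei(params: SimulationParams, rng: np.random.Generator,
                 retry_cap: int = 2000) -> pd.DataFrame:
    """Place non-overlapping spherical nuclei inside the imaged volume.

    ``pack`` mode rejection-samples random centres with a margin keeping
    every possible spot (and its fit window) inside the volume; ``grid``
    mode lays nuclei on a regular lattice with spacing 2.2 radii — used for
    very large cell counts in coordinate-level studies, where the extra
    spacing guarantees that spots in different nuclei can never fall within
    a 500 nm co-localization radius of each other, even in projection.
    """
    r = params.nuclear_radius
    extent = _field_extent_nm(params)
    if params.placement == "grid":
        spacing = 2.2 * r
        side = int(np.ceil(np.sqrt(params.n_cells)))
        ii, jj = np.divmod(np.arange(params.n_cells), side)
        z = np.full(params.n_cells, extent[0] / 2.0)
        y = r + spacing * ii.astype(float)
        x = r + spacing * jj.astype(float)
        centers = np.stack([z, y, x], axis=1)
    else:
        margin_xy = r + 12 * params.voxel_size_xy  # keep fit windows in-bounds
        margin_z = r + 3 * params.voxel_size_z
        lo = np.array([margin_z, margin_xy, margin_xy])
        hi = extent - lo
        if np.any(hi <= lo):
            raise ValueError(
                "image volume too small for a nucleus plus detection margins"
            )
        centers_list: list[np.ndarray] = []
        attempts = 0
        while len(centers_list) < params.n_cells:
            attempts += 1
            if attempts > retry_cap * params.n_cells:
                raise ValueError(
                    f"could not place {params.n_cells} non-overlapping nuclei of radius "
                    f"{r:.0f} nm in a {extent.astype(int).tolist()} nm volume; "
                    "reduce cell density or enlarge the field"
                )
            cand = rng.uniform(lo, hi)
            if all(np.linalg.norm(cand - c) >= 2 * r for c in centers_list):
                centers_list.append(cand)
        centers = np.array(centers_list)
    return pd.DataFrame({
        "cell_id": np.arange(params.n_cells),
        "z_nm": centers[:, 0],
        "y_nm": centers[:, 1],
        "x_nm": centers[:, 2],
        "radius_nm": r,
    })


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * u * radius


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def sample_spot_table(params: SimulationParams, burst_states: np.ndarray,
                      nuclei: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """True nascent-spot positions (reference frame, nm) for active loci.

    Without ``locus_offsets`` each spot is uniform inside its nucleus
    sphere, matching the spatial null model of random co-localization.  With
    ``locus_offsets`` all active genes of a cell sit at rigid offsets on a
    randomly rotated per-allele frame anchored inside the nucleus, so true
    pairwise inter-locus distances are exactly the offset geometry.
    """
    rows: list[dict] = []
    centers = nuclei[["z_nm", "y_nm", "x_nm"]].to_numpy()
    offsets = None
    anchor_radius = params.nuclear_radius
    if params.locus_offsets is not None:
        offsets = np.asarray(params.locus_offsets, dtype=float)
        anchor_radius = max(params.nuclear_radius - float(np.linalg.norm(offsets, axis=1).max()), 0.0)
    for cell in range(len(nuclei)):
        active = np.nonzero(burst_states[cell])[0]
        if len(active) == 0:
            continue
        for allele in range(params.spots_per_active_cell):
            if offsets is None:
                pos = centers[cell] + _uniform_in_ball(rng, len(active), params.nuclear_radius)
            else:
                anchor = centers[cell] + _uniform_in_ball(rng, 1, anchor_radius)[0]
                rot = _random_rotation(rng)
                pos = anchor + offsets[active] @ rot.T
            amps = params.spot_amplitude * np.abs(rng.normal(1.0, params.amplitude_cv, len(active)))
            for gi, g in enumerate(active):
                rows.append(dict(cell_id=cell, gene=params.genes[g],
                                 channel=params.probe_channels[g], allele=allele,
                                 z_nm=pos[gi, 0], y_nm=pos[gi, 1], x_nm=pos[gi, 2],
                                 amplitude=amps[gi]))
    return pd.DataFrame(rows, columns=["cell_id", "gene", "channel", "allele",
                                       "z_nm", "y_nm", "x_nm", "amplitude"])


# ---------------------------------------------------------------------------
# rendering


def _render_gaussian(volume: np.ndarray, center_px: np.ndarray, amplitude: float,
                     sigma_xy_px: float, sigma_z_px: float) -> None:
    nz, ny, nx = volume.shape
    z0, y0, x0 = center_px
    rz = max(int(np.ceil(4 * sigma_z_px)), 1)
    rxy = int(np.ceil(4 * sigma_xy_px))
    z_lo, z_hi = max(int(np.floor(z0)) - rz, 0), min(int(np.ceil(z0)) + rz + 1, nz)
    y_lo, y_hi = max(int(np.floor(y0)) - rxy, 0), min(int(np.ceil(y0)) + rxy + 1, ny)
    x_lo, x_hi = max(int(np.floor(x0)) - rxy, 0), min(int(np.ceil(x0)) + rxy + 1, nx)
    if z_lo >= z_hi or y_lo >= y_hi or x_lo >= x_hi:
        return
    z = np.arange(z_lo, z_hi)[:, None, None]
    y = np.arange(y_lo, y_hi)[None, :, None]
    x = np.arange(x_lo, x_hi)[None, None, :]
    volume[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += amplitude * np.exp(
        -((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma_xy_px ** 2)
        - ((z - z0) ** 2) / (2 * sigma_z_px ** 2)
    )


def _apply_camera_noise(img: np.ndarray, params: SimulationParams,
                        rng: np.random.Generator) -> np.ndarray:
    out = img
    if params.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if params.camera_noise_sd > 0:
        out = out + rng.normal(0.0, params.camera_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def render_section(params: SimulationParams,
                   burst_states: np.ndarray | None = None) -> tuple[ImageStack, GroundTruth]:
    """Render a full multi-channel section and return it with its answer key.

    Probe channels carry background, autofluorescent clutter and nascent
    spots; each non-reference channel is rendered *after* applying the
    inverse of its true chromatic transform, so that correcting fitted
    coordinates with the true transform recovers reference-frame positions.
    The DAPI channel renders filled nuclei at uniform voxel intensity.
    Poisson shot noise and Gaussian read noise are applied last.
    """
    rng = np.random.default_rng(params.seed)
    if burst_states is None:
        burst_states = sample_burst_states(params.n_cells, params.burst_probs,
                                           params.coupling_matrix(), rng)
    burst_states = np.asarray(burst_states)
    nuclei = place_nuclei(params, rng)
    spots = sample_spot_table(params, burst_states, nuclei, rng)

    nz, ny, nx = params.image_shape
    center_px = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    transforms = {ch: params.chromatic_transforms.get(ch, identity_transform(ch, center_px))
                  for ch in params.probe_channels}
    sigma_xy_px = params.psf_sigma_xy / params.voxel_size_xy
    sigma_z_px = params.psf_sigma_z / params.voxel_size_z
    volume_um3 = float(np.prod(_field_extent_nm(params))) / 1e9
    n_clutter = rng.poisson(params.autofluorescence_density * volume_um3 / 1000.0,
                            size=len(params.probe_channels))

    data = np.zeros((len(params.channels), nz, ny, nx), dtype=float)
    nuc_centers = nuclei[["z_nm", "y_nm", "x_nm"]].to_numpy()
    for ci, ch in enumerate(params.probe_channels):
        vol = data[ci]
        vol += params.background_level
        inv = transforms[ch].inverse()
        ch_spots = spots[spots["channel"] == ch]
        for _, s in ch_spots.iterrows():
            pos_px = nm_to_px(np.array([s.z_nm, s.y_nm, s.x_nm]),
                              voxel_size_xy=params.voxel_size_xy,
                              voxel_size_z=params.voxel_size_z)
            xy_chan = inv.apply(np.array([[pos_px[2], pos_px[1]]]))[0]  # (x, y)
            center = np.array([pos_px[0], xy_chan[1], xy_chan[0]])
            _render_gaussian(vol, center, float(s.amplitude), sigma_xy_px, sigma_z_px)
        # cytoplasmic autofluorescent clutter: uniform outside nuclei
        placed = 0
        guard = 0
        while placed < n_clutter[ci] and guard < 50 * (n_clutter[ci] + 1):
            guard += 1
            pos_nm = rng.uniform(np.zeros(3), _field_extent_nm(params))
            if len(nuc_centers) and np.min(np.linalg.norm(nuc_centers - pos_nm, axis=1)) < params.nuclear_radius:
                continue
            pos_px = nm_to_px(pos_nm, voxel_size_xy=params.voxel_size_xy,
                              voxel_size_z=params.voxel_size_z)
            amp = (params.autofluorescence_amplitude_fraction * params.spot_amplitude
                   * abs(rng.normal(1.0, 0.2)))
            _render_gaussian(vol, pos_px, amp, sigma_xy_px, sigma_z_px)
            placed += 1

    dapi = data[-1]
    _render_nuclei(dapi, nuclei, params)
    for ci in range(data.shape[0]):
        data[ci] = _apply_camera_noise(data[ci], params, rng)

    stack = ImageStack(data=data, voxel_size_xy=params.voxel_size_xy,
                       voxel_size_z=params.voxel_size_z, channels=params.channels)
    truth = GroundTruth(
        cells=nuclei,
        spots=spots,
        burst_states=pd.DataFrame(burst_states, columns=list(params.genes)),
        transforms=transforms,
    )
    return stack, truth


def _render_nuclei(dapi: np.ndarray, nuclei: pd.DataFrame, params: SimulationParams) -> None:
    nz, ny, nx = dapi.shape
    r = params.nuclear_radius
    for _, nuc in nuclei.iterrows():
        c_px = nm_to_px(np.array([nuc.z_nm, nuc.y_nm, nuc.x_nm]),
                        voxel_size_xy=params.voxel_size_xy, voxel_size_z=params.voxel_size_z)
        rz = r / params.voxel_size_z
        rxy = r / params.voxel_size_xy
        z_lo, z_hi = max(int(np.floor(c_px[0] - rz)), 0), min(int(np.ceil(c_px[0] + rz)) + 1, nz)
        y_lo, y_hi = max(int(np.floor(c_px[1] - rxy)), 0), min(int(np.ceil(c_px[1] + rxy)) + 1, ny)
        x_lo, x_hi = max(int(np.floor(c_px[2] - rxy)), 0), min(int(np.ceil(c_px[2] + rxy)) + 1, nx)
        z = np.arange(z_lo, z_hi)[:, None, None]
        y = np.arange(y_lo, y_hi)[None, :, None]
        x = np.arange(x_lo, x_hi)[None, None, :]
        inside = (((z - c_px[0]) / rz) ** 2 + ((y - c_px[1]) / rxy) ** 2
                  + ((x - c_px[2]) / rxy) ** 2) <= 1.0
        dapi[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi][inside] += params.dapi_intensity


# ---------------------------------------------------------------------------
# bead fields


def render_bead_field(true_transforms: Mapping[str, ChannelTransform],
                      n_beads: int,
                      channels: tuple[str, ...] = DEFAULT_PROBE_CHANNELS,
                      reference_channel: str = "farred",
                      image_shape: tuple[int, int, int] = (9, 256, 256),
                      voxel_size_xy: float = 110.0,
                      voxel_size_z: float = 1000.0,
                      amplitude: float = 800.0,
                      background: float = 20.0,
                      psf_sigma_xy: float = 150.0,
                      psf_sigma_z: float = 700.0,
                      camera_noise_sd: float = 2.0,
                      shot_noise: bool = True,
                      min_separation_px: float = 24.0,
                      seed: int = 0) -> tuple[ImageStack, pd.DataFrame]:
    """Render a multi-colour fiducial bead field with known transforms.

    Every bead appears in all channels; non-reference channels are displaced
    by the inverse of their true transform so that correcting fitted centres
    with the estimated transform should re-align them.  Ground-truth bead
    centres (reference frame, pixels) are returned alongside.
    """
    if n_beads < 3:
        raise ValueError("a similarity transform needs at least 3 beads")
    rng = np.random.default_rng(seed)
    nz, ny, nx = image_shape
    center_px = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    margin = min_separation_px / 2.0 + 4
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_beads:
        attempts += 1
        if attempts > 5000 * n_beads:
            raise ValueError("bead field too dense for the requested separation")
        cand = np.array([
            rng.uniform(nz / 2.0 - 0.5, nz / 2.0 + 0.5),
            rng.uniform(margin, ny - margin),
            rng.uniform(margin, nx - margin),
        ])
        if all(np.hypot(cand[1] - p[1], cand[2] - p[2]) >= min_separation_px for p in placed):
            placed.append(cand)
    centers = np.array(placed)

    sigma_xy_px = psf_sigma_xy / voxel_size_xy
    sigma_z_px = psf_sigma_z / voxel_size_z
    data = np.zeros((len(channels), nz, ny, nx), dtype=float)
    transforms = {ch: true_transforms.get(ch, identity_transform(ch, center_px))
                  for ch in channels}
    for ci, ch in enumerate(channels):
        vol = data[ci]
        vol += background
        inv = transforms[ch].inverse()
        for c in centers:
            xy = inv.apply(np.array([[c[2], c[1]]]))[0]
            _render_gaussian(vol, np.array([c[0], xy[1], xy[0]]), amplitude,
                             sigma_xy_px, sigma_z_px)
        if shot_noise:
            vol[:] = rng.poisson(np.clip(vol, 0, None))
        if camera_noise_sd > 0:
            vol += rng.normal(0, camera_noise_sd, vol.shape)
        np.clip(vol, 0, None, out=vol)

    stack = ImageStack(data=data, voxel_size_xy=voxel_size_xy, voxel_size_z=voxel_size_z,
                       channels=tuple(channels))
    truth = pd.DataFrame({"bead_id": np.arange(n_beads), "z_px": centers[:, 0],
                          "y_px": centers[:, 1], "x_px": centers[:, 2]})
    return stack, truth


# ---------------------------------------------------------------------------
# coordinate-level cohorts (no rendering)


def simulate_spot_fields(params: SimulationParams, localization_sd_xy: float = 25.0,
                         localization_sd_z: float = 120.0,
                         seed: int | np.random.Generator | None = None
                         ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate fitted-spot-like tables directly at coordinate level.

    Emulates the output of detection + registration on a section without
    rendering voxels: ground-truth spot positions get additive Gaussian
    localization error (nm).  Used for large-cell-count statistical studies
    where imaging is not the quantity under test.
    """
    if seed is None:
        seed = params.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burst = sample_burst_states(params.n_cells, params.burst_probs,
                                params.coupling_matrix(), rng)
    nuclei = place_nuclei(params, rng)
    spots = sample_spot_table(params, burst, nuclei, rng)
    tables: dict[str, pd.DataFrame] = {}
    for ch in params.probe_channels:
        sub = spots[spots["channel"] == ch].reset_index(drop=True)
        n = len(sub)
        err = np.column_stack([
            rng.normal(0, localization_sd_z, n),
            rng.normal(0, localization_sd_xy, n),
            rng.normal(0, localization_sd_xy, n),
        ])
        nm = sub[["z_nm", "y_nm", "x_nm"]].to_numpy() + err
        px = nm_to_px(nm.reshape(-1, 3), voxel_size_xy=params.voxel_size_xy,
                      voxel_size_z=params.voxel_size_z)
        tables[ch] = pd.DataFrame({
            "spot_id": np.arange(n), "channel": ch,
            "z_px": px[:, 0], "y_px": px[:, 1], "x_px": px[:, 2],
            "z_nm": nm[:, 0], "y_nm": nm[:, 1], "x_nm": nm[:, 2],
            "amplitude": sub["amplitude"], "accepted": True,
        })
    truth = GroundTruth(cells=nuclei, spots=spots,
                        burst_states=pd.DataFrame(burst, columns=list(params.genes)),
                        transforms={})
    return tables, truth
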