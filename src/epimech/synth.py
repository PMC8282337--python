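"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the microscopy observables:

* recoil vertex tracks -- two tricellular vertices separating as
  L0 + D*(1 - exp(-t/tau)) after ablation, with isotropic Gaussian
  tracking jitter per vertex per frame and lognormal inter-embryo
  variability of (L0, D, tau) across an ensemble;
* epithelium images -- a Voronoi polygonal cell lattice whose junctions
  carry a bright signal of tunable punctateness (a sinusoidal modulation
  along junction arclength), over Gaussian background noise, replicated
  across z-slices;
* clone/control apical-width ensembles -- lognormal per-cell widths with
  a programmed constriction factor applied to the clone cells.

Every generator is deterministic given its seed and reports its
ground-truth parameters alongside the data so recovery tests can close
the loop. Defaults mirror the acquisition regime of the embryo ablation
experiments these generators emulate: one frame every 4 s, 9 post-ablation
frames covering 36 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi

from .morphometry import CloneMeasurementSet
from .recoil import VertexTrack, kelvin_voigt_displacement

__all__ = [
    "RecoilSimParams",
    "EnsembleSpec",
    "ConditionEnsemble",
    "SyntheticEpithelium",
    "simulate_recoil_track",
    "simulate_condition_ensemble",
    "synth_epithelium_image",
    "synth_clone_widths",
    "lognormal_params",
]

_SEED_MOD = 2 ** 31


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{field_name}: {msg}")


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class RecoilSimParams:
    """Ground-truth parameters for one simulated ablated junction.

    ``frame_interval`` and ``n_post`` default to the 4 s / 36 s acquisition
    window of the experiments being emulated. ``noise_sd`` is the standard
    deviation of the Gaussian jitter added independently to each vertex
    coordinate at each frame (a manual-tracking noise proxy).
    """

    L0: float                      # pre-ablation interface length, um
    D: float                       # asymptotic recoil amplitude, um
    tau: float                     # relaxation time, s
    frame_interval: float = 4.0    # s
    n_pre: int = 1
    n_post: int = 9
    noise_sd: float = 0.0          # um, per vertex coordinate per frame
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.L0 > 0, "L0", "must be > 0")
        _require(self.D >= 0, "D", "must be >= 0")
        _require(self.tau > 0, "tau", "must be > 0")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.n_pre >= 1, "n_pre", "must be >= 1")
        _require(self.n_post >= 2, "n_post", "must be >= 2")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass
class EnsembleSpec:
    """Inter-replicate (inter-embryo) variability for one condition.

    Per-replicate (L0, D, tau) are drawn lognormally with the stated
    arithmetic means and coefficients of variation; a CV of 0 makes the
    parameter deterministic at its mean.
    """

    n_replicates: int
    L0_mean: float = 4.0
    D_mean: float = 1.2
    tau_mean: float = 10.0
    L0_cv: float = 0.0
    D_cv: float = 0.0
    tau_cv: float = 0.0
    frame_interval: float = 4.0
    n_pre: int = 1
    n_post: int = 9
    noise_sd: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        for name in ("L0_cv", "D_cv", "tau_cv"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.L0_mean > 0, "L0_mean", "must be > 0")
        _require(self.D_mean >= 0, "D_mean", "must be >= 0")
        _require(self.tau_mean > 0, "tau_mean", "must be > 0")


@dataclass
class ConditionEnsemble:
    """Simulated tracks plus the per-replicate ground-truth parameters."""

    tracks: list[VertexTrack]
    params: list[RecoilSimParams]
    spec: EnsembleSpec

    def __len__(self) -> int:
        return len(self.tracks)


def simulate_recoil_track(params: RecoilSimParams) -> VertexTrack:
    """One noisy vertex track of an ablated junction.

    The two vertices lie on a line through a random centre at a random
    orientation (drawn from the seed); their separation is L0 on the
    ``n_pre`` pre-ablation frames and L0 + D*(1 - exp(-t/tau)) afterwards,
    t measured from the last pre-ablation frame. Gaussian noise of sd
    ``noise_sd`` is then added to every coordinate independently.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pre + params.n_post
    times = np.arange(n) * params.frame_interval
    t_post = (np.arange(1, params.n_post + 1)) * params.frame_interval
    sep = np.concatenate([
        np.full(params.n_pre, params.L0),
        params.L0 + kelvin_voigt_displacement(t_post, params.D, params.tau),
    ])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    center = rng.uniform(-20.0, 20.0, size=2)
    u = np.array([np.cos(theta), np.sin(theta)])
    half = (sep / 2.0)[:, None] * u[None, :]
    v1 = center[None, :] - half
    v2 = center[None, :] + half
    if params.noise_sd > 0:
        v1 = v1 + rng.normal(0.0, params.noise_sd, size=v1.shape)
        v2 = v2 + rng.normal(0.0, params.noise_sd, size=v2.shape)
    return VertexTrack(track_id=f"sim-{params.seed}", times=times,
                       vertex1_xy=v1, vertex2_xy=v2,
                       ablation_frame=params.n_pre - 1)


def simulate_condition_ensemble(spec: EnsembleSpec) -> ConditionEnsemble:
    """n_replicates junctions (one per embryo) for one condition.

    Per-replicate parameters are lognormal draws; per-replicate seeds are
    derived from ``spec.seed`` as ``default_rng(seed).integers(0, 2**31, n)``
    so each track is reproducible element-wise.
    """
    rng = np.random.default_rng(spec.seed)
    child_seeds = rng.integers(0, _SEED_MOD, size=spec.n_replicates)

    def draw(mean: float, cv: float, size: int) -> np.ndarray:
        if cv == 0 or mean == 0:
            return np.full(size, mean)
        mu, sigma = lognormal_params(mean, cv)
        return rng.lognormal(mu, sigma, size)

    L0s = draw(spec.L0_mean, spec.L0_cv, spec.n_replicates)
    Ds = draw(spec.D_mean, spec.D_cv, spec.n_replicates)
    taus = draw(spec.tau_mean, spec.tau_cv, spec.n_replicates)

    tracks, plist = [], []
    for i in range(spec.n_replicates):
        p = RecoilSimParams(L0=float(L0s[i]), D=float(Ds[i]), tau=float(taus[i]),
                            frame_interval=spec.frame_interval, n_pre=spec.n_pre,
                            n_post=spec.n_post, noise_sd=spec.noise_sd,
                            seed=int(child_seeds[i]))
        tr = simulate_recoil_track(p)
        tr.track_id = f"{spec.label or 'cond'}-{i:03d}"
        tracks.append(tr)
        plist.append(p)
    return ConditionEnsemble(tracks=tracks, params=plist, spec=spec)


@dataclass
class SyntheticEpithelium:
    """Synthetic epithelium stack with ground-truth junction geometry.

    ``image`` is (y, x) for a single slice or (z, y, x) for a stack;
    ``junction_mask`` marks the ground-truth junction pixels of the shared
    XY geometry; ``ridges`` holds the Voronoi ridge segments (um
    coordinates) from which the junctions were drawn.
    """

    image: np.ndarray
    pixel_size: float            # um / px
    z_step: float                # um
    junction_mask: np.ndarray
    punctateness: float
    ridges: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def longest_junction(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints (um) of the longest ground-truth junction segment."""
        if not self.ridges:
            raise ValueError("no junction segments recorded")
        return max(self.ridges, key=lambda r: np.linalg.norm(r[1] - r[0]))


def _clip_segment(p0: np.ndarray, p1: np.ndarray, lo: float, hi: float
                  ) -> tuple[np.ndarray, np.ndarray] | None:
    """Liang-Barsky clip of segment p0-p1 to the square [lo, hi]^2."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for dim in range(2):
        if d[dim] == 0:
            if not (lo <= p0[dim] <= hi):
                return None
            continue
        ta = (lo - p0[dim]) / d[dim]
        tb = (hi - p0[dim]) / d[dim]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def synth_epithelium_image(n_cells: int = 30,
                           pixel_size: float = 0.1,
                           junction_intensity: float = 100.0,
                           punctateness: float = 0.0,
                           background_noise_sd: float = 0.0,
                           n_slices: int = 1,
                           field_um: float = 30.0,
                           junction_width_um: float = 0.15,
                           puncta_period_um: float = 1.0,
                           seed: int = 0) -> SyntheticEpithelium:
    """Voronoi-lattice epithelium with bright junctions of tunable punctateness.

    Cell centres are uniform in a square field of side ``field_um``; the
    junctional network is the Voronoi ridge set, drawn as bands of
    half-width ``junction_width_um``. On the junction, intensity is
    ``junction_intensity * (1 + punctateness * sin(2*pi*s/puncta_period_um))``
    with ``s`` the arclength coordinate along the pixel's nearest ridge, so
    ``punctateness=0`` gives exactly uniform junctions. All z-slices share
    the geometry; background noise is Gaussian, independent per slice, and
    the image is clamped at zero.
    """
    _require(n_cells >= 2, "n_cells", "must be >= 2")
    _require(pixel_size > 0, "pixel_size", "must be > 0")
    _require(punctateness >= 0, "punctateness", "must be >= 0")
    _require(n_slices >= 1, "n_slices", "must be >= 1")
    rng = np.random.default_rng(seed)

    pts = rng.uniform(0.0, field_um, size=(n_cells, 2))
    # mirror the points across each edge so every interior ridge is finite
    mirrored = [pts]
    for dim in range(2):
        for bound in (0.0, field_um):
            m = pts.copy()
            m[:, dim] = 2 * bound - m[:, dim]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))

    n_px = int(round(field_um / pixel_size))
    extent = (n_px - 1) * pixel_size   # coordinate of the last pixel centre
    ridges: list[tuple[np.ndarray, np.ndarray]] = []
    for (a, b), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if a >= n_cells and b >= n_cells:
            continue
        if -1 in verts:
            continue
        p0, p1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        clipped = _clip_segment(p0, p1, 0.0, extent)
        if clipped is None:
            continue
        q0, q1 = clipped
        # snap rounding residue back into the pixel-centre extent
        q0, q1 = np.clip(q0, 0.0, extent), np.clip(q1, 0.0, extent)
        if np.linalg.norm(q1 - q0) < pixel_size:
            continue
        ridges.append((q0, q1))
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    # physical coordinates of pixel centres (origin at top-left pixel centre)
    px_pos = np.stack([xx * pixel_size, yy * pixel_size], axis=-1)   # (y, x, 2)

    dist = np.full((n_px, n_px), np.inf)
    arclen = np.zeros((n_px, n_px))
    for q0, q1 in ridges:
        d = q1 - q0
        length2 = float(d @ d)
        rel = px_pos - q0[None, None, :]
        tproj = np.clip((rel @ d) / length2, 0.0, 1.0)
        foot = q0[None, None, :] + tproj[..., None] * d[None, None, :]
        dseg = np.linalg.norm(px_pos - foot, axis=-1)
        closer = dseg < dist
        dist = np.where(closer, dseg, dist)
        arclen = np.where(closer, tproj * np.sqrt(length2), arclen)

    mask = dist <= junction_width_um
    modulation = 1.0 + punctateness * np.sin(2.0 * np.pi * arclen / puncta_period_um)
    base = np.where(mask, junction_intensity * modulation, 0.0)

    slices = []
    for _ in range(n_slices):
        img = base.copy()
        if background_noise_sd > 0:
            img = img + rng.normal(0.0, background_noise_sd, size=img.shape)
        slices.append(np.clip(img, 0.0, None))
    image = slices[0] if n_slices == 1 else np.stack(slices)
    return SyntheticEpithelium(image=image, pixel_size=pixel_size, z_step=0.5,
                               junction_mask=mask, punctateness=punctateness,
                               ridges=ridges)


def synth_clone_widths(n_cells: int = 40,
                       clone_fraction: float = 0.5,
                       constriction_factor: float = 1.0,
                       width_mean: float = 3.0,
                       width_cv: float = 0.15,
                       unit_id: str = "synthetic-unit",
                       seed: int = 0) -> CloneMeasurementSet:
    """Clone/control apical-width ensemble with a programmed constriction.

    Control widths are lognormal with arithmetic mean ``width_mean`` (um)
    and CV ``width_cv``; clone widths are independent draws from the same
    law scaled by ``constriction_factor`` (< 1 means apical constriction
    of the clone). ``width_cv=0`` makes both groups deterministic, so the
    clone/control ratio equals the constriction factor exactly.
    """
    _require(0 < clone_fraction < 1, "clone_fraction", "must be in (0, 1)")
    _require(constriction_factor > 0, "constriction_factor", "must be > 0")
    _require(n_cells >= 2, "n_cells", "must be >= 2")
    _require(width_mean > 0, "width_mean", "must be > 0")
    _require(width_cv >= 0, "width_cv", "must be >= 0")
    rng = np.random.default_rng(seed)
    n_clone = int(np.clip(round(n_cells * clone_fraction), 1, n_cells - 1))
    n_control = n_cells - n_clone

    def draw(size: int) -> np.ndarray:
        if width_cv == 0:
            return np.full(size, width_mean)
        mu, sigma = lognormal_params(width_mean, width_cv)
        return rng.lognormal(mu, sigma, size)

    control = draw(n_control)
    clone = constriction_factor * draw(n_clone)
    return CloneMeasurementSet(unit_id=unit_id, clone_values=clone,
                               control_values=control, measure_kind="width")
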