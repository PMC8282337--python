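"""Laser-ablation recoil analysis.

Severing a single cell-cell interface releases the tension borne by its
actomyosin cortex; the two tricellular vertices that flanked the interface
recoil apart. Modelling the interface as a Kelvin-Voigt element (a spring of
elasticity E and a dashpot of viscosity mu in parallel), the recoil of the
vertex-to-vertex distance follows

    dL(t) = D * (1 - exp(-t / tau)),    tau = mu / E,

where ``D`` is the asymptotic recoil amplitude and ``tau`` the relaxation
time. Two quantities are extracted per ablated junction:

* the retraction velocity -- the change in vertex separation between the
  frames immediately before and after ablation, divided by the elapsed time;
  a proxy for cortical tension,
* the Kelvin-Voigt fit ``(D, tau)`` -- ``tau`` reports the tissue's
  viscosity-to-elasticity ratio. ``mu`` and ``E`` are not separately
  identifiable from recoil alone and are deliberately kept as their ratio.

Vertex positions are an input (manually tracked in practice); no image
processing happens here. Time is measured from the last pre-ablation frame,
so the first post-ablation frame sits at t = frame interval: the exact
ablation instant within the inter-frame gap is unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VertexTrack",
    "InterfaceLengthSeries",
    "KelvinVoigtFit",
    "RecoilResult",
    "kelvin_voigt_displacement",
    "interface_length",
    "retraction_velocity",
    "fit_kelvin_voigt",
    "grid_search_fit",
    "analyze_track",
    "analyze_tracks",
    "results_to_frame",
]

_UNIFORM_TOL = 1e-6


def kelvin_voigt_displacement(t, D: float, tau: float):
    """Recoil displacement D*(1 - exp(-t/tau)) of a severed elastic fibre."""
    t = np.asarray(t, dtype=float)
    return D * (1.0 - np.exp(-t / tau))


@dataclass
class VertexTrack:
    """Per-frame positions of the two tricellular vertices of one junction.

    ``ablation_frame`` is the index (into ``times``) of the *last
    pre-ablation* frame; every later frame is post-ablation.
    """

    track_id: str
    times: np.ndarray          # s, uniformly spaced
    vertex1_xy: np.ndarray     # (n_frames, 2) in um
    vertex2_xy: np.ndarray     # (n_frames, 2) in um
    ablation_frame: int
    frames: np.ndarray | None = None   # acquisition frame indices, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vertex1_xy = np.asarray(self.vertex1_xy, dtype=float)
        self.vertex2_xy = np.asarray(self.vertex2_xy, dtype=float)
        if self.frames is None:
            self.frames = np.arange(self.times.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def validate(self) -> None:
        n = self.times.size
        if self.times.ndim != 1 or n < 3:
            raise ValueError("times: need at least 3 frames (1 pre + 2 post)")
        for name, arr in (("vertex1_xy", self.vertex1_xy),
                          ("vertex2_xy", self.vertex2_xy)):
            if arr.shape != (n, 2):
                raise ValueError(f"{name}: expected shape ({n}, 2), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: coordinates must be finite")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times: must be strictly increasing")
        if np.ptp(dt) > _UNIFORM_TOL:
            raise ValueError("times: spacing must be uniform (tolerance 1e-6 s)")
        if not (0 <= self.ablation_frame <= n - 3):
            raise ValueError(
                "ablation_frame: need >=1 frame at/before ablation and >=2 after"
            )


@dataclass
class InterfaceLengthSeries:
    """Vertex-to-vertex distance L(t); t = 0 at the last pre-ablation frame."""

    t: np.ndarray              # s; pre-ablation frames have t <= 0
    L: np.ndarray              # um
    ablation_index: int
    track_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.t.shape != self.L.shape:
            raise ValueError("t and L must have the same length")
        if np.any(self.L < 0):
            raise ValueError("L: interface lengths must be nonnegative")

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class KelvinVoigtFit:
    """Result of fitting dL(t) = D*(1 - exp(-t/tau)) to post-ablation frames."""

    D: float                   # asymptotic recoil amplitude, um
    tau: float                 # relaxation time mu/E, s (nan if not converged)
    L_ref: float               # pre-ablation reference length, um
    rss: float                 # residual sum of squares, um^2
    n_points: int              # post-ablation frames used
    converged: bool
    method: str                # optimizer path descriptor
    message: str = ""


@dataclass
class RecoilResult:
    track_id: str
    retraction_velocity: float   # um/s
    fit: KelvinVoigtFit


def interface_length(track: VertexTrack) -> InterfaceLengthSeries:
    """Euclidean vertex separation per frame, time-shifted to the ablation frame."""
    L = np.linalg.norm(track.vertex2_xy - track.vertex1_xy, axis=1)
    t = track.times - track.times[track.ablation_frame]
    return InterfaceLengthSeries(t=t, L=L, ablation_index=track.ablation_frame,
                                 track_id=track.track_id)


def retraction_velocity(series: InterfaceLengthSeries) -> float:
    """Initial recoil speed: (first post-ablation L - last pre-ablation L) / dt."""
    i0 = series.ablation_index
    if not np.isclose(series.t[i0], 0.0):
        raise ValueError("series must have its ablation frame at t = 0")
    if i0 + 1 >= series.t.size:
        raise ValueError("series has no post-ablation frame")
    dt = series.t[i0 + 1] - series.t[i0]
    return float((series.L[i0 + 1] - series.L[i0]) / dt)


def _reference_length(series: InterfaceLengthSeries,
                      l_ref_mode: Literal["last_pre", "mean_pre"]) -> float:
    if l_ref_mode == "last_pre":
        return float(series.L[series.ablation_index])
    if l_ref_mode == "mean_pre":
        return float(series.L[: series.ablation_index + 1].mean())
    raise ValueError(f"l_ref_mode: unknown mode {l_ref_mode!r}")


def _tau_bounds(t_post: np.ndarray) -> tuple[float, float]:
    dt = float(t_post[0]) if t_post.size == 1 else float(t_post[1] - t_post[0])
    return dt / 10.0, 10.0 * float(t_post[-1])


def _initial_tau(t_post: np.ndarray, dL: np.ndarray, D0: float,
                 lo: float, hi: float) -> float:
    """Earliest time at which dL reaches (1 - 1/e)*D0, by linear interpolation."""
    target = (1.0 - np.exp(-1.0)) * D0
    tt = np.concatenate([[0.0], t_post])   # recoil starts from 0 at t=0
    yy = np.concatenate([[0.0], dL])
    for i in range(1, tt.size):
        if yy[i] >= target:
            y0, y1 = yy[i - 1], yy[i]
            if y1 == y0:
                tau0 = tt[i]
            else:
                tau0 = tt[i - 1] + (target - y0) / (y1 - y0) * (tt[i] - tt[i - 1])
            return float(np.clip(tau0, lo, hi))
    return float(np.clip(tt[-1], lo, hi))


def grid_search_fit(t_post: np.ndarray, dL: np.ndarray,
                    n_d: int = 200, n_tau: int = 200,
                    d_max: float | None = None,
                    tau_bounds: tuple[float, float] | None = None,
                    ) -> tuple[float, float, float]:
    """Brute-force (D, tau) grid search minimising the residual sum of squares.

    Serves as the fallback optimizer and as a slow, assumption-free oracle:
    D on a linear grid over [0, d_max], tau log-spaced over ``tau_bounds``.
    Returns (D, tau, rss) of the best grid node.
    """
    t_post = np.asarray(t_post, dtype=float)
    dL = np.asarray(dL, dtype=float)
    if d_max is None:
        d_max = max(2.0 * float(np.max(dL, initial=0.0)), 1e-6)
    if tau_bounds is None:
        tau_bounds = _tau_bounds(t_post)
    D_grid = np.linspace(0.0, d_max, n_d)
    tau_grid = np.geomspace(tau_bounds[0], tau_bounds[1], n_tau)
    # residuals for all (D, tau) pairs at once: (n_d, n_tau, n_t)
    shape_fn = 1.0 - np.exp(-t_post[None, :] / tau_grid[:, None])   # (n_tau, n_t)
    pred = D_grid[:, None, None] * shape_fn[None, :, :]
    rss = np.sum((pred - dL[None, None, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(D_grid[i]), float(tau_grid[j]), float(rss[i, j])


def fit_kelvin_voigt(series: InterfaceLengthSeries,
                     l_ref_mode: Literal["last_pre", "mean_pre"] = "last_pre",
                     include_t0: bool = False) -> KelvinVoigtFit:
    """Bounded nonlinear least squares of the recoil increment.

    Fits dL(t) = L(t) - L_ref against D*(1 - exp(-t/tau)) over the
    post-ablation frames, with L_ref the length at the last pre-ablation
    frame (or the mean of all pre frames with ``l_ref_mode='mean_pre'``).
    Bounds: D >= 0, tau in [dt/10, 10*T_total]. Initialisation: D0 = final
    dL, tau0 = earliest time at which dL reaches (1 - 1/e)*D0. If the
    gradient-based solver fails, a 200x200 grid search takes over and the
    ``method`` field says so.

    A track with no net recoil (final dL <= 0) yields ``converged=False``
    with diagnostics rather than an exception.
    """
    if not (np.all(np.isfinite(series.t)) and np.all(np.isfinite(series.L))):
        raise ValueError("series: non-finite values")
    post = series.t > 0
    t_post = series.t[post]
    if t_post.size < 3:
        raise ValueError("fit requires at least 3 post-ablation frames")
    L_ref = _reference_length(series, l_ref_mode)
    dL = series.L[post] - L_ref
    if include_t0:
        t_post = np.concatenate([[0.0], t_post])
        dL = np.concatenate([[0.0], dL])

    tau_lo, tau_hi = _tau_bounds(series.t[series.t > 0])
    D0 = float(dL[-1])
    if D0 <= 0.0:
        rss0 = float(np.sum(dL ** 2))
        return KelvinVoigtFit(D=0.0, tau=float("nan"), L_ref=L_ref, rss=rss0,
                              n_points=int(t_post.size), converged=False,
                              method="none", message="no net recoil (final dL <= 0)")

    tau0 = _initial_tau(series.t[series.t > 0], series.L[post] - L_ref, D0,
                        tau_lo, tau_hi)

    def resid(p):
        return kelvin_voigt_displacement(t_post, p[0], p[1]) - dL

    starts = [(D0, tau0), (D0, float(np.sqrt(tau_lo * tau_hi)))]
    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0=x0, bounds=([0.0, tau_lo], [np.inf, tau_hi]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[2]:
            best = (float(res.x[0]), float(res.x[1]), rss)
    if best is not None:
        D_hat, tau_hat, rss = best
        return KelvinVoigtFit(D=D_hat, tau=tau_hat, L_ref=L_ref, rss=rss,
                              n_points=int(t_post.size), converged=True,
                              method="least_squares")
    D_hat, tau_hat, rss = grid_search_fit(t_post, dL, tau_bounds=(tau_lo, tau_hi))
    return KelvinVoigtFit(D=D_hat, tau=tau_hat, L_ref=L_ref, rss=rss,
                          n_points=int(t_post.size), converged=True,
                          method="grid_fallback",
                          message="gradient-based solver failed; grid minimum reported")


def analyze_track(track: VertexTrack, **fit_opts) -> RecoilResult:
    """Retraction velocity plus Kelvin-Voigt fit for one vertex track."""
    series = interface_length(track)
    return RecoilResult(track_id=track.track_id,
                        retraction_velocity=retraction_velocity(series),
                        fit=fit_kelvin_voigt(series, **fit_opts))


def analyze_tracks(tracks: Sequence[VertexTrack], **fit_opts) -> list[RecoilResult]:
    return [analyze_track(tr, **fit_opts) for tr in tracks]


def results_to_frame(results: Sequence[RecoilResult]) -> pd.DataFrame:
    """Tabulate per-junction results (one row per track)."""
    return pd.DataFrame(
        {
            "track_id": [r.track_id for r in results],
            "velocity_um_s": [r.retraction_velocity for r in results],
            "D_um": [r.fit.D for r in results],
            "tau_s": [r.fit.tau for r in results],
            "rss": [r.fit.rss for r in results],
            "converged": [r.fit.converged for r in results],
            "method": [r.fit.method for r in results],
        }
    )
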