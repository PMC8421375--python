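"""Monte Carlo packet propagation through scattering media with phase tracking.

The usual radiative-transfer random walk — exponential free paths against
μt = μs + μa, Henyey–Greenstein deflections parameterized by the
anisotropy g — augmented by optical-path accumulation Σ nᵢ·lᵢ so each
packet keeps a well-defined phase 2π·OPL/λ.  Media are homogeneous
axis-aligned slabs/cuvettes, index-matched at their boundaries (no
Fresnel reflection or refraction; the medium index enters only through
the optical path).  Packets leaving through any face other than the far
(detector-facing) one are discarded, and a sampled step that would leave
the slab is clipped exactly to the face intersection.

Absorption is sampled against μt with event probability μa/μt at each
interaction; absorbed packets terminate outright, keeping every surviving
packet at full, constant amplitude — partial packet weights have no phase
semantics in a coherent sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MediumSlab, PacketBatch, RngStream, Status
from .detect import FieldAccumulator

__all__ = [
    "Event",
    "TransportResult",
    "sample_free_path",
    "scatter_direction",
    "advance",
    "record_plane_crossings",
    "free_flight_to_plane",
    "propagate_in_medium",
]


class Event:
    """Step / terminal event codes."""

    SCATTER = 0
    ABSORB = 1
    EXIT_FAR = 2
    EXIT_SIDE = 3
    EXIT_BACK = 4
    MAX_EVENTS = 5


def sample_free_path(mu_t: float, rng: RngStream, n: int | None = None):
    """Exponential free path s = −ln(U)/μt in μm, U ∈ (0, 1].

    ``mu_t`` is in mm⁻¹; μt = 0 means free flight (infinite path).
    """
    u = rng.uniform(n)
    if mu_t <= 0:
        return np.full_like(np.asarray(u, dtype=float), np.inf)
    return -np.log(u) / (mu_t * 1e-3)


def scatter_direction(direction: np.ndarray, g: float, rng: RngStream) -> np.ndarray:
    """New unit direction(s) after a Henyey–Greenstein scattering event.

    The deflection cosine is drawn from the HG phase function with
    asymmetry g (g = 0: isotropic), the azimuth uniformly.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    n = d.shape[0]
    u = rng.uniform(n)
    if abs(g) < 1e-12:
        cos_t = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * rng.uniform(n)

    # orthonormal frame around each incident direction
    ref = np.where(np.abs(d[:, 2:3]) < 0.999, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (cos_t[:, None] * d
           + (sin_t * np.cos(phi))[:, None] * e1
           + (sin_t * np.sin(phi))[:, None] * e2)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out if np.asarray(direction).ndim == 2 else out[0]


def advance(batch: PacketBatch, distance, n_medium: float = 1.0) -> PacketBatch:
    """Move packets along their directions; OPL grows by n·distance."""
    dist = np.asarray(distance, dtype=float)
    if np.any(dist < 0):
        raise ValueError("advance distance must be non-negative")
    batch.position = batch.position + dist[..., None] * batch.direction
    batch.optical_path = batch.optical_path + n_medium * dist
    return batch


# ---------------------------------------------------------------------------
# Coherent recording along straight segments
# ---------------------------------------------------------------------------


def record_plane_crossings(points, dirs, opl, seg_len, n_medium, accumulators,
                           amplitude, wavelength) -> None:
    """Add packet fields to plane accumulators crossed by straight segments.

    For every accumulator (which must carry ``plane_z``) the crossing point
    of each segment with that z-plane is found; packets whose segment spans
    the plane deposit E₀·exp(i·2π·OPL(z)/λ) into the bin at the crossing.
    """
    if not accumulators:
        return
    dz = dirs[:, 2]
    for acc in accumulators:
        if acc.plane_z is None:
            raise ValueError("plane accumulator needs plane_z")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (acc.plane_z - points[:, 2]) / dz
        hit = (t > 0) & (t <= seg_len) & np.isfinite(t)
        if not np.any(hit):
            continue
        xy = points[hit, :2] + t[hit, None] * dirs[hit, :2]
        opl_at = opl[hit] + n_medium * t[hit]
        fields = amplitude * np.exp(2j * np.pi * opl_at / wavelength)
        acc.add_fields(xy, fields)


def free_flight_to_plane(points, dirs, opl, z_plane: float, n_medium: float = 1.0):
    """Propagate rays ballistically to a z-plane; returns (hit_xy, opl_at)."""
    dz = dirs[:, 2]
    if np.any(dz <= 0):
        raise ValueError("rays must travel toward the plane")
    t = (z_plane - points[:, 2]) / dz
    if np.any(t < 0):
        raise ValueError("plane lies behind some rays")
    xy = points[:, :2] + t[:, None] * dirs[:, :2]
    return xy, opl + n_medium * t


# ---------------------------------------------------------------------------
# Slab propagation
# ---------------------------------------------------------------------------


@dataclass
class TransportResult:
    """Terminal state of a propagated batch."""

    event: np.ndarray        # terminal Event code per packet
    exit_point: np.ndarray   # (n, 3); valid for exit events
    optical_path: np.ndarray
    n_scatter: np.ndarray    # scattering events per packet
    counts: dict

    @property
    def detected(self) -> np.ndarray:
        return self.event == Event.EXIT_FAR


def _boundary_distance(p, d, lo, hi):
    """Distance to the slab boundary along d and the face crossed."""
    with np.errstate(divide="ignore"):
        t_pos = (hi - p) / d
        t_neg = (lo - p) / d
    t_face = np.where(d > 0, t_pos, np.where(d < 0, t_neg, np.inf))
    t_exit = t_face.min(axis=1)
    axis = t_face.argmin(axis=1)
    return t_exit, axis


def propagate_in_medium(batch: PacketBatch, medium: MediumSlab, rng: RngStream,
                        plane_accumulators=(), max_events: int = 100_000) -> TransportResult:
    """Random-walk packets through the slab until they leave (terminal).

    Packets must start on (or inside) the entry face travelling into the
    medium.  Each iteration samples a free path, clips it against the slab
    boundary, advances with OPL accumulation (recording any interior plane
    crossings coherently), and either terminates at a face, absorbs, or
    scatters.  Far-face exits are detected; side/back exits are discarded.
    """
    props = medium.properties
    n_med = props.n
    mu_t = props.mu_t
    p_abs = props.mu_a / mu_t if mu_t > 0 else 0.0
    lo = np.asarray(medium.origin, dtype=float)
    hi = lo + np.asarray(medium.extent, dtype=float)
    n = len(batch)

    event = np.full(n, -1, dtype=np.int8)
    n_scatter = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    pos = batch.position.copy()
    dirs = batch.direction.copy()
    opl = batch.optical_path.copy()

    for _ in range(max_events):
        if active.size == 0:
            break
        m = active.size
        s = sample_free_path(mu_t, rng, m)
        t_exit, axis = _boundary_distance(pos[active], dirs[active], lo, hi)
        leaves = s >= t_exit
        move = np.where(leaves, t_exit, s)

        record_plane_crossings(pos[active], dirs[active], opl[active], move, n_med,
                               plane_accumulators, batch.amplitude, batch.wavelength)
        pos[active] += move[:, None] * dirs[active]
        opl[active] += n_med * move

        leaving = active[leaves]
        ax = axis[leaves]
        dz = dirs[leaving, 2]
        ev = np.where(ax != 2, Event.EXIT_SIDE,
                      np.where(dz > 0, Event.EXIT_FAR, Event.EXIT_BACK))
        event[leaving] = ev.astype(np.int8)

        staying = active[~leaves]
        if staying.size:
            u = rng.uniform(staying.size)
            absorbed = u < p_abs
            event[staying[absorbed]] = Event.ABSORB
            scat = staying[~absorbed]
            if scat.size:
                dirs[scat] = scatter_direction(dirs[scat], props.g, rng)
                n_scatter[scat] += 1
            active = scat
        else:
            active = staying
    else:
        event[active] = Event.MAX_EVENTS

    batch.position = pos
    batch.direction = dirs
    batch.optical_path = opl
    batch.status = np.where(event == Event.EXIT_FAR, Status.DETECTED,
                            Status.DISCARDED).astype(np.int8)

    counts = {
        "launched": n,
        "detected": int((event == Event.EXIT_FAR).sum()),
        "discarded": int(np.isin(event, [Event.EXIT_SIDE, Event.EXIT_BACK,
                                         Event.ABSORB, Event.MAX_EVENTS]).sum()),
        "absorbed": int((event == Event.ABSORB).sum()),
        "exit_side": int((event == Event.EXIT_SIDE).sum()),
        "exit_back": int((event == Event.EXIT_BACK).sum()),
    }
    return TransportResult(event, pos, opl, n_scatter, counts)
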