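"""Packet launching from slits, apertures, lenses and axicons.

Every wavefront-shaping element is treated the same way: packets are
placed on the element's emitting surface (slit area, lens exit surface,
axicon cone) with the optical path accumulated up to that surface by
geometric ray tracing (exact vector Snell refraction inside glass), and
the Huygens–Fresnel principle then assigns each packet a direction by
uniformly sampling a point on the downstream target plane (detector or
medium entry face) — forward-going wavelets only.

The launch-position density plays the role of the aperture *field
amplitude* in the coherent bin sums, because the expected accumulated
field in a bin is ∝ ∫ p(ρ)·exp(ik·L(ρ)) dρ.  Uniformly illuminated
apertures therefore use uniform sampling, and a Gaussian beam with 1/e²
intensity radius w samples launch positions from the *amplitude* profile
exp(−ρ²/w²) (a normal with σ = w/√2 per axis) while the per-packet
amplitude E₀ stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, RngStream

__all__ = [
    "BeamSpec",
    "SlitPairSpec",
    "SquareApertureSpec",
    "PlanoConvexLensSpec",
    "AxiconSpec",
    "ExitRays",
    "TargetPlane",
    "initial_amplitude",
    "sample_gaussian_xy",
    "sample_slit_pair",
    "sample_square_aperture",
    "sample_huygens_direction",
    "trace_planoconvex",
    "trace_axicon",
    "apply_helical_delay",
    "launch_element",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamSpec:
    """Illumination beam: vacuum wavelength (μm), power (W), transverse profile.

    ``e2_width`` is the 1/e² intensity *diameter* D for a Gaussian profile.
    ``area`` is the illuminated area (μm²) used by the packet power
    normalization; if omitted it defaults to the 1/e² disk area for a
    Gaussian beam and must be supplied for a plane wave.
    """

    wavelength: float
    power: float = 1e-3
    profile: str = "plane"
    e2_width: float | None = None
    area: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be positive")
        if self.power < 0:
            raise ConfigurationError("beam power must be non-negative")
        if self.profile not in ("plane", "gaussian"):
            raise ConfigurationError(f"unknown beam profile {self.profile!r}")
        if self.profile == "gaussian" and (self.e2_width is None or self.e2_width <= 0):
            raise ConfigurationError("gaussian profile requires a positive e2_width")

    @property
    def norm_area(self) -> float:
        if self.area is not None:
            if self.area <= 0:
                raise ConfigurationError("beam area must be positive")
            return self.area
        if self.profile == "gaussian":
            return np.pi * (self.e2_width / 2.0) ** 2
        raise ConfigurationError("plane-wave beam needs an explicit area")


@dataclass(frozen=True)
class SlitPairSpec:
    """Young's double slit: slit (full) width 2b, centre separation d, screen at L."""

    slit_width: float
    separation: float
    screen_distance: float
    screen_extent: float
    slit_length: float | None = None  # along the slit axis; defaults to slit_width

    def __post_init__(self) -> None:
        if not (self.separation > self.slit_width > 0):
            raise ConfigurationError("need separation > slit_width > 0")
        if self.screen_distance <= 0:
            raise ConfigurationError("screen distance must be positive")

    @property
    def exit_z(self) -> float:
        return 0.0


@dataclass(frozen=True)
class SquareApertureSpec:
    """Square aperture of side l with the detector screen a distance r₀ away."""

    side: float
    screen_distance: float

    def __post_init__(self) -> None:
        if self.side <= 0 or self.screen_distance <= 0:
            raise ConfigurationError("aperture side and screen distance must be positive")

    @property
    def exit_z(self) -> float:
        return 0.0


@dataclass(frozen=True)
class PlanoConvexLensSpec:
    """Plano-convex singlet: aperture semi-diameter, centre thickness, ROC, index.

    ``orientation``: ``"convex_first"`` places the curved surface toward the
    collimated source (the standard focusing orientation, whose working
    distance f − t/n matches the quoted value for the modelled singlet);
    ``"flat_first"`` reverses it.
    """

    radius: float
    thickness: float
    roc: float
    n_lens: float = 1.4631
    orientation: str = "convex_first"

    def __post_init__(self) -> None:
        if self.roc <= 0 or self.radius <= 0 or self.thickness <= 0:
            raise ConfigurationError("lens geometry must be positive")
        if self.n_lens <= 1.0:
            raise ConfigurationError("lens index must exceed 1")
        if self.orientation not in ("convex_first", "flat_first"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")

    @property
    def effective_aperture(self) -> float:
        """Usable aperture radius: the mechanical semi-diameter clamped to the
        extent of the spherical surface (rays beyond the cap cannot refract)."""
        return min(self.radius, 0.999 * self.roc)

    @property
    def exit_z(self) -> float:
        """Axial position of the exit reference plane (flat face or vertex)."""
        return self.thickness


@dataclass(frozen=True)
class AxiconSpec:
    """Axicon: flat entry face, conical exit surface with opening angle α.

    The cone tip points downstream; ``thickness`` is the centre (apex)
    thickness, so the exit surface is z = thickness − r·tan α.  A nonzero
    ``helical_order`` adds an azimuthal phase delay of that many cycles,
    producing a higher-order Bessel beam.
    """

    alpha: float
    radius: float
    n_lens: float = 1.4631
    helical_order: int = 0
    thickness: float = 2200.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < np.pi / 2):
            raise ConfigurationError("opening angle must lie in (0, π/2)")
        if self.radius <= 0:
            raise ConfigurationError("axicon radius must be positive")
        if self.n_lens <= 1.0:
            raise ConfigurationError("axicon index must exceed 1")
        if self.helical_order < 0 or int(self.helical_order) != self.helical_order:
            raise ConfigurationError("helical order must be a non-negative integer")

    @property
    def exit_z(self) -> float:
        """Axial position of the cone tip."""
        return self.thickness


@dataclass
class ExitRays:
    """Rays on an element's exit surface: points, accumulated OPL, directions.

    ``direction`` is the exact-Snell refracted geometric direction (used by
    the focal-length oracles); Huygens launching replaces it.  ``valid``
    flags rays that made it through (no aperture miss, no TIR).
    """

    points: np.ndarray
    optical_path: np.ndarray
    direction: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class TargetPlane:
    """Axis-normal rectangle toward which Huygens directions are sampled."""

    z: float
    center: tuple[float, float] = (0.0, 0.0)
    half_extent: tuple[float, float] = (20.0, 20.0)


# ---------------------------------------------------------------------------
# Launch-position sampling
# ---------------------------------------------------------------------------


def initial_amplitude(beam: BeamSpec, n_packets: int) -> float:
    """Per-packet field amplitude E₀ = √(P/A)/N.

    N in-phase packets landing in a bin of area A then accumulate an
    intensity of N²·E₀² = P/A, i.e. the beam's power density.
    """
    if n_packets < 1:
        raise ConfigurationError("need at least one packet")
    if beam.power == 0:
        return 0.0
    return float(np.sqrt(beam.power / beam.norm_area) / n_packets)


def sample_gaussian_xy(e2_width: float, rng: RngStream, n: int,
                       max_radius: float | None = None) -> np.ndarray:
    """Sample (x, y) from the amplitude profile of a Gaussian beam.

    Density ∝ exp(−r²/w²) with w = e2_width/2, i.e. σ = w/√2 per axis;
    points outside ``max_radius`` (element aperture) are redrawn.
    """
    w = e2_width / 2.0
    sigma = w / np.sqrt(2.0)
    xy = rng.normal(0.0, sigma, (n, 2))
    if max_radius is not None:
        bad = np.einsum("ij,ij->i", xy, xy) > max_radius**2
        while np.any(bad):
            xy[bad] = rng.normal(0.0, sigma, (int(bad.sum()), 2))
            bad = np.einsum("ij,ij->i", xy, xy) > max_radius**2
    return xy


def _entry_xy(beam: BeamSpec, aperture_radius: float, rng: RngStream, n: int) -> np.ndarray:
    if beam.profile == "gaussian":
        return sample_gaussian_xy(beam.e2_width, rng, n, max_radius=aperture_radius)
    # plane wave filling the aperture: uniform over the disk
    u = rng.uniform(n)
    r = aperture_radius * np.sqrt(u)
    phi = 2.0 * np.pi * rng.uniform(n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def sample_slit_pair(spec: SlitPairSpec, beam: BeamSpec, rng: RngStream, n: int = 1) -> ExitRays:
    """Uniform positions over the union of the two slit areas (½ each).

    Plane-wave illumination: zero optical path at the slit plane.
    """
    length = spec.slit_length if spec.slit_length is not None else spec.slit_width
    pick = rng.uniform(n) < 0.5
    centers = np.where(pick, -spec.separation / 2.0, spec.separation / 2.0)
    x = centers + (rng.uniform(n) - 0.5) * spec.slit_width
    y = (rng.uniform(n) - 0.5) * length
    pts = np.column_stack([x, y, np.zeros(n)])
    return ExitRays(pts, np.zeros(n), np.tile([0.0, 0.0, 1.0], (n, 1)), np.ones(n, bool))


def sample_square_aperture(spec: SquareApertureSpec, beam: BeamSpec, rng: RngStream,
                           n: int = 1) -> ExitRays:
    """Uniform positions over the square aperture, zero optical path."""
    x = (rng.uniform(n) - 0.5) * spec.side
    y = (rng.uniform(n) - 0.5) * spec.side
    pts = np.column_stack([x, y, np.zeros(n)])
    return ExitRays(pts, np.zeros(n), np.tile([0.0, 0.0, 1.0], (n, 1)), np.ones(n, bool))


def sample_huygens_direction(origins: np.ndarray, target: TargetPlane, rng: RngStream):
    """Forward-going Huygens directions toward a uniformly sampled plane point.

    Returns ``(directions, target_points)``; every direction is normalized
    and has a strictly positive component toward the target plane (no
    backward wavelets).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    n = origins.shape[0]
    tx = target.center[0] + (2.0 * rng.uniform(n) - 1.0) * target.half_extent[0]
    ty = target.center[1] + (2.0 * rng.uniform(n) - 1.0) * target.half_extent[1]
    targets = np.column_stack([tx, ty, np.full(n, target.z)])
    d = targets - origins
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm == 0):
        raise ValueError("origin lies on the target plane")
    d /= norm[:, None]
    return d, targets


# ---------------------------------------------------------------------------
# Refractive elements
# ---------------------------------------------------------------------------


def _refract(d: np.ndarray, normal: np.ndarray, n_in: float, n_out: float):
    """Exact vector Snell refraction of unit rays ``d`` at surfaces ``normal``.

    ``normal`` need not oppose the ray; its sign is fixed internally.
    Returns (refracted unit vectors, TIR mask); TIR rays are left unchanged.
    """
    d = np.atleast_2d(d)
    normal = np.atleast_2d(normal)
    cos_i = np.einsum("ij,ij->i", d, normal)
    nrm = np.where(cos_i[:, None] > 0, -normal, normal)  # oppose the ray
    cos_i = np.abs(cos_i)
    eta = n_in / n_out
    sin2_t = eta**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    t = eta * d + (eta * cos_i - cos_t)[:, None] * nrm
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return np.where(tir[:, None], d, t), tir


def trace_planoconvex(entry_xy: np.ndarray, spec: PlanoConvexLensSpec) -> ExitRays:
    """Trace axis-parallel rays through the lens to its exit surface.

    The phase reference is the plane z = 0 touching the first surface's
    vertex; the returned optical path is Σ nᵢ·lᵢ from that plane to the
    exit point.  Rays outside the aperture or totally internally reflected
    are flagged invalid.
    """
    xy = np.atleast_2d(np.asarray(entry_xy, dtype=float))
    n = xy.shape[0]
    r2 = np.einsum("ij,ij->i", xy, xy)
    valid = r2 <= spec.effective_aperture**2
    r2c = np.where(valid, r2, 0.0)
    R, t, ng = spec.roc, spec.thickness, spec.n_lens
    sag = R - np.sqrt(R * R - r2c)
    d0 = np.tile([0.0, 0.0, 1.0], (n, 1))

    if spec.orientation == "convex_first":
        # curved surface toward the source, vertex at z = 0, centre at (0,0,R)
        hit = np.column_stack([xy, sag])
        normal = (hit - np.array([0.0, 0.0, R])) / R  # outward (toward source)
        d_glass, tir = _refract(d0, normal, 1.0, ng)
        valid &= ~tir
        # propagate inside glass to the flat exit face z = t
        dz = d_glass[:, 2]
        glass_len = np.where(dz > 0, (t - hit[:, 2]) / np.where(dz > 0, dz, 1.0), np.inf)
        exit_pts = hit + d_glass * glass_len[:, None]
        opl = sag + ng * glass_len
        d_out, tir2 = _refract(d_glass, np.tile([0.0, 0.0, 1.0], (n, 1)), ng, 1.0)
        valid &= ~tir2 & np.isfinite(glass_len)
    else:
        # flat face toward the source at z = 0; curved exit, vertex at z = t
        hit = np.column_stack([xy, t - sag])  # sphere centred at (0, 0, t - R)
        opl = ng * hit[:, 2]
        normal = (hit - np.array([0.0, 0.0, t - R])) / R  # outward (+z side)
        d_out, tir = _refract(d0, normal, ng, 1.0)
        valid &= ~tir
        exit_pts = hit

    return ExitRays(exit_pts, opl, d_out, valid)


def trace_axicon(entry_xy: np.ndarray, spec: AxiconSpec) -> ExitRays:
    """Trace axis-parallel rays through the axicon to its conical surface.

    Flat entry face at z = 0; the cone z = thickness − r·tan α is the exit
    surface.  The refracted direction follows exact Snell at the cone and
    is deflected toward the axis by β = arcsin(n·sin α) − α; a ray exactly
    on the axis (apex) is left undeviated by convention.
    """
    xy = np.atleast_2d(np.asarray(entry_xy, dtype=float))
    n = xy.shape[0]
    r = np.sqrt(np.einsum("ij,ij->i", xy, xy))
    valid = r <= spec.radius
    tan_a = np.tan(spec.alpha)
    z_exit = spec.thickness - r * tan_a
    exit_pts = np.column_stack([xy, z_exit])
    opl = spec.n_lens * z_exit

    sin_a, cos_a = np.sin(spec.alpha), np.cos(spec.alpha)
    on_axis = r == 0.0
    rsafe = np.where(on_axis, 1.0, r)
    normal = np.column_stack([sin_a * xy[:, 0] / rsafe, sin_a * xy[:, 1] / rsafe,
                              np.full(n, cos_a)])
    d0 = np.tile([0.0, 0.0, 1.0], (n, 1))
    d_out, tir = _refract(d0, normal, spec.n_lens, 1.0)
    d_out = np.where(on_axis[:, None], d0, d_out)
    valid &= ~(tir & ~on_axis)
    return ExitRays(exit_pts, opl, d_out, valid)


def apply_helical_delay(rays: ExitRays, spec: AxiconSpec, wavelength: float) -> ExitRays:
    """Add the azimuthal phase delay of an m'th-order (vortex) axicon.

    OPL increases by m·φ·λ/(2π) with φ = atan2(y, x) in [0, 2π), i.e. a
    phase increment of m times the azimuthal angle.
    """
    if spec.helical_order == 0:
        return rays
    phi = np.mod(np.arctan2(rays.points[:, 1], rays.points[:, 0]), 2.0 * np.pi)
    rays.optical_path = rays.optical_path + spec.helical_order * phi * wavelength / (2.0 * np.pi)
    return rays


def bundle_compression(element) -> float:
    """Paraxial area-compression amplitude factor of an element, m = h_exit/h_entry.

    Between its entry and exit surfaces a refractive element can compress
    the ray bundle transversely (a convex-first lens converges rays inside
    the glass).  The launch-position density carries the *entry* amplitude
    profile, so energy conservation of the wavelet sum requires each
    packet's field to be scaled by √(exit area / entry area) = m; without
    it a compressing element would over-weight its beam's field by 1/m.
    Thin elements and elements that refract only at their exit surface
    (slits, apertures, flat-first lenses, axicons) have m = 1.
    """
    if isinstance(element, PlanoConvexLensSpec) and element.orientation == "convex_first":
        t, R, n = element.thickness, element.roc, element.n_lens
        return 1.0 - t * (n - 1.0) / (n * R)
    return 1.0


# ---------------------------------------------------------------------------
# Unified element launch
# ---------------------------------------------------------------------------


def launch_element(element, beam: BeamSpec, rng: RngStream, n: int) -> ExitRays:
    """Sample ``n`` packets on the exit surface of any element.

    Dispatches on the spec type; invalid rays (aperture misses, TIR) stay
    flagged in the result and are discarded by the caller.
    """
    if isinstance(element, SlitPairSpec):
        return sample_slit_pair(element, beam, rng, n)
    if isinstance(element, SquareApertureSpec):
        return sample_square_aperture(element, beam, rng, n)
    if isinstance(element, PlanoConvexLensSpec):
        xy = _entry_xy(beam, element.effective_aperture, rng, n)
        return trace_planoconvex(xy, element)
    if isinstance(element, AxiconSpec):
        xy = _entry_xy(beam, element.radius, rng, n)
        rays = trace_axicon(xy, element)
        return apply_helical_delay(rays, element, beam.wavelength)
    raise ConfigurationError(f"unknown element spec {type(element).__name__}")
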