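"""Analytic reference curves and beam-matching relations.

Every function here is a pure, deterministic oracle used to validate the
Monte Carlo engine: Fraunhofer double-slit and Fresnel/Fraunhofer square
aperture diffraction, Gaussian beam propagation, Bessel beam profiles
from axicons, the core-width matching relations between Gaussian and
Bessel beams, and the Intralipid dilution arithmetic of the tissue
phantom.  All lengths are in μm unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = [
    "sinc",
    "double_slit_intensity",
    "fresnel_number",
    "diffraction_regime",
    "square_aperture_intensity",
    "square_aperture_quadrature",
    "gaussian_waist",
    "rayleigh_range",
    "focused_gaussian_waist",
    "lens_focal_length",
    "lens_back_focal_distance",
    "axicon_deflection",
    "bessel_profile",
    "kappa_for_metric",
    "bessel_core_radius",
    "matched_axicon_angle",
    "intralipid_dilution",
]


def sinc(u):
    """Unnormalized sinc, sin(u)/u with sinc(0) = 1 (wavevector arguments)."""
    u = np.asarray(u, dtype=float)
    return np.where(u == 0.0, 1.0, np.sin(np.where(u == 0.0, 1.0, u)) / np.where(u == 0.0, 1.0, u))


# ---------------------------------------------------------------------------
# Double slit
# ---------------------------------------------------------------------------


def double_slit_intensity(x, spec, wavelength: float):
    """Relative double-slit intensity at screen coordinate(s) x (μm).

    I(x) ∝ cos²(k·d·x / (2√(L²+x²))) · sinc²(k·b·x / √(L²+x²)) with
    centre-to-centre separation d, slit half-width b and screen distance
    L, normalized to 1 at x = 0.
    """
    x = np.asarray(x, dtype=float)
    k = 2.0 * np.pi / wavelength
    d = spec.separation
    b = spec.slit_width / 2.0
    L = spec.screen_distance
    hyp = np.sqrt(L * L + x * x)
    return np.cos(k * d * x / (2.0 * hyp)) ** 2 * sinc(k * b * x / hyp) ** 2


# ---------------------------------------------------------------------------
# Square aperture
# ---------------------------------------------------------------------------


def fresnel_number(aperture_side: float, wavelength: float, distance: float) -> float:
    """Fresnel number F = l²/(λ·r₀)."""
    if aperture_side <= 0 or wavelength <= 0 or distance <= 0:
        raise ValueError("aperture side, wavelength and distance must be positive")
    return aperture_side**2 / (wavelength * distance)


def diffraction_regime(F: float) -> str:
    """'fresnel' (near field) if F > 1 else 'fraunhofer' (far field)."""
    return "fresnel" if F > 1.0 else "fraunhofer"


def _edge_integral(x, half: float, wavelength: float, distance: float):
    """Fresnel integral difference across one aperture axis (paraxial)."""
    s = np.sqrt(2.0 / (wavelength * distance))
    u1 = s * (x - half)
    u2 = s * (x + half)
    S1, C1 = special.fresnel(u1)
    S2, C2 = special.fresnel(u2)
    return (C2 - C1) + 1j * (S2 - S1)


def square_aperture_intensity(x, y, spec, wavelength: float):
    """Paraxial Fresnel diffraction intensity behind a square aperture.

    Separable product of Fresnel cosine/sine integral differences over the
    aperture edges; valid in both regimes and converging to the Fraunhofer
    sinc² product as F → 0.  Normalized so that the unobstructed wave has
    intensity 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = spec.side / 2.0
    fx = _edge_integral(x, half, wavelength, spec.screen_distance)
    fy = _edge_integral(y, half, wavelength, spec.screen_distance)
    return 0.25 * np.abs(fx) ** 2 * np.abs(fy) ** 2


def square_aperture_quadrature(x, y, spec, wavelength: float, n: int = 801):
    """Brute-force Huygens integral for the square aperture (oracle).

    Direct 2D quadrature of ∫∫ exp(ik·r)/r over the aperture, normalized
    like :func:`square_aperture_intensity`; used only as an independent
    cross-check at small grids.
    """
    half = spec.side / 2.0
    z = spec.screen_distance
    k = 2.0 * np.pi / wavelength
    s = np.linspace(-half, half, n)
    ds = s[1] - s[0]
    sx, sy = np.meshgrid(s, s, indexing="ij")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.empty(np.broadcast(x, y).shape, dtype=float)
    it = np.nditer([np.broadcast_to(x, out.shape), np.broadcast_to(y, out.shape)],
                   flags=["multi_index"])
    for xv, yv in it:
        r = np.sqrt(z * z + (xv - sx) ** 2 + (yv - sy) ** 2)
        u = np.sum(np.exp(1j * k * r) / r) * ds * ds
        # normalize so the unobstructed paraxial wave has unit intensity
        out[it.multi_index] = np.abs(u * k / (2.0 * np.pi * 1j) * np.exp(-1j * k * z)) ** 2
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Gaussian beams
# ---------------------------------------------------------------------------


def rayleigh_range(w0: float, wavelength: float) -> float:
    """z_R = π·w0²/λ."""
    return np.pi * w0**2 / wavelength


def gaussian_waist(z, w0: float, wavelength: float):
    """1/e² beam radius w(z) = w0·√(1 + (z/z_R)²), z measured from focus."""
    if w0 <= 0:
        raise ValueError("waist must be positive")
    z = np.asarray(z, dtype=float)
    zr = rayleigh_range(w0, wavelength)
    return w0 * np.sqrt(1.0 + (z / zr) ** 2)


def focused_gaussian_waist(wavelength: float, f: float, D: float) -> float:
    """Focal waist w0 = 2λf/(πD) of a collimated Gaussian (1/e² diameter D)."""
    return 2.0 * wavelength * f / (np.pi * D)


def lens_focal_length(roc: float, n_lens: float) -> float:
    """Thin-lens focal length f = R/(n−1) of a plano-convex singlet."""
    return roc / (n_lens - 1.0)


def lens_back_focal_distance(roc: float, thickness: float, n_lens: float,
                             orientation: str = "convex_first") -> float:
    """Distance from the exit surface to the paraxial focus.

    ``convex_first`` (curved side toward the collimated source): the focus
    sits f − t/n behind the flat exit face — the lens's working distance.
    ``flat_first``: the focus sits f behind the curved exit vertex.
    """
    f = lens_focal_length(roc, n_lens)
    if orientation == "convex_first":
        return f - thickness / n_lens
    if orientation == "flat_first":
        return f
    raise ValueError(f"unknown lens orientation {orientation!r}")


# ---------------------------------------------------------------------------
# Axicons and Bessel beams
# ---------------------------------------------------------------------------


def axicon_deflection(alpha: float, n_lens: float, exact: bool = True) -> float:
    """Deflection β of a ray refracted at the conical surface.

    Exact Snell: β = arcsin(n·sin α) − α; the small-angle form is
    β = (n−1)·α.
    """
    if exact:
        return float(np.arcsin(n_lens * np.sin(alpha)) - alpha)
    return (n_lens - 1.0) * alpha


def bessel_profile(r, k_r: float):
    """Transverse Bessel beam intensity J₀²(k_r·r), normalized to 1 at r=0."""
    if k_r <= 0:
        raise ValueError("radial wavevector must be positive")
    return special.j0(k_r * np.asarray(r, dtype=float)) ** 2


def kappa_for_metric(metric: str) -> float:
    """Core-width constant κ for a given width metric of J₀².

    ``"first_zero"``: the smallest positive root of J₀ (≈ 2.4048);
    ``"e2"``: the smallest positive κ with J₀²(κ) = e⁻² (≈ 1.75).
    """
    if metric == "first_zero":
        return float(special.jn_zeros(0, 1)[0])
    if metric == "e2":
        return float(optimize.brentq(
            lambda x: special.j0(x) ** 2 - np.exp(-2.0), 1e-9, float(special.jn_zeros(0, 1)[0])))
    raise ValueError(f"unknown core-width metric {metric!r}")


def bessel_core_radius(kappa: float, wavelength: float, beta: float) -> float:
    """Bessel core radius r₀ = κ/(k·sin β) = κ·λ/(2π·sin β)."""
    if not (0.0 < beta < np.pi / 2):
        raise ValueError("deflection angle must lie in (0, π/2)")
    return kappa * wavelength / (2.0 * np.pi * np.sin(beta))


def matched_axicon_angle(n_axicon: float, D: float, f: float) -> float:
    """Axicon opening angle matching the Bessel 1/e² core to a Gaussian waist.

    From κ=1.75: 1.75·λ/(2π·sin β) = 2λf/(πD) ⇒ sin β = 1.75·D/(4f), and
    with the small-angle relation β = (n−1)α,

        α = arcsin(1.75·D/(4f)) / (n − 1).
    """
    if n_axicon <= 1.0:
        raise ValueError("axicon refractive index must exceed 1")
    arg = 1.75 * D / (4.0 * f)
    if arg >= 1.0:
        raise ValueError("no physical axicon: 1.75·D/(4f) must be < 1")
    return float(np.arcsin(arg) / (n_axicon - 1.0))


# ---------------------------------------------------------------------------
# Intralipid phantom dilutions
# ---------------------------------------------------------------------------

#: Anchor row of the stock dilution series: 2 μL of Intralipid-20% in
#: 500 μL of water gives μs = 557.14 m⁻¹ and 0.0908% scattering particles.
INTRALIPID_ANCHOR_UL = 2.0
INTRALIPID_ANCHOR_MU_S = 557.14  # m⁻¹
INTRALIPID_ANCHOR_PARTICLE_PCT = 0.0908
#: Default anisotropy of Intralipid at 488 nm.
INTRALIPID_G = 0.82


def intralipid_dilution(v_stock: float, v_water: float = 500.0,
                        scaling: str = "volume_fraction"):
    """Concentration and scattering coefficient of an Intralipid dilution.

    Parameters
    ----------
    v_stock, v_water : μL of stock Intralipid-20% and of water.
    scaling : ``"volume_fraction"`` scales μs (and particle %) linearly in
        the stock volume *fraction* — physically correct in the
        independent-scattering regime; ``"table"`` scales linearly in the
        added stock *volume*, reproducing the printed dilution series
        exactly (its μs column is an exact multiple of the 2 μL row).

    Returns ``(volume_percent, particle_percent, mu_s_per_m)``.
    """
    if v_stock < 0 or v_water < 0:
        raise ValueError("volumes must be non-negative")
    if v_stock + v_water == 0:
        raise ValueError("total volume must be positive")
    vol_pct = 100.0 * v_stock / (v_stock + v_water)
    if scaling == "table":
        ratio = v_stock / INTRALIPID_ANCHOR_UL
    elif scaling == "volume_fraction":
        anchor_pct = 100.0 * INTRALIPID_ANCHOR_UL / (INTRALIPID_ANCHOR_UL + 500.0)
        ratio = vol_pct / anchor_pct
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (vol_pct,
            INTRALIPID_ANCHOR_PARTICLE_PCT * ratio,
            INTRALIPID_ANCHOR_MU_S * ratio)
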