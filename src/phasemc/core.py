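"""Domain types, unit conventions, and the seeded random-number contract.

The internal canonical length unit is the micrometre (μm).  Configuration
values may carry explicit unit suffixes (``"488 nm"``, ``"2 mm"``) and are
converted on load; scattering/absorption coefficients are stored in mm⁻¹,
beam power in watts.

A *packet* is a discrete carrier of optical power traced through the
scene.  On top of the usual Monte Carlo radiation transfer state
(position, direction) each packet carries its accumulated optical path
length ``Σ nᵢ·lᵢ`` so that a complex field ``E₀·exp(i·2π·OPL/λ)`` can be
summed coherently per detector bin or voxel.  Packets are stored
struct-of-arrays style in :class:`PacketBatch`; a batch of size one is a
single packet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LENGTH_UNITS",
    "parse_length",
    "parse_inverse_length",
    "parse_power",
    "Status",
    "PacketBatch",
    "OpticalProperties",
    "MediumSlab",
    "RngStream",
    "make_field_accumulator",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value is missing, malformed or unphysical."""


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

#: Conversion factors to micrometres.
LENGTH_UNITS = {
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
    "mm": 1e3,
    "cm": 1e4,
    "m": 1e6,
}

_POWER_UNITS = {"w": 1.0, "mw": 1e-3, "uw": 1e-6, "µw": 1e-6, "μw": 1e-6, "nw": 1e-9}

_NUM_UNIT = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def _split(value: str) -> tuple[float, str]:
    m = _NUM_UNIT.match(value)
    if m is None:
        raise ConfigurationError(f"cannot parse quantity {value!r}")
    try:
        num = float(m.group(1))
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse quantity {value!r}") from exc
    return num, m.group(2)


def parse_length(value: float | str, default_unit: str = "um") -> float:
    """Parse a length with optional unit suffix into μm.

    Bare numbers are interpreted in ``default_unit``.
    """
    if isinstance(value, (int, float)):
        return float(value) * LENGTH_UNITS[default_unit]
    num, unit = _split(value)
    if not unit:
        unit = default_unit
    if unit not in LENGTH_UNITS:
        raise ConfigurationError(f"unknown length unit {unit!r} in {value!r}")
    return num * LENGTH_UNITS[unit]


def parse_inverse_length(value: float | str, default_unit: str = "1/mm") -> float:
    """Parse an inverse length (e.g. a scattering coefficient) into mm⁻¹.

    Accepts suffixes of the form ``1/m``, ``/m``, ``m-1``, ``m^-1``.
    """
    if isinstance(value, (int, float)):
        value = f"{value} {default_unit}"
    num, unit = _split(value)
    if not unit:
        unit = default_unit
    unit = unit.replace("^", "").replace("−", "-")
    for pat in ("1/", "/"):
        if unit.startswith(pat):
            unit = unit[len(pat):]
            break
    else:
        if unit.endswith("-1"):
            unit = unit[:-2]
        else:
            raise ConfigurationError(f"unknown inverse-length unit in {value!r}")
    if unit not in LENGTH_UNITS:
        raise ConfigurationError(f"unknown inverse-length unit in {value!r}")
    per_um = num / LENGTH_UNITS[unit]
    return per_um * 1e3  # μm⁻¹ → mm⁻¹


def parse_power(value: float | str) -> float:
    """Parse a power with optional unit suffix into watts."""
    if isinstance(value, (int, float)):
        return float(value)
    num, unit = _split(value)
    if not unit:
        return num
    unit = unit.lower()
    if unit not in _POWER_UNITS:
        raise ConfigurationError(f"unknown power unit {unit!r} in {value!r}")
    return num * _POWER_UNITS[unit]


# ---------------------------------------------------------------------------
# Packets
# ---------------------------------------------------------------------------


class Status:
    """Terminal / in-flight packet states."""

    IN_FLIGHT = 0
    DETECTED = 1
    DISCARDED = 2


@dataclass
class PacketBatch:
    """A batch of photon power packets (struct-of-arrays).

    Attributes
    ----------
    position : (n, 3) float array, μm
    direction : (n, 3) float array, unit vectors
    optical_path : (n,) float array, μm — accumulated Σ nᵢ·lᵢ
    wavelength : float, vacuum wavelength in μm (shared by the batch)
    amplitude : float, per-packet field amplitude E₀ (shared, constant)
    status : (n,) int8 array of :class:`Status` codes
    """

    position: np.ndarray
    direction: np.ndarray
    optical_path: np.ndarray
    wavelength: float
    amplitude: float
    status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.direction = np.atleast_2d(np.asarray(self.direction, dtype=float))
        self.optical_path = np.atleast_1d(np.asarray(self.optical_path, dtype=float))
        if self.status is None:
            self.status = np.full(len(self.optical_path), Status.IN_FLIGHT, dtype=np.int8)
        norms = np.linalg.norm(self.direction, axis=1)
        live = self.status == Status.IN_FLIGHT
        if np.any(np.abs(norms[live] - 1.0) > 1e-9):
            raise ValueError("packet directions must be unit vectors")
        if self.amplitude < 0:
            raise ValueError("packet amplitude must be non-negative")

    def __len__(self) -> int:
        return self.position.shape[0]

    @property
    def phase(self) -> np.ndarray:
        """Phase angle 2π·OPL/λ of each packet, radians."""
        return 2.0 * np.pi * self.optical_path / self.wavelength

    @property
    def field(self) -> np.ndarray:
        """Complex field E₀·exp(i·2π·OPL/λ) carried by each packet."""
        return self.amplitude * np.exp(1j * self.phase)


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous medium.

    mu_s, mu_a in mm⁻¹; anisotropy g in (−1, 1); refractive index n ≥ 1.
    """

    mu_s: float = 0.0
    mu_a: float = 0.0
    g: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_s < 0 or self.mu_a < 0:
            raise ConfigurationError("mu_s and mu_a must be non-negative")
        if not (-1.0 < self.g < 1.0):
            raise ConfigurationError("anisotropy g must lie strictly inside (-1, 1)")
        if self.n < 1.0:
            raise ConfigurationError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient μt = μs + μa, mm⁻¹."""
        return self.mu_s + self.mu_a

    @property
    def mu_t_per_um(self) -> float:
        return self.mu_t * 1e-3

    @property
    def albedo(self) -> float:
        """Single-scattering albedo μs/μt (1 for a purely scattering medium)."""
        mt = self.mu_t
        return self.mu_s / mt if mt > 0 else 1.0


@dataclass(frozen=True)
class MediumSlab:
    """Axis-aligned homogeneous slab/cuvette with a voxel grid.

    The slab occupies ``[origin, origin + extent)``; packets enter through
    the low-z face and are detected on the high-z (far) face.  Voxel
    indexing is 0-based with half-open intervals ``[i·Δ, (i+1)·Δ)``, so a
    point exactly on an internal boundary belongs to the higher-index
    voxel.
    """

    extent: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    properties: OpticalProperties = OpticalProperties()
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    entry_face: str = "z-"
    exit_face: str = "z+"

    def __post_init__(self) -> None:
        ext = np.asarray(self.extent, dtype=float)
        vox = np.asarray(self.voxel_size, dtype=float)
        if np.any(ext <= 0) or np.any(vox <= 0):
            raise ConfigurationError("slab extent and voxel size must be positive")
        counts = ext / vox
        if np.any(np.abs(counts - np.round(counts)) > 1e-9):
            raise ConfigurationError("extent must be an integer number of voxels")

    @property
    def voxel_counts(self) -> tuple[int, int, int]:
        ext = np.asarray(self.extent, dtype=float)
        vox = np.asarray(self.voxel_size, dtype=float)
        return tuple(int(round(c)) for c in ext / vox)

    @property
    def z_entry(self) -> float:
        return self.origin[2]

    @property
    def z_exit(self) -> float:
        return self.origin[2] + self.extent[2]

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Map points (…, 3) to integer voxel indices (half-open convention)."""
        pts = np.asarray(points, dtype=float)
        rel = (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        return np.floor(rel).astype(np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return np.all((pts >= lo) & (pts < hi), axis=-1)


# ---------------------------------------------------------------------------
# Random numbers
# ---------------------------------------------------------------------------


class RngStream:
    """Deterministic uniform(0,1) stream with spawnable substreams.

    A run is fully determined by (config, seed, packet count): the packet
    index space is partitioned into fixed-size blocks, each drawing from
    its own child stream of the master seed, so results do not depend on
    how the work is chunked or parallelized.
    """

    #: Fixed block size of the reproducibility contract.
    BLOCK = 1_000_000

    def __init__(self, seed: int | np.random.SeedSequence):
        if isinstance(seed, np.random.SeedSequence):
            self.seed_sequence = seed
            self.seed = seed.entropy
        else:
            self.seed_sequence = np.random.SeedSequence(int(seed))
            self.seed = int(seed)
        self.generator = np.random.default_rng(self.seed_sequence)

    def uniform(self, size=None) -> np.ndarray:
        """Uniform samples on the half-open interval (0, 1]."""
        return 1.0 - self.generator.random(size)

    def normal(self, loc=0.0, scale=1.0, size=None) -> np.ndarray:
        return self.generator.normal(loc, scale, size)

    def integers(self, low, high=None, size=None) -> np.ndarray:
        return self.generator.integers(low, high, size)

    def spawn(self, n: int) -> list["RngStream"]:
        return [RngStream(ss) for ss in self.seed_sequence.spawn(n)]

    def blocks(self, n_packets: int) -> list[tuple[int, "RngStream"]]:
        """Partition ``n_packets`` into (block_size, substream) pairs."""
        n_blocks = max(1, -(-n_packets // self.BLOCK))
        streams = self.spawn(n_blocks)
        out = []
        remaining = n_packets
        for s in streams:
            size = min(self.BLOCK, remaining)
            out.append((size, s))
            remaining -= size
        return out


def make_field_accumulator(shape_spec):
    """Create an all-zero complex :class:`~phasemc.detect.FieldAccumulator`.

    ``shape_spec`` is ``(origin, bin_size, counts)`` with origin/bin_size in
    μm; 2-tuples give a detector plane, 3-tuples a voxel volume.
    """
    from .detect import FieldAccumulator

    origin, bin_size, counts = shape_spec
    return FieldAccumulator(origin=origin, bin_size=bin_size, counts=counts)
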