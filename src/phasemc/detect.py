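"""Coherent field accumulation and conversion to intensity images.

Interference is evaluated per area/volume element: each packet adds its
complex field ``E₀·exp(i·2π·OPL/λ)`` to exactly the bin containing its hit
point, and an intensity image is the squared modulus of the per-bin sums,

    I(ξ) = |Σ_ξ E₀ cos(2π·OPL/λ) + i Σ_ξ E₀ sin(2π·OPL/λ)|².

Packets never interfere at a point — only through the bins — so the bin
size is a resolution/coherence trade-off surfaced in the configuration
(1 μm detector bins by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, PacketBatch

__all__ = [
    "FieldAccumulator",
    "IntensityImage",
    "packet_field",
    "accumulate",
    "to_intensity",
    "line_profile",
]


def packet_field(amplitude: float, optical_path, wavelength: float) -> np.ndarray:
    """Complex field of a packet: E₀·[cos(2π·OPL/λ) + i·sin(2π·OPL/λ)]."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    opl = np.asarray(optical_path, dtype=float)
    return amplitude * np.exp(2j * np.pi * opl / wavelength)


class FieldAccumulator:
    """Complex-valued bin grid: a 2D detector plane or a 3D voxel volume.

    Bins are half-open ``[origin + i·Δ, origin + (i+1)·Δ)`` along each
    axis.  For a 2D plane the two axes are transverse (x, y) and
    ``plane_z`` records the axial position of the plane.
    """

    def __init__(self, origin, bin_size, counts, plane_z: float | None = None):
        self.origin = np.asarray(origin, dtype=float)
        self.bin_size = np.asarray(bin_size, dtype=float)
        self.counts = tuple(int(c) for c in np.atleast_1d(counts))
        if np.any(self.bin_size <= 0) or any(c <= 0 for c in self.counts):
            raise ConfigurationError("bin sizes and bin counts must be positive")
        if not (len(self.origin) == len(self.bin_size) == len(self.counts)):
            raise ConfigurationError("origin, bin_size and counts must have equal rank")
        if len(self.counts) not in (2, 3):
            raise ConfigurationError("accumulator must be 2D or 3D")
        self.values = np.zeros(self.counts, dtype=complex)
        self.plane_z = plane_z
        self.n_added = 0
        self.n_clipped = 0

    @property
    def ndim(self) -> int:
        return len(self.counts)

    @property
    def extent(self) -> np.ndarray:
        return self.bin_size * np.asarray(self.counts)

    def bin_centers(self, axis: int) -> np.ndarray:
        n = self.counts[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.bin_size[axis]

    def bin_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))[:, : self.ndim]
        return np.floor((pts - self.origin) / self.bin_size).astype(np.int64)

    def add_fields(self, points: np.ndarray, fields: np.ndarray) -> int:
        """Add complex fields at hit points; returns the number accepted.

        Hits outside the accumulator extent are ignored and counted in
        ``n_clipped`` (detector clipping log).
        """
        idx = self.bin_index(points)
        shape = np.asarray(self.counts)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        fields = np.broadcast_to(np.asarray(fields, dtype=complex), (idx.shape[0],))
        flat = np.ravel_multi_index(tuple(idx[ok].T), self.counts)
        nbins = int(np.prod(self.counts))
        re = np.bincount(flat, weights=fields[ok].real, minlength=nbins)
        im = np.bincount(flat, weights=fields[ok].imag, minlength=nbins)
        self.values += (re + 1j * im).reshape(self.counts)
        self.n_added += int(ok.sum())
        self.n_clipped += int((~ok).sum())
        return int(ok.sum())

    def add_packets(self, batch: PacketBatch, hit_points: np.ndarray) -> int:
        return self.add_fields(hit_points, batch.field)

    def intensity(self, normalization: str = "raw") -> "IntensityImage":
        return to_intensity(self, normalization)


@dataclass
class IntensityImage:
    """Non-negative intensity per bin, |Σ field|², optionally max-normalized."""

    values: np.ndarray
    origin: np.ndarray
    bin_size: np.ndarray
    normalization: str = "raw"
    all_zero: bool = False
    plane_z: float | None = None

    def bin_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.bin_size[axis]


def accumulate(acc: FieldAccumulator, packet: PacketBatch, hit_point: np.ndarray) -> FieldAccumulator:
    """Add packet field(s) to the bin(s) containing ``hit_point`` (in place)."""
    acc.add_packets(packet, hit_point)
    return acc


def to_intensity(acc: FieldAccumulator, normalization: str = "raw") -> IntensityImage:
    """Square the accumulated field per bin; optionally divide by the max.

    With ``normalization="max_pixel"`` the brightest bin is scaled to 1,
    matching how simulated and experimental images are compared.  An
    all-zero field cannot be normalized; the raw zeros are returned with
    ``all_zero=True`` and a warning.
    """
    if normalization not in ("raw", "max_pixel"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    vals = np.abs(acc.values) ** 2
    all_zero = False
    if normalization == "max_pixel":
        peak = vals.max() if vals.size else 0.0
        if peak > 0:
            vals = vals / peak
        else:
            all_zero = True
            warnings.warn("all-zero field: max_pixel normalization skipped")
    return IntensityImage(
        values=vals,
        origin=acc.origin.copy(),
        bin_size=acc.bin_size.copy(),
        normalization=normalization,
        all_zero=all_zero,
        plane_z=acc.plane_z,
    )


def line_profile(image: IntensityImage, axis: int = 0, index: int | None = None):
    """Extract a row/column of a 2D intensity image.

    Parameters
    ----------
    axis : the axis *along* which the profile runs (0 = x, 1 = y).
    index : bin index on the other axis; defaults to the middle row.

    Returns ``(coords, values)`` with bin-centre coordinates in μm.
    """
    if image.values.ndim != 2:
        raise ValueError("line_profile expects a 2D image")
    other = 1 - axis
    if index is None:
        index = image.values.shape[other] // 2
    if not (0 <= index < image.values.shape[other]):
        raise IndexError(f"profile index {index} out of bounds")
    vals = image.values[:, index] if axis == 0 else image.values[index, :]
    return image.bin_centers(axis), vals.copy()
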