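"""Directional quadrature filters and local phase estimation.

Local image phase is probed with a bank of K complex band-pass filters, one
per direction n_k. Each filter lives on one half of frequency space
(n_k . u > 0, the quadrature property) with a log-normal radial profile

    R(rho) = exp(-4/ln 2 * ln^2(rho/rho0) / B^2)

peaking at the center frequency rho0 (radians/voxel) with bandwidth B
octaves, and a (n_k . u_hat)^2 angular profile. The argument of the filter
response is the local phase: it encodes the position of edge/line structure
independently of image contrast, which is what makes phase differences a
usable registration force across modalities.

For a fixed image f and moving image m the per-filter certainty is the
product of the response amplitudes, c_k(x) = A_f(x;k) A_m(x;k), and the
global certainty map is their sum over filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume

__all__ = [
    "QuadratureFilterBank",
    "build_filter_bank",
    "local_phase",
    "phase_certainty",
    "PhaseCertainty",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def _directions(dim: int) -> np.ndarray:
    if dim == 2:
        # 4 evenly spaced half-plane directions: 0, 45, 90, 135 degrees
        ang = np.deg2rad([0.0, 45.0, 90.0, 135.0])
        return np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if dim == 3:
        # 6 non-antipodal vertex directions of an icosahedron
        p = _GOLDEN
        raw = np.array(
            [
                [0, 1, p],
                [0, -1, p],
                [1, p, 0],
                [-1, p, 0],
                [p, 0, 1],
                [p, 0, -1],
            ],
            dtype=np.float64,
        )
        return raw / np.linalg.norm(raw, axis=1, keepdims=True)
    raise ValueError(f"dim must be 2 or 3, got {dim}")


@dataclass
class QuadratureFilterBank:
    """K directional complex band-pass filters probing local phase.

    Kernels are built lazily in the frequency domain for each lattice shape
    and cached; filtering is periodic (FFT) multiplication.
    """

    dim: int
    center_frequency: float = np.pi / 3
    bandwidth: float = 2.0
    directions: np.ndarray = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if not (0.0 < self.center_frequency < np.pi):
            raise ValueError(
                f"center frequency must lie in (0, pi) rad/voxel, got {self.center_frequency}"
            )
        if self.bandwidth <= 0:
            raise ValueError("bandwidth (octaves) must be positive")
        if self.directions is None:
            self.directions = _directions(self.dim)
        self.directions = np.asarray(self.directions, dtype=np.float64)

    @property
    def n_filters(self) -> int:
        return len(self.directions)

    def kernels(self, shape) -> np.ndarray:
        """Frequency-domain kernels for a lattice shape, (K, *shape) real array."""
        shape = tuple(int(s) for s in shape)
        if len(shape) != self.dim:
            raise ValueError(f"lattice is {len(shape)}D but bank is {self.dim}D")
        if shape not in self._cache:
            self._cache[shape] = self._build(shape)
        return self._cache[shape]

    def _build(self, shape):
        grids = np.meshgrid(
            *[2 * np.pi * np.fft.fftfreq(s) for s in shape], indexing="ij"
        )
        u = np.stack(grids)  # (dim, *shape), radians/voxel
        rho = np.sqrt(np.sum(u * u, axis=0))
        radial = np.zeros_like(rho)
        nz = rho > 0
        radial[nz] = np.exp(
            -4.0 / np.log(2.0) * np.log(rho[nz] / self.center_frequency) ** 2 / self.bandwidth**2
        )
        kernels = np.zeros((self.n_filters,) + shape)
        for k, n in enumerate(self.directions):
            proj = np.tensordot(n, u, axes=1)  # n . u
            ang = np.zeros_like(rho)
            ang[nz] = np.maximum(proj[nz] / rho[nz], 0.0) ** 2  # (n.u_hat)^2, half-space
            ang[proj <= 0] = 0.0
            kernels[k] = radial * ang
        return kernels


def build_filter_bank(dim: int, center_frequency: float = np.pi / 3, bandwidth: float = 2.0) -> QuadratureFilterBank:
    """Construct the standard direction set for 2D (K=4) or 3D (K=6)."""
    return QuadratureFilterBank(dim=dim, center_frequency=center_frequency, bandwidth=bandwidth)


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def local_phase(v, bank: QuadratureFilterBank) -> np.ndarray:
    """Complex filter responses q_k, shape (K, *lattice).

    amplitude = |q_k|, local phase = arg(q_k).
    """
    data = _as_array(v)
    kernels = bank.kernels(data.shape)
    spectrum = np.fft.fftn(data)
    return np.stack([np.fft.ifftn(spectrum * kern) for kern in kernels])


@dataclass
class PhaseCertainty:
    """Per-filter phase differences and certainties between two images.

    dphi[k] is wrapped to (-pi, pi]; ck[k] = amp_f[k] * amp_m[k] >= 0;
    theta_c = sum_k ck[k] is the global certainty map.
    """

    dphi: np.ndarray
    amp_f: np.ndarray
    amp_m: np.ndarray
    ck: np.ndarray
    theta_c: np.ndarray


def phase_certainty(f, m, bank: QuadratureFilterBank) -> PhaseCertainty:
    """Phase differences and certainty maps between fixed f and moving m."""
    fa, ma = _as_array(f), _as_array(m)
    if fa.shape != ma.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {ma.shape}")
    qf = local_phase(fa, bank)
    qm = local_phase(ma, bank)
    amp_f = np.abs(qf)
    amp_m = np.abs(qm)
    # arg(qf * conj(qm)) is already wrapped to (-pi, pi]
    dphi = np.angle(qf * np.conj(qm))
    ck = amp_f * amp_m
    return PhaseCertainty(dphi=dphi, amp_f=amp_f, amp_m=amp_m, ck=ck, theta_c=ck.sum(axis=0))
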