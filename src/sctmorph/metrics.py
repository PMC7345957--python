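"""Registration and synthesis quality metrics.

Mutual information is computed from a joint intensity histogram,

    MI(f; m) = sum p(f, m) log2[ p(f, m) / (p(f) p(m)) ]   (bits),

and the sum of local phase differences (SLPD) accumulates |sin(dphi_k)|
over all voxels and quadrature-filter directions. Lower SLPD / higher MI
indicate better alignment; MI is invariant to monotone intensity remaps (up
to binning) which makes it usable across modalities, while SLPD directly
measures residual structural dephasing. MAE and Pearson correlation
quantify intensity agreement of a synthetic CT against a reference CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quadrature import QuadratureFilterBank, build_filter_bank, phase_certainty
from .volume import Volume

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "mutual_information",
    "slpd",
    "mae",
    "pearson_cc",
]


def _arr(v) -> np.ndarray:
    a = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    return a.ravel()


@dataclass
class JointHistogram:
    """Joint intensity histogram with derived probabilities."""

    counts: np.ndarray
    edges_f: np.ndarray
    edges_m: np.ndarray

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def marginal_f(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_m(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def joint_histogram(f, m, n_bins: int = 64) -> JointHistogram:
    fa, ma = _arr(f), _arr(m)
    if fa.shape != ma.shape:
        raise ValueError("shape mismatch")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, ef, em = np.histogram2d(fa, ma, bins=n_bins)
    return JointHistogram(counts, ef, em)


def mutual_information(f, m, n_bins: int = 64) -> float:
    """MI in bits over equal-width bins spanning each image's range.

    Constant images occupy a single bin and give MI = 0.
    """
    h = joint_histogram(f, m, n_bins)
    p = h.joint
    pf = h.marginal_f[:, None]
    pm = h.marginal_m[None, :]
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pf * pm + 1e-300)[nz])))


def entropy(v, n_bins: int = 64) -> float:
    """Binned Shannon entropy in bits (equals MI(v, v))."""
    a = _arr(v)
    counts, _ = np.histogram(a, bins=n_bins)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def slpd(f, m, bank: QuadratureFilterBank | None = None) -> float:
    """Sum over voxels and filter directions of |sin(local phase difference)|.

    Summed, not averaged, so the value scales with image size; zero iff the
    two images dephase nowhere. |sin| keeps opposite-signed differences from
    cancelling, so lower always means better aligned.
    """
    fa = f.data if isinstance(f, Volume) else np.asarray(f, dtype=np.float64)
    ma = m.data if isinstance(m, Volume) else np.asarray(m, dtype=np.float64)
    if fa.shape != ma.shape:
        raise ValueError("shape mismatch")
    if bank is None:
        bank = build_filter_bank(fa.ndim)
    pc = phase_certainty(fa, ma, bank)
    return float(np.sum(np.abs(np.sin(pc.dphi))))


def mae(a, b) -> float:
    """Mean absolute error."""
    aa, ba = _arr(a), _arr(b)
    if aa.shape != ba.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(aa - ba)))


def pearson_cc(a, b) -> float:
    """Pearson correlation coefficient, in [-1, 1]."""
    aa, ba = _arr(a), _arr(b)
    if aa.shape != ba.shape:
        raise ValueError("shape mismatch")
    if aa.std() == 0 or ba.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant image")
    return float(np.corrcoef(aa, ba)[0, 1])
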