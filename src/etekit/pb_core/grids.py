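"""Nonuniform tensor-product grids for the finite-volume PB solvers."""
from __future__ import annotations

import numpy as np

__all__ = ["stretched", "axis_edges", "TensorGrid"]


def stretched(h0: float, hmax: float, ratio: float, start: float, end: float) -> np.ndarray:
    """Edge positions from ``start`` towards ``end`` with spacing growing
    geometrically from ``h0`` to at most ``hmax``."""
    if ratio <= 1.0:
        raise ValueError("stretch ratio must exceed 1")
    xs = [start]
    h = h0
    s = 1.0 if end >= start else -1.0
    while (end - xs[-1]) * s > 1e-12:
        xs.append(xs[-1] + s * h)
        h = min(h * ratio, hmax)
    xs[-1] = end
    return np.asarray(xs)


def axis_edges(fine_lo: float, fine_hi: float, h_fine: float,
               lo: float, hi: float, h_max: float, ratio: float = 1.18) -> np.ndarray:
    """Edges for one axis: uniform ``h_fine`` over [fine_lo, fine_hi], then
    geometric stretching out to the domain limits [lo, hi]."""
    nf = max(1, int(round((fine_hi - fine_lo) / h_fine)))
    core = np.linspace(fine_lo, fine_hi, nf + 1)
    left = stretched(h_fine, h_max, ratio, fine_lo, lo)[::-1]
    right = stretched(h_fine, h_max, ratio, fine_hi, hi)
    return np.concatenate([left[:-1], core, right[1:]])


class TensorGrid:
    """Cell-centred tensor-product grid in up to three dimensions.

    ``edges`` is a tuple of per-axis edge arrays; cell centres, widths and
    volumes follow. Used by the 2D and 3D solvers; the axisymmetric solver
    carries its own cylindrical volume weights.
    """

    def __init__(self, *edges: np.ndarray):
        self.edges = tuple(np.asarray(e, float) for e in edges)
        for e in self.edges:
            if len(e) < 3 or np.any(np.diff(e) <= 0):
                raise ValueError("each axis needs at least 2 strictly increasing cells")
        self.centers = tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)
        self.widths = tuple(np.diff(e) for e in self.edges)
        self.shape = tuple(len(c) for c in self.centers)
        self.ndim = len(self.edges)
        self.size = int(np.prod(self.shape))

    def cell_volumes(self) -> np.ndarray:
        """Cartesian cell volumes with singleton broadcasting over axes."""
        out = np.ones(self.shape)
        for ax, w in enumerate(self.widths):
            sh = [1] * self.ndim
            sh[ax] = -1
            out = out * w.reshape(sh)
        return out

    def meshgrid(self):
        return np.meshgrid(*self.centers, indexing="ij")
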