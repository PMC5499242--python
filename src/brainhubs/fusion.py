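"""Fusing streamline counts with fractional anisotropy.

Raw streamline counts (NoS) over-weight large regions because bigger
parcels intercept more tracts.  FA, a per-tract diffusion-directionality
index in (0, 1), is used as a correction factor: FA values on existing
edges are min-max normalized and the fused weight is the elementwise
product ``w_ij = NoS_ij * FA'_ij``.
"""

from __future__ import annotations

import numpy as np

from .matrices import (
    ConnectivityMatrix,
    DimensionError,
    EmptyNetworkError,
    IntegrityError,
    MatrixRole,
)

__all__ = ["normalize_fa", "fuse", "build_nosfa"]


def normalize_fa(fa: ConnectivityMatrix, mask: ConnectivityMatrix) -> ConnectivityMatrix:
    """Min-max normalize FA over the edges present in the NoS matrix.

    The minimum and maximum are taken over off-diagonal entries where
    ``mask > 0`` — structural zeros (absent edges) do not participate, so
    the normalization is not dragged to zero by missing connections.
    Entries on absent edges are set to 0.  If all edge FA values are equal
    the normalized value is 1 on every existing edge, so fusion degrades
    gracefully to the pure NoS network.
    """
    if not fa.same_regions(mask):
        raise DimensionError("FA and NoS matrices must share shape and region ids")
    edge = (mask.values > 0) & ~np.eye(fa.n, dtype=bool)
    if not edge.any():
        raise EmptyNetworkError("NoS mask has no positive off-diagonal entries")
    vals = fa.values[edge]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(fa.values)
    if hi == lo:
        out[edge] = 1.0
    else:
        out[edge] = (fa.values[edge] - lo) / (hi - lo)
    return fa.with_values(out, MatrixRole.FA_NORMALIZED)


def fuse(nos: ConnectivityMatrix, fa_norm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise product of NoS and normalized FA.

    The edge carrying the minimum FA normalizes to exactly 0 and therefore
    drops out of the fused network; this is the literal consequence of the
    product rule and is documented rather than patched.
    """
    if not nos.same_regions(fa_norm):
        raise DimensionError("NoS and normalized-FA matrices must share shape and region ids")
    if fa_norm.role is not MatrixRole.FA_NORMALIZED:
        raise IntegrityError("second operand must be a normalized FA matrix")
    fused = nos.values * fa_norm.values
    return nos.with_values(fused, MatrixRole.NOSFA)


def build_nosfa(nos: ConnectivityMatrix, fa: ConnectivityMatrix) -> ConnectivityMatrix:
    """Convenience pipeline: normalize FA against the NoS mask, then fuse."""
    return fuse(nos, normalize_fa(fa, nos))
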