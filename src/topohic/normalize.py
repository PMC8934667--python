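"""Bin masking and sequential component normalization (SCN).

SCN iteratively divides each row, then each column, of the contact matrix
by its marginal (L1 norm by default) until every unmasked row sum is within
``tol`` of 1, and finally symmetrizes by averaging with the transpose.
After normalization a bin's row reads as its contact-frequency
distribution over the genome (sums to ~1 with the L1 norm), which is what
the virtual-4C readout relies on.

The coverage mask is applied before balancing: bins whose marginal falls
below a fraction of the median nonzero marginal are excluded and their
rows/columns kept at zero.  The exact masking rule is a package policy
(explicit and logged), not a published one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contact_map import ContactMap

logger = logging.getLogger(__name__)


@dataclass
class MaskPolicy:
    """Which bins to exclude before normalization.

    min_coverage_fraction : float in [0, 1]
        Bins with marginal sum below this fraction of the median nonzero
        marginal are masked.
    explicit_bins : list of int, optional
        Bins to mask unconditionally.
    """

    min_coverage_fraction: float = 0.1
    explicit_bins: Optional[list] = None

    def __post_init__(self):
        if not 0.0 <= self.min_coverage_fraction <= 1.0:
            raise ValueError("min_coverage_fraction must be in [0, 1]")


def mask_sparse_bins(cmap: ContactMap, policy: Optional[MaskPolicy] = None) -> ContactMap:
    """Return a copy with under-covered bins masked and zeroed."""
    if policy is None:
        policy = MaskPolicy()
    out = cmap.copy()
    marginals = out.values.sum(axis=1)
    nonzero = marginals[(marginals > 0) & ~out.mask]
    threshold = (policy.min_coverage_fraction * float(np.median(nonzero))
                 if nonzero.size else np.inf)
    new_mask = out.mask | (marginals < threshold)
    if policy.explicit_bins:
        new_mask[np.asarray(policy.explicit_bins, dtype=int)] = True
    if new_mask.all():
        raise ValueError("matrix too sparse: all bins masked")
    n_new = int(new_mask.sum() - out.mask.sum())
    if n_new:
        logger.info("masking %d under-covered bin(s) (threshold %.4g)", n_new, threshold)
    out.mask = new_mask
    out.apply_mask()
    out.meta["mask_threshold"] = threshold
    return out


def scn_normalize(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 200,
                  norm: str = "l1") -> ContactMap:
    """Sequential component normalization of a raw, masked contact map.

    Alternates row and column division by the chosen component norm until
    the maximum deviation of unmasked row norms from 1 is below ``tol``,
    then symmetrizes with ``(M + M.T) / 2``.  With ``norm='l1'`` unmasked
    row sums end within ``2 * tol`` of 1; ``norm='l2'`` balances Euclidean
    row norms instead.
    """
    if norm not in ("l1", "l2"):
        raise ValueError("norm must be 'l1' or 'l2'")
    live = ~cmap.mask
    if live.sum() < 2:
        raise ValueError("need at least 2 unmasked bins")
    M = cmap.values.astype(float).copy()
    M[cmap.mask, :] = 0.0
    M[:, cmap.mask] = 0.0

    def _component(v, axis):
        if norm == "l1":
            return v.sum(axis=axis)
        return np.sqrt((v ** 2).sum(axis=axis))

    row_norm = _component(M, 1)
    if np.any(row_norm[live] == 0):
        bad = np.flatnonzero(live & (row_norm == 0))
        raise ValueError(f"unmasked bin(s) {bad.tolist()} have zero marginal; "
                         "re-mask before normalizing")
    residual = np.inf
    for _ in range(max_iter):
        row_norm = _component(M, 1)
        M[live, :] /= row_norm[live, None]
        col_norm = _component(M, 0)
        M[:, live] /= col_norm[None, live]
        residual = float(np.max(np.abs(_component(M, 1)[live] - 1.0)))
        if residual < tol:
            break
    else:
        raise RuntimeError(f"SCN did not converge in {max_iter} iterations "
                           f"(last residual {residual:.3g})")
    M = (M + M.T) / 2.0
    out = ContactMap(cmap.genome, cmap.bin_size, M, cmap.mask.copy(),
                     state="normalized", meta=dict(cmap.meta))
    out.meta.update({"scn_tol": tol, "scn_norm": norm})
    return out
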