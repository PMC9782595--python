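"""Effective connectivity from binarized activity via Transfer Entropy.

For every ordered ROI pair (I, J), the transfer entropy

    TE_{I->J} = sum p(j_next, j_past, i_past)
                * log2[ p(j_next | j_past, i_past) / p(j_next | j_past) ]

is estimated with a plug-in (histogram) estimator over binary words of
length ``markov_order`` (default 2).  With *instant feedback* (the
calcium-imaging convention, default on) the source word is shifted one
bin forward so that it includes the same bin as the predicted target
sample, compensating for the slow indicator blurring the causal lag.

Significance of each pair is judged against the joint distribution of all
TE values that share the pair's target column or source row:

    z = (TE_{I->J} - TE_joint) / sigma_joint,

and connections with z >= 1 (default) are accepted, yielding a directed,
unweighted effective network.  No surrogate shuffling is involved: the
pooled-null z-score alone separates synchronous pairs (large TE relative
to their row/column pool) from incidental ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calcium import EventRaster

__all__ = [
    "TEMatrix",
    "EffectiveNetwork",
    "transfer_entropy",
    "significance_scores",
    "threshold_connections",
    "infer_effective_network",
]


@dataclass
class TEMatrix:
    """Pairwise transfer entropies (bits), zero diagonal."""

    te: np.ndarray
    markov_order: int
    instant_feedback: bool
    bin_frames: int
    node_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.te = np.asarray(self.te, dtype=float)
        if self.node_ids is None:
            self.node_ids = np.arange(self.te.shape[0])


@dataclass
class EffectiveNetwork:
    """Directed unweighted network of significant TE connections."""

    adjacency: np.ndarray
    z: np.ndarray
    threshold: float
    node_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency).astype(np.int8)
        if self.node_ids is None:
            self.node_ids = np.arange(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def _word_codes(bits: np.ndarray, order: int) -> np.ndarray:
    """Integer codes of the sliding binary word ending at each frame.

    ``codes[:, t]`` encodes (b_t, b_{t-1}, ..., b_{t-order+1}) for
    t >= order-1; earlier columns are not meaningful and are trimmed by
    the caller.
    """
    n, T = bits.shape
    codes = np.zeros((n, T), dtype=np.int64)
    for k in range(order):
        codes[:, k:] += bits[:, : T - k].astype(np.int64) << k
    return codes


def _rebin(bits: np.ndarray, bin_frames: int) -> np.ndarray:
    if bin_frames == 1:
        return bits
    n, T = bits.shape
    T2 = T // bin_frames
    return (
        bits[:, : T2 * bin_frames].reshape(n, T2, bin_frames).max(axis=2)
    )


def transfer_entropy(
    raster: EventRaster,
    markov_order: int = 2,
    instant_feedback: bool = True,
    bin_frames: int = 1,
    live: np.ndarray | None = None,
) -> TEMatrix:
    """Plug-in transfer entropy between every ordered ROI pair.

    ``live`` restricts the computation to non-removed ROIs; excluded ROIs
    get zero rows/columns but keep their place in the matrix.  Negative
    estimates (a floating-point artifact of the plug-in form) are clipped
    at zero; a constant target train yields TE 0 by convention.
    """
    k = int(markov_order)
    if k < 1:
        raise ValueError("markov_order must be >= 1")
    bits = _rebin(raster.bits, bin_frames)
    n, T = bits.shape
    if n < 2:
        raise ValueError("transfer entropy needs at least 2 ROIs")
    if T < 4 ** (2 * k):
        warnings.warn(
            f"train of {T} bins is short for Markov order {k}; "
            "estimates will be strongly biased"
        )
    live_mask = np.ones(n, dtype=bool) if live is None else np.asarray(live)
    idx = np.flatnonzero(live_mask)

    codes = _word_codes(bits, k)
    # sample t predicts target bin t+1; valid t: word at t complete
    t0, t1 = k - 1, T - 1
    jnext = bits[:, t0 + 1 : t1 + 1].astype(np.int64)  # target next sample
    jpast = codes[:, t0:t1]  # target word ending at t
    # source word: ends at t+1 with instant feedback, at t without
    ipast = codes[:, t0 + 1 : t1 + 1] if instant_feedback else codes[:, t0:t1]

    nw = 1 << k  # number of distinct words
    nsamp = jnext.shape[1]
    te = np.zeros((n, n))
    # target-side code: jnext + 2 * jpast, in [0, 2 * nw)
    tgt_code = jnext + 2 * jpast
    for j in idx:
        if bits[j].min() == bits[j].max():
            continue  # degenerate target: TE = 0 by convention
        cj = tgt_code[j]
        # marginals over the target side only (shared across sources)
        n_ab = np.bincount(cj, minlength=2 * nw).astype(float)
        n_b = n_ab[::2] + n_ab[1::2]  # counts of jpast words
        for i in idx:
            if i == j:
                continue
            full = cj + (2 * nw) * ipast[i]
            n_abc = np.bincount(full, minlength=2 * nw * nw).astype(float)
            n_abc = n_abc.reshape(nw, 2 * nw)  # [source word, target code]
            n_bc = n_abc[:, ::2] + n_abc[:, 1::2]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (
                    n_abc.reshape(nw, nw, 2)
                    * n_b.reshape(1, nw, 1)
                    / (
                        n_bc.reshape(nw, nw, 1)
                        * n_ab.reshape(nw, 2).transpose(0, 1).reshape(1, nw, 2)
                    )
                )
                term = n_abc.reshape(nw, nw, 2) * np.log2(ratio)
            te[i, j] = np.nansum(term) / nsamp
    np.clip(te, 0.0, None, out=te)
    return TEMatrix(
        te=te,
        markov_order=k,
        instant_feedback=instant_feedback,
        bin_frames=bin_frames,
    )


def significance_scores(
    te: TEMatrix | np.ndarray,
    include_self: bool = True,
    live: np.ndarray | None = None,
) -> np.ndarray:
    """Joint-distribution z-score of every ordered pair's TE.

    The null sample for pair (I, J) pools all inputs to J (TE_{X->J},
    X != J) with all outputs of I (TE_{I->Y}, Y != I); the pair's own
    value belongs to both pools and is counted once (``include_self=False``
    drops it entirely).  z = (TE_{I->J} - mean) / sd of that pool; pairs
    whose pool has zero spread get z = 0.  Removed ROIs are excluded from
    every pool.
    """
    m = te.te if isinstance(te, TEMatrix) else np.asarray(te, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("TE matrix must be square")
    live_mask = np.ones(n, dtype=bool) if live is None else np.asarray(live)
    nl = int(live_mask.sum())
    if nl < 3:
        raise ValueError("z-scores need at least 3 live ROIs")

    w = m.copy()
    w[~live_mask, :] = 0.0
    w[:, ~live_mask] = 0.0
    np.fill_diagonal(w, 0.0)
    col_sum = w.sum(axis=0)  # sum over X of TE[X, J]
    row_sum = w.sum(axis=1)  # sum over Y of TE[I, Y]
    col_sq = (w**2).sum(axis=0)
    row_sq = (w**2).sum(axis=1)

    s = col_sum[None, :] + row_sum[:, None] - w
    ss = col_sq[None, :] + row_sq[:, None] - w**2
    cnt = 2 * (nl - 1) - 1
    if not include_self:
        s = s - w
        ss = ss - w**2
        cnt -= 1
    mean = s / cnt
    var = np.maximum(ss / cnt - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - mean) / sd
    z[sd == 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z[~live_mask, :] = 0.0
    z[:, ~live_mask] = 0.0
    return z


def threshold_connections(
    z: np.ndarray,
    z_min: float = 1.0,
    node_ids: np.ndarray | None = None,
) -> EffectiveNetwork:
    """Accept connections with z >= z_min into a directed binary network."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z matrix must be finite")
    adj = (z >= z_min).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return EffectiveNetwork(
        adjacency=adj, z=z, threshold=float(z_min), node_ids=node_ids
    )


def infer_effective_network(
    raster: EventRaster,
    markov_order: int = 2,
    instant_feedback: bool = True,
    bin_frames: int = 1,
    z_min: float = 1.0,
    live: np.ndarray | None = None,
    include_self: bool = True,
) -> EffectiveNetwork:
    """Full inference path: raster -> TE -> z-scores -> thresholding."""
    te = transfer_entropy(
        raster,
        markov_order=markov_order,
        instant_feedback=instant_feedback,
        bin_frames=bin_frames,
        live=live,
    )
    z = significance_scores(te, include_self=include_self, live=live)
    return threshold_connections(z, z_min=z_min, node_ids=te.node_ids)
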