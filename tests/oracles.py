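"""Independent brute-force oracles used to cross-check the estimators.

These deliberately avoid the code paths they validate: the peak oracle
is an exhaustive grid search with closed-form amplitudes, and the epoch
oracle enumerates window placements one by one.
"""

import numpy as np


def brute_force_epoch_count(n_samples: int, epoch_len: int, step: int) -> int:
    """Count window placements by walking starts until the window no
    longer fits."""
    count, start = 0, 0
    while start + epoch_len <= n_samples:
        count += 1
        start += step
    return count


def grid_search_peak_center(
    freqs: np.ndarray,
    ratio: np.ndarray,
    centers: np.ndarray | None = None,
    widths: np.ndarray | None = None,
) -> float:
    """Exhaustive least-squares Gaussian peak search on a flattened band.

    For every (center, width) pair on a fine grid the optimal nonnegative
    amplitude of ``1 + A exp(-(f-c)^2/(2w^2))`` has the closed form
    ``A* = max(0, sum(g (r-1)) / sum(g^2))``; the SSE surface is then
    evaluated exhaustively and the argmin center returned.
    """
    if centers is None:
        centers = np.arange(7.0, 13.0 + 1e-9, 0.01)
    if widths is None:
        widths = np.arange(0.2, 6.0 + 1e-9, 0.05)
    f = np.asarray(freqs, float)
    y = np.asarray(ratio, float) - 1.0
    # g: (n_centers, n_widths, n_freqs)
    g = np.exp(
        -((f[None, None, :] - centers[:, None, None]) ** 2)
        / (2.0 * widths[None, :, None] ** 2)
    )
    amp = np.clip((g * y).sum(-1) / (g * g).sum(-1), 0.0, None)
    sse = ((y[None, None, :] - amp[..., None] * g) ** 2).sum(-1)
    i, _ = np.unravel_index(np.argmin(sse), sse.shape)
    return float(centers[i])
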