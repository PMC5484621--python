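"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library code paths (and scipy.ndimage): the
normalization, Gaussian convolution, thresholding, and counting are written
out explicitly so they can disagree with the package if the package is
wrong.
"""

import numpy as np


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Discretized, normalized Gaussian taps truncated at 4 sigma."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return w / w.sum()


def convolve_symmetric_1d(row: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Explicit 1-D convolution with symmetric (edge-mirrored) padding."""
    r = (len(w) - 1) // 2
    padded = np.pad(row, r, mode="symmetric")
    out = np.empty_like(row, dtype=float)
    for i in range(len(row)):
        acc = 0.0
        for k in range(len(w)):
            acc += w[k] * padded[i + k]
        out[i] = acc
    return out


def smooth_2d(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing: rows along axis 0, then axis 1."""
    w = gaussian_kernel_1d(sigma)
    out = np.empty_like(img, dtype=float)
    for j in range(img.shape[1]):
        out[:, j] = convolve_symmetric_1d(img[:, j].astype(float), w)
    out2 = np.empty_like(out)
    for i in range(img.shape[0]):
        out2[i, :] = convolve_symmetric_1d(out[i, :], w)
    return out2


def brute_force_activity(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    roi_mask: np.ndarray,
    sigma: float = 1.0,
    threshold: float = 0.25,
) -> int:
    """Changed-pixel count by explicit normalization, convolution, threshold."""
    a = frame_a.astype(float)
    b = frame_b.astype(float)
    pair_mean = (a + b) / 2.0
    denom = pair_mean[roi_mask].mean()
    if denom <= 0:
        return 0
    diff = np.abs(b - a) / denom
    smooth = smooth_2d(diff, sigma) if sigma > 0 else diff
    count = 0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            if roi_mask[y, x] and smooth[y, x] > threshold:
                count += 1
    return count


def exact_rank_sum_p(a, b) -> float:
    """Two-sided rank-sum p-value by full enumeration of rank assignments."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    n_a = len(a)
    observed = ranks[:n_a].sum()
    all_idx = range(len(pooled))
    sums = [ranks[list(c)].sum() for c in combinations(all_idx, n_a)]
    sums = np.asarray(sums)
    mean = sums.mean()
    extreme = np.abs(sums - mean) >= abs(observed - mean) - 1e-12
    return float(extreme.mean())
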