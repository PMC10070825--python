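import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_region(rng, shape=(16, 16), max_pixels=50):
    """Random connected-ish nonempty region with at most max_pixels pixels."""
    n_seeds = int(rng.integers(1, 4))
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        r = int(rng.integers(1, shape[0] - 1))
        c = int(rng.integers(1, shape[1] - 1))
        rad = int(rng.integers(1, 4))
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2
    if mask.sum() > max_pixels:
        keep = np.flatnonzero(mask.ravel())[:max_pixels]
        new = np.zeros(mask.size, dtype=bool)
        new[keep] = True
        mask = new.reshape(shape)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


# ---------------------------------------------------------------------------
# independent brute-force oracles for the surface-distance metrics

def brute_surface(mask):
    """Region pixels with a 4-neighbor outside (border counts as outside)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def brute_directed_dists(src, dst, spacing=(1.0, 1.0)):
    """All-pairs nearest Euclidean distances from src pixels to dst pixels."""
    sp = np.asarray(spacing, dtype=float)
    a = np.argwhere(src) * sp
    b = np.argwhere(dst) * sp
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return np.sqrt(d2.min(axis=1))


def brute_hausdorff(a, b, spacing=(1.0, 1.0)):
    sa, sb = brute_surface(a), brute_surface(b)
    d_ab = brute_directed_dists(sa, sb, spacing)
    d_ba = brute_directed_dists(sb, sa, spacing)
    return max(d_ab.max(), d_ba.max())


def brute_assd(a, b, spacing=(1.0, 1.0)):
    sa, sb = brute_surface(a), brute_surface(b)
    d_ab = brute_directed_dists(sa, sb, spacing)
    d_ba = brute_directed_dists(sb, sa, spacing)
    return (d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size)


def brute_dice(a, b):
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
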