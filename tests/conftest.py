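"""Shared builders for synthetic scenes and traces used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

G1, G2 = 1.7, -0.712  # reference stable AR(2) calcium kernel
KERNEL_PEAK = 2.833557832  # max of its impulse response


def ar2_trace(spike_frames, T, g1=G1, g2=G2, amplitude=1.0):
    """Noiseless AR(2) calcium trace from unit spikes."""
    s = np.zeros(T)
    s[np.asarray(spike_frames, dtype=int)] = 1.0
    return amplitude * sps.lfilter([1.0], [1.0, -g1, -g2], s)


def refractory_spikes(rng, T, rate, refractory=12, edge=25):
    """Bernoulli spikes with a refractory interval and an end margin.

    The clustering stage cannot resolve events closer than ~2x its blur
    width, and a spike in the final frames has no observable transient, so
    recovery scenarios space spikes accordingly.
    """
    frames, last = [], -(10**9)
    for t in range(max(T - edge, 0)):
        if rng.random() < rate and t - last >= refractory:
            frames.append(t)
            last = t
    return np.array(frames, dtype=int)


def gaussian_spot_image(shape, centers, amplitude=50.0, sigma=2.0,
                        noise_sd=1.0, rng=None):
    """Frame with Gaussian spots on Gaussian background noise."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    img = np.zeros(shape, dtype=float)
    for r, c in centers:
        img += amplitude * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img += rng.normal(0, noise_sd, shape)
    return img


def two_soma_scene(T=700, H=80, W=80, sigma=2.5, seed=5):
    """Two somata inside one 25x25 ROI with interleaved calcium transients.

    The two cells fire alternately (with random jitter), so their traces are
    uncorrelated by construction and any correlation an extracted trace
    shows with the neighbour measures signal mixing, not chance overlap.
    Returns (green_stack, nucleus_pos_A, cal_A, cal_B, soma_A, soma_B).
    """
    rng = np.random.default_rng(seed)

    def cal(base_frames):
        frames = np.asarray(base_frames) + rng.integers(
            -8, 9, size=len(base_frames)
        )
        s = np.zeros(T)
        s[np.clip(frames, 0, T - 1)] = 1.0
        c = sps.lfilter([1.0], [1.0, -G1, -G2], s)
        return c / max(c.std(), 1e-12)

    # balanced firing pattern: the neighbour fires both inside and between
    # the tracked cell's transients, so the two unit-SD traces are
    # uncorrelated by construction and neighbour-correlation measures
    # signal mixing rather than chance overlap
    a_frames = np.array([80, 320, 560])
    cal_a = cal(a_frames)
    cal_b = cal(np.sort(np.concatenate([a_frames + 30, [200, 440, 680]])))
    pos_a = np.array([30.0, 30.0])
    soma_a = pos_a + np.array([3.0, 2.0])
    soma_b = np.array([30.0, 40.0])
    rr, cc = np.mgrid[0:H, 0:W]
    s2 = 2 * sigma * sigma
    ga = np.exp(-((rr - soma_a[0]) ** 2 + (cc - soma_a[1]) ** 2) / s2)
    gb = np.exp(-((rr - soma_b[0]) ** 2 + (cc - soma_b[1]) ** 2) / s2)
    green = (
        100.0
        + (20.0 + 60.0 * cal_a)[:, None, None] * ga[None]
        + (20.0 + 60.0 * cal_b)[:, None, None] * gb[None]
    )
    green += rng.normal(0, 2.0, green.shape)
    return green, pos_a, cal_a, cal_b, soma_a, soma_b


def brute_force_lap(cost, eta):
    """Exhaustive optimum of the assignment-with-non-link-cost problem."""
    import itertools

    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    best = eta * (n + m)  # empty matching
    for k in range(1, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                c = sum(cost[i, j] for i, j in zip(rows, cols))
                if not np.isfinite(c):
                    continue
                best = min(best, c + eta * (n - k) + eta * (m - k))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(0)
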