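"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import palate3d as p3


def flood_fill_labels(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Brute-force BFS connected-component labeling, independent of scipy."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nxt = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                q = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and mask[rr, cc] and labels[rr, cc] == 0):
                            labels[rr, cc] = nxt
                            q.append((rr, cc))
    return labels


def mean_filter_oracle(img: np.ndarray, window: int) -> np.ndarray:
    """Direct double-loop windowed mean with edge replication."""
    h = window // 2
    padded = np.pad(img, h, mode="edge")
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = padded[r:r + window, c:c + window].mean()
    return out


@pytest.fixture(scope="session")
def desk_spec():
    """Pre-elevation phantom at desk-test scale, default noise and jitter."""
    return p3.embryo_preset("pre-elevation", size_factor=0.25, seed=1)


@pytest.fixture(scope="session")
def desk_truth(desk_spec):
    return p3.build_truth(desk_spec)


@pytest.fixture(scope="session")
def desk_stack(desk_spec, desk_truth):
    return p3.render_stack(desk_truth, desk_spec)


@pytest.fixture(scope="session")
def desk_masks(desk_stack):
    return p3.segment_stack(desk_stack)


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless, jitter-free phantom: silhouettes recoverable exactly."""
    return p3.embryo_preset("pre-elevation", size_factor=0.25, seed=1,
                            noise_sd=0.0, jitter_sd=(0.0, 0.0))


@pytest.fixture(scope="session")
def clean_truth(clean_spec):
    return p3.build_truth(clean_spec)


@pytest.fixture(scope="session")
def clean_stack(clean_spec, clean_truth):
    return p3.render_stack(clean_truth, clean_spec)
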