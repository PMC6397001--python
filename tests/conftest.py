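"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


def flood_fill_components(pixels: np.ndarray) -> list[set[tuple[int, int]]]:
    """Independent 8-connected component oracle: breadth-first flood fill.

    Deliberately naive (pure-Python BFS) so it shares no code with the
    skimage-backed segmentation it checks.
    """
    pixels = np.asarray(pixels, dtype=bool)
    seen = np.zeros_like(pixels)
    comps = []
    nrow, ncol = pixels.shape
    for r0 in range(nrow):
        for c0 in range(ncol):
            if pixels[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < nrow and 0 <= cc < ncol and pixels[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                comps.append(comp)
    return comps


def brute_force_nnd(query_xy: np.ndarray, reference_xy: np.ndarray) -> np.ndarray:
    """O(n*m) all-pairs nearest-neighbour distance oracle."""
    q = np.atleast_2d(query_xy)
    r = np.atleast_2d(reference_xy)
    d = np.sqrt(((q[:, None, :] - r[None, :, :]) ** 2).sum(axis=2))
    return d.min(axis=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
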