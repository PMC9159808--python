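"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and kept independent of the code
paths it checks: subset enumeration uses itertools + BFS, CRC-32 is a
table-driven reimplementation, and regression baselines come from
closed-form least squares.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from holopls.hologram import HologramConfig, _build_parent_graph, _fragment_key_from_subset
from holopls.molecule_io import StandardizedMolecule


def naive_fragment_counts(mol: StandardizedMolecule, config: HologramConfig) -> Counter:
    """Per-key occurrence counts via exhaustive subset enumeration.

    Tries every vertex combination of each size in the window and keeps
    the connected ones (BFS check).  Shares only the keying function with
    the implementation under test — enumeration is fully independent.
    """
    parent = _build_parent_graph(mol, config.distinctions)
    n = parent.n
    counts: Counter = Counter()
    for k in range(config.min_atoms, config.max_atoms + 1):
        for subset in itertools.combinations(range(n), k):
            in_set = set(subset)
            seen = {subset[0]}
            stack = [subset[0]]
            while stack:
                v = stack.pop()
                for u in parent.adj[v]:
                    if u in in_set and u not in seen:
                        seen.add(u)
                        stack.append(u)
            if len(seen) == k:
                counts[_fragment_key_from_subset(list(subset), parent).key] += 1
    return counts


_CRC_TABLE = []
for _i in range(256):
    _c = _i
    for _ in range(8):
        _c = (_c >> 1) ^ 0xEDB88320 if _c & 1 else _c >> 1
    _CRC_TABLE.append(_c)


def crc32_oracle(data: bytes) -> int:
    """Table-driven CRC-32 (IEEE 802.3 polynomial, reflected)."""
    crc = 0xFFFFFFFF
    for byte in data:
        crc = (crc >> 8) ^ _CRC_TABLE[(crc ^ byte) & 0xFF]
    return crc ^ 0xFFFFFFFF


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form least-squares solution (no intercept; pre-centered data)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def greedy_maxmin_by_hand(distance: np.ndarray, first: int, n_select: int) -> list[int]:
    """Re-run greedy MaxMin from a precomputed distance matrix."""
    n = distance.shape[0]
    selected = [first]
    while len(selected) < n_select:
        best, best_d = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            d = min(distance[i][j] for j in selected)
            if d > best_d:
                best, best_d = i, d
        selected.append(best)
    return selected


def best_subset_r2(X: np.ndarray, y: np.ndarray, size: int) -> tuple[tuple[int, ...], float]:
    """Exhaustive best subset of a given size by R^2 (intercept included)."""
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    best, best_r2 = None, -np.inf
    for subset in itertools.combinations(range(p), size):
        A = np.column_stack([np.ones(n), X[:, subset]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ beta) ** 2))
        r2 = 1.0 - rss / tss
        if r2 > best_r2:
            best, best_r2 = subset, r2
    return best, best_r2
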