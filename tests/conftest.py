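"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (plain-Python dynamic programs and
exhaustive enumeration) so they stay independent of the library code paths
they are used to check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest


def naive_edit_distance(a: str, b: str) -> int:
    """Textbook unit-cost Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def naive_self_alignment(
    s: str, match: int, mismatch: int, gap: int
) -> np.ndarray:
    """Reference diagonal-free local alignment table, plain triple loop."""
    n = len(s)
    D = np.zeros((n + 1, n + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            sub = match if (s[i - 1] == s[j - 1] and s[i - 1] != "N") else mismatch
            D[i, j] = max(
                0,
                D[i - 1, j - 1] + sub,
                D[i - 1, j] + gap,
                D[i, j - 1] + gap,
            )
    return D


def brute_force_bottleneck(
    edges: Dict[Tuple[int, int], int],
    sizes: List[int],
    required: float,
) -> Optional[int]:
    """Best bottleneck over all simple cycles (length >= 2) covering more
    than ``required`` positions, by DFS enumeration anchored at each cycle's
    minimum node. Returns the bottleneck value or None."""
    adj: Dict[int, List[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    best: Optional[int] = None

    def dfs(start: int, node: int, visited: List[int], bottleneck: int) -> None:
        nonlocal best
        for nxt in adj.get(node, ()):  # only nodes >= start keep cycles unique
            if nxt == start and len(visited) >= 2:
                cov = sum(sizes[v] for v in visited)
                b = min(bottleneck, edges[(node, start)])
                if cov > required and (best is None or b > best):
                    best = b
            elif nxt > start and nxt not in visited:
                dfs(start, nxt, visited + [nxt], min(bottleneck, edges[(node, nxt)]))

    for start in range(len(sizes)):
        dfs(start, start, [start], 10**9)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
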