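"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: simplex projection +
projected gradient ascent for the sparse-attention mapping, brute-force
set reachability for ontology queries, and a direct confusion-counting
macro F1.
"""

from __future__ import annotations

import numpy as np


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, v.shape[1] + 1)
    rho = (u - css / ind > 0).sum(axis=1)
    theta = css[np.arange(len(v)), rho - 1] / rho
    return np.clip(v - theta[:, None], 0.0, None)


def entmax15_pga(z: np.ndarray, iters: int = 3000) -> np.ndarray:
    """Maximize p @ z + H_1.5(p) over the simplex by projected gradient
    ascent with a decaying step; H_1.5(p) = (4/3) sum_j (p_j - p_j^1.5)."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    p = np.full_like(z, 1.0 / z.shape[1])
    for k in range(iters):
        step = 0.1 / (1.0 + 0.02 * k)
        grad = z + 4.0 / 3.0 - 2.0 * np.sqrt(np.clip(p, 0.0, None))
        p = project_to_simplex(p + step * grad)
    return p


def reachable(edges: set[tuple[str, str]], start: str) -> set[str]:
    """All nodes reachable from ``start`` along child->parent edges."""
    out: set[str] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for child, parent in edges:
            if child == node and parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def macro_f1_exact(preds, truths) -> float:
    """Plain (non-hierarchical) macro F1 over classes present in truths."""
    classes = sorted(set(truths))
    f1s = []
    for c in classes:
        tp = sum(p == c and t == c for p, t in zip(preds, truths))
        fp = sum(p == c and t != c for p, t in zip(preds, truths))
        fn = sum(p != c and t == c for p, t in zip(preds, truths))
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(f1s))
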