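"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes the slow, explicit route — per-pixel
flood fill, Python-set pixel accounting, exhaustive pair counting, a
direct quadratic-programme solve — so that agreement with the package's
vectorised/analytic code is a meaningful check rather than a tautology.
"""

from collections import deque
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import minimize


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> List[Set[Tuple[int, int]]]:
    """Connected components of a binary mask by explicit BFS flood fill."""
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            comp = set()
            queue = deque([(y, x)])
            seen[y, x] = True
            while queue:
                cy, cx = queue.popleft()
                comp.add((cy, cx))
                for dy, dx in neigh:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(comp)
    return components


def box_pixels(x0: int, y0: int, x1: int, y1: int) -> Set[Tuple[int, int]]:
    return {(y, x) for y in range(y0, y1) for x in range(x0, x1)}


def match_oracle(
    gt_boxes: Sequence[Tuple[int, int, int, int]],
    det_boxes: Sequence[Tuple[int, int, int, int]],
    shape: Tuple[int, int],
    overlap_min: float = 0.2,
    mode: str = "strict",
    denominator: str = "gt",
) -> Dict[str, object]:
    """Set-based pixel accounting of the filled-box overlap protocol."""
    gt_sets = [box_pixels(*b) for b in gt_boxes]
    det_sets = [box_pixels(*b) for b in det_boxes]

    def qualifies(g: Set, d: Set) -> bool:
        inter = len(g & d)
        if inter == 0:
            return False
        if mode == "any_overlap":
            return True
        denom = len(g) if denominator == "gt" else min(len(g), len(d))
        return inter / denom > overlap_min

    found = [any(qualifies(g, d) for d in det_sets) for g in gt_sets]
    matched = [any(qualifies(g, d) for g in gt_sets) for d in det_sets]
    tp_set: Set = set()
    for g, f in zip(gt_sets, found):
        if f:
            tp_set |= g
    fn_set: Set = set()
    for g, f in zip(gt_sets, found):
        if not f:
            fn_set |= g
    fn_set -= tp_set
    fp_set: Set = set()
    for d, m in zip(det_sets, matched):
        if not m:
            fp_set |= d
    fp_set -= tp_set | fn_set
    total = shape[0] * shape[1]
    return {
        "tp": len(tp_set),
        "fp": len(fp_set),
        "fn": len(fn_set),
        "tn": total - len(tp_set) - len(fp_set) - len(fn_set),
        "found": found,
        "matched": matched,
    }


def auc_oracle(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the exhaustive positive-beats-negative pair probability."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def hard_margin_oracle(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    """Hard-margin separator by direct QP: min ||w||^2/2 s.t. y(w.x+b) >= 1.

    y is in {-1, +1}; the data must be linearly separable. Uses SLSQP
    from a least-squares warm start independent of any SVM library.
    """
    n, d = X.shape
    A = np.hstack([X, np.ones((n, 1))])
    wb0, *_ = np.linalg.lstsq(A, y.astype(float), rcond=None)
    margins = y * (A @ wb0)
    if margins.min() <= 0:
        raise ValueError("warm start is not separating; choose clearer test data")
    wb0 = wb0 / margins.min()  # feasible start

    def objective(wb):
        return 0.5 * float(wb[:d] @ wb[:d])

    constraints = [
        {"type": "ineq", "fun": (lambda wb, i=i: y[i] * (X[i] @ wb[:d] + wb[d]) - 1.0)}
        for i in range(n)
    ]
    res = minimize(objective, wb0, method="SLSQP", constraints=constraints,
                   options={"maxiter": 500, "ftol": 1e-12})
    if not res.success:
        raise RuntimeError(f"QP oracle failed: {res.message}")
    return res.x[:d], float(res.x[d])
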