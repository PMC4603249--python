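import numpy as np
import pytest

import scca


@pytest.fixture
def make_signal_pair():
    """Standardized paired views sharing a sparse latent factor."""

    def make(n=40, p1=30, p2=30, s1=5, s2=5, seed=0, **kw):
        X1, X2, truths = scca.generate_paired_views(
            n=n, p1=p1, p2=p2, s1=s1, s2=s2, seed=seed, **kw
        )
        return scca.standardize_columns(X1), scca.standardize_columns(X2), truths

    return make


@pytest.fixture
def make_null_pair():
    """Standardized independent views (no inter-view association)."""

    def make(n=40, p1=30, p2=30, seed=0):
        X1, X2 = scca.generate_null_views(n, p1, p2, seed=seed)
        return scca.standardize_columns(X1), scca.standardize_columns(X2)

    return make


def l1_project_bisection_oracle(a, s, nonnegative=False, tol=1e-10):
    """Independent scalar-bisection reference for the L1-sphere projection."""
    a = np.asarray(a, dtype=float)
    if nonnegative:
        a = np.maximum(a, 0.0)
    norm = np.linalg.norm(a)
    assert norm > 0
    w = a / norm
    if np.abs(w).sum() <= s + 1e-12:
        return w
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t = np.maximum(a - mid, 0.0) if nonnegative else (
            np.sign(a) * np.maximum(np.abs(a) - mid, 0.0)
        )
        n2 = np.linalg.norm(t)
        if n2 == 0:
            hi = mid
            continue
        ratio = np.abs(t).sum() / n2
        if abs(ratio - s) < tol:
            break
        if ratio > s:
            lo = mid
        else:
            hi = mid
    t = np.maximum(a - mid, 0.0) if nonnegative else (
        np.sign(a) * np.maximum(np.abs(a) - mid, 0.0)
    )
    return t / np.linalg.norm(t)
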