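"""Permutation p-values for the extracted canonical correlations.

Significance of the observed canonical correlation q_i of component i is
assessed by refitting the full m-component deflation pipeline on row-permuted
views (which destroys any true inter-view correspondence) and counting how
often the like-indexed permuted correlation reaches the observed one.  The
add-one form p = (#exceedances + 1) / (k + 1) is used so p is never exactly
zero and the test is valid at finite k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SparsityParams, ViewMatrix, fit_scca
from .selection import permute_views

__all__ = ["ComponentSignificance", "component_p_values", "p_value_from_null"]


@dataclass(frozen=True)
class ComponentSignificance:
    """One component's observed correlation and its permutation p-value."""

    index: int
    q_obs: float
    p_value: float
    k: int
    exceed_count: int


def p_value_from_null(q_obs: float, q_null: np.ndarray) -> tuple[float, int]:
    """One-sided (greater) permutation p-value with add-one correction.

    Returns ``(p, exceed_count)`` where ``exceed_count = #{q_null >= q_obs}``
    and ``p = (exceed_count + 1) / (k + 1)``; p is monotone non-increasing in
    ``q_obs`` and invariant to the order of the null values.
    """
    q_null = np.asarray(q_null, dtype=np.float64)
    k = q_null.size
    exceed = int(np.count_nonzero(q_null >= q_obs))
    return (exceed + 1) / (k + 1), exceed


def component_p_values(
    X1: ViewMatrix,
    X2: ViewMatrix,
    params: SparsityParams,
    m: int,
    k: int,
    seed: int,
    *,
    init_seed: int = 0,
) -> list[ComponentSignificance]:
    """Permutation p-values for the first ``m`` components at fixed
    (typically the selected) sparsity parameters.

    Each of the k replicates independently permutes the rows of both views
    and refits the full m-component deflation, so component i's null is the
    distribution of i-th extracted correlations under no inter-view
    association.  Replicates whose extraction stops early (degenerate
    deflated problem) contribute q = 0 for the missing components.  A
    degenerate *observed* component i is reported as p = 1, as are all
    components above it.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        observed, _ = fit_scca(X1, X2, params, n_components=m, init_seed=init_seed)
        q_obs = np.array(
            [c.q for c in observed] + [np.nan] * (m - len(observed))
        )
        valid = np.array(
            [not c.degenerate for c in observed] + [False] * (m - len(observed))
        )

        null = np.zeros((k, m))
        for j, child in enumerate(np.random.SeedSequence(seed).spawn(k)):
            rng = np.random.default_rng(child)
            X1p, X2p = permute_views(X1, X2, rng)
            perm_comps, _ = fit_scca(X1p, X2p, params, n_components=m,
                                     init_seed=init_seed)
            for i in range(min(m, len(perm_comps))):
                null[j, i] = perm_comps[i].q

    results: list[ComponentSignificance] = []
    for i in range(m):
        if valid[i]:
            p, exceed = p_value_from_null(float(q_obs[i]), null[:, i])
            results.append(
                ComponentSignificance(index=i + 1, q_obs=float(q_obs[i]),
                                      p_value=p, k=k, exceed_count=exceed)
            )
        else:
            results.append(
                ComponentSignificance(index=i + 1, q_obs=0.0, p_value=1.0,
                                      k=k, exceed_count=k)
            )
    return results


def significance_table(results: list[ComponentSignificance]) -> pd.DataFrame:
    """Tabular view (component, q, p_value, exceed_count, k)."""
    return pd.DataFrame(
        [(r.index, r.q_obs, r.p_value, r.exceed_count, r.k) for r in results],
        columns=["component", "q", "p_value", "exceed_count", "k"],
    )
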