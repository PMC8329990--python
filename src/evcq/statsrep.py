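"""Rank-based group comparisons and cross-method correlation.

Groups of per-replicate measurements (copy numbers, %GFP+, MFI, ...) are
compared with the Kruskal–Wallis H test (midranks, tie correction,
chi-square p with k-1 df) followed by Dunn's post-hoc z tests with
Bonferroni family-wise adjustment over all pairs — the Bonferroni-type rule
is the original Dunn (1964) procedure.  Cross-method agreement is assessed
by Pearson correlation of per-condition vectors normalized to the
untransfected control.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from evcq._errors import ConfigError, EvcqError

__all__ = [
    "kruskal_wallis",
    "kruskal_wallis_permutation_p",
    "dunn_posthoc",
    "normalize_to_control",
    "correlate_methods",
]


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ConfigError("need >= 2 groups")
    if any(g.size < 1 for g in gs):
        raise ConfigError("every group needs >= 1 observation")
    if sum(g.size for g in gs) < 3:
        raise ConfigError("need >= 3 total observations")
    return gs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p with k-1 df.

    All observations identical is a degenerate but valid input: H = 0, p = 1.
    """
    gs = _validate_groups(groups)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*gs)
    return float(h), float(p)


def kruskal_wallis_permutation_p(
    groups: Sequence[Sequence[float]], max_total: int = 10
) -> float:
    """Exact permutation p for the KW statistic by full enumeration.

    Enumerates every assignment of the pooled observations to the group
    sizes (multiset combinations) and reports the fraction with H >= the
    observed H.  Only feasible for tiny samples; guarded by ``max_total``.
    """
    gs = _validate_groups(groups)
    sizes = [g.size for g in gs]
    n = sum(sizes)
    if n > max_total:
        raise ConfigError(f"permutation enumeration limited to N <= {max_total}")
    pooled = np.concatenate(gs)
    h_obs, _ = kruskal_wallis(gs)
    count = 0
    total = 0
    idx = np.arange(n)
    for perm in itertools.permutations(idx):
        start = 0
        parts = []
        for s in sizes:
            parts.append(pooled[list(perm[start : start + s])])
            start += s
        h, _ = kruskal_wallis(parts)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's post-hoc z tests on pooled midranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with the
    tie term T = sum(t^3 - t) / (12(N-1)); two-sided normal p, multiplied by
    the number of pairs (capped at 1).  Returns (z matrix, adjusted-p matrix)
    as labelled DataFrames; z is antisymmetric.
    """
    gs = _validate_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ConfigError("labels length must match number of groups")
    sizes = np.array([g.size for g in gs])
    n = int(sizes.sum())
    pooled = np.concatenate(gs)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    mean_ranks = np.array(mean_ranks)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    z = np.zeros((k, k))
    p = np.ones((k, k))
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            denom = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if denom == 0:
                zij = 0.0
            else:
                zij = (mean_ranks[i] - mean_ranks[j]) / denom
            z[i, j] = zij
            p[i, j] = min(1.0, 2.0 * stats.norm.sf(abs(zij)) * m)
    zf = pd.DataFrame(z, index=labels, columns=labels)
    pf = pd.DataFrame(p, index=labels, columns=labels)
    return zf, pf


def normalize_to_control(
    values: Mapping[str, float], control_label: str
) -> tuple[dict[str, float], bool]:
    """Divide each condition value by the control value.

    Returns the normalized mapping (control maps to 1) and a flag that is
    True when the control value is negative (division proceeds, sign
    preserved, but the result needs scrutiny).
    """
    if control_label not in values:
        raise ConfigError(f"control condition {control_label!r} absent")
    ctrl = values[control_label]
    if ctrl == 0:
        raise EvcqError("zero control value: normalization undefined")
    return {k: v / ctrl for k, v in values.items()}, ctrl < 0


def correlate_methods(
    x: Mapping[str, float] | Sequence[float],
    y: Mapping[str, float] | Sequence[float],
) -> dict:
    """Pearson r and R^2 between two per-condition method vectors.

    Mappings are aligned on their shared condition labels; sequences must
    already be aligned.  Zero variance in either vector makes r undefined —
    reported as NaN with ``undefined=True``, never fabricated.
    """
    if isinstance(x, Mapping) and isinstance(y, Mapping):
        keys = sorted(set(x) & set(y))
        xv = np.array([x[k] for k in keys], dtype=float)
        yv = np.array([y[k] for k in keys], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ConfigError("method vectors must align")
    if xv.size < 3:
        raise ConfigError("need >= 3 aligned conditions")
    if np.std(xv) == 0 or np.std(yv) == 0:
        return {"r": float("nan"), "r2": float("nan"), "n": int(xv.size), "undefined": True}
    r, _ = stats.pearsonr(xv, yv)
    return {"r": float(r), "r2": float(r * r), "n": int(xv.size), "undefined": False}
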