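"""Brute-force oracle helpers for the acceptance script (independent of the package)."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd


def indicator(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def dense_nested_V(V_sire, V_dam, V_resid, sire_ids, dam_ids) -> np.ndarray:
    Zs = indicator(sire_ids)
    Zd = indicator([f"{s}|{d}" for s, d in zip(sire_ids, dam_ids)])
    n = Zs.shape[0]
    return V_sire * Zs @ Zs.T + V_dam * Zd @ Zd.T + V_resid * np.eye(n)


def dense_restricted_loglik(V: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, logdetV = np.linalg.slogdet(V)
    _, logdetI = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdetV + logdetI + float(y @ P @ y))


def kinship_A(parents: dict[str, tuple[str | None, str | None]]) -> dict[tuple[str, str], float]:
    depth: dict[str, int] = {}

    def get_depth(i: str) -> int:
        if i not in depth:
            s, d = parents.get(i, (None, None))
            depth[i] = 1 + max(
                get_depth(s) if s in parents else 0,
                get_depth(d) if d in parents else 0,
            )
        return depth[i]

    @lru_cache(maxsize=None)
    def phi(i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            s, d = parents.get(i, (None, None))
            return 0.5 * (1.0 + phi(s, d))
        if get_depth(i) < get_depth(j):
            i, j = j, i
        s, d = parents.get(i, (None, None))
        return 0.5 * (phi(s, j) + phi(d, j))

    ids = list(parents)
    return {(a, b): 2.0 * phi(a, b) for a in ids for b in ids}


def balanced_data(rng: np.random.Generator, s=40, d=3, k=4, vs=2.0, vd=1.0, ve=4.0):
    """Balanced nested Gaussian data with interior variance components."""
    y = (
        10.0
        + np.repeat(rng.normal(0, math.sqrt(vs), s), d * k)
        + np.repeat(rng.normal(0, math.sqrt(vd), s * d), k)
        + rng.normal(0, math.sqrt(ve), s * d * k)
    )
    sire_ids = np.repeat([f"s{i}" for i in range(s)], d * k)
    dam_ids = np.repeat([f"d{i}" for i in range(s * d)], k)
    return y, sire_ids, dam_ids
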