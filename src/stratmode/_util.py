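"""Shared helpers: RNG coercion and time-grid validation."""

from __future__ import annotations

import numpy as np

#: two time points closer than this (in Myr) are treated as duplicates
TIME_TOL = 1e-12


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    return np.random.default_rng(int(seed))


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one root seed."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(int(seed)).spawn(n)


def merge_time_grids(primary, extra, tol: float = 1e-9) -> np.ndarray:
    """Union of two time grids, dropping ``extra`` values within ``tol`` of a
    primary one so the primary times survive exactly."""
    p = np.asarray(primary, dtype=float)
    e = np.asarray(extra, dtype=float)
    if e.size == 0:
        return np.sort(p)
    idx = np.searchsorted(p, e)
    near_right = (idx < p.size) & (np.abs(p[np.minimum(idx, p.size - 1)] - e) <= tol)
    near_left = (idx > 0) & (np.abs(p[np.maximum(idx - 1, 0)] - e) <= tol)
    keep = e[~(near_right | near_left)]
    out = np.sort(np.concatenate([p, keep]))
    # collapse residual near-duplicates within the extras themselves
    if out.size > 1:
        out = np.concatenate([[out[0]], out[1:][np.diff(out) > tol]])
    return out


def validate_times(times, *, allow_zero_start: bool = True) -> np.ndarray:
    """Validate a strictly increasing, non-negative, finite time grid (Myr)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if t[0] < (0.0 if allow_zero_start else TIME_TOL):
        raise ValueError("times must be non-negative")
    if t.size > 1 and np.min(np.diff(t)) <= TIME_TOL:
        raise ValueError("times must be strictly increasing (no duplicates)")
    return t
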