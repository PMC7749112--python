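"""Compiled inner loops for the forward simulator.

Numerically identical numpy fallbacks are provided so the simulator works
(more slowly) without numba; equivalence of the two paths is covered by the
test suite.  All randomness stays outside these kernels.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _apply_crossovers_nb(haps, positions, out, fix_child, fix_rowb, bp_offsets, bp_values):
    s = positions.shape[0]
    for f in range(fix_child.shape[0]):
        child_row = fix_child[f]
        row_b = fix_rowb[f]
        lo = bp_offsets[f]
        hi = bp_offsets[f + 1]
        for j in range(s):
            count = 0
            for b in range(lo, hi):
                if bp_values[b] <= positions[j]:
                    count += 1
            if count % 2 == 1:
                out[child_row, j] = haps[row_b, j]


@njit(cache=True, fastmath=True)
def _fitness_nb(haps, eff_cols, eff_allele, eff_s, w):
    ne = w.shape[0]
    m = eff_cols.shape[0]
    for i in range(ne):
        acc = 1.0
        for t in range(m):
            col = eff_cols[t]
            cnt = (haps[2 * i, col] == eff_allele[t]) + (haps[2 * i + 1, col] == eff_allele[t])
            acc *= 1.0 + eff_s[t] * cnt * 0.5
        w[i] = max(acc, 0.0)


@njit(cache=True)
def _offspring_copy_nb(haps, src, out, s):
    for i in range(src.shape[0]):
        r = src[i]
        for j in range(s):
            out[i, j] = haps[r, j]


def offspring_copy(haps: np.ndarray, src: np.ndarray, out: np.ndarray) -> None:
    if HAVE_NUMBA:
        # element loop vectorises well and avoids numpy's gather temporary
        _offspring_copy_nb(haps, src, out, haps.shape[1])
    else:
        out[:, : haps.shape[1]] = haps[src]


def apply_crossovers(
    haps: np.ndarray,
    positions: np.ndarray,
    out: np.ndarray,
    fixups: list,
) -> None:
    """Overwrite crossover gametes in ``out`` columns [0, S) with the
    alternate parental haplotype wherever an odd number of breakpoints lies
    at or left of the site."""
    if not fixups:
        return
    if HAVE_NUMBA:
        fix_child = np.array([f[0] for f in fixups], dtype=np.int64)
        fix_rowb = np.array([f[2] for f in fixups], dtype=np.int64)
        lens = np.array([len(f[3]) for f in fixups], dtype=np.int64)
        bp_offsets = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        bp_values = (
            np.concatenate([f[3] for f in fixups]) if lens.sum() else np.empty(0)
        )
        _apply_crossovers_nb(
            haps, positions, out[:, : haps.shape[1]], fix_child, fix_rowb, bp_offsets, bp_values
        )
    else:
        s = haps.shape[1]
        for child_row, _row_a, row_b, bp in fixups:
            parity = (bp[:, None] <= positions[None, :]).sum(axis=0) % 2
            take_b = parity.astype(bool)
            out[child_row, :s] = np.where(take_b, haps[row_b], out[child_row, :s])


def fitness_multiplicative(
    haps: np.ndarray, eff_cols: np.ndarray, eff_allele: np.ndarray, eff_s: np.ndarray
) -> np.ndarray:
    """Multiplicative fitness with additive within-locus dominance (s/2)."""
    ne = haps.shape[0] // 2
    if eff_cols.size == 0:
        return np.ones(ne)
    if HAVE_NUMBA:
        w = np.empty(ne)
        _fitness_nb(haps, eff_cols.astype(np.int64), eff_allele, eff_s, w)
        return w
    sub = haps[:, eff_cols]
    count = (sub[0::2] == eff_allele).astype(np.int8)
    count += sub[1::2] == eff_allele
    w = np.prod(1.0 + eff_s * (count * 0.5), axis=1)
    return np.clip(w, 0.0, None)
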