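"""Brute-force sums-of-squares oracle for balanced mixed designs.

Written independently of the package engine: every SS comes from explicit
mean-deviation arithmetic on the data array — no design matrices, no
contrasts, no regression.  The pure effect deviations are obtained by
applying the centering operator (subtract the mean along an axis) once per
involved factor axis, which is the inclusion-exclusion decomposition of a
balanced factorial.  Valid for one between factor with EQUAL group sizes and
any number of fully-crossed within factors (where all SS types coincide),
which is all the equivalence tests need.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def _center(Y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Apply (I - mean) along each axis in turn: the pure-effect deviations."""
    out = np.asarray(Y, dtype=float)
    for ax in axes:
        out = out - out.mean(axis=ax, keepdims=True)
    return out


def brute_force_mixed_anova(Y: np.ndarray) -> dict[str, dict[str, float]]:
    """F tests for a balanced mixed design.

    ``Y`` has shape (a, n, k1, ..., km): ``a`` groups of ``n`` subjects each,
    m fully-crossed within factors.  Returns ``{effect: {ss, df_num, ss_err,
    df_den, F, p}}`` with the between factor named ``"A"``, within factors
    ``"W1"``... and interactions joined with `` x ``.
    """
    a, n = Y.shape[:2]
    m = Y.ndim - 2
    within_axes = tuple(range(2, 2 + m))
    p_within = int(np.prod(Y.shape[2:])) if m else 1

    results: dict[str, dict[str, float]] = {}

    subj_mean = Y.mean(axis=within_axes) if m else Y           # (a, n)
    group_mean = subj_mean.mean(axis=1)                        # (a,)
    ss_a = p_within * n * float(np.sum((group_mean - group_mean.mean()) ** 2))
    ss_subj = p_within * float(np.sum((subj_mean - group_mean[:, None]) ** 2))
    results["A"] = _pack(ss_a, a - 1, ss_subj, a * (n - 1))

    for r in range(1, m + 1):
        for waxes in itertools.combinations(within_axes, r):
            wname = " x ".join(f"W{ax - 1}" for ax in waxes)
            df_w = int(np.prod([Y.shape[ax] - 1 for ax in waxes]))
            other = tuple(ax for ax in within_axes if ax not in waxes)
            Yc = Y.mean(axis=other) if other else Y            # (a, n, *kept)
            kept = tuple(range(2, 2 + r))
            mult = p_within // int(np.prod([Y.shape[ax] for ax in waxes]))

            cell = Yc.mean(axis=(0, 1))                        # (*kept,)
            eff_w = _center(cell, tuple(range(cell.ndim)))
            ss_w = a * n * mult * float(np.sum(eff_w ** 2))

            gcell = Yc.mean(axis=1)                            # (a, *kept)
            eff_aw = _center(gcell, tuple(range(gcell.ndim)))
            ss_aw = n * mult * float(np.sum(eff_aw ** 2))

            subj_ie = _center(Yc, kept)                        # (a, n, *kept)
            group_ie = _center(gcell, tuple(range(1, gcell.ndim)))
            resid = subj_ie - group_ie[:, None]
            ss_err = mult * float(np.sum(resid ** 2))
            df_err = a * (n - 1) * df_w

            results[wname] = _pack(ss_w, df_w, ss_err, df_err)
            results[f"A x {wname}"] = _pack(ss_aw, (a - 1) * df_w, ss_err, df_err)
    return results


def _pack(ss, df_num, ss_err, df_den) -> dict[str, float]:
    F = (ss / df_num) / (ss_err / df_den)
    return {"ss": ss, "df_num": df_num, "ss_err": ss_err, "df_den": df_den,
            "F": F, "p": float(stats.f.sf(F, df_num, df_den))}
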