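"""Mixed-design ANOVA with Greenhouse-Geisser correction.

The engine implements the classical univariate approach to designs with one
or more between-subject factors (subjects nested in their between-group cell)
and one or more fully-crossed within-subject (repeated-measures) factors:

* Every within-subject effect is expressed through an orthonormal contrast
  matrix; subject-level contrast scores reduce the repeated measures to a
  between-subjects linear model per effect stratum.
* Sums of squares are Type III (model-comparison on an effect-coded design
  matrix), so unequal group sizes — e.g. 18 older vs 20 younger adults — are
  handled by unweighted-means logic for every effect.
* Each stratum containing a within effect uses its own error term
  (effect x subjects within groups); Greenhouse-Geisser epsilon is estimated
  from the pooled residual covariance of that stratum's contrast scores and
  applied to both numerator and denominator df.
* Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).

Degrees of freedom bookkeeping matches the standard closed forms: for a
design with N subjects in a between groups and a k-level within factor, the
within main effect has df = (k-1, (N-a)(k-1)) — e.g. (2, 72) for a 3-level
modality factor with 38 subjects in 2 age groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mixed_anova",
    "gg_epsilon",
    "simple_effects",
    "pairwise",
    "DesignError",
]


class DesignError(ValueError):
    """The long table is not a balanced complete design."""


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix, rows orthogonal to the unit vector."""
    if k < 2:
        return np.zeros((0, k))
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def gg_epsilon(contrast_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a (k-1)x(k-1) contrast-score covariance.

    epsilon = trace(S)^2 / (q * trace(S @ S)), clamped to [1/q, 1] where
    q = k - 1.  Identity covariance (sphericity) gives 1; a rank-one
    covariance (maximal violation) gives the lower bound 1/q.
    """
    S = np.asarray(contrast_cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("contrast covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("contrast covariance must be symmetric")
    q = S.shape[0]
    if q == 0:
        return 1.0
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0 / q
    eps = tr * tr / (q * tr2)
    return float(min(1.0, max(1.0 / q, eps)))


def _effect_code(levels: pd.Series, order: list) -> np.ndarray:
    """Sum-to-zero coding: n x (k-1) columns, last level coded -1."""
    k = len(order)
    idx = pd.Categorical(levels, categories=order).codes
    if np.any(idx < 0):
        raise DesignError("level outside declared order")
    X = np.zeros((len(levels), k - 1))
    for j in range(k - 1):
        X[idx == j, j] = 1.0
    X[idx == k - 1, :] = -1.0
    return X


def _type3_ss(Z: np.ndarray, X: np.ndarray, blocks: dict[tuple, slice]):
    """Type III SS per between-term on responses Z (n x q), plus residual SS.

    Returns ({term: SS}, residual_SS, residual_df, residuals).
    """
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    rss_full = float(np.sum(resid**2))
    ss = {}
    for term, sl in blocks.items():
        keep = np.ones(p, dtype=bool)
        keep[sl] = False
        Xr = X[:, keep]
        beta_r, _, _, _ = np.linalg.lstsq(Xr, Z, rcond=None)
        rss_r = float(np.sum((Z - Xr @ beta_r) ** 2))
        ss[term] = max(rss_r - rss_full, 0.0)
    return ss, rss_full, n - rank, resid


@dataclass
class _Design:
    subjects: pd.DataFrame          # one row per subject with between levels
    Y: np.ndarray                   # n_subjects x n_within_cells
    between: list[str]
    within: list[str]
    between_levels: dict[str, list]
    within_levels: dict[str, list]


def _prepare(table: pd.DataFrame, dv: str, subject: str,
             between: list[str], within: list[str]) -> _Design:
    for col in [dv, subject, *between, *within]:
        if col not in table.columns:
            raise DesignError(f"column {col!r} missing from table")
    if not np.all(np.isfinite(table[dv].to_numpy(dtype=float))):
        raise DesignError("dependent variable contains non-finite values")

    between_levels = {f: list(pd.unique(table[f])) for f in between}
    within_levels = {f: list(pd.unique(table[f])) for f in within}

    # subject-to-between consistency
    subj_between = table.groupby(subject, sort=False)[between].nunique() if between else None
    if between and (subj_between > 1).any().any():
        raise DesignError("a subject appears in more than one between-group cell")

    if within:
        pivot = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="count", fill_value=0)
        counts = pivot.to_numpy()
        if counts.shape[1] != int(np.prod([len(v) for v in within_levels.values()])):
            raise DesignError("missing within-subject cells")
        if not np.all(counts == 1):
            raise DesignError("unbalanced design: every subject needs exactly one value per within cell")
        wide = table.pivot_table(index=subject, columns=within, values=dv, sort=False)
        # reorder columns to the canonical within-level product order
        combos = list(itertools.product(*(within_levels[f] for f in within)))
        cols = [c if len(within) > 1 else c[0] for c in combos]
        wide = wide[cols]
    else:
        counts = table.groupby(subject, sort=False)[dv].count()
        if not np.all(counts == 1):
            raise DesignError("without within factors each subject needs exactly one value")
        wide = table.set_index(subject)[[dv]]

    subj_order = list(wide.index)
    if between:
        meta = table.drop_duplicates(subject).set_index(subject).loc[subj_order, between].reset_index()
    else:
        meta = pd.DataFrame({subject: subj_order})
    for f in between:
        if (meta.groupby(f).size() < 2).any():
            raise DesignError("each between-group cell needs at least 2 subjects")
    return _Design(meta, wide.to_numpy(dtype=float), between, within, between_levels, within_levels)


def _between_design(d: _Design):
    """Effect-coded design matrix over subjects with per-term column blocks."""
    n = len(d.subjects)
    cols = [np.ones((n, 1))]
    blocks: dict[tuple, slice] = {(): slice(0, 1)}
    start = 1
    factor_codes = {f: _effect_code(d.subjects[f], d.between_levels[f]) for f in d.between}
    for r in range(1, len(d.between) + 1):
        for term in itertools.combinations(d.between, r):
            mats = [factor_codes[f] for f in term]
            block = mats[0]
            for m in mats[1:]:
                block = np.einsum("ij,ik->ijk", block, m).reshape(n, -1)
            cols.append(block)
            blocks[term] = slice(start, start + block.shape[1])
            start += block.shape[1]
    return np.hstack(cols), blocks


def mixed_anova(table: pd.DataFrame, dv: str, subject: str,
                between: list[str] | None = None,
                within: list[str] | None = None) -> pd.DataFrame:
    """Full-factorial mixed ANOVA on a long-format table.

    Returns one row per effect with columns ``effect, df_num, df_den, F, p,
    eps_gg, p_gg, pes`` (pes = partial eta squared).  ``eps_gg`` is NaN for
    purely between-subject effects, exactly 1 for 2-level within strata, and
    the corrected p equals the uncorrected p in both cases.

    Raises :class:`DesignError` on missing cells, duplicated cells, or
    between-group cells with fewer than 2 subjects.
    """
    between = list(between or [])
    within = list(within or [])
    d = _prepare(table, dv, subject, between, within)
    X, blocks = _between_design(d)
    n = len(d.subjects)

    contrasts = {f: _orthonormal_contrasts(len(d.within_levels[f])) for f in within}
    means = {f: np.full((1, len(d.within_levels[f])), 1.0 / np.sqrt(len(d.within_levels[f])))
             for f in within}

    rows = []

    def add_row(name, df_num, df_den, ss_eff, ss_err, eps):
        if ss_err <= 0 or df_den <= 0:
            # degenerate stratum (zero error variance): report the limiting p
            # and flag F as undefined rather than infinite
            F = np.nan
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            F = (ss_eff / df_num) / (ss_err / df_den)
            p = float(stats.f.sf(F, df_num, df_den))
        if eps is None or np.isnan(eps):
            p_gg = p
        else:
            p_gg = float(stats.f.sf(F, eps * df_num, eps * df_den)) if np.isfinite(F) else p
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append({"effect": name, "df_num": df_num, "df_den": df_den, "F": float(F),
                     "p": p, "eps_gg": np.nan if eps is None else float(eps),
                     "p_gg": p_gg, "pes": float(pes)})

    # purely between-subject stratum: subject means across within cells
    if within:
        m_all = means[within[0]]
        for f in within[1:]:
            m_all = np.kron(m_all, means[f])
        Z0 = d.Y @ m_all.T
    else:
        Z0 = d.Y
    ss_b, rss_b, df_b, _ = _type3_ss(Z0, X, blocks)
    for term in blocks:
        if term == ():
            continue
        df_num = int(np.prod([len(d.between_levels[f]) - 1 for f in term]))
        add_row(" x ".join(term), df_num, df_b, ss_b[term], rss_b, None)

    # within strata: one per nonempty subset of within factors
    for r in range(1, len(within) + 1):
        for wsub in itertools.combinations(within, r):
            M = None
            for f in within:
                part = contrasts[f] if f in wsub else means[f]
                M = part if M is None else np.kron(M, part)
            q = M.shape[0]
            Z = d.Y @ M.T
            ss_w, rss_w, df_resid, resid = _type3_ss(Z, X, blocks)
            df_den = df_resid * q
            if q > 1 and df_resid > 0:
                S = resid.T @ resid / df_resid
                if np.trace(S @ S) <= 1e-300:
                    eps = 1.0 / q
                else:
                    eps = gg_epsilon(S)
            else:
                eps = 1.0
            for term, _sl in blocks.items():
                df_num = q * int(np.prod([len(d.between_levels[f]) - 1 for f in term])) if term else q
                name = " x ".join([*term, *wsub]) if term else " x ".join(wsub)
                add_row(name, df_num, df_den, ss_w[term], rss_w, eps)

    return pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "F", "p", "eps_gg", "p_gg", "pes"])


def simple_effects(table: pd.DataFrame, dv: str, subject: str, target: str,
                   conditioning: list[str],
                   between: list[str] | None = None,
                   within: list[str] | None = None) -> pd.DataFrame:
    """Effect of ``target`` at each combination of ``conditioning`` levels.

    Each sub-design is analyzed with its own error term by running
    :func:`mixed_anova` on the subset table (separate-error-term approach),
    so heterogeneity across conditioning cells cannot leak into the test.
    Returns the target-effect rows with the conditioning levels attached.
    """
    between = list(between or [])
    within = list(within or [])
    if target in conditioning:
        raise ValueError("target factor cannot also be a conditioning factor")
    if target not in between and target not in within:
        raise ValueError(f"target {target!r} is not a design factor")
    sub_between = [f for f in between if f not in conditioning]
    sub_within = [f for f in within if f not in conditioning]

    out = []
    level_sets = [list(pd.unique(table[f])) for f in conditioning]
    for combo in itertools.product(*level_sets):
        mask = np.ones(len(table), dtype=bool)
        for f, lev in zip(conditioning, combo):
            mask &= (table[f] == lev).to_numpy()
        sub = table.loc[mask]
        res = mixed_anova(sub, dv, subject, between=sub_between, within=sub_within)
        row = res.loc[res["effect"] == target].iloc[0].to_dict()
        for f, lev in zip(conditioning, combo):
            row[f] = lev
        out.append(row)
    cols = conditioning + ["effect", "df_num", "df_den", "F", "p", "eps_gg", "p_gg", "pes"]
    return pd.DataFrame(out)[cols]


def pairwise(table: pd.DataFrame, dv: str, subject: str, factor: str,
             paired: bool, correction: str | None = None) -> pd.DataFrame:
    """All pairwise comparisons between levels of ``factor``.

    ``paired=True`` runs paired t-tests on subject-matched cell means (the
    within-subject case); otherwise two-sample t-tests (between-subject).
    Uncorrected p by default; ``correction`` may be ``"bonferroni"`` or
    ``"holm"``.
    """
    levels = list(pd.unique(table[factor]))
    cell = table.groupby([subject, factor], sort=False)[dv].mean()
    rows = []
    for a, b in itertools.combinations(levels, 2):
        xa = cell.xs(a, level=factor)
        xb = cell.xs(b, level=factor)
        if paired:
            common = xa.index.intersection(xb.index)
            res = stats.ttest_rel(xa.loc[common], xb.loc[common])
            diff = float((xa.loc[common] - xb.loc[common]).mean())
        else:
            res = stats.ttest_ind(xa, xb)
            diff = float(xa.mean() - xb.mean())
        rows.append({"level_a": a, "level_b": b, "mean_diff": diff,
                     "t": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    if correction is not None:
        p = df["p"].to_numpy()
        m = len(p)
        if correction == "bonferroni":
            df["p_corr"] = np.minimum(p * m, 1.0)
        elif correction == "holm":
            order = np.argsort(p)
            adj = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * p[i])
                adj[i] = min(running, 1.0)
            df["p_corr"] = adj
        else:
            raise ValueError(f"unknown correction {correction!r}")
    return df
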