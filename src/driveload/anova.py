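"""Repeated-measures ANOVA with Greenhouse-Geisser correction, adjusted
partial eta squared, and the jackknife F rescaling.

One- and two-factor fully-within designs are supported.  Sums of squares
follow the standard within-subject partitioning (each effect tested against
its subject-by-effect interaction).  The Greenhouse-Geisser epsilon is the
covariance-based estimator computed from orthonormal contrasts of the
effect; corrected p-values evaluate F at (eps*df1, eps*df2).  Effect sizes
use the bias-adjusted partial eta squared

    adj eta_p^2 = df1 * (F - 1) / (df1 * F + df2),

which is zero at F = 1 (negative values are floored at zero) and tends to
one as F grows.  Component values measured on leave-one-subject-out grand
averages yield F statistics inflated by (n-1)^2; dividing restores the
conventional scale, exactly for window means and approximately for peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnovaResult


def _check(data: np.ndarray, n_factors: int):
    data = np.asarray(data, dtype=float)
    if data.ndim != n_factors + 1:
        raise ValueError(f"expected subjects x {n_factors} factor axes")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(data).any():
        raise ValueError("design is incomplete (missing cells)")
    return data


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the complement of the constant."""
    h = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(h)
    return u[:, :k - 1].T


def _gg_epsilon(cell_data: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance.

    ``cell_data`` is subjects x cells, ``C`` the effect's orthonormal
    contrast matrix (df x cells).
    """
    df = C.shape[0]
    if df <= 1:
        return 1.0
    S = np.cov(cell_data, rowvar=False)
    M = C @ S @ C.T
    tr = np.trace(M)
    denom = df * np.sum(M * M)
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / df)))


def _result(effect, ss_eff, ss_err, df1, df2, eps, jackknife, n_subjects):
    F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else (
        0.0 if ss_eff == 0 else np.inf)
    if jackknife:
        F = jackknife_f_correction(F, n_subjects)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    return AnovaResult(effect=effect, F=float(F), df_effect=float(df1),
                       df_error=float(df2), epsilon_gg=float(eps),
                       p_uncorrected=p, p_gg=p_gg,
                       adj_eta_p2=adjusted_partial_eta_squared(F, df1, df2),
                       jackknife_corrected=jackknife)


def rm_anova(data: np.ndarray, factor_names=None,
             jackknife: bool = False) -> list[AnovaResult]:
    """Fully-within repeated-measures ANOVA.

    ``data`` is ``subjects x k`` for one factor or ``subjects x a x b`` for
    two.  With ``jackknife=True`` the input values are leave-one-subject-out
    measures and every F is divided by (n-1)^2.  Returns one
    :class:`AnovaResult` per effect (main effects and, for two factors, the
    interaction).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = _check(data, 1)
        names = factor_names or ("factor",)
        return [_one_way(data, names[0], jackknife)]
    data = _check(data, 2)
    names = factor_names or ("A", "B")
    return _two_way(data, names, jackknife)


def _one_way(data, name, jackknife=False):
    n, k = data.shape
    grand = data.mean()
    cond = data.mean(axis=0)
    subj = data.mean(axis=1)
    ss_eff = n * np.sum((cond - grand) ** 2)
    resid = data - cond[None, :] - subj[:, None] + grand
    ss_err = np.sum(resid ** 2)
    eps = _gg_epsilon(data, _orthonormal_contrast(k))
    return _result(name, ss_eff, ss_err, k - 1, (n - 1) * (k - 1), eps,
                   jackknife, n)


def _two_way(data, names, jackknife=False):
    n, a, b = data.shape
    grand = data.mean()
    A = data.mean(axis=(0, 2))
    B = data.mean(axis=(0, 1))
    AB = data.mean(axis=0)
    S = data.mean(axis=(1, 2))
    SA = data.mean(axis=2)
    SB = data.mean(axis=1)

    ss_a = n * b * np.sum((A - grand) ** 2)
    ss_b = n * a * np.sum((B - grand) ** 2)
    ss_ab = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    ss_sa = b * np.sum((SA - S[:, None] - A[None, :] + grand) ** 2)
    ss_sb = a * np.sum((SB - S[:, None] - B[None, :] + grand) ** 2)
    resid = (data - SA[:, :, None] - SB[:, None, :] - AB[None, :, :]
             + S[:, None, None] + A[None, :, None] + B[None, None, :] - grand)
    ss_sab = np.sum(resid ** 2)

    Qa = _orthonormal_contrast(a)
    Qb = _orthonormal_contrast(b)
    ones_a = np.full((1, a), 1 / np.sqrt(a))
    ones_b = np.full((1, b), 1 / np.sqrt(b))
    cells = data.reshape(n, a * b)
    eps_a = _gg_epsilon(cells, np.kron(Qa, ones_b))
    eps_b = _gg_epsilon(cells, np.kron(ones_a, Qb))
    eps_ab = _gg_epsilon(cells, np.kron(Qa, Qb))

    return [
        _result(names[0], ss_a, ss_sa, a - 1, (n - 1) * (a - 1), eps_a,
                jackknife, n),
        _result(names[1], ss_b, ss_sb, b - 1, (n - 1) * (b - 1), eps_b,
                jackknife, n),
        _result(f"{names[0]} x {names[1]}", ss_ab, ss_sab,
                (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1), eps_ab,
                jackknife, n),
    ]


def rm_anova_frame(df: pd.DataFrame, dv: str, within, subject: str,
                   jackknife: bool = False) -> list[AnovaResult]:
    """Long-format wrapper: pivots to a complete subjects x cells array."""
    within = [within] if isinstance(within, str) else list(within)
    wide = df.pivot_table(index=subject, columns=within, values=dv,
                          observed=True)
    if wide.isna().any().any():
        raise ValueError("design is incomplete (missing cells)")
    if len(within) == 1:
        return rm_anova(wide.to_numpy(), tuple(within), jackknife)
    a = wide.columns.get_level_values(0).unique()
    b = wide.columns.get_level_values(1).unique()
    arr = wide.to_numpy().reshape(len(wide), len(a), len(b))
    return rm_anova(arr, tuple(within), jackknife)


def adjusted_partial_eta_squared(F: float, df_effect: float,
                                 df_error: float) -> float:
    """Bias-adjusted partial eta squared, floored at zero."""
    if df_effect <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not np.isfinite(F):
        return 1.0
    raw = df_effect * (F - 1.0) / (df_effect * F + df_error)
    return float(max(0.0, raw))


def jackknife_f_correction(F_jk: float, n_subjects: int) -> float:
    """Rescale an F computed from leave-one-out values: F / (n-1)^2."""
    if n_subjects < 3:
        raise ValueError("jackknife correction needs at least 3 subjects")
    return F_jk / (n_subjects - 1) ** 2


def simple_effects(data: np.ndarray, by_axis: int = 2,
                   factor_name: str = "A", level_names=None,
                   jackknife: bool = False) -> list[AnovaResult]:
    """One-factor ANOVAs of ``subjects x a x b`` within each level of the
    other factor (``by_axis`` selects which axis to condition on)."""
    data = _check(np.asarray(data, dtype=float), 2)
    if by_axis not in (1, 2):
        raise ValueError("by_axis must be 1 or 2")
    k = data.shape[by_axis]
    out = []
    for lvl in range(k):
        sub = data[:, lvl, :] if by_axis == 1 else data[:, :, lvl]
        name = (level_names[lvl] if level_names is not None else f"level{lvl}")
        res = _one_way(sub, f"{factor_name} | {name}", jackknife)
        out.append(res)
    return out


def results_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabular view mirroring the conventional reporting style."""
    return pd.DataFrame([{
        "effect": r.effect, "F": r.F, "df_effect": r.df_effect,
        "df_error": r.df_error, "epsilon_gg": r.epsilon_gg,
        "p": r.p_uncorrected, "p_gg": r.p_gg, "adj_eta_p2": r.adj_eta_p2,
        "jackknife": r.jackknife_corrected,
    } for r in results])
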