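"""Per-array EWAS of a binary trait and cross-array concordance.

Each probe's beta is regressed (ordinary least squares) on the trait plus
covariates; the trait coefficient is the group difference in mean
methylation (delta beta), tested against the t distribution with the
residual degrees of freedom, with Benjamini–Hochberg FDR across probes
within each array.  Concordance across arrays is then summarized three
ways: the Venn overlap of significant probes at an FDR and a stringent
p-value threshold, the Pearson correlation of effect estimates, and the
count of probes whose direction of effect flips between arrays.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_bias import adjust_fdr

__all__ = [
    "fit_ewas",
    "cross_array_overlap",
    "compare_effects",
]


def _check_collinear(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = []
        for j in range(1, X.shape[1]):          # skip intercept
            others = np.delete(X, j, axis=1)
            coef, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ coef
            denom = np.var(X[:, j])
            if denom == 0 or np.sum(resid ** 2) / (denom * len(resid)) < 1e-10:
                offending.append(names[j])
        raise ValueError(f"collinear design columns: {offending or names[1:]}")


def fit_ewas(beta: pd.DataFrame, trait: pd.Series,
             covariates: pd.DataFrame | None = None,
             group_levels: Sequence | None = None) -> pd.DataFrame:
    """Per-probe OLS of beta (probes x samples) on a binary trait + covariates.

    The effect is the trait coefficient with sign convention
    ``mean(group 1) - mean(group 0)``; ``group_levels = (level0, level1)``
    fixes the coding explicitly (default: sorted levels).  Returns a table
    with effect, se, t_stat, p_value, q_value and n_used per probe.
    """
    samples = beta.columns
    trait = trait.reindex(samples)
    if trait.isna().any():
        raise ValueError("trait has missing values for some samples")
    levels = list(group_levels) if group_levels is not None \
        else sorted(trait.unique())
    if len(levels) != 2:
        raise ValueError(f"trait must be binary; levels found: {levels}")
    t_num = trait.map({levels[0]: 0.0, levels[1]: 1.0})
    if t_num.isna().any():
        raise ValueError("trait contains values outside the declared levels")

    cols = [np.ones(len(samples)), t_num.to_numpy(float)]
    names = ["intercept", "trait"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.reindex(samples)
        if cov.isna().any().any():
            raise ValueError("covariates have missing values")
        for c in cov.columns:
            col = cov[c]
            if not np.issubdtype(col.dtype, np.number):
                lv = sorted(col.unique())
                if len(lv) != 2:
                    raise ValueError(
                        f"non-numeric covariate {c!r} must be binary")
                col = col.map({lv[0]: 0.0, lv[1]: 1.0})
            cols.append(col.to_numpy(float))
            names.append(str(c))
    X = np.column_stack(cols)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than parameters ({k})")
    _check_collinear(X, names)

    B = beta.to_numpy(float)                        # probes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = B @ X @ xtx_inv.T                       # probes x k
    resid = B - coefs @ X.T
    df_resid = n - k
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    effect = coefs[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = effect / se
    p = 2.0 * stats.t.sf(np.abs(np.nan_to_num(t_stat)), df_resid)
    # zero residual variance: a constant probe carries no evidence (p = 1);
    # an exactly-fit nonzero effect is overwhelming evidence
    zero_se = se == 0
    p[zero_se & (effect == 0)] = 1.0
    p[zero_se & (effect != 0)] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({
        "effect": effect, "se": se, "t_stat": t_stat, "p_value": p,
        "n_used": n,
    }, index=beta.index)
    out["q_value"] = adjust_fdr(out["p_value"].to_numpy())
    return out


def cross_array_overlap(results: Mapping[str, pd.DataFrame],
                        q_thresh: float = 0.05,
                        p_thresh: float = 1e-8) -> dict:
    """Venn overlap of significant probes across arrays at two thresholds.

    Probes are restricted to the intersection of the result tables.  For
    each threshold the report carries per-membership-pattern counts and
    the fraction "stable across all arrays" = (significant on every
    array) / (significant on at least one array), as a percentage.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need >= 2 result tables")
    shared = results[names[0]].index
    for n in names[1:]:
        shared = shared.intersection(results[n].index)
    if len(shared) == 0:
        raise ValueError("result tables share no probes")
    report = {"arrays": names, "n_probes": len(shared),
              "denominator": "union of probes significant on >= 1 array"}
    for label, col, thr in (("fdr", "q_value", q_thresh),
                            ("pval", "p_value", p_thresh)):
        sig = {n: set(shared[results[n].loc[shared, col] < thr]) for n in names}
        union = set().union(*sig.values())
        inter = set.intersection(*sig.values()) if union else set()
        counts = {}
        for pid in union:
            member = tuple(sorted(n for n in names if pid in sig[n]))
            counts[member] = counts.get(member, 0) + 1
        report[label] = {
            "threshold": thr,
            "per_array_counts": {n: len(sig[n]) for n in names},
            "venn_counts": {"+".join(k): v for k, v in counts.items()},
            "n_union": len(union),
            "n_shared_all": len(inter),
            "pct_stable": 100.0 * len(inter) / len(union) if union else float("nan"),
        }
    return report


def compare_effects(res_a: pd.DataFrame, res_b: pd.DataFrame,
                    sig_probes: Sequence) -> dict:
    """Effect-size concordance between two arrays over selected probes.

    Returns the Pearson correlation of effects over ``sig_probes`` (NaN if
    either side is constant), the probes whose effect signs differ, and
    the discordant fraction as a percentage.  Zero effects cannot flip
    sign and are excluded from discordance counting.
    """
    probes = pd.Index(sig_probes)
    probes = probes[probes.isin(res_a.index) & probes.isin(res_b.index)]
    if len(probes) < 3:
        raise ValueError(f"need >= 3 shared probes, got {len(probes)}")
    ea = res_a.loc[probes, "effect"].to_numpy(float)
    eb = res_b.loc[probes, "effect"].to_numpy(float)
    if np.ptp(ea) == 0 or np.ptp(eb) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(ea, eb)[0, 1])
    nonzero = (ea != 0) & (eb != 0)
    disc_mask = nonzero & (np.sign(ea) != np.sign(eb))
    discordant = list(probes[disc_mask])
    n_eval = int(nonzero.sum())
    return {
        "pearson_r": r,
        "n_probes": len(probes),
        "discordant": discordant,
        "discordant_count": len(discordant),
        "discordant_pct": 100.0 * len(discordant) / n_eval if n_eval else float("nan"),
    }
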