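"""Per-probe reliability from technical replicates.

A probe is useful for population studies only when (a) duplicate
measurements of the same DNA agree — quantified by the one-way
random-effects intraclass correlation, ICC(1) — and (b) people actually
differ at the locus — quantified by the interquartile range of betas
across unrelated samples.  The joint "informative" criterion is
ICC > 0.5 and IQR > 0.01 (a 1% spread in methylation between the 25th and
75th percentiles), both strict.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_icc",
    "icc_matrix",
    "compute_iqr",
    "classify_informative",
    "reliability_table",
    "informative_gain",
]


def _icc_from_ss(values: np.ndarray) -> np.ndarray:
    """ICC(1) per probe from a (probes, subjects, k) array."""
    n, k = values.shape[1], values.shape[2]
    subj_mean = values.mean(axis=2)                       # (p, n)
    grand = values.mean(axis=(1, 2), keepdims=True)       # (p, 1, 1)
    ssb = k * ((subj_mean - grand[:, :, 0]) ** 2).sum(axis=1)
    ssw = ((values - subj_mean[:, :, None]) ** 2).sum(axis=(1, 2))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msb - msw) / denom
    icc[denom == 0] = np.nan
    return icc


def compute_icc(values) -> float:
    """One-way random-effects ICC(1) from a subjects x replicates matrix.

    ``ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW)`` where MSB/MSW are the
    between- and within-subject mean squares of the one-way ANOVA
    decomposition.  The value is returned unclipped (it can be negative);
    it is NaN when the denominator is zero.  Requires a balanced design:
    at least 2 subjects, each with the same number k >= 2 of replicates.
    """
    if isinstance(values, (list, tuple)):
        lens = {len(v) for v in values}
        if len(lens) > 1:
            raise ValueError("unequal replicate counts; ICC(1) requires a "
                             "balanced design")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subjects x replicates matrix")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 subjects with >= 2 replicates each")
    if np.isnan(arr).any():
        raise ValueError("missing replicate values; ICC(1) requires a "
                         "balanced design")
    return float(_icc_from_ss(arr[None, :, :])[0])


def icc_matrix(values: np.ndarray, probe_ids: Sequence | None = None) -> pd.Series:
    """Vectorized ICC(1) over a (probes, subjects, replicates) array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 3 or arr.shape[1] < 2 or arr.shape[2] < 2:
        raise ValueError("expected (probes, >=2 subjects, >=2 replicates)")
    icc = _icc_from_ss(arr)
    return pd.Series(icc, index=probe_ids, name="icc")


def compute_iqr(betas) -> float:
    """Interquartile range Q3 - Q1 with type-7 (linear) interpolation.

    Returns NaN when fewer than 4 non-missing values are available.
    """
    arr = np.asarray(betas, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        return float("nan")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return float(q3 - q1)


def classify_informative(table: pd.DataFrame, icc_thresh: float = 0.5,
                         iqr_thresh: float = 0.01) -> pd.DataFrame:
    """Set the informative flag: ICC > icc_thresh AND IQR > iqr_thresh (strict)."""
    out = table.copy()
    out["informative"] = (out["icc"] > icc_thresh) & (out["iqr"] > iqr_thresh)
    return out


def informative_gain(count_new: int, count_old: int) -> int:
    """Net change in informative-probe count between two arrays."""
    return int(count_new) - int(count_old)


def reliability_table(beta: pd.DataFrame, samples: pd.DataFrame,
                      icc_thresh: float = 0.5, iqr_thresh: float = 0.01
                      ) -> pd.DataFrame:
    """Per-probe ICC, IQR and informative flag for one array.

    ``samples`` must carry ``position_id``, ``donor_id`` and
    ``is_replicate`` columns.  ICC uses the donors measured more than once
    (each donor contributes its full, balanced set of replicate
    measurements); IQR uses each donor's primary (non-replicate) sample.
    """
    samples = samples.set_index("position_id") if "position_id" in samples.columns \
        else samples
    counts = samples["donor_id"].value_counts()
    rep_donors = counts[counts > 1]
    if rep_donors.nunique() > 1:
        raise ValueError("replicated donors have unequal replicate counts; "
                         "ICC(1) requires a balanced design")
    if len(rep_donors) >= 2:
        k = int(rep_donors.iloc[0])
        cube = np.empty((len(beta), len(rep_donors), k))
        for si, donor in enumerate(rep_donors.index):
            cols = samples.index[samples["donor_id"] == donor]
            cube[:, si, :] = beta[list(cols)].to_numpy()
        icc = icc_matrix(cube, probe_ids=beta.index)
    else:
        icc = pd.Series(np.nan, index=beta.index, name="icc")

    primary = samples.index[~samples["is_replicate"].astype(bool)]
    vals = beta[list(primary)].to_numpy()
    enough = (~np.isnan(vals)).sum(axis=1) >= 4
    iqr = np.full(len(beta), np.nan)
    if enough.any():
        q1, q3 = np.nanpercentile(vals[enough], [25, 75], axis=1, method="linear")
        iqr[enough] = q3 - q1
    table = pd.DataFrame({
        "icc": icc.to_numpy(),
        "iqr": iqr,
        "n_subjects": len(rep_donors),
        "n_reps": int(rep_donors.iloc[0]) if len(rep_donors) else 0,
    }, index=beta.index)
    return classify_informative(table, icc_thresh, iqr_thresh)
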