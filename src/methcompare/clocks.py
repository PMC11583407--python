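"""Generic linear epigenetic-clock engine.

An epigenetic clock is a linear predictor of chronological age (or of an
aging pace) over CpG beta values, optionally followed by a nonlinear output
transform.  The engine here evaluates any user-supplied coefficient set
against any beta matrix, and — because successive array generations drop
CpGs — accounts explicitly for the coefficient mass carried by probes that
are absent from a given array.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClockDefinition",
    "read_clock",
    "write_clock",
    "missing_weight_share",
    "estimate_age",
    "compare_estimates",
    "horvath_transform",
    "horvath_inverse",
]

IMPUTE_POLICIES = ("training_mean", "cohort_mean", "zero", "drop")


def horvath_transform(x: float | np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Map the linear predictor to years of age.

    Clocks trained on log-transformed age in childhood use a piecewise
    transform: exponential below the adult-age knot, linear above it.
    ``x = 0`` maps to ``adult_age`` on both branches (continuous).
    """
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, (1.0 + adult_age) * np.exp(x) - 1.0,
                    (1.0 + adult_age) * x + adult_age)


def horvath_inverse(age: float | np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Inverse of :func:`horvath_transform` (years -> linear-predictor scale)."""
    age = np.asarray(age, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(age < adult_age,
                        np.log((age + 1.0) / (1.0 + adult_age)),
                        (age - adult_age) / (1.0 + adult_age))


@dataclass
class ClockDefinition:
    """A linear clock: ``estimate = transform(intercept + sum_i w_i * beta_i)``.

    Parameters
    ----------
    name : clock label.
    intercept : additive constant of the linear predictor.
    weights : probe id -> signed coefficient.
    transform : ``"identity"`` or ``"horvath-age"``.
    adult_age : knot of the horvath-age transform (years).
    impute_values : optional probe id -> training-mean beta, used by the
        ``training_mean`` imputation policy.
    fit_residual : maximum absolute training residual, when the clock was
        fit by the synthetic generator (informational).
    """

    name: str
    intercept: float
    weights: Mapping[str, float]
    transform: str = "identity"
    adult_age: float = 20.0
    impute_values: Mapping[str, float] | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("clock weights must be non-empty")
        if self.transform not in ("identity", "horvath-age"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        if self.transform == "horvath-age" and self.adult_age <= 0:
            raise ValueError("adult_age must be > 0 for the horvath-age transform")

    @property
    def probes(self) -> list[str]:
        return list(self.weights)

    def apply_transform(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "horvath-age":
            return horvath_transform(x, self.adult_age)
        return np.asarray(x, dtype=float)

    def invert_transform(self, age: np.ndarray) -> np.ndarray:
        if self.transform == "horvath-age":
            return horvath_inverse(age, self.adult_age)
        return np.asarray(age, dtype=float)


def write_clock(clock: ClockDefinition, path) -> None:
    """Write a clock CSV with ``#key value`` metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"#name {clock.name}\n")
        fh.write(f"#intercept {clock.intercept!r}\n")
        fh.write(f"#transform {clock.transform}\n")
        if clock.transform == "horvath-age":
            fh.write(f"#adult_age {clock.adult_age!r}\n")
        fh.write("probe_id,weight")
        has_impute = clock.impute_values is not None
        if has_impute:
            fh.write(",impute_value")
        fh.write("\n")
        for pid, w in clock.weights.items():
            fh.write(f"{pid},{w!r}")
            if has_impute:
                fh.write(f",{clock.impute_values.get(pid, float('nan'))!r}")
            fh.write("\n")


def read_clock(path) -> ClockDefinition:
    """Read a clock CSV produced by :func:`write_clock` (or hand-written)."""
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(" ")
                meta[key] = value
            else:
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    if "probe_id" not in df.columns or "weight" not in df.columns:
        raise ValueError("clock CSV requires columns probe_id, weight")
    weights = dict(zip(df["probe_id"].astype(str), df["weight"].astype(float)))
    impute = None
    if "impute_value" in df.columns:
        impute = dict(zip(df["probe_id"].astype(str), df["impute_value"].astype(float)))
    return ClockDefinition(
        name=meta.get("name", "clock"),
        intercept=float(meta.get("intercept", 0.0)),
        weights=weights,
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
        impute_values=impute,
    )


def missing_weight_share(clock: ClockDefinition,
                         available: Iterable[str]) -> tuple[float, float]:
    """Share of a clock carried by probes absent from ``available``.

    Returns ``(pct_missing_probes, pct_missing_weight)``:

    * ``pct_missing_probes`` — 100 * (number of clock CpGs absent) / (total
      clock CpGs);
    * ``pct_missing_weight`` — coefficient magnitudes normalized so they sum
      to 100%, then the percentage of that sum carried by the absent CpGs.
      Absolute values are used because clock weights are signed.

    Values are returned unrounded; round only for display.
    """
    available = set(available)
    weights = pd.Series(clock.weights, dtype=float)
    missing = ~weights.index.isin(available)
    pct_missing_probes = 100.0 * missing.sum() / len(weights)
    total = weights.abs().sum()
    if total == 0:
        pct_missing_weight = 0.0
    else:
        pct_missing_weight = 100.0 * weights.abs()[missing].sum() / total
    return float(pct_missing_probes), float(pct_missing_weight)


def estimate_age(beta: pd.DataFrame, clock: ClockDefinition,
                 impute_policy: str = "cohort_mean") -> pd.DataFrame:
    """Evaluate a clock on a beta matrix (probes x samples).

    Probes the clock uses but the matrix lacks are handled per
    ``impute_policy``:

    * ``training_mean`` — substitute the clock's stored training means
      (falls back to cohort mean when a probe has no stored mean);
    * ``cohort_mean`` — substitute that probe's mean over the supplied
      samples (only possible when the probe row exists with some values);
      rows entirely absent contribute nothing, as with ``drop``;
    * ``zero`` — substitute 0;
    * ``drop`` — omit the term.

    Returns one row per sample: estimate, n_missing, pct_missing_probes,
    pct_missing_weight, impute_policy.
    """
    if impute_policy not in IMPUTE_POLICIES:
        raise ValueError(f"unknown impute policy: {impute_policy!r}")
    probes = pd.Index(clock.probes)
    present = probes[probes.isin(beta.index)]
    if len(present) == 0 and not (impute_policy == "training_mean"
                                  and clock.impute_values):
        raise ValueError(f"no probes of clock {clock.name!r} present in the beta matrix")
    missing = probes[~probes.isin(beta.index)]
    w = pd.Series(clock.weights, dtype=float)

    sub = beta.loc[present]  # present-probes x samples
    x = sub.mul(w[present], axis=0).sum(axis=0, skipna=True) + clock.intercept

    # contribution of absent probes
    if len(missing) > 0 and impute_policy != "drop":
        if impute_policy == "zero":
            fill = pd.Series(0.0, index=missing)
        elif impute_policy == "training_mean":
            tm = pd.Series(clock.impute_values or {}, dtype=float)
            fill = tm.reindex(missing)
            if fill.isna().any():
                raise ValueError(
                    "training_mean policy requires impute values for all missing probes; "
                    f"missing for {list(fill.index[fill.isna()])[:5]}")
        else:  # cohort_mean: no cohort values exist for absent rows -> drop
            fill = pd.Series(np.nan, index=missing)
        contrib = (fill * w[missing]).sum(skipna=True)
        x = x + contrib

    # within-matrix NaNs: cohort_mean imputes the probe's cohort mean
    if sub.isna().any().any():
        if impute_policy == "cohort_mean":
            row_means = sub.mean(axis=1, skipna=True).fillna(0.0)
            na_fill = sub.isna().mul(row_means * w[present], axis=0).sum(axis=0)
            x = x + na_fill
        # zero and drop: NaN terms already omitted by skipna

    pct_probes, pct_weight = missing_weight_share(clock, beta.index)
    est = clock.apply_transform(x.to_numpy())
    return pd.DataFrame({
        "sample_id": beta.columns,
        "clock": clock.name,
        "estimate": est,
        "n_missing": len(missing),
        "pct_missing_probes": pct_probes,
        "pct_missing_weight": pct_weight,
        "impute_policy": impute_policy,
    }).set_index("sample_id")


def compare_estimates(estimates: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise comparison of per-donor clock estimates across arrays.

    ``estimates`` maps array name -> Series indexed by donor id, ordered
    oldest array first.  For each ordered pair the difference score is
    earlier-generation estimate minus later-generation estimate, and the
    Pearson correlation is computed over shared donors.
    """
    names = list(estimates)
    if len(names) < 2:
        raise ValueError("need at least two arrays to compare")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            sa, sb = estimates[a], estimates[b]
            shared = sa.index.intersection(sb.index)
            if len(shared) < 3:
                raise ValueError(
                    f"need >= 3 shared samples between {a} and {b}, got {len(shared)}")
            diff = sa[shared] - sb[shared]
            va, vb = sa[shared].to_numpy(float), sb[shared].to_numpy(float)
            if np.std(va) == 0 or np.std(vb) == 0:
                r = math.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            rows.append({
                "array_a": a, "array_b": b, "n_shared": len(shared),
                "pearson_r": r,
                "mean_difference": float(diff.mean()),
                "sd_difference": float(diff.std(ddof=1)),
            })
    return pd.DataFrame(rows)


def pairwise_differences(estimates: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-sample difference scores (earlier minus later) for every pair."""
    names = list(estimates)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            shared = estimates[a].index.intersection(estimates[b].index)
            d = estimates[a][shared] - estimates[b][shared]
            out.append(pd.DataFrame({"sample_id": shared, "array_a": a,
                                     "array_b": b, "difference": d.to_numpy()}))
    return pd.concat(out, ignore_index=True)
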