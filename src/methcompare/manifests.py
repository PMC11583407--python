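"""Manifest harmonization across array generations.

Successive Illumina methylation arrays redesign their content: probes are
added, dropped, re-synthesized with new sequences or color channels, and
(on the newest generation) sometimes carried as several physical replicates
of one CpG locus, distinguished by an underscore-delimited suffix on the
probe id.  This module reads per-array manifests, computes probe-overlap
partitions on the CpG locus (base id), flags SNP fingerprint probes whose
design attributes changed relative to the older generations, applies the
detection-based probe filter, and collapses replicate probes.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "base_id",
    "load_manifest",
    "intersect_probes",
    "detect_snp_mismatches",
    "filter_probes",
    "collapse_replicate_probes",
]

REQUIRED_COLUMNS = ("IlmnID", "Category", "Infinium_Design_Type",
                    "AlleleA_ProbeSeq", "Color_Channel", "Next_Base",
                    "CHR", "MAPINFO")

_SUFFIX_RE = re.compile(r"^((?:cg|rs|ch)\w*?)_[A-Za-z0-9]+$")


def base_id(probe_id: str) -> str:
    """Strip a replicate suffix (trailing ``_<token>``) from a probe id.

    ``cg00000029_BC11`` -> ``cg00000029``; ids without a suffix pass
    through unchanged.
    """
    m = _SUFFIX_RE.match(probe_id)
    return m.group(1) if m else probe_id


def _ensure_manifest(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest {source} is missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"manifest {source} contains no probes")
    dup = df["IlmnID"].duplicated()
    if dup.any():
        raise ValueError(
            f"manifest {source} has duplicate probe ids, e.g. "
            f"{df.loc[dup, 'IlmnID'].iloc[0]!r}")
    out = df.copy()
    out["IlmnID"] = out["IlmnID"].astype(str)
    out["base_id"] = out["IlmnID"].map(base_id)
    return out


def load_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV; adds a ``base_id`` column."""
    try:
        df = pd.read_csv(path, dtype={"CHR": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {path} is empty") from None
    return _ensure_manifest(df, source=str(path))


def intersect_probes(manifests: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
                     category: str = "cg") -> dict:
    """Venn partition of probe base ids across arrays, within one category.

    Returns a dict with ``regions`` (frozenset of array names -> set of
    base ids), ``counts`` (same keys -> sizes), ``shared_all`` (the
    all-array intersection) and ``union`` size.  Regions partition the
    union of all probes of the category.
    """
    if not isinstance(manifests, Mapping):
        manifests = {f"array{i + 1}": m for i, m in enumerate(manifests)}
    if len(manifests) < 2:
        raise ValueError("need at least 2 manifests")
    sets = {}
    for name, df in manifests.items():
        df = _ensure_manifest(df, source=name) if "base_id" not in df.columns else df
        sets[name] = set(df.loc[df["Category"] == category, "base_id"])
    names = list(sets)
    union = set().union(*sets.values())
    regions: dict[frozenset, set] = {}
    for pid in union:
        member = frozenset(n for n in names if pid in sets[n])
        regions.setdefault(member, set()).add(pid)
    counts = {k: len(v) for k, v in regions.items()}
    shared_all = regions.get(frozenset(names), set())
    return {"arrays": names, "regions": regions, "counts": counts,
            "shared_all": shared_all, "n_union": len(union)}


def detect_snp_mismatches(manifests: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]
                          ) -> pd.DataFrame:
    """Flag SNP (rs) probes whose design changed on the newest array.

    The last manifest is taken as the newest generation.  For every rs
    probe present on the newest array and on at least one older array, the
    probe sequence, color channel and next base are compared against the
    older arrays' consensus.  Any disagreement sets the corresponding
    mismatch flag; ``bad_metric`` is their logical OR.  Probes absent from
    all older arrays — or whose older arrays disagree among themselves —
    are marked not comparable rather than bad.
    """
    if not isinstance(manifests, Mapping):
        manifests = {f"array{i + 1}": m for i, m in enumerate(manifests)}
    names = list(manifests)
    newest = names[-1]
    older = names[:-1]
    rs = {}
    for name, df in manifests.items():
        df = _ensure_manifest(df, source=name) if "base_id" not in df.columns else df
        sub = df[df["Category"] == "rs"].set_index("base_id")
        rs[name] = sub
    all_ids = sorted(set().union(*(set(s.index) for s in rs.values())))
    if not all_ids:
        warnings.warn("no rs probes found in any manifest")
        cols = ([f"present_{n}" for n in names]
                + ["comparable", "seq_mismatch", "channel_mismatch",
                   "nextbase_mismatch", "bad_metric"])
        return pd.DataFrame(columns=["probe_id"] + cols).set_index("probe_id")

    attrs = (("seq_mismatch", "AlleleA_ProbeSeq"),
             ("channel_mismatch", "Color_Channel"),
             ("nextbase_mismatch", "Next_Base"))
    rows = []
    for pid in all_ids:
        rec = {"probe_id": pid}
        for n in names:
            rec[f"present_{n}"] = pid in rs[n].index
        comparable = rec[f"present_{newest}"] and any(rec[f"present_{n}"] for n in older)
        flags = {flag: False for flag, _ in attrs}
        if comparable:
            for flag, col in attrs:
                older_vals = {rs[n].at[pid, col] for n in older
                              if rec[f"present_{n}"]}
                if len(older_vals) > 1:          # older generations disagree
                    comparable = False
                    flags = {f: False for f, _ in attrs}
                    break
                flags[flag] = rs[newest].at[pid, col] != next(iter(older_vals))
        rec["comparable"] = comparable
        rec.update(flags)
        rec["bad_metric"] = comparable and any(flags.values())
        rows.append(rec)
    return pd.DataFrame(rows).set_index("probe_id")


def filter_probes(beta: pd.DataFrame, detection_p: pd.DataFrame,
                  beads: pd.DataFrame, p_thresh: float = 0.01,
                  bead_thresh: float = 3, sample_fraction: float = 0.20
                  ) -> tuple[pd.DataFrame, list]:
    """Detection-based probe filter.

    A probe is removed iff the fraction of samples failing (detection
    p > ``p_thresh`` OR bead count < ``bead_thresh``) is strictly greater
    than ``sample_fraction``.  Returns (filtered beta, removed probe ids).
    """
    dp = np.asarray(detection_p, dtype=float)
    bd = np.asarray(beads, dtype=float)
    for name, m in (("detection_p", dp), ("beads", bd)):
        if m.shape != beta.shape:
            raise ValueError(f"{name} shape {m.shape} != beta shape {beta.shape}")
    fail = (dp > p_thresh) | (bd < bead_thresh)
    frac = fail.mean(axis=1)
    removed = list(beta.index[frac > sample_fraction])
    return beta.drop(index=removed), removed


def collapse_replicate_probes(beta: pd.DataFrame, manifest: pd.DataFrame,
                              policy: str = "mean",
                              detection_p: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Collapse replicate probes (shared base id) to one row per CpG locus.

    Policies: ``mean`` (average of replicate rows), ``first``
    (lexicographically first probe id), ``best_detection`` (row with the
    lowest mean detection p; requires ``detection_p``).
    """
    if policy not in ("mean", "first", "best_detection"):
        raise ValueError(f"unknown collapse policy: {policy!r}")
    manifest = (_ensure_manifest(manifest) if "base_id" not in manifest.columns
                else manifest)
    missing = beta.index.difference(manifest["IlmnID"])
    if len(missing):
        raise ValueError(f"beta matrix has probes absent from the manifest, "
                         f"e.g. {missing[0]!r}")
    base = manifest.set_index("IlmnID")["base_id"].reindex(beta.index)
    if policy == "mean":
        out = beta.groupby(base, sort=False).mean()
    elif policy == "first":
        keep = pd.Series(beta.index, index=beta.index).groupby(base).min()
        out = beta.loc[keep.to_numpy()]
        out.index = keep.index
    else:
        if detection_p is None:
            raise ValueError("best_detection policy requires detection_p")
        mean_p = detection_p.reindex(beta.index).mean(axis=1)
        keep = mean_p.groupby(base).idxmin()
        out = beta.loc[keep.to_numpy()]
        out.index = keep.index
    out.index.name = beta.index.name
    # preserve the original (manifest) probe order
    order = pd.unique(base)
    return out.loc[[b for b in order if b in out.index]]
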