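"""Per-probe report assembly and mQTL cis/trans classification.

The report gathers whatever upstream stages were run — presence per
array, per-array summary statistics, reliability (ICC/IQR/informative),
array-bias ANOVA and Tukey columns, and an mQTL class derived from a
user-supplied SNP–CpG pair table — into one tidy per-CpG table keyed on
the base probe id.
"""

from __future__ import annotations

import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["classify_mqtl", "classify_mqtl_pairs", "build_report", "write_report"]

CIS_P = 1e-8
TRANS_P = 1e-14
DISTANCE_BP = 1_000_000


def classify_mqtl_pairs(pairs: pd.DataFrame,
                        cis_p: float = CIS_P, trans_p: float = TRANS_P,
                        distance_bp: int = DISTANCE_BP) -> pd.DataFrame:
    """Classify each SNP–CpG pair as cis, trans or none.

    A pair is *cis* iff SNP and CpG share a chromosome, are strictly
    closer than ``distance_bp`` and p < ``cis_p``; *trans* iff they are on
    different chromosomes or strictly farther than ``distance_bp`` and
    p < ``trans_p``.  A distance of exactly ``distance_bp`` satisfies
    neither definition.  Malformed rows (missing fields, p outside (0, 1],
    non-positive positions) are skipped with a logged count.
    """
    required = ["snp_chr", "snp_pos", "cpg_chr", "cpg_pos", "p"]
    for col in required:
        if col not in pairs.columns:
            raise ValueError(f"pair table is missing column {col!r}")
    df = pairs.copy()
    pos = df[["snp_pos", "cpg_pos", "p"]].apply(pd.to_numeric, errors="coerce")
    bad = (pos.isna().any(axis=1) | df["snp_chr"].isna() | df["cpg_chr"].isna()
           | (pos["p"] <= 0) | (pos["p"] > 1)
           | (pos["snp_pos"] < 1) | (pos["cpg_pos"] < 1))
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("skipped %d malformed mQTL pair rows", n_bad)
    df = df[~bad].copy()
    df[["snp_pos", "cpg_pos", "p"]] = pos[~bad]
    same_chr = df["snp_chr"].astype(str) == df["cpg_chr"].astype(str)
    dist = (df["snp_pos"] - df["cpg_pos"]).abs()
    is_cis = same_chr & (dist < distance_bp) & (df["p"] < cis_p)
    is_trans = (~same_chr | (dist > distance_bp)) & (df["p"] < trans_p)
    n_boundary = int((same_chr & (dist == distance_bp)).sum())
    if n_boundary:
        logger.info("%d pairs at exactly %d bp classify as neither cis nor trans",
                    n_boundary, distance_bp)
    df["mqtl_class"] = np.select([is_cis, is_trans], ["cis", "trans"], "none")
    return df


def classify_mqtl(pairs: pd.DataFrame, **kwargs) -> pd.Series:
    """Per-CpG mQTL class in {cis, trans, both, none}: union over its pairs.

    CpGs are keyed by a ``cpg_id`` column when present, otherwise by
    ``chr:pos``.
    """
    classified = classify_mqtl_pairs(pairs, **kwargs)
    if "cpg_id" in classified.columns:
        key = classified["cpg_id"].astype(str)
    else:
        key = (classified["cpg_chr"].astype(str) + ":"
               + classified["cpg_pos"].astype(int).astype(str))

    def combine(classes) -> str:
        s = set(classes)
        has_cis, has_trans = "cis" in s, "trans" in s
        if has_cis and has_trans:
            return "both"
        if has_cis:
            return "cis"
        if has_trans:
            return "trans"
        return "none"

    out = classified.groupby(key, sort=True)["mqtl_class"].agg(combine)
    out.name = "mqtl_class"
    return out


def build_report(probe_ids: Sequence,
                 presence: pd.DataFrame | None = None,
                 reliability: Mapping[str, pd.DataFrame] | None = None,
                 bias: pd.DataFrame | None = None,
                 mqtl: pd.Series | None = None,
                 provenance: Mapping | None = None) -> pd.DataFrame:
    """Left-join upstream per-probe tables on the base probe id.

    Only supplied stages contribute columns; absent stages are absent from
    the report, never fabricated.  ``provenance`` (seeds, versions,
    decisions) is stored in ``report.attrs["provenance"]``.
    """
    if presence is None and reliability is None and bias is None and mqtl is None:
        raise ValueError("at least one upstream result table is required")
    index = pd.Index(pd.unique(pd.Series(list(probe_ids))), name="base_id")
    report = pd.DataFrame(index=index)
    universe_errors = []
    if presence is not None:
        extra = presence.index.difference(index)
        if len(extra):
            universe_errors.append(f"presence: {list(extra[:5])}")
        for c in presence.columns:
            report[f"present_{c}"] = presence[c].reindex(index)
    if reliability is not None:
        for arr, tab in reliability.items():
            extra = tab.index.difference(index)
            if len(extra):
                universe_errors.append(f"reliability[{arr}]: {list(extra[:5])}")
            for c in ("icc", "iqr", "informative"):
                if c in tab.columns:
                    report[f"{c}_{arr}"] = tab[c].reindex(index)
    if bias is not None:
        extra = bias.index.difference(index)
        if len(extra):
            universe_errors.append(f"bias: {list(extra[:5])}")
        for c in bias.columns:
            report[c] = bias[c].reindex(index)
    if mqtl is not None:
        report["mqtl_class"] = mqtl.reindex(index)
    if universe_errors:
        raise ValueError("probe universes conflict with the report index: "
                         + "; ".join(universe_errors))
    report.attrs["provenance"] = dict(provenance or {})
    return report


def write_report(report: pd.DataFrame, csv_path, jsonl_path=None) -> None:
    """Write the report as tidy CSV plus an optional JSON-lines variant."""
    report.to_csv(csv_path, index_label="base_id")
    if jsonl_path is not None:
        with open(jsonl_path, "w") as fh:
            if report.attrs.get("provenance"):
                fh.write(json.dumps({"_provenance":
                                     report.attrs["provenance"]}) + "\n")
            for pid, row in report.iterrows():
                rec = {"base_id": pid}
                for k, v in row.items():
                    if isinstance(v, (np.floating, float)) and np.isnan(v):
                        v = None
                    elif isinstance(v, np.generic):
                        v = v.item()
                    rec[k] = v
                fh.write(json.dumps(rec) + "\n")
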