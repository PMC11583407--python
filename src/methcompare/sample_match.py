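"""SNP-fingerprint genotype calling and cross-array sample matching.

Methylation arrays carry a few dozen SNP (rs) probes whose betas cluster
near 0, 0.5 and 1 by genotype.  Calling those clusters gives a genetic
fingerprint that verifies sample identity across array generations.
Matching uses call concordance — the fraction of co-called probes with
identical calls — which is robust to array-level intensity shifts, the
very failure mode under study; a best match is accepted only when its
concordance clears a minimum threshold, mirroring standard identity-QC
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "call_genotypes",
    "concordance",
    "match_samples",
    "MatchResult",
    "recommend_exclusions",
    "linkage_to_newick",
]


def call_genotypes(snp_beta: pd.DataFrame, t1: float = 0.25,
                   t2: float = 0.75) -> pd.DataFrame:
    """Call genotypes from SNP-probe betas (probes x samples).

    beta < t1 -> 0 copies, beta > t2 -> 2 copies, otherwise heterozygote
    (1); thresholds themselves call heterozygote (conservative).  Missing
    betas propagate as missing calls (NaN).
    """
    if not 0 < t1 < t2 < 1:
        raise ValueError("thresholds must satisfy 0 < t1 < t2 < 1")
    vals = snp_beta.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("betas must lie in [0, 1]")
    calls = np.full(vals.shape, np.nan)
    calls[vals < t1] = 0
    calls[(vals >= t1) & (vals <= t2)] = 1
    calls[vals > t2] = 2
    return pd.DataFrame(calls, index=snp_beta.index, columns=snp_beta.columns)


def concordance(calls_a: pd.Series, calls_b: pd.Series) -> tuple[float, int]:
    """Fraction of co-called shared probes with equal calls, and their count."""
    shared = calls_a.index.intersection(calls_b.index)
    a = calls_a[shared].to_numpy(float)
    b = calls_b[shared].to_numpy(float)
    ok = ~(np.isnan(a) | np.isnan(b))
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    return float((a[ok] == b[ok]).mean()), n


@dataclass
class MatchResult:
    pairwise: pd.DataFrame     # all cross-array sample pairs with concordance
    assignment: pd.DataFrame   # newest-array sample -> best older match
    linkage: np.ndarray        # average-linkage tree over all samples
    labels: list               # leaf labels "array:sample"
    newick: str
    min_concordance: float


def _call_blocks(calls_by_array: Mapping[str, pd.DataFrame],
                 exclude: set) -> dict:
    out = {}
    for name, df in calls_by_array.items():
        keep = df.index[~df.index.isin(exclude)]
        out[name] = df.loc[keep]
    return out


def match_samples(calls_by_array: Mapping[str, pd.DataFrame],
                  exclude: Iterable[str] = (),
                  min_concordance: float = 0.8,
                  min_shared: int = 5) -> MatchResult:
    """Match newest-array samples to older arrays by call concordance.

    ``calls_by_array`` maps array name -> calls (probes x samples), oldest
    first.  Probes in ``exclude`` are dropped before comparison.  For each
    newest-array sample and each older array, the older sample of maximal
    concordance is the candidate match; it is assigned only when the
    concordance is at least ``min_concordance`` and the maximum is unique.
    An average-linkage dendrogram over all samples of all arrays (distance
    1 - concordance) is also returned, with a Newick export.
    """
    if len(calls_by_array) < 2:
        raise ValueError("need calls from at least 2 arrays")
    exclude = set(exclude)
    blocks = _call_blocks(calls_by_array, exclude)
    names = list(blocks)
    newest = names[-1]

    shared_all = blocks[names[0]].index
    for n in names[1:]:
        shared_all = shared_all.intersection(blocks[n].index)
    if len(shared_all) < min_shared:
        raise ValueError(
            f"only {len(shared_all)} shared SNP probes after exclusion; "
            f"need >= {min_shared}")

    pair_rows = []
    assign_rows = []
    for older in names[:-1]:
        for s_new in blocks[newest].columns:
            best_c = -1.0
            tied_best: list = []
            for s_old in blocks[older].columns:
                c, n_shared = concordance(blocks[older][s_old],
                                          blocks[newest][s_new])
                pair_rows.append({"sample_a": s_old, "array_a": older,
                                  "sample_b": s_new, "array_b": newest,
                                  "n_shared": n_shared, "concordance": c})
                if np.isnan(c):
                    continue
                if c > best_c:
                    best_c, tied_best = c, [s_old]
                elif c == best_c:
                    tied_best.append(s_old)
            tied = len(tied_best) > 1
            assigned = (len(tied_best) == 1 and best_c >= min_concordance)
            if tied:
                warnings.warn(f"tied best match for {s_new} on {older}; "
                              "left unmatched")
            assign_rows.append({"sample": s_new, "array": newest,
                                "matched_array": older,
                                "best_match": tied_best[0] if assigned else None,
                                "tied_matches": tuple(tied_best) if tied else (),
                                "concordance": best_c if best_c >= 0 else np.nan,
                                "meets_threshold": best_c >= min_concordance,
                                "assigned": assigned})

    # dendrogram over all samples of all arrays
    labels = []
    cols = []
    for n in names:
        sub = blocks[n].loc[shared_all]
        for s in sub.columns:
            labels.append(f"{n}|{s}")
            cols.append(sub[s])
    m = len(cols)
    dist = np.zeros((m, m))
    mat = pd.concat(cols, axis=1).to_numpy(float)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = mat[:, i], mat[:, j]
            ok = ~(np.isnan(a) | np.isnan(b))
            c = (a[ok] == b[ok]).mean() if ok.any() else 0.0
            dist[i, j] = dist[j, i] = 1.0 - c
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = linkage_to_newick(Z, labels)
    return MatchResult(pairwise=pd.DataFrame(pair_rows),
                       assignment=pd.DataFrame(assign_rows),
                       linkage=Z, labels=labels, newick=newick,
                       min_concordance=min_concordance)


def assignment_accuracy(assignment: pd.DataFrame,
                        donor_of: Mapping[str, str]) -> float:
    """Fraction of newest-array samples assigned to their true donor.

    A sample counts as correct when it was assigned and the matched sample
    belongs to the same donor, or when its best matches tied above the
    acceptance threshold but all of them are positions of the true donor
    (duplicate positions of one donor are consistent, not ambiguous).
    Everything else — including rejection below the concordance
    threshold — counts as an error.
    """
    ok = 0
    for _, row in assignment.iterrows():
        truth = donor_of[row["sample"]]
        if row["assigned"] and row["best_match"] is not None and \
                donor_of[row["best_match"]] == truth:
            ok += 1
        elif len(row.get("tied_matches", ())) > 1 and \
                row.get("meets_threshold", False) and \
                all(donor_of[s] == truth for s in row["tied_matches"]):
            ok += 1
    return ok / len(assignment) if len(assignment) else float("nan")


def recommend_exclusions(mismatch_report: pd.DataFrame) -> set:
    """Probes to drop before sample matching: all with ``bad_metric`` set."""
    return set(mismatch_report.index[mismatch_report["bad_metric"].astype(bool)])


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z, rd=False)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"
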