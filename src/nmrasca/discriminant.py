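"""From model importances to discriminant-metabolite tables.

Candidate buckets are selected by VIP (or absolute loading), each is
screened by a Kruskal-Wallis test across groups, significant ones go to
rank-based pairwise post-hoc comparisons of every treated group against
the reference group with multiple-testing correction, and bucket-level
records are finally aggregated to annotated metabolite rows with
direction-of-change signs ("+" increase / "-" decrease vs reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationMap, BucketGrid

logger = logging.getLogger("nmrasca")

__all__ = [
    "KruskalResult",
    "select_candidates",
    "kruskal_wallis",
    "pairwise_posthoc",
    "annotate_and_summarize",
]

_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def select_candidates(
    scores: np.ndarray, mode: str = "vip", threshold: float = 1.0
) -> np.ndarray:
    """Bucket indices whose selection score reaches ``threshold``.

    ``mode='vip'`` uses the scores as-is (the VIP > 1 convention);
    ``mode='loading'`` takes absolute values first.
    """
    scores = np.asarray(scores, dtype=float)
    if mode == "loading":
        scores = np.abs(scores)
    elif mode != "vip":
        raise ValueError(f"unknown selection mode {mode!r}")
    selected = np.flatnonzero(scores >= threshold)
    if selected.size == 0:
        logger.warning("no buckets reach the %s threshold %g", mode, threshold)
    return selected


class KruskalResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def kruskal_wallis(values: np.ndarray, groups: Sequence) -> KruskalResult:
    """Kruskal-Wallis H (midrank ties, chi-square p on n_groups-1 df)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 samples per group")
    if np.ptp(values) == 0:
        return KruskalResult(statistic=0.0, pvalue=1.0, degenerate=True)
    h, p = stats.kruskal(*samples)
    return KruskalResult(statistic=float(h), pvalue=float(p))


def _dunn_z(values: np.ndarray, labels: np.ndarray, a, b) -> float:
    """Dunn's rank-based z statistic for one pair, with tie correction."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    ra = ranks[labels == a].mean()
    rb = ranks[labels == b].mean()
    na = int(np.sum(labels == a))
    nb = int(np.sum(labels == b))
    denom = np.sqrt(var_unit * (1.0 / na + 1.0 / nb))
    return float((ra - rb) / denom) if denom > 0 else 0.0


def pairwise_posthoc(
    values: np.ndarray,
    groups: Sequence,
    reference: str,
    method: str = "dunn",
    correction: str = "bh",
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Each non-reference group vs the reference, gated on the overall test.

    Returns an empty frame when the Kruskal-Wallis screen does not reach
    ``gate_alpha``.  ``method`` is ``'dunn'`` (rank z-test on the pooled
    ranking) or ``'mannwhitney'``; ``correction`` one of bh / bonferroni /
    holm.  Direction signs are reported only for comparisons significant
    after correction.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = list(dict.fromkeys(labels.tolist()))
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not present")

    gate = kruskal_wallis(values, labels)
    columns = [
        "group", "reference", "statistic", "p", "p_adjusted",
        "significant", "direction", "mean_group", "mean_reference",
    ]
    if gate.pvalue > gate_alpha:
        return pd.DataFrame(columns=columns)

    ref_mean = float(values[labels == reference].mean())
    rows = []
    for lv in levels:
        if lv == reference:
            continue
        if method == "dunn":
            z = _dunn_z(values, labels, lv, reference)
            p = 2.0 * stats.norm.sf(abs(z))
            stat = z
        elif method == "mannwhitney":
            stat, p = stats.mannwhitneyu(
                values[labels == lv], values[labels == reference],
                alternative="two-sided",
            )
            stat, p = float(stat), float(p)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        rows.append(
            {
                "group": lv,
                "reference": reference,
                "statistic": stat,
                "p": p,
                "mean_group": float(values[labels == lv].mean()),
                "mean_reference": ref_mean,
            }
        )
    df = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(df["p"], alpha=alpha, method=_CORRECTIONS[correction])
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    df["direction"] = [
        ("+" if m > ref_mean else "-") if sig else ""
        for m, sig in zip(df["mean_group"], df["significant"])
    ]
    return df[columns]


@dataclass(frozen=True)
class _BucketRecord:
    bucket: int
    score: float
    direction: str
    p_adjusted: float


def annotate_and_summarize(
    records: pd.DataFrame,
    annotation: AnnotationMap,
    grid: BucketGrid,
) -> pd.DataFrame:
    """Aggregate per-bucket records to one row per metabolite.

    ``records`` needs columns ``bucket`` (retained-bucket index),
    ``score`` (VIP or |loading|), ``direction`` ("+"/"-"/"") and
    ``p_adjusted``.  Buckets matching no annotation interval are reported
    as "unassigned d lo-hi"; conflicting signs within one metabolite are
    kept and flagged.
    """
    required = {"bucket", "score", "direction", "p_adjusted"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing column(s): {sorted(missing)}")

    by_name: dict[str, list[_BucketRecord]] = {}
    for rec in records.itertuples(index=False):
        names = annotation.metabolites_for_bucket(grid, int(rec.bucket))
        if not names:
            lo, hi = grid.bucket_edges[int(rec.bucket)]
            names = [f"unassigned d {lo:.2f}-{hi:.2f}"]
        for name in names:
            by_name.setdefault(name, []).append(
                _BucketRecord(int(rec.bucket), float(rec.score),
                              str(rec.direction), float(rec.p_adjusted))
            )

    rows = []
    for name, recs in by_name.items():
        signs = sorted({r.direction for r in recs if r.direction})
        rows.append(
            {
                "metabolite": name,
                "n_buckets": len(recs),
                "buckets": ",".join(str(r.bucket) for r in recs),
                "max_score": max(r.score for r in recs),
                "directions": "/".join(signs),
                "conflict": len(signs) > 1,
                "min_p_adjusted": min(r.p_adjusted for r in recs),
            }
        )
    out = pd.DataFrame(rows, columns=[
        "metabolite", "n_buckets", "buckets", "max_score",
        "directions", "conflict", "min_p_adjusted",
    ])
    return out.sort_values("max_score", ascending=False).reset_index(drop=True)
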