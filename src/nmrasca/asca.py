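"""ANOVA-simultaneous component analysis for two-factor omics designs.

The centered sample x feature matrix is split into additive effect blocks

    X_c = X_time + X_dose + X_interaction + X_residual

estimated from marginal level means (time first, then dose on the
time-corrected matrix, then cell means minus both main effects), so the
dose main effect is cleanly separated from the time*dose interaction.
Block sizes are summarized as percent contributions of squared Frobenius
norms; factor significance comes from label-permutation tests; each block
is then explored by PCA ("simultaneous component analysis"), and an
exhaustive subset search locates the time-level x dose-level combinations
with the strongest, significant interaction.

For balanced designs the blocks are mutually orthogonal and the sums of
squares coincide with textbook two-way ANOVA; for unbalanced designs the
(small) additivity deviation is measured and reported rather than hidden.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BucketMatrix, DesignTable

logger = logging.getLogger("nmrasca")

__all__ = [
    "AscaDecomposition",
    "ScaSubmodel",
    "InteractionSearchResult",
    "decompose",
    "permutation_test",
    "sca",
    "interaction_score_profile",
    "search_interaction",
]

BLOCKS = ("time", "dose", "interaction", "residual")


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

@dataclass
class AscaDecomposition:
    """Effect matrices of one two-factor decomposition.

    ``effects`` maps block name -> sample x feature matrix; ``percent``
    gives each block's squared-Frobenius share of the centered total.
    ``p_values`` is filled by :func:`permutation_test`.
    """

    design: DesignTable
    centered: np.ndarray
    effects: dict[str, np.ndarray]
    ssq: dict[str, float]
    ssq_total: float
    percent: dict[str, float]
    degenerate: bool
    additivity_deviation: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def reconstruction_error(self) -> float:
        """Relative Frobenius norm of X_c minus the sum of the four blocks."""
        total = sum(self.effects.values())
        denom = np.linalg.norm(self.centered)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(self.centered - total) / denom)


def _indices(labels: Sequence[str], levels: Sequence[str]) -> np.ndarray:
    lut = {lv: i for i, lv in enumerate(levels)}
    return np.fromiter((lut[v] for v in labels), dtype=int, count=len(labels))


def _level_means(x: np.ndarray, idx: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted level means of rows grouped by ``idx``; returns (means, counts)."""
    counts = np.bincount(idx, minlength=n_levels).astype(float)
    sums = np.zeros((n_levels, x.shape[1]))
    np.add.at(sums, idx, x)
    means = sums / np.maximum(counts, 1.0)[:, None]
    return means, counts


def _factor_ssq(x: np.ndarray, idx: np.ndarray, n_levels: int) -> float:
    means, counts = _level_means(x, idx, n_levels)
    return float(np.sum(counts * np.sum(means**2, axis=1)))


def _as_matrix_design(
    x: BucketMatrix | np.ndarray, design: DesignTable | None
) -> tuple[np.ndarray, DesignTable]:
    if isinstance(x, BucketMatrix):
        return x.values, x.design
    if design is None:
        raise ValueError("design table required when passing a bare array")
    return np.asarray(x, dtype=float), design


def _check_cells(design: DesignTable) -> None:
    counts = design.cell_counts()
    empty = [(t, d) for t in counts.index for d in counts.columns if counts.loc[t, d] == 0]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    if (counts.values == 1).any():
        logger.warning(
            "design has single-sample cells: interaction is confounded with the residual there"
        )


def decompose(
    x: BucketMatrix | np.ndarray, design: DesignTable | None = None
) -> AscaDecomposition:
    """Split the centered matrix into time / dose / interaction / residual.

    Main effects are unweighted marginal level means of the
    (grand-mean-centered) data, dose estimated on the time-corrected
    matrix; the interaction is cell means minus both main effects.
    Raises on empty cells; a constant matrix yields ``degenerate=True``
    with undefined (NaN) percents.
    """
    values, design = _as_matrix_design(x, design)
    if len(design.time_levels) < 2 or len(design.dose_levels) < 2:
        raise ValueError("need at least 2 levels per factor")
    _check_cells(design)

    t_idx = _indices(design.time, design.time_levels)
    d_idx = _indices(design.dose, design.dose_levels)
    n_t, n_d = len(design.time_levels), len(design.dose_levels)
    cell_idx = t_idx * n_d + d_idx

    xc = values - values.mean(axis=0, keepdims=True)
    t_means, _ = _level_means(xc, t_idx, n_t)
    x_time = t_means[t_idx]
    r1 = xc - x_time
    d_means, _ = _level_means(r1, d_idx, n_d)
    x_dose = d_means[d_idx]
    r2 = r1 - x_dose
    c_means, _ = _level_means(r2, cell_idx, n_t * n_d)
    x_int = c_means[cell_idx]
    x_res = r2 - x_int

    effects = {"time": x_time, "dose": x_dose, "interaction": x_int, "residual": x_res}
    ssq = {k: float(np.sum(v**2)) for k, v in effects.items()}
    ssq_total = float(np.sum(xc**2))
    degenerate = ssq_total <= 1e-300
    if degenerate:
        percent = {k: float("nan") for k in effects}
        deviation = 0.0
    else:
        percent = {k: 100.0 * v / ssq_total for k, v in ssq.items()}
        deviation = abs(sum(ssq.values()) - ssq_total) / ssq_total
        if deviation > 1e-9:
            logger.info(
                "unbalanced design: block SSQ additivity deviation %.3g (relative)",
                deviation,
            )
    return AscaDecomposition(
        design=design,
        centered=xc,
        effects=effects,
        ssq=ssq,
        ssq_total=ssq_total,
        percent=percent,
        degenerate=degenerate,
        additivity_deviation=deviation,
    )


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def _interaction_ssq(
    xc: np.ndarray, t_idx: np.ndarray, d_idx: np.ndarray, n_t: int, n_d: int
) -> float:
    t_means, _ = _level_means(xc, t_idx, n_t)
    r1 = xc - t_means[t_idx]
    d_means, _ = _level_means(r1, d_idx, n_d)
    r2 = r1 - d_means[d_idx]
    return _factor_ssq(r2, t_idx * n_d + d_idx, n_t * n_d)


def permutation_test(
    x: BucketMatrix | np.ndarray,
    design: DesignTable | None = None,
    n: int = 10_000,
    seed: int = 0,
    factors: Sequence[str] = ("time", "dose", "interaction"),
) -> dict[str, float]:
    """Label-permutation p-values for the requested effect blocks.

    The tested factor's labels are shuffled across samples while the other
    factor's labels stay attached to their samples (for the interaction
    the (time, dose) pairs are shuffled jointly); the factor's sum of
    squares is re-estimated each time, and

        p = (#{permuted SSQ >= observed} + 1) / (n + 1).
    """
    if n < 99:
        raise ValueError("use at least 99 permutations")
    values, design = _as_matrix_design(x, design)
    rng = np.random.default_rng(seed)
    t_idx = _indices(design.time, design.time_levels)
    d_idx = _indices(design.dose, design.dose_levels)
    n_t, n_d = len(design.time_levels), len(design.dose_levels)
    n_samples = values.shape[0]

    xc = values - values.mean(axis=0, keepdims=True)
    t_means, _ = _level_means(xc, t_idx, n_t)
    x_time = t_means[t_idx]
    r1 = xc - x_time

    observed = {
        "time": _factor_ssq(xc, t_idx, n_t),
        "dose": _factor_ssq(r1, d_idx, n_d),
        "interaction": _interaction_ssq(xc, t_idx, d_idx, n_t, n_d),
    }

    exceed = {f: 0 for f in factors}
    for _ in range(n):
        perm = rng.permutation(n_samples)
        if "time" in exceed:
            if _factor_ssq(xc, t_idx[perm], n_t) >= observed["time"]:
                exceed["time"] += 1
        if "dose" in exceed:
            if _factor_ssq(r1, d_idx[perm], n_d) >= observed["dose"]:
                exceed["dose"] += 1
        if "interaction" in exceed:
            p2 = rng.permutation(n_samples)
            ssq_i = _interaction_ssq(xc, t_idx[p2], d_idx[p2], n_t, n_d)
            if ssq_i >= observed["interaction"]:
                exceed["interaction"] += 1
    return {f: (exceed[f] + 1) / (n + 1) for f in factors}


# ---------------------------------------------------------------------------
# Per-block component analysis
# ---------------------------------------------------------------------------

@dataclass
class ScaSubmodel:
    """PCA of one effect block (simultaneous component analysis)."""

    block: str
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # features x components
    explained: np.ndarray         # percent variance per component
    singular_values: np.ndarray
    design: DesignTable
    degenerate: bool = False


def sca(
    block: np.ndarray,
    design: DesignTable,
    block_name: str = "effect",
    n_components: int | None = None,
) -> ScaSubmodel:
    """SVD of a sample-expanded effect matrix.

    Scores carry the singular values (PCA convention); explained variance
    is per-component share of the block's total sum of squares.
    """
    block = np.asarray(block, dtype=float)
    total = float(np.sum(block**2))
    if total <= 1e-300:
        logger.warning("SCA on a zero block %r", block_name)
        k = 1
        return ScaSubmodel(
            block=block_name,
            scores=np.zeros((block.shape[0], k)),
            loadings=np.zeros((block.shape[1], k)),
            explained=np.zeros(k),
            singular_values=np.zeros(k),
            design=design,
            degenerate=True,
        )
    u, s, vt = np.linalg.svd(block, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    k = rank if n_components is None else min(n_components, rank)
    # deterministic sign: largest-magnitude loading positive per component
    for a in range(k):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    return ScaSubmodel(
        block=block_name,
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained=100.0 * s[:k] ** 2 / total,
        singular_values=s[:k],
        design=design,
    )


def interaction_score_profile(
    submodel: ScaSubmodel, design: DesignTable | None = None, component: int = 0
) -> pd.DataFrame:
    """Mean component score per (time, dose) cell, times as rows.

    The cell-mean profile of the interaction block's first component is
    the standard line plot showing how dose trajectories diverge over
    time.
    """
    design = design or submodel.design
    df = design.to_frame()
    df["score"] = submodel.scores[:, component]
    prof = df.pivot_table(index="time", columns="dose", values="score", aggfunc="mean")
    return prof.reindex(index=design.time_levels, columns=design.dose_levels)


# ---------------------------------------------------------------------------
# Interaction subset search
# ---------------------------------------------------------------------------

@dataclass
class InteractionSearchResult:
    """Exhaustive scan over time-level x dose-level subsets."""

    records: pd.DataFrame
    k_range: tuple[int, int]
    h_range: tuple[int, int]
    n_permutations: int
    alpha: float

    @property
    def n_combinations(self) -> int:
        return len(self.records)

    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]

    def best(self) -> pd.Series:
        """Record with the largest interaction contribution."""
        return self.records.loc[self.records["interaction_percent"].idxmax()]


def search_interaction(
    x: BucketMatrix | np.ndarray,
    design: DesignTable | None = None,
    k_range: tuple[int, int] = (3, 5),
    h_range: tuple[int, int] = (2, 5),
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> InteractionSearchResult:
    """Scan all combinations of k time levels and h dose levels.

    Each subset is re-decomposed from scratch and the interaction block's
    contribution and permutation p-value recorded (``n_perm=0`` skips the
    permutation test, leaving p as NaN).  Subsets with an empty cell are
    skipped and logged.  At least 3 time levels per subset are required.
    """
    values, design = _as_matrix_design(x, design)
    if k_range[0] < 3:
        raise ValueError("time subsets must contain at least 3 levels")
    times, doses = design.time_levels, design.dose_levels
    if k_range[1] > len(times) or h_range[1] > len(doses):
        raise ValueError("subset range exceeds factor cardinality")

    t_arr = np.asarray(design.time)
    d_arr = np.asarray(design.dose)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for k in range(k_range[0], k_range[1] + 1):
        for t_sub in itertools.combinations(times, k):
            t_mask = np.isin(t_arr, t_sub)
            for h in range(h_range[0], h_range[1] + 1):
                for d_sub in itertools.combinations(doses, h):
                    mask = t_mask & np.isin(d_arr, d_sub)
                    sub_design = design.subset(mask)
                    if (sub_design.cell_counts().values == 0).any() or \
                            len(sub_design.time_levels) < k or len(sub_design.dose_levels) < h:
                        logger.info("skipping %s x %s: empty cell", t_sub, d_sub)
                        continue
                    dec = decompose(values[mask], sub_design)
                    if n_perm > 0:
                        p = permutation_test(
                            values[mask], sub_design, n=n_perm,
                            seed=int(rng.integers(2**31)),
                            factors=("interaction",),
                        )["interaction"]
                    else:
                        p = float("nan")
                    rows.append(
                        {
                            "time_subset": ",".join(t_sub),
                            "dose_subset": ",".join(d_sub),
                            "k": k,
                            "h": h,
                            "time_percent": dec.percent["time"],
                            "dose_percent": dec.percent["dose"],
                            "interaction_percent": dec.percent["interaction"],
                            "residual_percent": dec.percent["residual"],
                            "p_interaction": p,
                            "n_permutations": n_perm,
                            "significant": bool(p <= alpha) if np.isfinite(p) else False,
                        }
                    )
    records = pd.DataFrame(rows).drop_duplicates(subset=["time_subset", "dose_subset"])
    return InteractionSearchResult(
        records=records.reset_index(drop=True),
        k_range=k_range,
        h_range=h_range,
        n_permutations=n_perm,
        alpha=alpha,
    )
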