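"""Synthetic cohorts with known Time / Dose / interaction structure.

The generator emulates a longitudinal toxicology design — several dose
groups sampled destructively at several ages, with unequal cell counts —
producing a bucketed, total-area-normalized intensity matrix together with
the exact effect structure used to build it, so every downstream stage
(decomposition, permutation tests, discriminant statistics) can be checked
against ground truth.

Model
-----
Per metabolite *m* and sample *i* in cell (t, d):

    log c_im = log b_m + T_m(t) + D_m(d) + G_m(t, d) + eps_im,
    eps_im ~ N(0, sigma^2)

with T zero-mean over time levels, D zero-mean over dose levels and G
double-centered over the cell grid, so the additive decomposition of the
noise-free log matrix is exact.  Concentrations map to 1-4 disjoint bucket
resonances each, a constant spectral floor is added, an optional additive
noise floor is applied, and rows are normalized to total area — the same
closure step applied to real spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datamodel import (
    BucketGrid,
    BucketMatrix,
    DesignTable,
    build_bucket_grid,
    normalize_total_area,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "NullBatchResult",
    "simulate_cohort",
    "simulate_null_batch",
]

#: serum-like default grid: 0.01-ppm buckets over 0.70-9.00 ppm with the
#: water and ethanol windows removed (738 retained buckets).
DEFAULT_REGION = (0.70, 9.00)
DEFAULT_EXCLUSIONS = ((4.40, 5.10), (3.60, 3.70), (1.10, 1.25))

_STUDY_TIMES = ("PND21", "PND50", "PND90", "PND140", "PND200")
_STUDY_DOSES = ("Control", "BPA0.25", "BPA2.5", "BPA25", "BPA250")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design and effect sizes (log-concentration units).

    Amplitudes are root-mean-square effect sizes across factor levels on
    the natural-log concentration scale; ``sigma`` is the standard
    deviation of the multiplicative (log-normal) noise.  ``n_per_cell``
    may be a fixed integer, a (lo, hi) range sampled per cell, or an
    explicit (n_times, n_doses) table.
    """

    n_doses: int = 5
    n_times: int = 5
    n_per_cell: int | tuple[int, int] | Sequence[Sequence[int]] = (6, 10)
    n_metabolites: int = 30
    buckets_per_metabolite: tuple[int, int] = (1, 4)
    time_amplitude: float = 0.4
    dose_amplitude: float = 0.2
    interaction_amplitude: float = 0.2
    affected_fraction_time: float = 0.5
    affected_fraction_dose: float = 0.3
    affected_fraction_interaction: float = 0.2
    #: confine the interaction to a (time indices, dose indices) block
    interaction_cells: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    sigma: float = 0.1
    additive_floor: float = 0.0
    region: tuple[float, float] = DEFAULT_REGION
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    width: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("time_amplitude", "dose_amplitude", "interaction_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("affected_fraction_time", "affected_fraction_dose",
                     "affected_fraction_interaction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Noise-free effect structure behind a simulated cohort.

    The log-scale effect matrices satisfy the additive decomposition
    exactly; ``noise_free`` is the cohort mapped to buckets and normalized
    with ``eps = 0``, and ``true_shares`` are the percent contributions of
    its (deterministic) decomposition.  ``expected_shares`` adds the
    first-order inflation of each block's expected sum of squares by the
    configured noise, i.e. the estimand of the decomposition under the
    generative model.
    """

    log_baseline: np.ndarray            # (n_metabolites,)
    log_time: np.ndarray                # samples x metabolites
    log_dose: np.ndarray
    log_interaction: np.ndarray
    affected_time: np.ndarray           # boolean flags per metabolite
    affected_dose: np.ndarray
    affected_interaction: np.ndarray
    metabolite_buckets: list[list[int]]  # retained-bucket indices per metabolite
    noise_free: BucketMatrix
    true_shares: dict[str, float]
    sigma: float
    interaction_cells: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    _noise_ssq_per_entry: float = field(default=0.0, repr=False)

    def log_effect_sum(self) -> np.ndarray:
        """Exact additive reconstruction of the noise-free log signal."""
        return self.log_baseline[None, :] + self.log_time + self.log_dose + self.log_interaction

    def expected_shares(self) -> dict[str, float]:
        """Percent contributions expected from a noisy realization.

        Each block's expected sum of squares exceeds its noise-free value
        by (block degrees of freedom) x (per-entry noise variance summed
        over buckets), to first order in ``sigma^2``.
        """
        design = self.noise_free.design
        n = len(design)
        lt, ld = len(design.time_levels), len(design.dose_levels)
        dfs = {
            "time": lt - 1,
            "dose": ld - 1,
            "interaction": (lt - 1) * (ld - 1),
            "residual": n - lt * ld,
        }
        s = self._noise_ssq_per_entry
        from .asca import decompose  # local import to avoid cycle at load

        d0 = decompose(self.noise_free)
        ssq = {k: d0.ssq[k] + dfs[k] * s for k in dfs}
        total = d0.ssq_total + (n - 1) * s
        return {k: 100.0 * v / total for k, v in ssq.items()}


def _zero_mean(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _scaled(v: np.ndarray, rms: float) -> np.ndarray:
    norm = np.sqrt(np.mean(v**2))
    return v * (rms / norm) if norm > 0 else v


def _time_curve(rng: np.random.Generator, n_levels: int, amplitude: float) -> np.ndarray:
    """Seeded low-order polynomial trajectory, zero-mean, fixed RMS."""
    x = np.linspace(-1.0, 1.0, n_levels)
    degree = int(rng.integers(1, 4))
    coefs = rng.normal(size=degree)
    curve = sum(c * x ** (k + 1) for k, c in enumerate(coefs))
    return _scaled(_zero_mean(curve), amplitude)


def _dose_shape(rng: np.random.Generator, n_levels: int, amplitude: float) -> np.ndarray:
    """Monotone or U-shaped dose response (non-monotone EDC mimicry)."""
    x = np.linspace(0.0, 1.0, n_levels)
    if rng.random() < 0.5:
        shape = x if rng.random() < 0.5 else -x
    else:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        shape = sign * (x - 0.5) ** 2
    return _scaled(_zero_mean(shape), amplitude)


def _double_center(g: np.ndarray) -> np.ndarray:
    return g - g.mean(axis=0, keepdims=True) - g.mean(axis=1, keepdims=True) + g.mean()


def _interaction_grid(
    rng: np.random.Generator,
    n_times: int,
    n_doses: int,
    amplitude: float,
    cells: tuple[tuple[int, ...], tuple[int, ...]] | None,
) -> np.ndarray:
    g = np.zeros((n_times, n_doses))
    if cells is None:
        g = _double_center(rng.normal(size=(n_times, n_doses)))
    else:
        t_idx, d_idx = (np.asarray(ix, dtype=int) for ix in cells)
        # every selected cell must be genuinely perturbed: resample until no
        # row or column of the block is degenerate after double-centering
        for _ in range(200):
            block = _double_center(rng.normal(size=(len(t_idx), len(d_idx))))
            row_rms = np.sqrt(np.mean(block**2, axis=1))
            col_rms = np.sqrt(np.mean(block**2, axis=0))
            if row_rms.min() >= 0.5 * row_rms.max() and col_rms.min() >= 0.5 * col_rms.max():
                break
        # double-centered within the block => globally double-centered
        g[np.ix_(t_idx, d_idx)] = block
    return _scaled(g, amplitude)


def _resolve_cell_counts(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    spec = cfg.n_per_cell
    if isinstance(spec, int):
        return np.full((cfg.n_times, cfg.n_doses), spec, dtype=int)
    spec_arr = np.asarray(spec)
    if spec_arr.shape == (2,):
        lo, hi = int(spec_arr[0]), int(spec_arr[1])
        return rng.integers(lo, hi + 1, size=(cfg.n_times, cfg.n_doses))
    if spec_arr.shape == (cfg.n_times, cfg.n_doses):
        return spec_arr.astype(int)
    raise ValueError("n_per_cell must be an int, a (lo, hi) pair, or a full table")


def _level_names(n: int, study: tuple[str, ...], prefix: str) -> list[str]:
    return list(study) if n == len(study) else [f"{prefix}{i + 1}" for i in range(n)]


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[BucketMatrix, DesignTable, SyntheticTruth]:
    """Draw one cohort; the seed fully determines the output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = build_bucket_grid(cfg.region, cfg.width, cfg.exclusions)

    lo_res, hi_res = cfg.buckets_per_metabolite
    n_res = rng.integers(lo_res, hi_res + 1, size=cfg.n_metabolites)
    if n_res.sum() > grid.n_buckets:
        raise ValueError(
            f"grid has {grid.n_buckets} buckets but {int(n_res.sum())} resonances requested"
        )
    positions = rng.choice(grid.n_buckets, size=int(n_res.sum()), replace=False)
    metabolite_buckets: list[list[int]] = []
    cursor = 0
    for r in n_res:
        metabolite_buckets.append(sorted(int(b) for b in positions[cursor:cursor + r]))
        cursor += r
    res_weight = [rng.uniform(0.5, 1.5, size=len(b)) for b in metabolite_buckets]

    counts = _resolve_cell_counts(cfg, rng)
    times = _level_names(cfg.n_times, _STUDY_TIMES, "T")
    doses = _level_names(cfg.n_doses, _STUDY_DOSES, "D")
    sample_time_idx, sample_dose_idx, sample_ids, animal_ids = [], [], [], []
    for ti in range(cfg.n_times):
        for di in range(cfg.n_doses):
            for a in range(counts[ti, di]):
                sample_time_idx.append(ti)
                sample_dose_idx.append(di)
                sample_ids.append(f"S{len(sample_ids):04d}")
                animal_ids.append(f"A{doses[di]}_{a:02d}")
    t_idx = np.asarray(sample_time_idx)
    d_idx = np.asarray(sample_dose_idx)
    n_samples = len(sample_ids)
    design = DesignTable(
        sample_id=tuple(sample_ids),
        dose=tuple(doses[i] for i in d_idx),
        time=tuple(times[i] for i in t_idx),
        animal_id=tuple(animal_ids),
    )

    # per-metabolite effect structure
    log_baseline = rng.normal(loc=0.0, scale=0.8, size=cfg.n_metabolites)
    aff_t = rng.random(cfg.n_metabolites) < cfg.affected_fraction_time
    aff_d = rng.random(cfg.n_metabolites) < cfg.affected_fraction_dose
    aff_i = rng.random(cfg.n_metabolites) < cfg.affected_fraction_interaction
    t_curves = np.zeros((cfg.n_metabolites, cfg.n_times))
    d_shapes = np.zeros((cfg.n_metabolites, cfg.n_doses))
    g_grids = np.zeros((cfg.n_metabolites, cfg.n_times, cfg.n_doses))
    for m in range(cfg.n_metabolites):
        if aff_t[m] and cfg.time_amplitude > 0:
            t_curves[m] = _time_curve(rng, cfg.n_times, cfg.time_amplitude)
        if aff_d[m] and cfg.dose_amplitude > 0:
            d_shapes[m] = _dose_shape(rng, cfg.n_doses, cfg.dose_amplitude)
        if aff_i[m] and cfg.interaction_amplitude > 0:
            g_grids[m] = _interaction_grid(
                rng, cfg.n_times, cfg.n_doses, cfg.interaction_amplitude,
                cfg.interaction_cells,
            )

    log_time = t_curves[:, t_idx].T             # samples x metabolites
    log_dose = d_shapes[:, d_idx].T
    log_inter = g_grids[:, t_idx, d_idx].T
    log_signal = log_baseline[None, :] + log_time + log_dose + log_inter
    noise = rng.normal(scale=cfg.sigma, size=log_signal.shape) if cfg.sigma > 0 else 0.0

    def to_buckets(log_conc: np.ndarray, rng_add: np.random.Generator | None) -> np.ndarray:
        conc = np.exp(log_conc)
        raw = np.zeros((n_samples, grid.n_buckets))
        for m, (bks, w) in enumerate(zip(metabolite_buckets, res_weight)):
            raw[:, bks] += conc[:, m][:, None] * w[None, :]
        raw += 1e-3  # constant spectral floor so empty buckets stay positive
        if cfg.additive_floor > 0 and rng_add is not None:
            raw = np.clip(raw + rng_add.normal(scale=cfg.additive_floor, size=raw.shape), 0.0, None)
        return raw

    raw_noisefree = to_buckets(log_signal, None)
    raw_noisy = to_buckets(log_signal + noise, rng)

    matrix0 = normalize_total_area(
        BucketMatrix(values=raw_noisefree, grid=grid, design=design)
    )
    matrix = normalize_total_area(
        BucketMatrix(values=raw_noisy, grid=grid, design=design)
    )

    # Per-entry noise variance summed over buckets, on the normalized scale.
    # Delta method around the noise-free row: a bucket of metabolite m with
    # noise-free share v0 has var sigma^2 v0^2 (1 - 2 S_m + Q), where S_m is
    # the metabolite's share of the row total (the closure term from
    # normalizing by a noisy total) and Q = sum_m S_m^2.
    v0 = matrix0.values
    var_sum = np.zeros(n_samples)
    shares = np.stack([v0[:, bks].sum(axis=1) for bks in metabolite_buckets], axis=1)
    q = np.sum(shares**2, axis=1)
    for m, bks in enumerate(metabolite_buckets):
        var_sum += np.sum(v0[:, bks] ** 2, axis=1) * (1.0 - 2.0 * shares[:, m] + q)
    s = float(np.mean(var_sum) * (np.exp(2 * cfg.sigma**2) - np.exp(cfg.sigma**2)))
    if cfg.additive_floor > 0:
        mean_total = float(np.mean(raw_noisefree.sum(axis=1)))
        s += grid.n_buckets * (cfg.additive_floor / mean_total) ** 2

    from .asca import decompose  # deferred: asca does not import simulate

    d0 = decompose(matrix0)
    truth = SyntheticTruth(
        log_baseline=log_baseline,
        log_time=log_time,
        log_dose=log_dose,
        log_interaction=log_inter,
        affected_time=aff_t,
        affected_dose=aff_d,
        affected_interaction=aff_i,
        metabolite_buckets=metabolite_buckets,
        noise_free=matrix0,
        true_shares=dict(d0.percent),
        sigma=cfg.sigma,
        interaction_cells=cfg.interaction_cells,
        _noise_ssq_per_entry=s,
    )
    return matrix, design, truth


@dataclass(frozen=True)
class NullBatchResult:
    """Per-dataset p-values from an analysis hook run on null cohorts."""

    pvalues: np.ndarray
    level: float

    @property
    def rejection_rate(self) -> float:
        return float(np.mean(self.pvalues <= self.level))


def simulate_null_batch(
    config: SyntheticConfig,
    n_datasets: int,
    hook: Callable[[BucketMatrix, DesignTable], float],
    level: float = 0.05,
) -> NullBatchResult:
    """Type-I-error harness: run ``hook`` on cohorts with all effects zeroed.

    ``hook(matrix, design)`` must return one p-value; failures are
    re-raised with the dataset index attached.
    """
    from dataclasses import replace as _replace

    null_cfg = _replace(
        config, time_amplitude=0.0, dose_amplitude=0.0, interaction_amplitude=0.0
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(n_datasets) % (2**31)
    pvals = np.empty(n_datasets)
    for i, s in enumerate(seeds):
        matrix, design, _ = simulate_cohort(_replace(null_cfg, seed=int(s)))
        try:
            pvals[i] = float(hook(matrix, design))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"analysis hook failed on null dataset {i}") from exc
    return NullBatchResult(pvalues=pvals, level=level)
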