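"""Permutation-based differential-expression test with an empirical null.

For each contrast (test condition vs the reference condition) a pooled-variance
two-sample T statistic is computed per gene. The null distribution of that
statistic is estimated empirically: the contrast's samples are relabeled over
every balanced reassignment except the identity, the T statistic is recomputed
for every gene under every reassignment, and the pooled values are smoothed
with a Gaussian kernel density estimate (Silverman's rule-of-thumb bandwidth).
Two-tailed p-values are read off the KDE's CDF; differentially expressed genes
are the ones with adjusted p <= alpha and |log2 fold change| >= a threshold
(defaults 0.05 and 1.0).

With two replicates per group the balanced-reassignment space has C(4,2)-1 = 5
non-identity elements, so "random permutation" reduces to exhaustive
enumeration; general group sizes are enumerated the same way.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from .errors import (CalibrationError, DegenerateVarianceError,
                     InvalidDesignError, ParameterError)
from .synthetic import StudyDesign

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.0


@dataclass(frozen=True)
class Contrast:
    """A two-condition comparison, test vs reference (reference = MEF-like)."""

    test: str
    reference: str

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise InvalidDesignError(
                f"contrast test and reference are both {self.test!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.test}_vs_{self.reference}"


def t_statistic(a, b) -> float:
    """Pooled-variance two-sample T statistic, mean(a) - mean(b) direction.

    Zero pooled variance with equal means gives 0; zero pooled variance with
    unequal means raises :class:`DegenerateVarianceError` (the statistic
    diverges and such genes are handled separately by the caller).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("group values must be finite")
    diff = a.mean() - b.mean()
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
        / (a.size + b.size - 2)
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means"
        )
    return float(diff / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))


def log2_fold_change(a, b) -> float:
    """Mean difference on the log2 scale (inputs are already log2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("group values must be finite")
    return float(a.mean() - b.mean())


def _t_matrix(values: np.ndarray, idx_a, idx_b):
    """Vectorized pooled T and mean difference for all genes at once.

    Returns (t, diff, degenerate) where ``degenerate`` flags genes whose
    pooled variance is exactly zero; their ``t`` entry is 0 when the means
    agree and NaN otherwise.
    """
    a = values[:, idx_a]
    b = values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1)
           + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2)
    degenerate = sp2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[degenerate & (diff == 0.0)] = 0.0
    t[degenerate & (diff != 0.0)] = np.nan
    return t, diff, degenerate


def balanced_assignments(test_samples: list[str], ref_samples: list[str]
                         ) -> list[tuple[list[str], list[str]]]:
    """All balanced relabelings of the contrast's samples except the identity.

    Every way of choosing |test| of the pooled samples as the pseudo-test
    group is enumerated; the observed labeling itself is excluded. For the
    2 vs 2 case this yields C(4,2) - 1 = 5 reassignments.
    """
    pooled = list(test_samples) + list(ref_samples)
    k = len(test_samples)
    observed = frozenset(test_samples)
    out = []
    for combo in itertools.combinations(range(len(pooled)), k):
        pseudo_test = [pooled[i] for i in combo]
        if frozenset(pseudo_test) == observed:
            continue
        pseudo_ref = [pooled[i] for i in range(len(pooled)) if i not in combo]
        out.append((pseudo_test, pseudo_ref))
    if len(out) < 2:
        raise InvalidDesignError(
            "fewer than 2 distinct balanced reassignments are possible"
        )
    return out


def permuted_t_pool(matrix: pd.DataFrame, design: StudyDesign,
                    contrast: Contrast) -> tuple[np.ndarray, int]:
    """Pool T statistics over all genes and all non-identity reassignments.

    Returns (pool, n_skipped) where ``n_skipped`` counts degenerate-variance
    values that were dropped from the pool (logged).
    """
    test_s = design.samples_for(contrast.test)
    ref_s = design.samples_for(contrast.reference)
    col = {s: i for i, s in enumerate(matrix.columns)}
    values = matrix.to_numpy(dtype=float)
    pool_parts = []
    n_skipped = 0
    for pseudo_test, pseudo_ref in balanced_assignments(test_s, ref_s):
        idx_a = [col[s] for s in pseudo_test]
        idx_b = [col[s] for s in pseudo_ref]
        t, _, degenerate = _t_matrix(values, idx_a, idx_b)
        n_skipped += int(degenerate.sum())
        pool_parts.append(t[~degenerate])
    pool = np.concatenate(pool_parts) if pool_parts else np.empty(0)
    if n_skipped:
        logger.info("permuted_t_pool(%s): skipped %d degenerate-variance "
                    "values", contrast.name, n_skipped)
    return pool, n_skipped


class EmpiricalNull:
    """Gaussian-KDE-smoothed null distribution of pooled permuted T values.

    The density is a Gaussian kernel density estimate with Silverman's
    rule-of-thumb bandwidth, 0.9 * min(sd, IQR/1.34) * n^(-1/5). The robust
    scale matters: with two replicates per group a near-degenerate gene can
    contribute a permuted T in the thousands, and a bandwidth proportional to
    the plain standard deviation would oversmooth the entire null. The CDF is
    obtained by trapezoidal integration on an adaptive grid spanning
    [min - 5*bw, max + 5*bw]: dense where the bulk of the pool lies, locally
    refined around isolated outliers so their kernel mass is still captured.
    P-values derived from it are floored at 1/(pool size + 1) so they are
    strictly positive.
    """

    MIN_POOL = 100

    def __init__(self, pool: np.ndarray, *, bandwidth: float | None = None,
                 grid_size: int = 4096) -> None:
        pool = np.asarray(pool, dtype=float)
        if pool.size < self.MIN_POOL:
            raise CalibrationError(
                f"permutation pool too small ({pool.size} < {self.MIN_POOL})"
            )
        self.pool_size = int(pool.size)
        sd = float(pool.std(ddof=1))
        if bandwidth is None:
            q25, q75 = np.percentile(pool, [25, 75])
            scale = min(sd, (q75 - q25) / 1.349)
            if scale <= 0.0:
                scale = sd
            bandwidth = 0.9 * scale * pool.size ** (-0.2)
        if not bandwidth > 0.0 or sd <= 0.0:
            raise CalibrationError("permutation pool has no spread")
        self.bandwidth = float(bandwidth)
        self._kde = sps.gaussian_kde(pool, bw_method=self.bandwidth / sd)
        lo = pool.min() - 5.0 * self.bandwidth
        hi = pool.max() + 5.0 * self.bandwidth
        core_lo, core_hi = np.quantile(pool, [0.0005, 0.9995])
        core = np.linspace(core_lo - 5.0 * self.bandwidth,
                           core_hi + 5.0 * self.bandwidth, grid_size)
        parts = [np.array([lo, hi]), core]
        outliers = np.unique(pool[(pool < core[0]) | (pool > core[-1])])
        for x in outliers:
            parts.append(np.linspace(x - 6.0 * self.bandwidth,
                                     x + 6.0 * self.bandwidth, 33))
        grid = np.unique(np.concatenate(parts))
        self.grid = grid[(grid >= lo) & (grid <= hi)]
        self._density = self._kde(self.grid)
        cdf = cumulative_trapezoid(self._density, self.grid, initial=0.0)
        self.total_mass = float(cdf[-1])
        self._cdf_grid = np.clip(cdf / self.total_mass, 0.0, 1.0)
        self.p_floor = 1.0 / (self.pool_size + 1)

    def density(self, x) -> np.ndarray:
        """Exact KDE density at ``x`` (not interpolated from the grid)."""
        return self._kde(np.atleast_1d(np.asarray(x, dtype=float)))

    def cdf(self, x):
        """CDF at ``x`` by interpolation on the integration grid."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid, self._cdf_grid, left=0.0, right=1.0)


def fit_empirical_null(pool: np.ndarray, **kwargs) -> EmpiricalNull:
    """Fit the Gaussian-KDE empirical null to a pool of permuted T values."""
    return EmpiricalNull(pool, **kwargs)


def empirical_p(t, null: EmpiricalNull):
    """Two-tailed empirical p-value(s) of T statistic(s) under the null.

    p = min(1, 2 * min(CDF(t), 1 - CDF(t))), floored at 1/(pool size + 1).
    NaN inputs (degenerate-variance genes) yield p = 1.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    cdf = null.cdf(np.atleast_1d(t))
    p = 2.0 * np.minimum(cdf, 1.0 - cdf)
    p = np.clip(p, null.p_floor, 1.0)
    p[np.isnan(np.atleast_1d(t))] = 1.0
    return float(p[0]) if scalar else p


def select_degs(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                lfc: float = DEFAULT_LFC) -> pd.DataFrame:
    """Attach up/down/ns calls using boundary-inclusive thresholds.

    up: p_adj <= alpha and log2fc >= lfc; down: p_adj <= alpha and
    log2fc <= -lfc; everything else ns.
    """
    if alpha <= 0 or lfc < 0:
        raise ParameterError("alpha must be > 0 and lfc >= 0")
    out = table.copy()
    sig = out["p_adj"] <= alpha
    call = np.where(sig & (out["log2fc"] >= lfc), "up",
                    np.where(sig & (out["log2fc"] <= -lfc), "down", "ns"))
    out["call"] = call
    return out


def run_contrast(matrix: pd.DataFrame, design: StudyDesign, contrast: Contrast,
                 *, alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC,
                 fdr_adjust: bool = False,
                 null: EmpiricalNull | None = None) -> pd.DataFrame:
    """Full per-gene statistics table for one contrast.

    Columns: t_value, log2fc, p_adj, call. Degenerate-variance genes get
    t_value NaN, p_adj 1 and call ns. ``fdr_adjust`` applies an optional
    Benjamini-Hochberg correction on top of the empirical p-values (off by
    default: the empirical-null p is itself treated as the adjusted p).
    A pre-fitted ``null`` may be supplied to share one null across contrasts.
    """
    test_s = design.samples_for(contrast.test)
    ref_s = design.samples_for(contrast.reference)
    col = {s: i for i, s in enumerate(matrix.columns)}
    values = matrix.to_numpy(dtype=float)
    idx_a = [col[s] for s in test_s]
    idx_b = [col[s] for s in ref_s]
    t, diff, degenerate = _t_matrix(values, idx_a, idx_b)
    if null is None:
        pool, _ = permuted_t_pool(matrix, design, contrast)
        null = fit_empirical_null(pool)
    p = empirical_p(t, null)
    if fdr_adjust:
        p = sps.false_discovery_control(p, method="bh")
    table = pd.DataFrame(
        {"t_value": t, "log2fc": diff, "p_adj": p}, index=matrix.index
    )
    table.loc[degenerate, "p_adj"] = 1.0
    return select_degs(table, alpha=alpha, lfc=lfc)


def run_all_contrasts(matrix: pd.DataFrame, design: StudyDesign, *,
                      alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC,
                      fdr_adjust: bool = False,
                      permutation_scope: str = "within",
                      ) -> dict[str, pd.DataFrame]:
    """Statistics tables for every non-reference condition vs the reference.

    ``permutation_scope`` selects the null: "within" fits one empirical null
    per contrast from that contrast's 4 (or 2n) samples; "pooled" pools the
    permuted T values of all contrasts into a single shared null.
    """
    contrasts = [Contrast(c, design.reference)
                 for c in design.contrast_conditions]
    if permutation_scope not in {"within", "pooled"}:
        raise ParameterError(
            f"unknown permutation_scope {permutation_scope!r}"
        )
    shared_null = None
    if permutation_scope == "pooled":
        pools = [permuted_t_pool(matrix, design, c)[0] for c in contrasts]
        shared_null = fit_empirical_null(np.concatenate(pools))
    return {
        c.test: run_contrast(matrix, design, c, alpha=alpha, lfc=lfc,
                             fdr_adjust=fdr_adjust, null=shared_null)
        for c in contrasts
    }


def write_contrast_table(table: pd.DataFrame, path) -> None:
    """Write a per-contrast result table as TSV (gene, t, log2fc, p, call)."""
    table.to_csv(path, sep="\t", index_label="gene")
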