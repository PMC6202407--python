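"""Seeded simulation of microarray-like log2 expression data with known truth.

The generator emulates the structure of a small multi-condition two-color
array study: a handful of cell populations (by default MEF, MDSC, iMSC and
sort-iMSC), two biological replicates per condition, log2 intensities with a
per-gene baseline, additive condition effects planted relative to the first
(reference) condition, and i.i.d. Gaussian noise on the log2 scale.

Every planted effect is recorded in a :class:`SyntheticTruth` object so that
downstream stages (normalization, differential testing, pattern clustering)
can be validated against known ground truth without any external download.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, ParameterError

logger = logging.getLogger(__name__)

#: Default condition names; the first entry is the reference for all contrasts.
DEFAULT_CONDITIONS = ("MEF", "MDSC", "iMSC", "sort-iMSC")


@dataclass(frozen=True)
class StudyDesign:
    """Assignment of array samples to biological conditions.

    Parameters
    ----------
    sample_ids
        Unique labels of the arrays, in column order of the expression matrix.
    condition_of
        Mapping from sample id to condition name.
    conditions
        Ordered condition names; the first is the reference condition used by
        all contrasts.
    """

    sample_ids: tuple[str, ...]
    condition_of: dict[str, str] = field(compare=True)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidDesignError("sample ids must be unique")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise InvalidDesignError("conditions must be non-empty and unique")
        for s in self.sample_ids:
            if s not in self.condition_of:
                raise InvalidDesignError(f"sample {s!r} has no condition")
            if self.condition_of[s] not in self.conditions:
                raise InvalidDesignError(
                    f"sample {s!r} maps to unknown condition {self.condition_of[s]!r}"
                )
        for c in self.conditions:
            if len(self.samples_for(c)) < 2:
                raise InvalidDesignError(
                    f"condition {c!r} has fewer than 2 samples; "
                    "the permutation null needs at least 2 per group"
                )

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids assigned to ``condition``, in design order."""
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def contrast_conditions(self) -> tuple[str, ...]:
        """Non-reference conditions, i.e. the test side of each contrast."""
        return self.conditions[1:]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.sample_ids),
             "condition": [self.condition_of[s] for s in self.sample_ids]}
        )


def make_design(replicates: int = 2,
                conditions: tuple[str, ...] | list[str] = DEFAULT_CONDITIONS,
                ) -> StudyDesign:
    """Build a balanced design with ``replicates`` samples per condition.

    Sample ids are deterministic: ``<condition>_r<i>`` with ``i`` starting
    at 1. ``replicates`` must be at least 2 because the within-contrast
    permutation null requires at least two samples per group.
    """
    if replicates < 2:
        raise InvalidDesignError(
            f"replicates must be >= 2 (got {replicates}); "
            "the permutation null needs >= 2 samples per group"
        )
    conditions = tuple(conditions)
    if not conditions or len(set(conditions)) != len(conditions):
        raise InvalidDesignError("conditions must be non-empty and unique")
    condition_of = {
        f"{c}_r{i + 1}": c for c in conditions for i in range(replicates)
    }
    sample_ids = tuple(condition_of)
    return StudyDesign(sample_ids=sample_ids, condition_of=condition_of,
                       conditions=conditions)


def read_design(path) -> StudyDesign:
    """Read a two-column sample/condition TSV into a :class:`StudyDesign`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"}.issubset(df.columns):
        raise InvalidDesignError(
            f"design table {path} must have 'sample' and 'condition' columns"
        )
    conditions = tuple(dict.fromkeys(df["condition"]))
    return StudyDesign(
        sample_ids=tuple(df["sample"]),
        condition_of=dict(zip(df["sample"], df["condition"])),
        conditions=conditions,
    )


def write_design(design: StudyDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SyntheticTruth:
    """Record of every planted effect in a simulated dataset.

    Attributes
    ----------
    signs
        Integer DataFrame (genes x contrasts) with entries in {-1, 0, +1};
        columns are the non-reference conditions in design order. A +1 in
        column ``c`` means the gene was shifted up by ``effect_size`` log2
        units in condition ``c`` relative to the reference.
    effect_size
        Magnitude of every planted shift, in log2 units (>= 0).
    noise_sd
        Standard deviation of the i.i.d. Gaussian noise on the log2 scale.
    baseline
        Per-gene baseline log2 intensity shared by all samples.
    seed
        Seed of the random generator that produced the dataset.
    """

    signs: pd.DataFrame
    effect_size: float
    noise_sd: float
    baseline: pd.Series
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ParameterError("effect_size must be finite and >= 0")
        if not np.isfinite(self.noise_sd) or self.noise_sd <= 0:
            raise ParameterError("noise_sd must be finite and > 0")

    @property
    def planted_genes(self) -> pd.Index:
        """Genes whose sign vector is not all zero."""
        return self.signs.index[(self.signs != 0).any(axis=1)]

    def to_frame(self) -> pd.DataFrame:
        out = self.signs.copy()
        out.insert(0, "baseline", self.baseline)
        return out


def _nonzero_sign_vectors(n_contrasts: int) -> np.ndarray:
    """All sign vectors in {-1,0,+1}^n_contrasts except the all-zero one."""
    vecs = [v for v in itertools.product((-1, 0, 1), repeat=n_contrasts)
            if any(v)]
    return np.array(vecs, dtype=int)


def simulate_dataset(n_genes: int,
                     design: StudyDesign,
                     *,
                     deg_fraction: float = 0.1,
                     effect_size: float = 2.0,
                     noise_sd: float = 0.25,
                     baseline_range: tuple[float, float] = (6.0, 12.0),
                     seed: int = 0,
                     ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a log2 expression matrix with planted differential expression.

    A fraction ``deg_fraction`` of genes (rounded to the nearest integer
    count) receives a sign vector drawn uniformly from the 3^C - 1 nonzero
    patterns over the design's C contrasts; each nonzero entry shifts every
    replicate of that condition by ``+-effect_size`` log2 units relative to
    the reference condition. Baselines are uniform on ``baseline_range`` so
    that quantile normalization is exercised nontrivially.

    Returns the matrix (genes x samples) and the :class:`SyntheticTruth`.
    Identical arguments and seed give a bit-identical matrix.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not 0.0 <= deg_fraction <= 1.0:
        raise ParameterError("deg_fraction must be in [0, 1]")
    if not np.isfinite(effect_size) or effect_size < 0:
        raise ParameterError("effect_size must be finite and >= 0")
    if not np.isfinite(noise_sd) or noise_sd <= 0:
        raise ParameterError("noise_sd must be finite and > 0")
    lo, hi = baseline_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ParameterError("baseline_range must be a finite (lo, hi) pair")

    rng = np.random.default_rng(seed)
    contrasts = design.contrast_conditions
    width = len(str(n_genes))
    genes = pd.Index([f"g{i + 1:0{width}d}" for i in range(n_genes)],
                     name="gene")

    n_deg = int(round(n_genes * deg_fraction))
    signs = np.zeros((n_genes, len(contrasts)), dtype=int)
    if n_deg > 0:
        if not contrasts:
            raise InvalidDesignError(
                "cannot plant DEGs in a single-condition design"
            )
        deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
        patterns = _nonzero_sign_vectors(len(contrasts))
        signs[deg_idx] = patterns[rng.integers(0, len(patterns), size=n_deg)]

    baseline = rng.uniform(lo, hi, size=n_genes)
    values = np.empty((n_genes, design.n_samples))
    cond_offset = {c: signs[:, j] * effect_size
                   for j, c in enumerate(contrasts)}
    for j, s in enumerate(design.sample_ids):
        cond = design.condition_of[s]
        offset = cond_offset.get(cond, 0.0)
        values[:, j] = baseline + offset
    values += rng.normal(0.0, noise_sd, size=values.shape)

    matrix = pd.DataFrame(values, index=genes,
                          columns=list(design.sample_ids))
    truth = SyntheticTruth(
        signs=pd.DataFrame(signs, index=genes, columns=list(contrasts)),
        effect_size=float(effect_size),
        noise_sd=float(noise_sd),
        baseline=pd.Series(baseline, index=genes, name="baseline"),
        seed=int(seed),
    )
    logger.info("simulated %d genes x %d samples (%d planted DEGs, seed %d)",
                n_genes, design.n_samples, n_deg, seed)
    return matrix, truth


def null_dataset(n_genes: int,
                 design: StudyDesign,
                 noise_sd: float = 0.25,
                 seed: int = 0,
                 *,
                 baseline_range: tuple[float, float] = (6.0, 12.0),
                 ) -> pd.DataFrame:
    """Simulate a dataset with no condition effect (type-I-error calibration)."""
    matrix, _ = simulate_dataset(
        n_genes, design, deg_fraction=0.0, effect_size=0.0,
        noise_sd=noise_sd, baseline_range=baseline_range, seed=seed,
    )
    return matrix
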