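"""Synthetic expression matrices with planted co-expression structure.

A single latent factor per block drives correlation: gene g in block b is

    expr = center + scale * (loading * f_b + noise_sd * eps) / sqrt(loading^2 + noise_sd^2)

with f_b and eps standard normal, so every within-block gene pair has
expected Pearson correlation

    r_within = loading^2 / (loading^2 + noise_sd^2)

and genes in different blocks are uncorrelated.  Background genes are
independent noise in the same expressed range; low-expression genes sit
below the quantile-filter cutoff so filtering removes them.  With strong
separation (r_within well above the edge threshold, sample size large
enough that null correlations stay below it) each block becomes a clique
in the thresholded graph and the whole selection pipeline has closed-form
expected behavior (:func:`planted_expectations`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "loading_noise_for_r",
    "generate_block_expression",
    "generate_validation_cohort",
    "planted_expectations",
]

# Expressed genes are centered well above the filter cutoff (5), the
# low-expression mode well below it, mimicking the bimodal distribution of
# per-gene upper-quantile expression in log-scale tumor array data.
EXPRESSED_CENTER = 8.0
EXPRESSED_SCALE = 1.5
LOW_CENTER = 2.0
LOW_SCALE = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults plant 5 blocks of 10 genes with expected within-block
    r = 0.8 (loading 0.9, noise sd 0.45) across 500 samples, plus 100
    uncorrelated background genes and a low-expression fraction of 0.4
    of the expressed genes.
    """

    n_blocks: int = 5
    block_size: int = 10
    n_samples: int = 500
    within_loading: float = 0.9
    noise_sd: float = 0.45
    n_background: int = 100
    low_expression_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.block_size, self.n_samples, self.n_background) < 0:
            raise ValueError("all counts must be >= 0")
        if not 0.0 < self.within_loading <= 1.0:
            raise ValueError(f"within_loading must be in (0, 1], got {self.within_loading}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.low_expression_fraction < 1.0:
            raise ValueError("low_expression_fraction must be in [0, 1)")

    @property
    def expected_within_r(self) -> float:
        """Expected Pearson correlation of two genes in the same block."""
        l2 = self.within_loading**2
        return l2 / (l2 + self.noise_sd**2)

    @property
    def n_low(self) -> int:
        """Low-expression gene count: fraction of the expressed genes."""
        n_expressed = self.n_blocks * self.block_size + self.n_background
        return round(self.low_expression_fraction * n_expressed)


def loading_noise_for_r(expected_r: float, loading: float = 0.9) -> tuple[float, float]:
    """Noise sd achieving a target expected within-block correlation at a
    given loading: sd = loading * sqrt((1 - r) / r)."""
    if not 0.0 < expected_r < 1.0:
        raise ValueError(f"expected_r must be in (0, 1), got {expected_r}")
    return loading, loading * math.sqrt((1.0 - expected_r) / expected_r)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated matrix."""

    block_of: dict[str, int]
    background_genes: list[str]
    low_genes: list[str]
    expected_within_r: float
    spec: SyntheticSpec = field(repr=False, default=None)


def _gene_names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    block = [
        f"BLK{b:02d}_G{i:02d}"
        for b in range(spec.n_blocks)
        for i in range(spec.block_size)
    ]
    background = [f"BG_{i:03d}" for i in range(spec.n_background)]
    low = [f"LOW_{i:03d}" for i in range(spec.n_low)]
    return block, background, low


def _draw(
    spec: SyntheticSpec, rng: np.random.Generator, n_samples: int, noise_sd: float,
    sample_prefix: str,
) -> pd.DataFrame:
    block_names, background_names, low_names = _gene_names(spec)
    samples = [f"{sample_prefix}{j:04d}" for j in range(n_samples)]
    norm = math.sqrt(spec.within_loading**2 + noise_sd**2)
    factors = rng.standard_normal((spec.n_blocks, n_samples))
    rows = []
    for b in range(spec.n_blocks):
        eps = rng.standard_normal((spec.block_size, n_samples))
        z = (spec.within_loading * factors[b] + noise_sd * eps) / norm
        rows.append(EXPRESSED_CENTER + EXPRESSED_SCALE * z)
    blocks = np.vstack(rows) if rows else np.empty((0, n_samples))
    background = EXPRESSED_CENTER + EXPRESSED_SCALE * rng.standard_normal(
        (spec.n_background, n_samples)
    )
    low = LOW_CENTER + LOW_SCALE * rng.standard_normal((len(low_names), n_samples))
    values = np.vstack([blocks, background, low])
    expr = pd.DataFrame(
        values, index=block_names + background_names + low_names, columns=samples
    )
    expr.index.name = "gene"
    return expr


def generate_block_expression(spec: SyntheticSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes × samples matrix with planted block structure.

    Deterministic given ``spec.seed``.  Returns the matrix and the ground
    truth (block assignment, background and low-expression gene lists, and
    the analytic expected within-block correlation).
    """
    rng = np.random.default_rng(spec.seed)
    expr = _draw(spec, rng, spec.n_samples, spec.noise_sd, "S")
    block_names, background_names, low_names = _gene_names(spec)
    truth = SyntheticTruth(
        block_of={g: i // spec.block_size for i, g in enumerate(block_names)},
        background_genes=background_names,
        low_genes=low_names,
        expected_within_r=spec.expected_within_r,
        spec=spec,
    )
    return expr, truth


def generate_validation_cohort(
    spec: SyntheticSpec,
    n_samples: int | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """A paired cohort over the same gene universe and block structure but
    new samples — optionally a different noise level, emulating an
    independent population or platform for cross-dataset evaluation."""
    n_samples = spec.n_samples if n_samples is None else n_samples
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    seed = spec.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    return _draw(spec, rng, n_samples, noise_sd, "V")


def planted_expectations(
    spec: SyntheticSpec, threshold: float, redundancy: int, dm_size: int
) -> dict[str, int]:
    """Expected eligible/DM/predictable counts under perfect edge recovery.

    Assumes the threshold separates within-block from background
    correlation exactly, so each block is an isolated clique of
    ``block_size`` genes.  Eligibility requires block_size - 1 >=
    redundancy.  Greedy selection then visits blocks round-robin (each DM
    pick lowers its own block's pruned degrees below fresh blocks'); a
    block's remaining genes all become predictable the moment it holds
    ``redundancy`` DM genes, after which its edges are gone.  Hence at
    most ``redundancy`` DM genes are ever drawn per block.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if threshold >= spec.expected_within_r:
        raise ValueError(
            f"threshold {threshold} is not below the expected within-block "
            f"correlation {spec.expected_within_r:.3f}; blocks would not be cliques"
        )
    if spec.block_size - 1 < redundancy:
        return {"n_eligible": 0, "n_dm": 0, "n_predictable": 0}
    n_eligible = spec.n_blocks * spec.block_size
    n_dm = min(dm_size, redundancy * spec.n_blocks)
    full_rounds, rem = divmod(n_dm, spec.n_blocks)
    per_block = [full_rounds + (1 if b < rem else 0) for b in range(spec.n_blocks)]
    complete = sum(1 for c in per_block if c >= redundancy)
    return {
        "n_eligible": n_eligible,
        "n_dm": n_dm,
        "n_predictable": complete * (spec.block_size - redundancy),
    }
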