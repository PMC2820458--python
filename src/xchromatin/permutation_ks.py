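"""Permutation-sampling two-sample Kolmogorov-Smirnov testing of chromosome
arms against the genome-wide value pool.

Each permutation draws a fixed-size random sample (without replacement by
default) from one arm's values and an equally sized sample from the pooled
genome values, and runs an asymptotic two-sided two-sample KS test.  The
full distribution of P values over permutations is the result; Bonferroni
adjustment (truncated at 1.0) accounts for the number of arms tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZE = 1000
DOT_SAMPLE_SIZE = 200


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic P value.

    D = sup |ECDF_a - ECDF_b|.  The asymptotic P value is appropriate for
    the sample sizes used throughout (>= 200).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample: empty sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted P value, truncated at 1.0."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


@dataclass
class PermutationResult:
    arm: str
    n_perm: int
    n_sample: int
    stats: pd.DataFrame  # columns: permutation, D, p, p_adj
    median_p: float
    median_p_adj: float
    frac_below: float  # fraction of adjusted P values below alpha
    alpha: float

    def __post_init__(self) -> None:
        assert len(self.stats) == self.n_perm


def default_sample_sizes(annotation: GenomeAnnotation) -> dict[str, int]:
    """Default sampling rule: 1000 per arm, 200 for the small dot arm."""
    return {
        a.name: DOT_SAMPLE_SIZE if a.arm_class == "dot" else DEFAULT_SAMPLE_SIZE
        for a in annotation.arms
    }


def permutation_arm_test(
    arm_values: Mapping[str, Sequence[float]],
    genome_values: Sequence[float] | None = None,
    n_sample: int | Mapping[str, int] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    replace: bool = False,
    exclude_self: bool = False,
) -> dict[str, PermutationResult]:
    """Permutation KS test of each arm's values against the genome pool.

    ``n_sample`` defaults to 1000 per arm.  By default the genome pool
    includes the tested arm's own values; ``exclude_self`` drops them.  If
    an arm holds fewer values than its sample size, the sample size is
    reduced with a warning.  Bonferroni adjustment uses the number of arms
    tested.  Deterministic for a fixed seed.
    """
    arms = {k: np.asarray(v, dtype=float) for k, v in arm_values.items()}
    for name, vals in arms.items():
        if vals.size == 0:
            raise ValueError(f"arm {name!r} has no values")
    pool_all = (
        np.concatenate(list(arms.values()))
        if genome_values is None
        else np.asarray(genome_values, dtype=float)
    )
    m = len(arms)
    rng = np.random.default_rng(seed)
    results: dict[str, PermutationResult] = {}
    for name, vals in arms.items():
        if isinstance(n_sample, Mapping):
            size = n_sample.get(name, DEFAULT_SAMPLE_SIZE)
        elif n_sample is None:
            size = DEFAULT_SAMPLE_SIZE
        else:
            size = int(n_sample)
        if not replace and size > vals.size:
            logger.warning(
                "arm %s: sample size reduced from %d to %d", name, size, vals.size
            )
            size = vals.size
        if exclude_self and genome_values is None:
            pool = np.concatenate([v for k, v in arms.items() if k != name])
        else:
            pool = pool_all
        Ds = np.empty(n_perm)
        ps = np.empty(n_perm)
        for i in range(n_perm):
            sample_arm = rng.choice(vals, size=size, replace=replace)
            sample_pool = rng.choice(pool, size=size, replace=replace)
            Ds[i], ps[i] = ks_two_sample(sample_arm, sample_pool)
        p_adj = np.minimum(1.0, ps * m)
        stats_df = pd.DataFrame(
            {"permutation": np.arange(1, n_perm + 1), "D": Ds, "p": ps,
             "p_adj": p_adj}
        )
        results[name] = PermutationResult(
            arm=name,
            n_perm=n_perm,
            n_sample=size,
            stats=stats_df,
            median_p=float(np.median(ps)),
            median_p_adj=float(np.median(p_adj)),
            frac_below=float(np.mean(p_adj < alpha)),
            alpha=alpha,
        )
    return results


def results_table(results: Mapping[str, PermutationResult]) -> pd.DataFrame:
    """Long table: one row per arm x permutation."""
    frames = []
    for name, res in results.items():
        df = res.stats.copy()
        df.insert(0, "arm", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summary_table(results: Mapping[str, PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm": r.arm,
                "n_perm": r.n_perm,
                "n_sample": r.n_sample,
                "median_p": r.median_p,
                "median_p_adj": r.median_p_adj,
                "frac_adj_below_alpha": r.frac_below,
                "alpha": r.alpha,
            }
            for r in results.values()
        ]
    )
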