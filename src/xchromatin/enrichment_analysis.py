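"""Per-arm ratio statistics, X-vs-autosome fold enrichment, cross-sample
correlations, percentile-rank enrichment classes, and expression / sex-bias
association tests.

"N-fold higher" is the ratio of linear-scale geometric means,
F = 2^(mean log2 ratio on X genes - mean log2 ratio on autosome genes),
the definition self-consistent with handling all quantities as log2 ratios.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .permutation_ks import bonferroni, ks_two_sample

logger = logging.getLogger(__name__)


def compare_arms(
    values: pd.Series,
    gene_arms: pd.Series,
    min_genes: int = 2,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Pairwise KS tests of per-gene value distributions between arms.

    Bonferroni adjustment defaults to the number of pairs tested.  Arms with
    fewer than ``min_genes`` values are skipped with a warning.
    """
    values = values.dropna()
    arms = gene_arms.reindex(values.index)
    groups = {}
    for arm, sub in values.groupby(arms):
        if len(sub) < min_genes:
            logger.warning("compare_arms: arm %s skipped (<%d genes)", arm, min_genes)
            continue
        groups[arm] = sub.to_numpy()
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = n_comparisons if n_comparisons is not None else max(len(pairs), 1)
    rows = []
    for a, b in pairs:
        D, p = ks_two_sample(groups[a], groups[b])
        rows.append(
            {"arm_a": a, "arm_b": b, "n_a": len(groups[a]), "n_b": len(groups[b]),
             "D": D, "p": p, "p_adj": bonferroni(p, m), "m": m}
        )
    return pd.DataFrame(rows)


def fold_enrichment(
    values: pd.Series,
    gene_arms: pd.Series,
    annotation=None,
    include_dot: bool = True,
) -> float:
    """X-vs-autosome fold: F = 2^(mean X log2 ratio - mean autosome log2 ratio).

    ``gene_arms`` maps gene id to arm name; ``annotation`` (if given)
    supplies arm classes, otherwise fly naming conventions are used.  The
    dot chromosome counts as an autosome ("all autosome genes") unless
    ``include_dot`` is False.
    """
    from .genome_model import infer_arm_class

    values = values.dropna()
    arms = gene_arms.reindex(values.index)
    if annotation is not None:
        cls = arms.map({a.name: a.arm_class for a in annotation.arms})
    else:
        cls = arms.map(infer_arm_class)
    x_vals = values[cls == "X"]
    if include_dot:
        auto_vals = values[cls != "X"]
    else:
        auto_vals = values[cls == "major_autosome"]
    if x_vals.empty or auto_vals.empty:
        raise ValueError("fold_enrichment: empty X or autosome gene set")
    return float(2.0 ** (x_vals.mean() - auto_vals.mean()))


def cross_correlations(
    matrix: pd.DataFrame,
    gene_arms: pd.Series,
    annotation=None,
) -> pd.DataFrame:
    """Spearman correlation between all sample pairs, X and autosomes
    separately, over the genes present (non-missing) in every sample."""
    from .genome_model import infer_arm_class

    complete = matrix.dropna()
    arms = gene_arms.reindex(complete.index)
    if annotation is not None:
        cls = arms.map({a.name: a.arm_class for a in annotation.arms})
    else:
        cls = arms.map(infer_arm_class)
    subsets = {"X": complete[cls == "X"], "autosomes": complete[cls != "X"]}
    rows = []
    for subset_name, sub in subsets.items():
        if len(sub) < 3:
            raise ValueError(
                f"cross_correlations: <3 shared genes in subset {subset_name}"
            )
        for a, b in itertools.combinations(matrix.columns, 2):
            rho, p = stats.spearmanr(sub[a], sub[b])
            rows.append(
                {"sample_a": a, "sample_b": b, "subset": subset_name,
                 "rho": float(rho), "p": float(p), "n": len(sub)}
            )
    return pd.DataFrame(rows)


def percentile_classes(
    values: pd.Series, hi: float = 0.90, lo: float = 0.10
) -> pd.Series:
    """Per-gene enrichment class from the percentile rank of the ratio.

    Percentile rank uses mean ranks for ties scaled as (rank - 0.5) / n;
    strict inequalities (> hi enriched, < lo depleted) leave boundary ties
    in neither class.  With distinct values this yields the top and bottom
    deciles at the default cuts, assuring similar class sizes.
    """
    if hi <= lo:
        raise ValueError("hi percentile must exceed lo")
    values = values.dropna()
    if len(values) < 10:
        raise ValueError("percentile_classes: need >= 10 genes")
    ranks = stats.rankdata(values.to_numpy(), method="average")
    pct = (ranks - 0.5) / len(values)
    out = np.where(pct > hi, "enriched", np.where(pct < lo, "depleted", "neither"))
    return pd.Series(out, index=values.index, name="class")


def expression_association(
    classes: pd.Series,
    expression: pd.Series,
    n_tests: int = 1,
) -> dict:
    """Expression fold between mark-enriched and mark-depleted genes.

    fold = 2^(mean log2 expression of enriched - mean of depleted); KS test
    between the two expression distributions, Bonferroni-adjusted over the
    ``n_tests`` association tests performed in the analysis run.
    """
    enr = expression.reindex(classes.index[classes == "enriched"]).dropna()
    dep = expression.reindex(classes.index[classes == "depleted"]).dropna()
    if enr.empty or dep.empty:
        raise ValueError("expression_association: empty class")
    D, p = ks_two_sample(enr, dep)
    return {
        "fold": float(2.0 ** (enr.mean() - dep.mean())),
        "mean_enriched": float(enr.mean()),
        "mean_depleted": float(dep.mean()),
        "n_enriched": len(enr),
        "n_depleted": len(dep),
        "D": D,
        "p": p,
        "p_adj": bonferroni(p, n_tests),
    }


def sexbias_association(
    values: pd.Series,
    gene_arms: pd.Series,
    labels: pd.Series,
    sex: str,
    annotation=None,
    n_tests: int = 1,
) -> dict:
    """Mean X-chromosome ratio per sex-bias class and biased-vs-non-biased KS.

    ``labels`` holds ``{sex}_biased`` / ``non_biased`` (other labels are
    treated as a third class and ignored in the test).  Genes without a
    label are dropped with a logged count.
    """
    from .genome_model import infer_arm_class

    values = values.dropna()
    arms = gene_arms.reindex(values.index)
    if annotation is not None:
        cls = arms.map({a.name: a.arm_class for a in annotation.arms})
    else:
        cls = arms.map(infer_arm_class)
    x_vals = values[cls == "X"]
    lab = labels.reindex(x_vals.index)
    n_dropped = int(lab.isna().sum())
    if n_dropped:
        logger.info("sexbias_association: %d unlabeled X genes dropped", n_dropped)
    x_vals = x_vals[lab.notna()]
    lab = lab.dropna()
    biased = x_vals[lab == f"{sex}_biased"]
    nonbiased = x_vals[lab == "non_biased"]
    if biased.empty or nonbiased.empty:
        raise ValueError("sexbias_association: need both biased and non-biased genes")
    D, p = ks_two_sample(biased, nonbiased)
    class_means = x_vals.groupby(lab.to_numpy()).mean().to_dict()
    return {
        "class_means": class_means,
        "mean_biased": float(biased.mean()),
        "mean_nonbiased": float(nonbiased.mean()),
        "n_biased": len(biased),
        "n_nonbiased": len(nonbiased),
        "n_dropped": n_dropped,
        "D": D,
        "p": p,
        "p_adj": bonferroni(p, n_tests),
    }


@dataclass
class EnrichmentReport:
    """Aggregated per-sample enrichment analytics (built by the pipeline)."""

    arm_ks: dict[str, pd.DataFrame] = field(default_factory=dict)
    folds: dict[str, float] = field(default_factory=dict)
    correlations: pd.DataFrame | None = None
    classes: dict[str, pd.Series] = field(default_factory=dict)
    expression: dict[str, dict] = field(default_factory=dict)
    sex_bias: dict[str, dict] = field(default_factory=dict)
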