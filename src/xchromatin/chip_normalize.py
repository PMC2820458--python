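"""Two-channel ChIP-chip normalization: raw element intensities to a
gene x sample matrix of averaged log2 ChIP/input ratios.

The chain runs in this order (a ``background_first`` switch is provided for
sensitivity checks):

1. per-array median-centering of log2 ChIP/input ratios;
2. quantile normalization of the input channel across arrays (reference =
   mean of order statistics), with the ChIP channel reconstructed as
   normalized input + centered ratio so every element's centered ratio is
   preserved exactly;
3. background correction against non-genomic control elements: elements
   below the mean control intensity in BOTH channels are excluded, then the
   per-channel control means are subtracted from all remaining elements on
   the linear scale; intensities driven <= 0 become missing rather than
   clamped, to avoid fabricating ratios;
4. duplicate probes merged by averaging ratios per gene;
5. replicate ratios averaged per sample (individual replicates retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ArrayBatch

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Elementary steps


def log2_ratio(chip: pd.DataFrame, input_: pd.DataFrame) -> pd.DataFrame:
    """log2(ChIP/input) where both channels are positive, NaN otherwise."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(chip.where(chip > 0)) - np.log2(input_.where(input_ > 0))
    return r


def median_center(ratios: pd.Series | pd.DataFrame):
    """Subtract the (per-array) median log2 ratio; output median is 0."""
    if isinstance(ratios, pd.Series):
        return ratios - ratios.median()
    return ratios - ratios.median(axis=0)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean-of-order-statistics reference.

    After normalization every column shares one empirical distribution.
    On complete equal-length columns the reference is exactly the mean of
    order statistics; ties within a column receive the mean of their tied
    reference quantiles.  Missing entries are left missing and do not
    consume quantiles (the reference is the mean of the columns' quantile
    functions on plotting positions (k - 0.5)/n).
    """
    if values.shape[1] < 2:
        raise NormalizationError("quantile normalization needs >= 2 arrays")
    arr = values.to_numpy(dtype=float)
    n_rows, n_cols = arr.shape
    counts = (~np.isnan(arr)).sum(axis=0)
    if (counts == 0).any():
        raise NormalizationError("an array has no usable values")
    n_grid = int(counts.max())
    p_grid = (np.arange(n_grid) + 0.5) / n_grid
    reference = np.zeros(n_grid)
    for j in range(n_cols):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        p_col = (np.arange(len(col)) + 0.5) / len(col)
        reference += np.interp(p_grid, p_col, col)
    reference /= n_cols
    out = np.full_like(arr, np.nan)
    for j in range(n_cols):
        ok = ~np.isnan(arr[:, j])
        ranks = stats.rankdata(arr[ok, j], method="average")
        p = (ranks - 0.5) / ok.sum()
        out[ok, j] = np.interp(p, p_grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Batch-level pipeline


@dataclass
class NormalizedBatch:
    """Element-level state after normalization of one sample's arrays."""

    sample: str
    gene_id: pd.Series          # element_id -> gene id ("" for controls)
    is_control: pd.Series       # element_id -> bool
    chip_log2: pd.DataFrame     # elements x arrays, NaN = excluded/missing
    input_log2: pd.DataFrame
    ratio: pd.DataFrame         # log2 ChIP/input per element per array
    n_excluded: pd.Series       # per array, elements dropped by background rule


def _pivot(batch: ArrayBatch) -> tuple[pd.Series, pd.Series, pd.DataFrame, pd.DataFrame]:
    df = batch.elements
    meta = df.drop_duplicates("element_id").set_index("element_id")
    chip = df.pivot(index="element_id", columns="array_id", values="chip_intensity")
    input_ = df.pivot(index="element_id", columns="array_id", values="input_intensity")
    if chip.isna().any().any() or input_.isna().any().any():
        raise NormalizationError(
            f"{batch.sample}: arrays have unequal element sets"
        )
    # keep original element order and array order
    order = df["element_id"].drop_duplicates()
    arrays = df["array_id"].drop_duplicates()
    chip = chip.loc[order, arrays]
    input_ = input_.loc[order, arrays]
    gene_id = meta["gene_id"].loc[order].fillna("")
    is_control = meta["is_control"].loc[order].astype(bool)
    return gene_id, is_control, chip, input_


def normalize_batch(
    batch: ArrayBatch, background_first: bool = False
) -> NormalizedBatch:
    """Run the element-level normalization chain on one sample's arrays."""
    gene_id, is_control, chip, input_ = _pivot(batch)
    if not is_control.any():
        raise NormalizationError(f"{batch.sample}: no control elements")

    def _background(chip_lin: pd.DataFrame, input_lin: pd.DataFrame):
        ctrl_chip = chip_lin.loc[is_control].mean(axis=0)
        ctrl_input = input_lin.loc[is_control].mean(axis=0)
        below_both = chip_lin.lt(ctrl_chip, axis=1) & input_lin.lt(ctrl_input, axis=1)
        chip_c = (chip_lin - ctrl_chip).where(~below_both)
        input_c = (input_lin - ctrl_input).where(~below_both)
        chip_c = chip_c.where(chip_c > 0)
        input_c = input_c.where(input_c > 0)
        return chip_c, input_c, below_both.sum(axis=0)

    if background_first:
        chip, input_, n_excluded = _background(chip, input_)

    centered = median_center(log2_ratio(chip, input_))
    input_log2 = quantile_normalize(np.log2(input_.where(input_ > 0)))
    chip_log2 = input_log2 + centered

    if not background_first:
        chip_lin = 2.0 ** chip_log2
        input_lin = 2.0 ** input_log2
        chip_lin, input_lin, n_excluded = _background(chip_lin, input_lin)
        with np.errstate(invalid="ignore"):
            chip_log2 = np.log2(chip_lin)
            input_log2 = np.log2(input_lin)

    ratio = chip_log2 - input_log2
    return NormalizedBatch(
        sample=batch.sample,
        gene_id=gene_id,
        is_control=is_control,
        chip_log2=chip_log2,
        input_log2=input_log2,
        ratio=ratio,
        n_excluded=n_excluded,
    )


def merge_duplicates(normalized: NormalizedBatch) -> pd.DataFrame:
    """Per-gene per-array ratios: available-case mean over duplicate probes."""
    keep = ~normalized.is_control
    ratio = normalized.ratio.loc[keep]
    genes = normalized.gene_id.loc[keep]
    merged = ratio.groupby(genes.to_numpy()).mean()
    merged.index.name = "gene_id"
    return merged


@dataclass
class GeneRatioMatrix:
    """Gene x sample matrix of replicate-averaged log2 ChIP/input ratios."""

    averaged: pd.DataFrame                 # genes x samples
    replicates: dict[str, pd.DataFrame]    # sample -> genes x arrays

    def sample(self, name: str) -> pd.Series:
        return self.averaged[name]

    def to_tsv(self, path) -> None:
        self.averaged.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "GeneRatioMatrix":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
        return cls(averaged=df, replicates={})


def build_ratio_matrix(
    batches: Iterable[ArrayBatch], background_first: bool = False
) -> GeneRatioMatrix:
    """Full normalization chain over a set of samples.

    Replicate-averaged entries are means over the replicates in which the
    gene survived normalization (available-case).
    """
    averaged = {}
    replicates = {}
    for batch in batches:
        norm = normalize_batch(batch, background_first=background_first)
        per_gene = merge_duplicates(norm)
        surviving = per_gene.notna().any(axis=1).sum()
        if surviving == 0:
            raise NormalizationError(f"{batch.sample}: zero surviving genes")
        replicates[batch.sample] = per_gene
        averaged[batch.sample] = per_gene.mean(axis=1)
    matrix = pd.DataFrame(averaged)
    matrix.index.name = "gene_id"
    return GeneRatioMatrix(averaged=matrix, replicates=replicates)


def ma_table(normalized: NormalizedBatch) -> pd.DataFrame:
    """MA pairs per replicate for inspection: A = mean log2 intensity,
    M = log2 ratio."""
    frames = []
    for array_id in normalized.ratio.columns:
        a = 0.5 * (normalized.chip_log2[array_id] + normalized.input_log2[array_id])
        m = normalized.ratio[array_id]
        ok = a.notna() & m.notna()
        frames.append(
            pd.DataFrame(
                {"array_id": array_id, "element_id": a.index[ok],
                 "A": a[ok].to_numpy(), "M": m[ok].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)
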