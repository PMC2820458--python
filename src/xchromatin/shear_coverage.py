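"""Per-base depth, normalized coverage, 1 kb windows, gene-feature coverage,
and meta-profiles of shearing-biased read density.

Normalization is average depth per base, per kilobase of region, per
million sequenced base pairs:

    C = (sum_depth / (region_len / 1000)) / (total_sequenced_bp / 1e6)

applied identically to windows and gene features, so samples of slightly
different sequencing depth are comparable.  Reads are unstranded for
coverage purposes (chromatin fragments carry no transcriptional strand) and
full read bodies are counted, not 5' ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .genome_model import ChromosomeArm, GenomeAnnotation, GeneModel, gene_anchor
from .synthetic_data import ReadSet

logger = logging.getLogger(__name__)

FeatureKind = Literal["exon", "intron", "TSS_flank", "TTS_flank"]
RegionKind = Literal["gene_body", "TSS", "TTS"]


@dataclass
class CoverageTrack:
    arm: str
    depth: np.ndarray  # per-base integer read depth
    total_sequenced_bp: int

    def __post_init__(self) -> None:
        if self.total_sequenced_bp <= 0:
            raise ValueError("total_sequenced_bp must be positive")

    @property
    def cumdepth(self) -> np.ndarray:
        """Prefix sums (length+1) for O(1) range-sum queries; cached."""
        if not hasattr(self, "_cumdepth"):
            self._cumdepth = np.concatenate([[0], np.cumsum(self.depth)])
        return self._cumdepth

    def range_sum(self, start: int, end: int) -> int:
        return int(self.cumdepth[end] - self.cumdepth[start])


def depth_track(reads: ReadSet, arm: ChromosomeArm) -> CoverageTrack:
    """Per-base read depth on one arm: depth[b] = number of reads covering b."""
    sub = reads.on_arm(arm.name)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if len(starts) and (starts.min() < 0 or ends.max() > arm.length_bp):
        raise ValueError(f"read out of bounds on arm {arm.name!r}")
    diff = np.zeros(arm.length_bp + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])
    return CoverageTrack(arm.name, depth, reads.total_sequenced_bp)


def depth_tracks(reads: ReadSet, annotation: GenomeAnnotation) -> dict[str, CoverageTrack]:
    return {a.name: depth_track(reads, a) for a in annotation.arms}


def normalized_coverage(
    sum_depth, region_len: int, total_sequenced_bp: int
):
    """Average depth per base, per kb, per million sequenced bp (vectorized)."""
    if region_len <= 0:
        raise ValueError("region_len must be positive")
    if total_sequenced_bp <= 0:
        raise ValueError("total_sequenced_bp must be positive")
    return (np.asarray(sum_depth, dtype=float) / (region_len / 1000.0)) / (
        total_sequenced_bp / 1e6
    )


def window_coverage(track: CoverageTrack, width: int = 1000) -> pd.DataFrame:
    """Non-overlapping window tiling from the arm start.

    A trailing partial window is dropped, keeping window-value distributions
    comparable across arms.  Returns columns arm, start, end, sum_depth,
    coverage.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    n = len(track.depth) // width
    cum = track.cumdepth
    starts = np.arange(n) * width
    ends = starts + width
    sums = cum[ends] - cum[starts]
    return pd.DataFrame(
        {
            "arm": track.arm,
            "start": starts,
            "end": ends,
            "sum_depth": sums,
            "coverage": normalized_coverage(sums, width, track.total_sequenced_bp),
        }
    )


def _feature_intervals(
    gene: GeneModel, feature: FeatureKind, flank: int, arm_length: int
) -> list[tuple[int, int]]:
    if feature == "exon":
        return list(gene.exons)
    if feature == "intron":
        return list(gene.introns)
    if feature == "TSS_flank":
        s, e, _ = gene_anchor(gene, "TSS", flank, arm_length)
        return [(s, e)] if e > s else []
    if feature == "TTS_flank":
        s, e, _ = gene_anchor(gene, "TTS", flank, arm_length)
        return [(s, e)] if e > s else []
    raise ValueError(f"unknown feature {feature!r}")


def feature_coverage(
    tracks: Mapping[str, CoverageTrack],
    annotation: GenomeAnnotation,
    feature: FeatureKind,
    sex: str,
    karyotype_correct: bool = False,
    flank: int = 3000,
) -> pd.DataFrame:
    """Per-gene normalized coverage over the union of one feature's bases.

    All exons (resp. introns) of a gene are pooled into one value.  When
    ``karyotype_correct`` and the sample is male, X-gene values are doubled
    to correct for the single male X.  Genes lacking the feature (e.g. no
    intron) get a missing value, never zero.
    """
    rows = []
    for g in annotation.genes:
        arm = annotation.arm(g.arm)
        track = tracks[g.arm]
        intervals = _feature_intervals(g, feature, flank, arm.length_bp)
        total_len = sum(e - s for s, e in intervals)
        if total_len == 0:
            value = np.nan
        else:
            total = sum(track.range_sum(s, e) for s, e in intervals)
            value = float(
                normalized_coverage(total, total_len, track.total_sequenced_bp)
            )
            if karyotype_correct and sex == "male" and arm.arm_class == "X":
                value *= 2.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "arm": g.arm,
                "arm_class": arm.arm_class,
                "feature": feature,
                "coverage": value,
                "karyotype_corrected": bool(
                    karyotype_correct and sex == "male" and arm.arm_class == "X"
                ),
            }
        )
    return pd.DataFrame(rows)


def meta_profile(
    tracks: Mapping[str, CoverageTrack],
    annotation: GenomeAnnotation,
    region: RegionKind,
    n_windows: int = 100,
    flank: int = 3000,
) -> pd.DataFrame:
    """Average coverage profile over a normalized gene coordinate system.

    Per gene, ``n_windows`` overlapping windows of width 1/10 of the region
    are centered at evenly spaced positions from region start + w/2 to
    region end - w/2; the per-window normalized coverage is averaged over
    genes, oriented 5'->3' by strand, and grouped by arm class (major
    autosome arms pooled).  Genes whose region is shorter than ``n_windows``
    bases are skipped (count logged).

    Returns a DataFrame with columns arm_class, window (0-based), position
    (relative window-center position in [0, 1]), coverage, n_genes.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    skipped = 0
    for g in annotation.genes:
        arm = annotation.arm(g.arm)
        track = tracks[g.arm]
        if region == "gene_body":
            start, end, reverse = g.tx_start, g.tx_end, g.strand == "-"
        else:
            start, end, reverse = gene_anchor(g, region, flank, arm.length_bp)
        length = end - start
        if length < n_windows:
            skipped += 1
            continue
        w = length / 10.0
        centers = np.linspace(start + w / 2.0, end - w / 2.0, n_windows)
        los = np.maximum(np.round(centers - w / 2.0).astype(int), start)
        his = np.minimum(np.round(centers + w / 2.0).astype(int), end)
        cum = track.cumdepth
        vals = (cum[his] - cum[los]) / np.maximum(his - los, 1)
        vals = vals * 1000.0 / (track.total_sequenced_bp / 1e6)
        if reverse:
            vals = vals[::-1]
        cls = arm.arm_class
        if cls not in sums:
            sums[cls] = np.zeros(n_windows)
            counts[cls] = 0
        sums[cls] += vals
        counts[cls] += 1
    if skipped:
        logger.info("meta_profile: skipped %d genes with region < %d bp",
                    skipped, n_windows)
    frames = []
    for cls, total in sums.items():
        frames.append(
            pd.DataFrame(
                {
                    "arm_class": cls,
                    "window": np.arange(n_windows),
                    "position": np.linspace(0.0, 1.0, n_windows),
                    "coverage": total / counts[cls],
                    "n_genes": counts[cls],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["arm_class", "window", "position", "coverage", "n_genes"]
    )
    out.attrs["skipped_genes"] = skipped
    return out


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Depth track as bedGraph (runs of equal depth collapsed)."""
    depth = track.depth
    change = np.nonzero(np.diff(depth))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depth)]])
    vals = depth[starts]
    keep = vals != 0
    df = pd.DataFrame(
        {"chrom": track.arm, "start": starts[keep], "end": ends[keep],
         "value": vals[keep]}
    )
    df.to_csv(path, sep="\t", header=False, index=False)
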