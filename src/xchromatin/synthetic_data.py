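"""Synthetic reads, two-channel array batches, and expression tables.

The generator plants the statistical structure the analysis stack is built
to detect, so every downstream stage can be tested without any external
download:

* **Reads** are independent draws from a per-base shearing-propensity
  distribution: open chromatin (higher ``arm_openness``), exonic bases, and
  TSS/TTS-proximal bases shear preferentially, and the male X carries a
  single copy (half the DNA of a diploid arm).
* **Arrays** carry a per-gene true log2 ChIP/input ratio — an X-chromosome
  shift plus a gene-level effect correlated between the sexes through a
  latent bivariate normal — observed through per-array additive bias,
  element-level noise, duplicate spots, and low-intensity control elements.
* **Expression** is linearly linked to the mark ratio so that the fold
  between mark-enriched and mark-depleted deciles equals a configured
  target, and sex-bias labels are assigned preferentially to low-ratio
  genes to plant the mark depletion at sex-biased genes.

A fixed seed reproduces byte-identical BED/TSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ChromosomeArm, GenomeAnnotation, gene_anchor

Sex = Literal["male", "female"]
SEXES: tuple[Sex, Sex] = ("male", "female")


class ConfigError(ValueError):
    """Impossible or inconsistent generator configuration."""


def latent_correlation(rho_spearman: float) -> float:
    """Bivariate-normal latent Pearson correlation hitting a Spearman target.

    Uses the closed form rho_latent = 2 sin(pi * rho_S / 6), exact for
    bivariate normal variables.
    """
    if abs(rho_spearman) > 1:
        raise ConfigError(f"impossible Spearman target {rho_spearman}")
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


# ---------------------------------------------------------------------------
# Shearing model and read simulation


@dataclass(frozen=True)
class ShearModel:
    """Generative counterpart of chromatin openness.

    Per-base shearing propensity on an arm is
    ``copy_number * arm_openness * exon_boost^[exonic] * anchor boosts``,
    with anchor boosts applying within ``flank_bp`` of the TSS/TTS.
    """

    arm_openness: Mapping[str, float]
    exon_boost: float = 1.0
    tss_boost: float = 1.0
    tts_boost: float = 1.0
    flank_bp: int = 3000

    def __post_init__(self) -> None:
        for k, v in self.arm_openness.items():
            if v <= 0:
                raise ConfigError(f"arm_openness[{k!r}] must be > 0")
        for name in ("exon_boost", "tss_boost", "tts_boost"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @staticmethod
    def copy_number(arm: ChromosomeArm, sex: Sex) -> int:
        """Karyotype copy number: males carry a single X, all else diploid."""
        return 1 if (sex == "male" and arm.arm_class == "X") else 2

    @classmethod
    def uniform(cls, annotation: GenomeAnnotation, **kwargs) -> "ShearModel":
        return cls(arm_openness={a.name: 1.0 for a in annotation.arms}, **kwargs)

    @classmethod
    def default(cls, annotation: GenomeAnnotation) -> "ShearModel":
        """Openness pattern typical of the fly system: X slightly open,
        dot chromosome shearing-resistant, exons and gene ends preferred."""
        openness = {"X": 1.2, "major_autosome": 1.0, "dot": 0.45}
        return cls(
            arm_openness={a.name: openness[a.arm_class] for a in annotation.arms},
            exon_boost=1.6,
            tss_boost=1.4,
            tts_boost=1.3,
            flank_bp=3000,
        )


@dataclass
class ReadSet:
    """Uniquely-mapped read intervals for one sequenced sample."""

    reads: pd.DataFrame  # columns: arm, start, end, read_id, strand
    sex: Sex
    read_length: int
    total_sequenced_bp: int

    def on_arm(self, arm: str) -> pd.DataFrame:
        return self.reads[self.reads["arm"] == arm]

    def to_bed(self, path: str | Path) -> None:
        """Write as BED6 (score 0, uniformly sampled strand)."""
        df = self.reads
        bed = pd.DataFrame(
            {
                "chrom": df["arm"],
                "start": df["start"],
                "end": df["end"],
                "name": df["read_id"],
                "score": 0,
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(
        cls, path: str | Path, sex: Sex, read_length: int,
        total_sequenced_bp: int | None = None,
    ) -> "ReadSet":
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        reads = pd.DataFrame(
            {
                "arm": bed["chrom"],
                "start": bed["start"],
                "end": bed["end"],
                "read_id": bed["name"],
                "strand": bed["strand"],
            }
        )
        if total_sequenced_bp is None:
            total_sequenced_bp = int((bed["end"] - bed["start"]).sum())
        return cls(reads, sex, read_length, total_sequenced_bp)


def shear_propensity(
    annotation: GenomeAnnotation, shear: ShearModel, sex: Sex, arm_name: str
) -> np.ndarray:
    """Per-base shearing propensity for one arm (float vector of arm length)."""
    arm = annotation.arm(arm_name)
    prop = np.full(
        arm.length_bp,
        shear.arm_openness[arm_name] * ShearModel.copy_number(arm, sex),
        dtype=float,
    )
    if shear.exon_boost != 1.0:
        mask = np.zeros(arm.length_bp, dtype=bool)
        for g in annotation.genes_on(arm_name):
            for s, e in g.exons:
                mask[s:e] = True
        prop[mask] *= shear.exon_boost
    for which, boost in (("TSS", shear.tss_boost), ("TTS", shear.tts_boost)):
        if boost == 1.0:
            continue
        mask = np.zeros(arm.length_bp, dtype=bool)
        for g in annotation.genes_on(arm_name):
            s, e, _ = gene_anchor(g, which, shear.flank_bp, arm.length_bp)
            mask[s:e] = True
        prop[mask] *= boost
    return prop


def simulate_shear_reads(
    annotation: GenomeAnnotation,
    shear: ShearModel,
    sex: Sex,
    n_reads: int,
    read_length: int = 35,
    seed: int = 0,
) -> ReadSet:
    """Sample ``n_reads`` fixed-length reads proportional to shearing propensity.

    Read start positions are drawn proportional to the per-base propensity;
    a read that would extend past the arm end is never emitted (starts are
    restricted to positions where the full read fits, which is the
    stationary distribution of resampling such reads).
    """
    if n_reads <= 0:
        raise ConfigError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    arm_names = [a.name for a in annotation.arms]
    weights = {}
    masses = np.empty(len(arm_names))
    for i, name in enumerate(arm_names):
        prop = shear_propensity(annotation, shear, sex, name)
        w = prop[: len(prop) - read_length + 1]
        weights[name] = np.cumsum(w)
        masses[i] = weights[name][-1]
    counts = rng.multinomial(n_reads, masses / masses.sum())
    frames = []
    offset = 0
    for name, count in zip(arm_names, counts):
        if count == 0:
            continue
        cum = weights[name]
        starts = np.searchsorted(cum, rng.random(count) * cum[-1], side="right")
        starts.sort()
        frames.append(
            pd.DataFrame(
                {
                    "arm": name,
                    "start": starts,
                    "end": starts + read_length,
                    "read_id": [f"r{offset + j + 1:07d}" for j in range(count)],
                    "strand": np.where(rng.random(count) < 0.5, "+", "-"),
                }
            )
        )
        offset += count
    reads = pd.concat(frames, ignore_index=True)
    return ReadSet(
        reads=reads,
        sex=sex,
        read_length=read_length,
        total_sequenced_bp=n_reads * read_length,
    )


# ---------------------------------------------------------------------------
# Array simulation


@dataclass(frozen=True)
class EffectConfig:
    """Planted effect sizes and nuisance magnitudes for one ChIP mark.

    All shift/effect/noise magnitudes are log2 units.  ``x_shift`` maps sex
    to the X-chromosome log2-ratio shift (log2 of the planted X-vs-autosome
    fold); ``shared_effect_correlation`` is the target Spearman correlation
    of gene effects between the sexes; ``expression_fold`` maps sex to the
    planted expression fold between mark-enriched and mark-depleted decile
    classes.
    """

    x_shift: Mapping[Sex, float] = field(
        default_factory=lambda: {"male": 0.0, "female": 0.0}
    )
    gene_effect_sd: float = 0.5
    shared_effect_correlation: float = 0.0
    array_bias_sd: float = 0.15
    noise_sd: float = 0.06
    input_base_log2: float = 12.0
    input_noise_sd: float = 0.3
    arm_class_openness: Mapping[str, float] = field(
        default_factory=lambda: {"X": 1.2, "major_autosome": 1.0, "dot": 0.45}
    )
    control_fraction: float = 0.02
    control_base_log2: float = 6.0
    control_noise_sd: float = 0.5
    duplicate_fraction: float = 0.10
    expression_fold: Mapping[Sex, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.0}
    )
    expression_base_log2: float = 8.0
    expression_noise_sd: float = 0.5
    sex_bias_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.15, "female": 0.15}
    )
    sex_bias_strength: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "gene_effect_sd", "array_bias_sd", "noise_sd", "input_noise_sd",
            "control_noise_sd", "expression_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("control_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for v in self.sex_bias_fraction.values():
            if not 0 <= v <= 1:
                raise ConfigError("sex_bias_fraction values must be in [0, 1]")
        latent_correlation(self.shared_effect_correlation)  # validates |rho|<=1


# Reference effect catalog: planted X-vs-autosome folds, cross-sex
# Spearman targets on the X, enriched-vs-depleted expression folds, and
# replicate counts for each assayed histone mark.  These are the fixed
# conditions the recovery tests and the acceptance script run under
# (rationale for each value in docs/methods.md).
REFERENCE_X_FOLDS: dict[str, dict[Sex, float]] = {
    "H4K16ac": {"male": 1.39, "female": 1.06},
    "H3S10ph": {"male": 1.09, "female": 1.02},
    "H3K4me2": {"male": 1.15, "female": 1.10},
}
REFERENCE_CROSS_SEX_SPEARMAN_X: dict[str, float] = {
    "H4K16ac": 0.46,
    "H3S10ph": 0.68,
    "H3K4me2": 0.92,
}
REFERENCE_EXPRESSION_FOLDS: dict[str, dict[Sex, float]] = {
    "H4K16ac": {"male": 2.68, "female": 3.77},
    "H3S10ph": {"male": 2.0, "female": 2.0},
    "H3K4me2": {"male": 2.0, "female": 2.0},
}
REFERENCE_REPLICATES: dict[str, dict[Sex, int]] = {
    "H4K16ac": {"male": 4, "female": 3},
    "H3S10ph": {"male": 2, "female": 2},
    "H3K4me2": {"male": 2, "female": 2},
}


def reference_effects(mark: str) -> EffectConfig:
    """EffectConfig planting the reference effect sizes for ``mark``."""
    if mark not in REFERENCE_X_FOLDS:
        raise ConfigError(f"unknown mark {mark!r}")
    return EffectConfig(
        x_shift={s: math.log2(REFERENCE_X_FOLDS[mark][s]) for s in SEXES},
        shared_effect_correlation=REFERENCE_CROSS_SEX_SPEARMAN_X[mark],
        expression_fold=dict(REFERENCE_EXPRESSION_FOLDS[mark]),
    )


@dataclass
class ArrayBatch:
    """Raw two-channel element intensities for one mark x sex sample."""

    elements: pd.DataFrame
    # columns: array_id, sample, replicate, element_id, gene_id, is_control,
    #          chip_intensity, input_intensity  (intensities linear scale)
    mark: str
    sex: Sex

    @property
    def sample(self) -> str:
        return f"{self.mark}_{self.sex}"

    @property
    def array_ids(self) -> list[str]:
        return list(dict.fromkeys(self.elements["array_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.elements.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path, mark: str, sex: Sex) -> "ArrayBatch":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df, mark, sex)


def simulate_array_batch(
    annotation: GenomeAnnotation,
    effects: EffectConfig,
    mark: str,
    sexes: Sequence[Sex] = SEXES,
    n_replicates: Mapping[Sex, int] | None = None,
    seed: int = 0,
) -> dict[Sex, ArrayBatch]:
    """Paired male/female array batches with shared latent gene effects.

    Per gene g and sex s the true log2 ratio is ``x_shift[s]`` (X genes
    only) plus a gene effect ``e_gs``; (e_g,male, e_g,female) are bivariate
    normal with latent Pearson correlation 2 sin(pi rho_S / 6) so the true
    effects hit the target Spearman.  Observed element ratios add a
    per-array bias and element noise; input intensities scale with arm-class
    openness; a configured fraction of elements are non-genomic controls
    with low background intensities, and a fraction of genes are spotted in
    duplicate.
    """
    if n_replicates is None:
        n_replicates = REFERENCE_REPLICATES.get(mark, {s: 2 for s in sexes})
    for s in sexes:
        if n_replicates[s] < 1:
            raise ConfigError("n_replicates must be >= 1 per sex")
    rng = np.random.default_rng(seed)
    genes = annotation.genes
    n = len(genes)
    gene_ids = np.array([g.gene_id for g in genes])
    arm_class = np.array([annotation.arm_class_of(g.arm) for g in genes])
    on_x = arm_class == "X"

    rho = latent_correlation(effects.shared_effect_correlation)
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n
    ) * effects.gene_effect_sd
    gene_effect = {"male": z[:, 0], "female": z[:, 1]}

    dup = rng.random(n) < effects.duplicate_fraction
    spot_gene_idx = np.concatenate([np.arange(n), np.nonzero(dup)[0]])
    n_gene_elements = len(spot_gene_idx)
    n_controls = int(round(
        effects.control_fraction * n_gene_elements / (1 - effects.control_fraction)
    )) if effects.control_fraction > 0 else 0

    openness = np.array(
        [effects.arm_class_openness[c] for c in arm_class]
    )[spot_gene_idx]

    batches: dict[Sex, ArrayBatch] = {}
    for sex in sexes:
        true_ratio = np.where(on_x, effects.x_shift[sex], 0.0) + gene_effect[sex]
        spot_ratio = true_ratio[spot_gene_idx]
        frames = []
        for rep in range(1, n_replicates[sex] + 1):
            array_id = f"{mark}_{sex}_r{rep}"
            bias = rng.normal(0.0, effects.array_bias_sd)
            input_log2 = (
                effects.input_base_log2
                + np.log2(openness)
                + rng.normal(0.0, effects.input_noise_sd, n_gene_elements)
            )
            obs_ratio = spot_ratio + bias + rng.normal(
                0.0, effects.noise_sd, n_gene_elements
            )
            chip_log2 = input_log2 + obs_ratio
            ctrl_input = rng.normal(
                effects.control_base_log2, effects.control_noise_sd, n_controls
            )
            ctrl_chip = rng.normal(
                effects.control_base_log2, effects.control_noise_sd, n_controls
            ) + bias
            frames.append(
                pd.DataFrame(
                    {
                        "array_id": array_id,
                        "sample": f"{mark}_{sex}",
                        "replicate": rep,
                        "element_id": (
                            [f"el{j + 1:06d}" for j in range(n_gene_elements)]
                            + [f"ctrl{j + 1:04d}" for j in range(n_controls)]
                        ),
                        "gene_id": (
                            list(gene_ids[spot_gene_idx]) + [""] * n_controls
                        ),
                        "is_control": (
                            [False] * n_gene_elements + [True] * n_controls
                        ),
                        "chip_intensity": np.concatenate(
                            [2.0 ** chip_log2, 2.0 ** ctrl_chip]
                        ),
                        "input_intensity": np.concatenate(
                            [2.0 ** input_log2, 2.0 ** ctrl_input]
                        ),
                    }
                )
            )
        batches[sex] = ArrayBatch(
            pd.concat(frames, ignore_index=True), mark=mark, sex=sex
        )
    return batches


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(
    annotation: GenomeAnnotation,
    gene_ratios: pd.Series,
    effects: EffectConfig,
    sex: Sex,
    seed: int = 0,
    hi: float = 0.90,
    lo: float = 0.10,
) -> tuple[pd.Series, pd.Series]:
    """Expression table plus sex-bias labels linked to a mark's gene ratios.

    log2 expression = baseline + slope * ratio + noise, with the slope
    calibrated on the decile classes of ``gene_ratios`` so that the planted
    enriched-vs-depleted expression fold equals
    ``effects.expression_fold[sex]`` exactly in the noise-free limit.

    Sex-bias labels partition the genes into ``{sex}_biased`` and
    ``non_biased`` with the configured fraction; biased genes are sampled
    preferentially among low-ratio genes (exponential tilting with strength
    ``sex_bias_strength``), planting the mark depletion at sex-biased genes.

    Returns ``(expression, labels)`` indexed like ``gene_ratios`` (missing
    ratios dropped).
    """
    from .enrichment_analysis import percentile_classes

    rng = np.random.default_rng(seed)
    ratios = gene_ratios.dropna()
    classes = percentile_classes(ratios, hi=hi, lo=lo)
    enr = ratios[classes == "enriched"]
    dep = ratios[classes == "depleted"]
    delta_r = float(enr.mean() - dep.mean()) if len(enr) and len(dep) else 0.0
    target = effects.expression_fold[sex]
    slope = math.log2(target) / delta_r if delta_r != 0 else 0.0
    expr = (
        effects.expression_base_log2
        + slope * ratios
        + rng.normal(0.0, effects.expression_noise_sd, len(ratios))
    )
    expr.name = f"log2_expression_{sex}"

    frac = effects.sex_bias_fraction.get(sex, 0.0)
    n_biased = int(round(frac * len(ratios)))
    sd = float(ratios.std(ddof=0))
    if sd > 0 and effects.sex_bias_strength != 0:
        zscores = (ratios.to_numpy() - float(ratios.mean())) / sd
        w = np.exp(-effects.sex_bias_strength * zscores)
    else:
        w = np.ones(len(ratios))
    biased_idx = rng.choice(
        len(ratios), size=n_biased, replace=False, p=w / w.sum()
    )
    labels = pd.Series("non_biased", index=ratios.index, name="sex_bias")
    labels.iloc[biased_idx] = f"{sex}_biased"
    return expr, labels


def write_expression(
    expression: pd.Series, labels: pd.Series, path: str | Path
) -> None:
    df = pd.DataFrame({"gene_id": expression.index,
                       "log2_expression": expression.to_numpy(),
                       "sex_bias": labels.reindex(expression.index).to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_expression(path: str | Path) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
    return df["log2_expression"], df["sex_bias"]
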