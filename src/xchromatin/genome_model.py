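"""Genome and gene-model types, annotation I/O, and deterministic toy genomes.

All internal coordinates are 0-based half-open (BED convention).  GFF3's
1-based inclusive coordinates are converted at the parsing boundary and
nowhere else.  A genome is a set of chromosome arms, each classified as the
X, a major autosome arm, or the small heterochromatic dot chromosome; the
classification drives every downstream X-vs-autosome comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

ArmClass = Literal["X", "major_autosome", "dot"]

#: Arm lengths mimicking the fly karyotype proportions: five major arms each
#: carry close to 20% of the genome and the dot chromosome under 1%.
DEFAULT_ARM_LENGTHS: dict[str, int] = {
    "X": 1_000_000,
    "2L": 1_010_000,
    "2R": 1_020_000,
    "3L": 1_000_000,
    "3R": 990_000,
    "4": 40_000,
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def infer_arm_class(name: str) -> ArmClass:
    """Classify an arm from its conventional fly name.

    ``X`` is the X chromosome, ``4`` (or ``chr4``) the dot chromosome, and
    everything else a major autosome arm.
    """
    stripped = name.removeprefix("chr")
    if stripped == "X":
        return "X"
    if stripped == "4":
        return "dot"
    return "major_autosome"


@dataclass(frozen=True)
class ChromosomeArm:
    name: str
    length_bp: int
    arm_class: ArmClass

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise AnnotationError(f"arm {self.name!r}: length must be positive")
        if self.arm_class not in ("X", "major_autosome", "dot"):
            raise AnnotationError(f"arm {self.name!r}: bad class {self.arm_class!r}")


@dataclass(frozen=True)
class GeneModel:
    """One transcript model per gene, with exons in 0-based half-open bp."""

    gene_id: str
    arm: str
    strand: Literal["+", "-"]
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise AnnotationError(f"gene {self.gene_id!r}: bad transcript bounds")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon [{s},{e}) outside transcript"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Complement of the exons within [tx_start, tx_end)."""
        out = []
        cursor = self.tx_start
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s))
            cursor = e
        if cursor < self.tx_end:
            out.append((cursor, self.tx_end))
        return tuple(out)

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class GenomeAnnotation:
    arms: list[ChromosomeArm]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise AnnotationError("duplicate arm names")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate gene ids")
        by_name = {a.name: a for a in self.arms}
        for g in self.genes:
            arm = by_name.get(g.arm)
            if arm is None:
                raise AnnotationError(f"gene {g.gene_id!r} on unknown arm {g.arm!r}")
            if g.tx_end > arm.length_bp:
                raise AnnotationError(
                    f"gene {g.gene_id!r} extends past arm {g.arm!r} end"
                )

    def arm(self, name: str) -> ChromosomeArm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    def genes_on(self, arm: str) -> list[GeneModel]:
        return [g for g in self.genes if g.arm == arm]

    @property
    def genome_length(self) -> int:
        return sum(a.length_bp for a in self.arms)

    def arm_class_of(self, arm_name: str) -> ArmClass:
        return self.arm(arm_name).arm_class

    def gene_arms(self) -> "pd.Series":  # noqa: F821 - deferred import
        """gene_id -> arm name as a pandas Series (handy index for analytics)."""
        import pandas as pd

        return pd.Series(
            {g.gene_id: g.arm for g in self.genes}, name="arm", dtype="object"
        )


# ---------------------------------------------------------------------------
# Anchors


def gene_anchor(
    gene: GeneModel,
    which: Literal["TSS", "TTS"],
    flank: int,
    arm_length: int | None = None,
) -> tuple[int, int, bool]:
    """Interval ``[anchor - flank, anchor + flank)`` around the TSS or TTS.

    Returns ``(start, end, reversed)`` where ``reversed`` is True for minus
    strand genes, so profiles can be oriented 5'->3'.  The interval is
    clipped to ``[0, arm_length)`` when ``arm_length`` is given.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    anchor = gene.tss if which == "TSS" else gene.tts
    start = max(0, anchor - flank)
    end = anchor + flank
    if arm_length is not None:
        end = min(end, arm_length)
    return start, end, gene.strand == "-"


# ---------------------------------------------------------------------------
# GFF3 I/O


def _read_gff3(path: Path, arms: Sequence[ChromosomeArm] | None) -> GenomeAnnotation:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationError(f"cannot parse GFF3 {path}: {exc}") from exc

    if arms is None:
        arm_list = []
        for directive in db.directives:
            parts = directive.split()
            if parts and parts[0] == "sequence-region" and len(parts) >= 4:
                name, _, end = parts[1], parts[2], parts[3]
                arm_list.append(
                    ChromosomeArm(name, int(end), infer_arm_class(name))
                )
        if not arm_list:
            raise AnnotationError(
                f"{path}: no ##sequence-region directives; pass arms explicitly"
            )
    else:
        arm_list = list(arms)

    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (child.start - 1, child.end)  # 1-based inclusive -> 0-based half-open
            for child in db.children(feat, featuretype="exon")
        )
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                arm=feat.seqid,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                tx_start=feat.start - 1,
                tx_end=feat.end,
                exons=tuple(exons),
            )
        )
    return GenomeAnnotation(arms=arm_list, genes=genes)


def _write_gff3(annotation: GenomeAnnotation, path: Path) -> None:
    lines = ["##gff-version 3"]
    for arm in annotation.arms:
        lines.append(f"##sequence-region {arm.name} 1 {arm.length_bp}")
    for g in annotation.genes:
        lines.append(
            "\t".join(
                [
                    g.arm, "xchromatin", "gene",
                    str(g.tx_start + 1), str(g.tx_end), ".", g.strand, ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                "\t".join(
                    [
                        g.arm, "xchromatin", "exon",
                        str(s + 1), str(e), ".", g.strand, ".",
                        f"ID={g.gene_id}.e{i};Parent={g.gene_id}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED12 I/O


def _read_bed12(path: Path, arms: Sequence[ChromosomeArm] | None) -> GenomeAnnotation:
    genes = []
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                strand = fields[5]
                count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != count or len(starts) != count:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name, arm=chrom, strand=strand,
                    tx_start=start, tx_end=end, exons=exons,
                )
            )
            max_end[chrom] = max(max_end.get(chrom, 0), end)
    if arms is None:
        arm_list = [
            ChromosomeArm(name, end, infer_arm_class(name))
            for name, end in sorted(max_end.items())
        ]
    else:
        arm_list = list(arms)
    return GenomeAnnotation(arms=arm_list, genes=genes)


def _write_bed12(annotation: GenomeAnnotation, path: Path) -> None:
    lines = []
    for g in annotation.genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
        lines.append(
            "\t".join(
                [
                    g.arm, str(g.tx_start), str(g.tx_end), g.gene_id, "0",
                    g.strand, str(g.tx_start), str(g.tx_end), "0",
                    str(len(g.exons)), sizes, starts,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_annotation(
    path: str | Path,
    format: Literal["GFF3", "BED12"] | None = None,
    arms: Sequence[ChromosomeArm] | None = None,
) -> GenomeAnnotation:
    """Read gene models from GFF3 or BED12 into a validated annotation.

    ``format`` is inferred from the suffix when omitted.  Arm lengths come
    from GFF3 ``##sequence-region`` directives; BED12 carries none, so pass
    ``arms`` explicitly for exact lengths (otherwise the maximal gene end per
    chromosome is used).  Arm classes are inferred from fly naming
    conventions unless ``arms`` is given.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "BED12" if suffix == ".bed" else "GFF3"
    if format == "GFF3":
        return _read_gff3(path, arms)
    if format == "BED12":
        return _read_bed12(path, arms)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation(
    annotation: GenomeAnnotation,
    path: str | Path,
    format: Literal["GFF3", "BED12"] | None = None,
) -> None:
    path = Path(path)
    if format is None:
        format = "BED12" if path.suffix.lower() == ".bed" else "GFF3"
    if format == "GFF3":
        _write_gff3(annotation, path)
    elif format == "BED12":
        _write_bed12(annotation, path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Toy genome


def make_toy_genome(
    n_genes_per_arm: int | Mapping[str, int] = 40,
    arm_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
) -> GenomeAnnotation:
    """Deterministic toy genome with fly-like karyotype proportions.

    Genes are placed one per equal-width slot along each arm, so they never
    overlap; each gene is multi-exon and strands alternate deterministically
    in expectation (drawn from the seeded generator).  Raises if the
    requested gene count cannot fit without overlap.
    """
    if arm_lengths is None:
        arm_lengths = DEFAULT_ARM_LENGTHS
    rng = np.random.default_rng(seed)
    arms = [
        ChromosomeArm(name, int(length), infer_arm_class(name))
        for name, length in arm_lengths.items()
    ]
    genes: list[GeneModel] = []
    for arm in arms:
        n_genes = (
            n_genes_per_arm[arm.name]
            if isinstance(n_genes_per_arm, Mapping)
            else int(n_genes_per_arm)
        )
        if n_genes == 0:
            continue
        slot = arm.length_bp // n_genes
        # need room for >=2 exons and an intron plus a 2 bp margin per side
        if slot < 150:
            raise AnnotationError(
                f"arm {arm.name!r}: {n_genes} genes cannot fit without overlap"
            )
        for i in range(n_genes):
            slot_start = i * slot
            max_span = slot - 10
            span = int(rng.integers(max(120, max_span // 3), max_span + 1))
            offset = int(rng.integers(0, slot - span - 5 + 1))
            tx_start = slot_start + offset
            tx_end = tx_start + span
            n_exons = int(rng.integers(2, 5))
            # 2*(n_exons-1) interior breakpoints alternate exon/intron ends
            n_breaks = 2 * (n_exons - 1)
            breaks = np.sort(
                rng.choice(np.arange(tx_start + 1, tx_end), n_breaks, replace=False)
            )
            bounds = [tx_start, *breaks.tolist(), tx_end]
            exons = tuple(
                (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"{arm.name}g{i + 1:05d}",
                    arm=arm.name,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                )
            )
    return GenomeAnnotation(arms=arms, genes=genes)
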