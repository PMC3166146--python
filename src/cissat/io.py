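"""Containers and readers/writers for cohort data.

A cohort bundles one genotype matrix (individuals x SNPs, allele-count
dosages), one expression matrix per tissue (transcripts x individuals),
and positional annotation for SNPs and transcript start sites.  Formats
are the plain-text standards: VCF 4.2 for genotypes, TSV for expression,
BED4 for TSS annotation.

Coordinate convention: SNP positions and TSS are 1-based in memory (VCF
convention); BED input is 0-based half-open and converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical tissue labels (A/B/C stand for omental adipose, subcutaneous
#: adipose and liver in the motivating three-tissue design)
TISSUES = ("A", "B", "C")

MISSING = -1  # sentinel for a missing genotype call


class CohortFormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class SnpAnnotation:
    """SNP identifiers and 1-based genomic positions (single chromosome)."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(set(self.ids)) != len(self.ids):
            raise CohortFormatError("duplicate SNP ids")
        if self.pos.size and self.pos.min() < 1:
            raise CohortFormatError("SNP positions must be >= 1")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TranscriptAnnotation:
    """Transcript identifiers and 1-based transcription start sites."""

    ids: np.ndarray
    chrom: np.ndarray
    tss: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.tss = np.asarray(self.tss, dtype=np.int64)
        if len(set(self.ids)) != len(self.ids):
            raise CohortFormatError("duplicate transcript ids")
        if self.tss.size and self.tss.min() < 1:
            raise CohortFormatError("TSS positions must be >= 1")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of allele-count dosages {0,1,2}, -1 missing."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortFormatError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise CohortFormatError("duplicate SNP ids")
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise CohortFormatError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            raise CohortFormatError("genotype values must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_samples(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids[indices], self.snp_ids,
                              self.values[np.asarray(indices)])


@dataclass
class ExpressionMatrix:
    """Transcripts x individuals matrix of expression intensities for one tissue."""

    tissue: str
    sample_ids: np.ndarray
    transcript_ids: np.ndarray
    values: np.ndarray  # float64, shape (n_transcripts, n_samples)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise CohortFormatError("duplicate transcript ids")
        if self.values.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise CohortFormatError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise CohortFormatError("expression values must be finite")

    def take_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.tissue, self.sample_ids[indices],
                                self.transcript_ids,
                                self.values[:, np.asarray(indices)])


@dataclass
class Cohort:
    """Aligned genotype + multi-tissue expression data for one individual set.

    All matrices share one sample order (the genotype order); this is
    established by :func:`align_samples` or by the simulator.
    """

    genotypes: GenotypeMatrix
    snps: SnpAnnotation
    expression: dict[str, ExpressionMatrix]
    transcripts: TranscriptAnnotation
    architecture: pd.DataFrame | None = None  # ground truth, simulation only

    def __post_init__(self) -> None:
        if not self.expression:
            raise CohortFormatError("cohort needs at least one tissue")
        if not np.array_equal(self.genotypes.snp_ids, self.snps.ids):
            raise CohortFormatError("genotype SNP order differs from annotation")
        for tissue, expr in self.expression.items():
            if expr.tissue != tissue:
                raise CohortFormatError(f"tissue key {tissue!r} != label {expr.tissue!r}")
            if not np.array_equal(expr.sample_ids, self.genotypes.sample_ids):
                raise CohortFormatError(
                    f"tissue {tissue}: samples not aligned with genotypes "
                    "(run align_samples first)"
                )
            if not np.array_equal(expr.transcript_ids, self.transcripts.ids):
                raise CohortFormatError(
                    f"tissue {tissue}: transcript order differs from annotation"
                )

    @property
    def sample_ids(self) -> np.ndarray:
        return self.genotypes.sample_ids

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.expression)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, SnpAnnotation]:
    """Parse a VCF into a dosage matrix plus SNP annotation.

    GT is decoded as the alternate-allele count; ``./.`` becomes missing.
    Multi-allelic records are rejected.  Errors carry the 1-based record
    number within the VCF body.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise CohortFormatError(f"{path}: VCF has no sample columns")
    ids, chroms, positions, columns = [], [], [], []
    for record_no, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise CohortFormatError(
                f"{path}: record {record_no}: multi-allelic records are not supported"
            )
        if "GT" not in (variant.FORMAT or []):
            raise CohortFormatError(f"{path}: record {record_no}: missing GT FORMAT")
        dosage = np.empty(len(samples), dtype=np.int8)
        for j, call in enumerate(variant.genotypes):
            alleles = [a for a in call[:-1] if a is not None]
            if len(alleles) != 2 or min(alleles) < 0:
                dosage[j] = MISSING
            else:
                dosage[j] = sum(1 for a in alleles if a > 0)
        ids.append(variant.ID if variant.ID not in (None, ".") else
                   f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        columns.append(dosage)
    vcf.close()
    if not columns:
        raise CohortFormatError(f"{path}: VCF has no variant records")
    values = np.stack(columns, axis=1)
    annotation = SnpAnnotation(np.array(ids, dtype=object),
                               np.array(chroms, dtype=object),
                               np.array(positions, dtype=np.int64))
    return GenotypeMatrix(np.array(samples, dtype=object),
                          annotation.ids, values), annotation


def read_expression_tsv(path: str | os.PathLike, tissue: str) -> ExpressionMatrix:
    """Read a transcripts x samples expression TSV (first column = transcript id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise CohortFormatError(f"{path}: duplicate transcript ids {dupes}")
    for column in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[column]):
            bad = frame[column][pd.to_numeric(frame[column], errors="coerce").isna()]
            raise CohortFormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {column!r}"
            )
    return ExpressionMatrix(tissue,
                            frame.columns.to_numpy(dtype=object),
                            frame.index.to_numpy(dtype=object),
                            frame.to_numpy(dtype=np.float64))


def read_tss_annotation(path: str | os.PathLike) -> TranscriptAnnotation:
    """Read a BED4 TSS annotation; converts 0-based starts to 1-based TSS.

    Rows are sorted by (chrom, tss) so downstream code can rely on
    positional order regardless of input order.
    """
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "name"],
                        dtype={"chrom": str, "name": str})
    if (frame["end"] < frame["start"]).any():
        bad = frame[frame["end"] < frame["start"]].iloc[0]
        raise CohortFormatError(
            f"{path}: interval end < start for {bad['name']!r}"
        )
    frame = frame.sort_values(["chrom", "start"], kind="stable")
    return TranscriptAnnotation(frame["name"].to_numpy(dtype=object),
                                frame["chrom"].to_numpy(dtype=object),
                                (frame["start"] + 1).to_numpy(dtype=np.int64))


def align_samples(
    genotypes: GenotypeMatrix,
    expressions: dict[str, ExpressionMatrix],
) -> tuple[GenotypeMatrix, dict[str, ExpressionMatrix]]:
    """Restrict genotypes and all tissues to their common samples.

    The intersection keeps the original genotype sample order (so repeated
    alignment is a no-op).  Requires at least two common samples.
    """
    common = set(genotypes.sample_ids.tolist())
    for expr in expressions.values():
        common &= set(expr.sample_ids.tolist())
    if len(common) == 0:
        raise CohortFormatError("no samples shared between genotypes and all tissues")
    if len(common) < 2:
        raise CohortFormatError(f"only {len(common)} common sample; need >= 2")
    keep = np.array([i for i, s in enumerate(genotypes.sample_ids) if s in common])
    geno = genotypes.take_samples(keep)
    aligned: dict[str, ExpressionMatrix] = {}
    for tissue, expr in expressions.items():
        order = {s: j for j, s in enumerate(expr.sample_ids)}
        idx = np.array([order[s] for s in geno.sample_ids])
        aligned[tissue] = expr.take_samples(idx)
    return geno, aligned


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genotypes_vcf(path: str | os.PathLike, genotypes: GenotypeMatrix,
                        snps: SnpAnnotation, chrom_length: int | None = None) -> None:
    """Emit an unphased biallelic (REF=A, ALT=G) GT-only VCF 4.2 file."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = pd.unique(snps.chrom)
        for contig in contigs:
            if chrom_length is not None:
                handle.write(f"##contig=<ID={contig},length={chrom_length}>\n")
            else:
                handle.write(f"##contig=<ID={contig}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, genotypes.sample_ids)) + "\n")
        for j in range(len(snps)):
            calls = "\t".join(gt_code[int(v)] for v in genotypes.values[:, j])
            handle.write(f"{snps.chrom[j]}\t{snps.pos[j]}\t{snps.ids[j]}"
                         f"\tA\tG\t.\t.\t.\tGT\t{calls}\n")


def write_expression_tsv(path: str | os.PathLike, expression: ExpressionMatrix) -> None:
    frame = pd.DataFrame(expression.values,
                         index=pd.Index(expression.transcript_ids, name="transcript_id"),
                         columns=expression.sample_ids)
    # %.17g round-trips float64 exactly through text
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_tss_bed(path: str | os.PathLike, transcripts: TranscriptAnnotation) -> None:
    frame = pd.DataFrame({
        "chrom": transcripts.chrom,
        "start": transcripts.tss - 1,
        "end": transcripts.tss,
        "name": transcripts.ids,
    })
    frame.to_csv(path, sep="\t", header=False, index=False)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a cohort as VCF + per-tissue expression TSVs + TSS BED (+ truth).

    Returns a name -> path map of everything written.  ``read_cohort`` on the
    output reproduces the cohort exactly.
    """
    if not cohort.expression:
        raise CohortFormatError("cohort has no tissues to write")
    os.makedirs(out_dir, exist_ok=True)
    paths = {"genotypes": os.path.join(out_dir, "genotypes.vcf"),
             "tss": os.path.join(out_dir, "tss.bed")}
    write_genotypes_vcf(paths["genotypes"], cohort.genotypes, cohort.snps)
    write_tss_bed(paths["tss"], cohort.transcripts)
    for tissue, expr in cohort.expression.items():
        key = f"expression_{tissue}"
        paths[key] = os.path.join(out_dir, f"expression_{tissue}.tsv")
        write_expression_tsv(paths[key], expr)
    if cohort.architecture is not None:
        paths["architecture"] = os.path.join(out_dir, "architecture.tsv")
        cohort.architecture.to_csv(paths["architecture"], sep="\t", index=False,
                                   float_format="%.17g")
    return paths


def read_cohort(in_dir: str | os.PathLike,
                tissues: tuple[str, ...] = TISSUES) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    genotypes, snps = read_genotypes_vcf(os.path.join(in_dir, "genotypes.vcf"))
    transcripts = read_tss_annotation(os.path.join(in_dir, "tss.bed"))
    expressions = {}
    for tissue in tissues:
        path = os.path.join(in_dir, f"expression_{tissue}.tsv")
        if os.path.exists(path):
            expressions[tissue] = read_expression_tsv(path, tissue)
    if not expressions:
        raise CohortFormatError(f"{in_dir}: no expression_<tissue>.tsv files found")
    genotypes, expressions = align_samples(genotypes, expressions)
    # re-order expression rows to annotation order
    order = {t: i for i, t in enumerate(transcripts.ids)}
    for tissue, expr in expressions.items():
        idx = np.array([order[t] for t in expr.transcript_ids])
        inv = np.empty_like(idx)
        inv[idx] = np.arange(len(idx))
        expressions[tissue] = ExpressionMatrix(
            tissue, expr.sample_ids, transcripts.ids, expr.values[inv])
    truth_path = os.path.join(in_dir, "architecture.tsv")
    architecture = None
    if os.path.exists(truth_path):
        architecture = pd.read_csv(truth_path, sep="\t",
                                   float_precision="round_trip")
        architecture["causal_snp"] = architecture["causal_snp"].fillna("")
    return Cohort(genotypes, snps, expressions, transcripts, architecture)
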