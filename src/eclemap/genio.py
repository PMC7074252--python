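"""Readers/writers for the external formats the pipeline touches, plus the
shared coordinate conventions.

All genomic coordinates are 1-based inclusive everywhere in this package.
BED files (0-based half-open) are converted at the boundary on read and
write.  Array genotypes travel as a :class:`GenotypeMatrix` (samples x
markers, alt-allele dosage coding), sequence-level variants as a
:class:`VariantSet`.

Supported dialects: PLINK transposed text (.tped/.tfam), VCF v4.x with GT
(read through pysam/htslib, written as minimal deterministic text), BED
intervals, a tab-separated transcript-model table, and tab-separated
reports.  Binary PLINK, BGEN, CRAM/BAM and phased formats are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = np.int8(-1)

PHENOTYPES = ("case", "control", "unknown")

# tfam phenotype column codes
_TFAM_PHENO = {"2": "case", "1": "control", "0": "unknown", "-9": "unknown"}
_TFAM_PHENO_INV = {"case": "2", "control": "1", "unknown": "0"}


class GenioParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Array-marker coordinates: id, chromosome label, 1-based position."""

    ids: list[str]
    chrom: np.ndarray  # dtype=object, chromosome label per marker
    pos: np.ndarray  # dtype=int64, 1-based bp

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.ids) == len(self.chrom) == len(self.pos)):
            raise ValidationError("MarkerMap field lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate marker ids")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"marker positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            [self.ids[i] for i in idx], self.chrom[idx], self.pos[idx]
        )


@dataclass
class GenotypeMatrix:
    """Biallelic array calls for samples x markers.

    ``calls[i, j]`` is the dosage of the second allele of marker j in sample
    i: 0 (hom first allele), 1 (het), 2 (hom second allele) or -1 (missing).
    ``alleles[j]`` holds the two allele labels (nucleotides or A/B codes).
    """

    samples: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8, (n_samples, n_markers)
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(self.alleles) != len(self.markers):
            raise ValidationError("alleles length != marker count")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValidationError("calls must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_rate(self) -> float:
        return float(np.mean(self.calls == MISSING))

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            list(keep), self.markers, self.calls[idx, :], self.alleles
        )

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples,
            self.markers.subset(idx),
            self.calls[:, idx],
            [self.alleles[i] for i in idx],
        )

    def normalized(self) -> "GenotypeMatrix":
        """Canonical allele order (lexicographic) so that semantically equal
        matrices compare equal regardless of which allele was labelled
        first."""
        calls = self.calls.copy()
        alleles = []
        for j, (a1, a2) in enumerate(self.alleles):
            if a2 < a1:
                a1, a2 = a2, a1
                nonmiss = calls[:, j] >= 0
                calls[nonmiss, j] = 2 - calls[nonmiss, j]
            alleles.append((a1, a2))
        return GenotypeMatrix(self.samples, self.markers, calls, alleles)


def make_sample_table(
    sample_ids: list[str], breed: list[str], phenotype: list[str]
) -> pd.DataFrame:
    """SampleTable constructor: columns sample_id / breed / phenotype.

    Phenotype must be one of case/control/unknown for every sample; it is
    never defaulted silently.
    """
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample ids in sample table")
    bad = set(phenotype) - set(PHENOTYPES)
    if bad:
        raise ValidationError(f"invalid phenotype labels: {sorted(bad)}")
    return pd.DataFrame(
        {"sample_id": sample_ids, "breed": breed, "phenotype": phenotype}
    )


@dataclass(frozen=True)
class Interval:
    """Closed genomic interval, 1-based inclusive on both ends."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"interval start {self.start_bp} > end {self.end_bp}"
            )

    def contains(self, chromosome: str, pos: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= pos <= self.end_bp
        )

    @property
    def span_bp(self) -> int:
        """end - start, the distance between the boundary positions."""
        return self.end_bp - self.start_bp

    @property
    def length_kb(self) -> int:
        """Boundary-to-boundary span in kb, rounded to the nearest integer."""
        return round(self.span_bp / 1000)


@dataclass
class VariantSet:
    """Columnar set of biallelic sequence variants with per-sample dosages.

    ``gt[k, i]`` is the alt-allele dosage of variant k in sample i
    (0/1/2, -1 missing).  Multi-allelic VCF records are split into one
    entry per alt allele on read.
    """

    samples: list[str]
    chrom: np.ndarray  # object
    pos: np.ndarray  # int64
    ref: np.ndarray  # object
    alt: np.ndarray  # object
    gt: np.ndarray  # int8 (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise ValidationError("VariantSet column lengths differ")
        if self.gt.shape != (n, len(self.samples)):
            raise ValidationError("VariantSet gt shape inconsistent")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ValidationError("ref == alt in a variant record")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chrom, self.pos.tolist(), self.ref, self.alt))

    def subset(self, idx: np.ndarray) -> "VariantSet":
        idx = np.asarray(idx)
        return VariantSet(
            self.samples,
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            self.alt[idx],
            self.gt[idx, :],
        )

    def subset_samples(self, keep: list[str]) -> "VariantSet":
        idx = [self.samples.index(s) for s in keep]
        return VariantSet(
            list(keep), self.chrom, self.pos, self.ref, self.alt,
            self.gt[:, idx],
        )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript, enabling genomic<->CDS<->protein
    coordinate arithmetic.

    ``cds_start_bp``/``cds_end_bp`` are genomic coordinates with
    ``cds_start_bp <= cds_end_bp``; the strand decides which end is the
    translation start.  ``cds_sequence`` carries the reference coding
    sequence (coding orientation, length divisible by 3) so consequence
    prediction does not need a genome FASTA.
    """

    gene: str
    transcript_id: str
    protein_id: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds_start_bp: int
    cds_end_bp: int
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        ex = sorted(self.exons, key=lambda e: e.start_bp)
        for a, b in zip(ex, ex[1:]):
            if a.end_bp >= b.start_bp:
                raise ValidationError("exons overlap or are unordered")
        self.exons = ex
        if self.cds_start_bp > self.cds_end_bp:
            raise ValidationError("cds_start_bp > cds_end_bp")
        for bound in (self.cds_start_bp, self.cds_end_bp):
            if not any(e.start_bp <= bound <= e.end_bp for e in ex):
                raise ValidationError(
                    f"CDS boundary {bound} falls outside all exons"
                )
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"CDS length {self.cds_length} not divisible by 3"
            )
        if self.cds_sequence is not None and len(self.cds_sequence) != self.cds_length:
            raise ValidationError("cds_sequence length != CDS length")

    @property
    def cds_length(self) -> int:
        n = 0
        for e in self.exons:
            lo = max(e.start_bp, self.cds_start_bp)
            hi = min(e.end_bp, self.cds_end_bp)
            if lo <= hi:
                n += hi - lo + 1
        return n

    @property
    def span(self) -> Interval:
        return Interval(
            self.chromosome, self.exons[0].start_bp, self.exons[-1].end_bp
        )


# ---------------------------------------------------------------------------
# PLINK transposed text
# ---------------------------------------------------------------------------


def _position_sort_index(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Stable per-chromosome position sort, chromosomes kept in first-
    appearance order."""
    order: dict[str, int] = {}
    for c in chrom:
        order.setdefault(c, len(order))
    keys = np.array([order[c] for c in chrom])
    return np.lexsort((pos, keys))


def read_tped(tped_path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK transposed text fileset (.tped plus sibling .tfam).

    Genotype code ``0`` denotes a missing allele; both alleles must be
    missing together.  The first allele label encountered in reading order
    becomes the dosage-0 allele of each marker.
    """
    tped_path = Path(tped_path)
    tfam_path = tped_path.with_suffix(".tfam")
    samples, breeds, phenos = [], [], []
    with open(tfam_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise GenioParseError(
                    f"{tfam_path} line {ln}: expected 6 fields, got {len(fields)}"
                )
            fam, iid, _father, _mother, _sex, phe = fields
            if phe not in _TFAM_PHENO:
                raise GenioParseError(
                    f"{tfam_path} line {ln}: bad phenotype code {phe!r}"
                )
            samples.append(iid)
            breeds.append(fam)
            phenos.append(_TFAM_PHENO[phe])
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{tfam_path}: duplicate sample id")
    table = make_sample_table(samples, breeds, phenos)

    n = len(samples)
    ids, chroms, poss, allele_pairs, call_rows = [], [], [], [], []
    with open(tped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4 + 2 * n:
                raise GenioParseError(
                    f"{tped_path} line {ln}: expected {4 + 2 * n} fields, "
                    f"got {len(fields)}"
                )
            chrom, mid, _cm, bp = fields[:4]
            try:
                bp_i = int(bp)
            except ValueError:
                raise GenioParseError(
                    f"{tped_path} line {ln}: bad position {bp!r}"
                ) from None
            pairs = list(zip(fields[4::2], fields[5::2]))
            labels: list[str] = []
            for a, b in pairs:
                if (a == "0") != (b == "0"):
                    raise GenioParseError(
                        f"{tped_path} line {ln}: half-missing genotype {a} {b}"
                    )
                for al in (a, b):
                    if al != "0" and al not in labels:
                        labels.append(al)
            if len(labels) > 2:
                raise GenioParseError(
                    f"{tped_path} line {ln}: more than two alleles {labels}"
                )
            while len(labels) < 2:
                labels.append("0")  # placeholder for unseen allele
            a1, a2 = labels
            row = np.empty(n, dtype=np.int8)
            for i, (a, b) in enumerate(pairs):
                if a == "0":
                    row[i] = MISSING
                else:
                    row[i] = (a == a2) + (b == a2)
            ids.append(mid)
            chroms.append(chrom)
            poss.append(bp_i)
            allele_pairs.append((a1, a2))
            call_rows.append(row)

    if len(set(ids)) != len(ids):
        raise ValidationError(f"{tped_path}: duplicate marker id")
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(poss, dtype=np.int64)
    srt = _position_sort_index(chrom_arr, pos_arr)
    markers = MarkerMap([ids[i] for i in srt], chrom_arr[srt], pos_arr[srt])
    calls = (
        np.vstack(call_rows).T[:, srt]
        if call_rows
        else np.empty((n, 0), dtype=np.int8)
    )
    g = GenotypeMatrix(samples, markers, calls, [allele_pairs[i] for i in srt])
    return g, table


def write_tped(
    g: GenotypeMatrix, table: pd.DataFrame, tped_path: str | Path
) -> None:
    """Write a GenotypeMatrix + sample table as .tped/.tfam text."""
    tped_path = Path(tped_path)
    tfam_path = tped_path.with_suffix(".tfam")
    meta = table.set_index("sample_id")
    with open(tfam_path, "w") as fh:
        for s in g.samples:
            row = meta.loc[s]
            fh.write(
                f"{row['breed']} {s} 0 0 0 {_TFAM_PHENO_INV[row['phenotype']]}\n"
            )
    with open(tped_path, "w") as fh:
        for j in range(g.n_markers):
            a1, a2 = g.alleles[j]
            words = [
                str(g.markers.chrom[j]),
                g.markers.ids[j],
                "0",
                str(g.markers.pos[j]),
            ]
            for c in g.calls[:, j]:
                if c == MISSING:
                    words += ["0", "0"]
                elif c == 0:
                    words += [a1, a1]
                elif c == 1:
                    words += [a1, a2]
                else:
                    words += [a2, a2]
            fh.write(" ".join(words) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> VariantSet:
    """Read an (uncompressed or bgzipped) VCF via pysam.

    Multi-allelic records are split into biallelic entries, one per alt
    allele, preserving position; ``./.`` maps to the same missing state as
    array no-calls.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for rec in vf:
        if rec.alts is None:
            continue
        for ai, alt in enumerate(rec.alts, start=1):
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                al = rec.samples[s]["GT"]
                if al is None or any(a is None for a in al):
                    row[i] = MISSING
                else:
                    row[i] = sum(a == ai for a in al)
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(alt)
            rows.append(row)
    vf.close()
    gt = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantSet(
        samples,
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.asarray(refs, dtype=object),
        np.asarray(alts, dtype=object),
        gt,
    )


def write_vcf(vs: VariantSet, path: str | Path) -> None:
    """Write a VariantSet as minimal VCF v4.2 text (GT only, unphased)."""
    contigs: dict[str, int] = {}
    for c, p in zip(vs.chrom, vs.pos):
        contigs[c] = max(contigs.get(c, 0), int(p))
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln + 1000}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vs.samples)
            + "\n"
        )
        for k in range(vs.n_variants):
            cols = [
                str(vs.chrom[k]),
                str(vs.pos[k]),
                ".",
                str(vs.ref[k]),
                str(vs.alt[k]),
                ".",
                ".",
                ".",
                "GT",
            ] + [gt_str[int(c)] for c in vs.gt[k]]
            fh.write("\t".join(cols) + "\n")


def variantset_to_genotypes(
    vs: VariantSet,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """View a VariantSet as an array-style GenotypeMatrix (ref = dosage-0
    allele).  Phenotype/breed are unknown: VCF carries neither."""
    srt = _position_sort_index(vs.chrom, vs.pos)
    ids = [
        f"{vs.chrom[i]}:{vs.pos[i]}_{vs.ref[i]}>{vs.alt[i]}" for i in srt
    ]
    markers = MarkerMap(ids, vs.chrom[srt], vs.pos[srt])
    g = GenotypeMatrix(
        list(vs.samples),
        markers,
        vs.gt[srt, :].T,
        [(vs.ref[i], vs.alt[i]) for i in srt],
    )
    table = make_sample_table(
        list(vs.samples),
        ["unknown"] * len(vs.samples),
        ["unknown"] * len(vs.samples),
    )
    return g, table


def read_genotypes(
    path: str | Path, dialect: str
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Dispatch on dialect: ``plink-transposed`` (path = .tped file with a
    sibling .tfam) or ``vcf``."""
    if dialect == "plink-transposed":
        return read_tped(path)
    if dialect == "vcf":
        return variantset_to_genotypes(read_vcf(path))
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open on disk, 1-based closed in memory)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise GenioParseError(
                    f"{path} line {ln}: expected >=3 BED fields"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            out.append(Interval(chrom, start + 1, end))
    return out


def write_bed(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start_bp - 1}\t{iv.end_bp}\n")


# ---------------------------------------------------------------------------
# Transcript-model table
# ---------------------------------------------------------------------------

_TX_COLUMNS = [
    "gene",
    "transcript_id",
    "protein_id",
    "chromosome",
    "strand",
    "exons",
    "cds_start_bp",
    "cds_end_bp",
    "cds_sequence",
]


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TX_COLUMNS) - set(df.columns)
    if missing:
        raise GenioParseError(
            f"{path}: missing transcript columns {sorted(missing)}"
        )
    out = []
    for _, r in df.iterrows():
        exons = []
        for part in r["exons"].split(","):
            s, e = part.split("-")
            exons.append(Interval(r["chromosome"], int(s), int(e)))
        seq = r["cds_sequence"]
        if pd.isna(seq) or seq == ".":
            seq = None
        out.append(
            TranscriptModel(
                gene=r["gene"],
                transcript_id=r["transcript_id"],
                protein_id=r["protein_id"],
                chromosome=r["chromosome"],
                strand=r["strand"],
                exons=exons,
                cds_start_bp=int(r["cds_start_bp"]),
                cds_end_bp=int(r["cds_end_bp"]),
                cds_sequence=seq,
            )
        )
    return out


def write_transcripts(
    transcripts: list[TranscriptModel], path: str | Path
) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "gene": t.gene,
                "transcript_id": t.transcript_id,
                "protein_id": t.protein_id,
                "chromosome": t.chromosome,
                "strand": t.strand,
                "exons": ",".join(
                    f"{e.start_bp}-{e.end_bp}" for e in t.exons
                ),
                "cds_start_bp": t.cds_start_bp,
                "cds_end_bp": t.cds_end_bp,
                "cds_sequence": t.cds_sequence or ".",
            }
        )
    pd.DataFrame(rows, columns=_TX_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Serialize a report as a tab-separated file.

    Accepts any object with a ``to_frame()`` method (FilterReport,
    GenotypeCountTable) or a pandas DataFrame (association results).
    Column order is deterministic and numbers carry no locale grouping.
    """
    if hasattr(report, "to_frame"):
        df = report.to_frame()
    elif isinstance(report, pd.DataFrame):
        df = report
    else:
        raise TypeError(f"cannot serialize {type(report).__name__} as report")
    df.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
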