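"""Minimal transcript-aware consequence annotation.

Maps genomic positions onto coding-DNA (c.) coordinates through a
:class:`~eclemap.genio.TranscriptModel`, translates ref/alt codons with the
standard genetic code, and emits HGVS-style ``c.``/``p.`` designations plus
a coarse consequence class.  The reference codon context comes from the
transcript's stored CDS sequence, so no genome FASTA is required.

Classes: missense, nonsense, synonymous, splice-site (within 2 intronic
bases of an exon boundary, the canonical GT/AG positions), intronic, utr,
intergenic, and frameshift-proxy for indels (no p. notation attempted).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genio import TranscriptModel, ValidationError, VariantSet

SPLICE_WINDOW = 2  # intronic bases adjacent to an exon treated as splice-site

PROTEIN_CHANGING = frozenset(
    {"missense", "nonsense", "splice-site", "frameshift-proxy"}
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """Declared ref allele disagrees with the transcript's CDS sequence."""


@dataclass
class ConsequenceCall:
    """One variant annotated against one transcript."""

    chromosome: str
    position_bp: int
    ref: str
    alt: str
    transcript_id: str
    consequence_class: str
    cds_position: int | None = None
    codon_index: int | None = None
    ref_residue: str | None = None  # 3-letter code
    alt_residue: str | None = None
    hgvs_c: str = ""
    hgvs_p: str = ""


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------


def _coding_positions(t: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in ascending genomic order."""
    out = []
    for e in t.exons:
        lo = max(e.start_bp, t.cds_start_bp)
        hi = min(e.end_bp, t.cds_end_bp)
        if lo <= hi:
            out.extend(range(lo, hi + 1))
    return out


def genomic_to_cds(position_bp: int, t: TranscriptModel,
                   chromosome: str | None = None) -> int | str:
    """Map a genomic position to a 1-based CDS coordinate, or return the
    non-coding category it falls in.

    On the + strand c.1 is the base at ``cds_start_bp``; on the − strand
    counting starts at ``cds_end_bp`` and proceeds leftward.  Intronic
    positions within :data:`SPLICE_WINDOW` bp of an exon boundary return
    ``"splice-site"``; exonic positions outside the CDS return ``"utr"``;
    other in-span positions ``"intronic"``; positions outside the
    transcript span ``"intergenic"``.
    """
    if chromosome is not None and chromosome != t.chromosome:
        raise ValidationError(
            f"position on {chromosome} but transcript {t.transcript_id} "
            f"is on {t.chromosome}"
        )
    span = t.span
    if not (span.start_bp <= position_bp <= span.end_bp):
        return "intergenic"
    in_exon = any(
        e.start_bp <= position_bp <= e.end_bp for e in t.exons
    )
    if not in_exon:
        near_boundary = any(
            0 < e.start_bp - position_bp <= SPLICE_WINDOW
            or 0 < position_bp - e.end_bp <= SPLICE_WINDOW
            for e in t.exons
        )
        return "splice-site" if near_boundary else "intronic"
    if not (t.cds_start_bp <= position_bp <= t.cds_end_bp):
        return "utr"
    coding = _coding_positions(t)
    idx = coding.index(position_bp)  # exonic+in-CDS => present
    if t.strand == "+":
        return idx + 1
    return len(coding) - idx


def cds_to_genomic(cds_position: int, t: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cds` for coding positions."""
    coding = _coding_positions(t)
    if not (1 <= cds_position <= len(coding)):
        raise ValidationError(
            f"CDS position {cds_position} outside 1..{len(coding)}"
        )
    if t.strand == "+":
        return coding[cds_position - 1]
    return coding[len(coding) - cds_position]


# ---------------------------------------------------------------------------
# Consequence prediction
# ---------------------------------------------------------------------------


def annotate(
    chromosome: str,
    position_bp: int,
    ref: str,
    alt: str,
    t: TranscriptModel,
) -> ConsequenceCall:
    """Annotate a single variant against one transcript.

    Single-nucleotide substitutions get full c./p. treatment; indels are
    classed ``frameshift-proxy`` without protein notation.  The transcript
    must carry its reference CDS sequence; a disagreement between that
    sequence and the declared ref allele raises
    :class:`ReferenceMismatchError`.
    """
    call = ConsequenceCall(
        chromosome=chromosome,
        position_bp=position_bp,
        ref=ref,
        alt=alt,
        transcript_id=t.transcript_id,
        consequence_class="intergenic",
    )
    loc = genomic_to_cds(position_bp, t, chromosome=chromosome)
    if isinstance(loc, str):
        call.consequence_class = loc
        return call

    # coding position
    c = loc
    if len(ref) != 1 or len(alt) != 1:
        call.consequence_class = "frameshift-proxy"
        call.cds_position = c
        return call
    if t.cds_sequence is None:
        raise ValidationError(
            f"transcript {t.transcript_id} has no CDS sequence; cannot "
            "predict a protein consequence"
        )
    ref_c = ref if t.strand == "+" else _revcomp(ref)
    alt_c = alt if t.strand == "+" else _revcomp(alt)
    seq = t.cds_sequence.upper()
    if seq[c - 1] != ref_c.upper():
        raise ReferenceMismatchError(
            f"CDS base {c} of {t.transcript_id} is {seq[c - 1]}, "
            f"declared ref (coding strand) is {ref_c}"
        )
    codon_index = (c - 1) // 3 + 1  # == ceil(c / 3)
    offset = (c - 1) % 3
    codon = seq[(codon_index - 1) * 3 : codon_index * 3]
    alt_codon = codon[:offset] + alt_c.upper() + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())

    if aa_alt == aa_ref:
        klass = "synonymous"
    elif aa_alt == "*":
        klass = "nonsense"
    else:
        klass = "missense"

    ref3 = "Ter" if aa_ref == "*" else seq3(aa_ref)
    alt3 = "Ter" if aa_alt == "*" else seq3(aa_alt)
    call.consequence_class = klass
    call.cds_position = c
    call.codon_index = codon_index
    call.ref_residue = ref3
    call.alt_residue = alt3
    call.hgvs_c = f"c.{c}{ref_c.upper()}>{alt_c.upper()}"
    if klass == "synonymous":
        call.hgvs_p = f"p.({ref3}{codon_index}=)"
    else:
        call.hgvs_p = f"p.({ref3}{codon_index}{alt3})"
    return call


def annotate_set(vs: VariantSet, t: TranscriptModel) -> list[ConsequenceCall]:
    """Annotate every variant of a set against one transcript (variants on
    other chromosomes come back intergenic)."""
    calls = []
    for k in range(vs.n_variants):
        if vs.chrom[k] != t.chromosome:
            calls.append(
                ConsequenceCall(
                    chromosome=vs.chrom[k],
                    position_bp=int(vs.pos[k]),
                    ref=vs.ref[k],
                    alt=vs.alt[k],
                    transcript_id=t.transcript_id,
                    consequence_class="intergenic",
                )
            )
        else:
            calls.append(
                annotate(vs.chrom[k], int(vs.pos[k]), vs.ref[k], vs.alt[k], t)
            )
    return calls


def is_protein_changing(call: ConsequenceCall) -> bool:
    """True for missense/nonsense/splice-site/frameshift-proxy calls."""
    return call.consequence_class in PROTEIN_CHANGING
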