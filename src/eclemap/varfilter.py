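"""Recessive-candidate prioritization cascade over case and control-panel
variant sets.

Five steps, mirroring the classic private-homozygous filtering layout:

1. variants homozygous-alt in every sequenced case, genome-wide;
2. of those, variants whose alt allele is absent from the control panel;
3. the step-1 set restricted to the critical interval;
4. of those, variants private against the panel;
5. of those, protein-changing by transcript annotation.

Step 3 is recomputed from step 1 (not from step 2), so counts are
non-increasing only against the applicable predecessor.  "Private" defaults
to strict allele absence: a single heterozygous panel genome disqualifies a
variant; a lenient mode requiring a homozygous panel carrier is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import Interval, ValidationError, VariantSet
from .varannot import TranscriptModel, annotate_set, is_protein_changing

CASCADE_STEPS = [
    "shared_homozygous_genome_wide",
    "private_genome_wide",
    "shared_homozygous_in_interval",
    "private_in_interval",
    "protein_changing_in_interval",
]

# step index -> applicable predecessor for the monotonicity audit
_PREDECESSOR = {1: 0, 2: 0, 3: 2, 4: 3}


@dataclass
class ControlPanel:
    """Allele-presence index over a panel of control genomes.

    Built from one or more VariantSets; queryable by
    (chromosome, position, ref, alt).  ``strict`` presence counts any
    genotype carrying the alt allele (het included); the lenient
    alternative counts homozygous-alt genomes only.
    """

    n_genomes: int
    _present: set = field(default_factory=set)
    _hom_present: set = field(default_factory=set)

    @classmethod
    def from_variant_sets(cls, panels: list[VariantSet]) -> "ControlPanel":
        present: set = set()
        hom: set = set()
        n = 0
        for vs in panels:
            n += len(vs.samples)
            carrier = (vs.gt >= 1).any(axis=1)
            hom_carrier = (vs.gt == 2).any(axis=1)
            for k in np.where(carrier)[0]:
                present.add(
                    (vs.chrom[k], int(vs.pos[k]), vs.ref[k], vs.alt[k])
                )
            for k in np.where(hom_carrier)[0]:
                hom.add((vs.chrom[k], int(vs.pos[k]), vs.ref[k], vs.alt[k]))
        return cls(n_genomes=n, _present=present, _hom_present=hom)

    def contains(
        self, chrom: str, pos: int, ref: str, alt: str, strict: bool = True
    ) -> bool:
        key = (chrom, int(pos), ref, alt)
        return key in (self._present if strict else self._hom_present)


@dataclass
class FilterReport:
    """Ordered per-step labels, survivor counts and survivor identifiers —
    the machine twin of a five-row filtering table."""

    steps: list[str]
    counts: list[int]
    survivors: list[list[tuple]]  # per step, (chrom,pos,ref,alt) keys

    def __post_init__(self) -> None:
        if self.steps != CASCADE_STEPS:
            raise ValidationError("cascade step labels out of canonical order")
        if len(self.counts) != len(self.steps):
            raise ValidationError("count per step required")
        for i, j in _PREDECESSOR.items():
            if self.counts[i] > self.counts[j]:
                raise ValidationError(
                    f"cascade not monotone: step {self.steps[i]} "
                    f"({self.counts[i]}) exceeds {self.steps[j]} "
                    f"({self.counts[j]})"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"filtering_step": self.steps, "variants": self.counts}
        )

    @property
    def final_survivors(self) -> list[tuple]:
        return self.survivors[-1]


# ---------------------------------------------------------------------------
# Primitive steps
# ---------------------------------------------------------------------------


def merge_case_sets(cases: list[VariantSet]) -> VariantSet:
    """Outer-join per-case VariantSets on (chrom, pos, ref, alt); a case
    without a record for a key is hom-ref (0) there."""
    if not cases:
        raise ValidationError("no case variant sets")
    if len(cases) == 1:
        return cases[0]
    keys: dict[tuple, int] = {}
    for vs in cases:
        for key in vs.keys():
            keys.setdefault(key, len(keys))
    samples: list[str] = []
    for vs in cases:
        samples.extend(vs.samples)
    gt = np.zeros((len(keys), len(samples)), dtype=np.int8)
    col = 0
    for vs in cases:
        ncol = len(vs.samples)
        for k, key in enumerate(vs.keys()):
            gt[keys[key], col : col + ncol] = vs.gt[k]
        col += ncol
    ordered = sorted(keys, key=lambda t: (t[0], t[1], t[2], t[3]))
    rows = np.array([keys[k] for k in ordered])
    return VariantSet(
        samples,
        np.array([k[0] for k in ordered], dtype=object),
        np.array([k[1] for k in ordered], dtype=np.int64),
        np.array([k[2] for k in ordered], dtype=object),
        np.array([k[3] for k in ordered], dtype=object),
        gt[rows],
    )


def shared_homozygous(cases: list[VariantSet]) -> VariantSet:
    """Variants homozygous-alt for the same alt allele in every sequenced
    case."""
    merged = merge_case_sets(cases)
    keep = (merged.gt == 2).all(axis=1)
    return merged.subset(np.where(keep)[0])


def private_against(
    vs: VariantSet, panel: ControlPanel, strict: bool = True
) -> VariantSet:
    """Retain variants whose alt allele is absent from the control panel."""
    keep = [
        k
        for k in range(vs.n_variants)
        if not panel.contains(
            vs.chrom[k], int(vs.pos[k]), vs.ref[k], vs.alt[k], strict=strict
        )
    ]
    return vs.subset(np.array(keep, dtype=int))


def restrict_to(vs: VariantSet, interval: Interval) -> VariantSet:
    """Variants with position inside the closed interval."""
    keep = (
        (vs.chrom == interval.chromosome)
        & (vs.pos >= interval.start_bp)
        & (vs.pos <= interval.end_bp)
    )
    return vs.subset(np.where(keep)[0])


def protein_changing(
    vs: VariantSet, transcripts: list[TranscriptModel]
) -> VariantSet:
    """Variants protein-changing against at least one transcript."""
    keep = np.zeros(vs.n_variants, dtype=bool)
    for t in transcripts:
        for k, call in enumerate(annotate_set(vs, t)):
            if is_protein_changing(call):
                keep[k] = True
    return vs.subset(np.where(keep)[0])


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def run_cascade(
    cases: list[VariantSet],
    panel: ControlPanel,
    interval: Interval,
    transcripts: list[TranscriptModel],
    strict_private: bool = True,
) -> FilterReport:
    """Execute the five-step prioritization cascade and report per-step
    survivor counts and identities."""
    s1 = shared_homozygous(cases)
    s2 = private_against(s1, panel, strict=strict_private)
    s3 = restrict_to(s1, interval)
    s4 = private_against(s3, panel, strict=strict_private)
    s5 = protein_changing(s4, transcripts)
    stages = [s1, s2, s3, s4, s5]
    return FilterReport(
        steps=list(CASCADE_STEPS),
        counts=[s.n_variants for s in stages],
        survivors=[s.keys() for s in stages],
    )
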