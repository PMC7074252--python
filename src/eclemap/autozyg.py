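"""Shared-homozygous-haplotype detection across cases and critical-interval
definition.

Under a fully penetrant recessive model, affected individuals from a closed
population are autozygous around the causal variant: they are homozygous
for the same ancestral allele at every marker of the shared segment.  This
module finds the maximal runs of consecutive markers at which every case is
homozygous for one common allele, and widens each run to the critical
interval bounded by the first flanking discordant (heterozygous or
allele-mismatched) markers — the region that must contain the causal
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, Interval, MarkerMap, MISSING, ValidationError


@dataclass
class SharedSegment:
    """A maximal run of markers homozygous-shared across all cases."""

    chromosome: str
    first_marker_index: int  # indices into the MarkerMap (global)
    last_marker_index: int
    n_markers: int
    interval: Interval  # critical interval (flank-to-flank)
    support: np.ndarray  # per-case count of homozygous-concordant markers

    def to_row(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "first_marker_index": self.first_marker_index,
            "last_marker_index": self.last_marker_index,
            "n_markers": self.n_markers,
            "interval_start_bp": self.interval.start_bp,
            "interval_end_bp": self.interval.end_bp,
            "interval_kb": self.interval.length_kb,
        }


def _marker_compatibility(
    case_calls: np.ndarray, max_missing_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker segment compatibility for a cases-only call matrix.

    A marker is compatible when no case is heterozygous, all non-missing
    calls agree on one homozygous state, and the missing fraction does not
    exceed the tolerance.  Returns (compatible, shared_allele_state) where
    state is 0/2 or -1 when all calls are missing.
    """
    n_cases, m = case_calls.shape
    het = (case_calls == 1).any(axis=0)
    n_missing = (case_calls == MISSING).sum(axis=0)
    has_ref = (case_calls == 0).any(axis=0)
    has_alt = (case_calls == 2).any(axis=0)
    discordant = has_ref & has_alt
    compatible = (
        ~het
        & ~discordant
        & (n_missing <= max_missing_fraction * n_cases)
    )
    state = np.full(m, -1, dtype=np.int8)
    state[has_alt] = 2
    state[has_ref] = 0
    return compatible, state


def find_shared_homozygous_segments(
    g: GenotypeMatrix,
    min_markers: int = 25,
    max_missing_fraction: float = 0.2,
) -> list[SharedSegment]:
    """Maximal runs of consecutive markers homozygous for one shared allele
    in every case.

    ``g`` must already be restricted to the case samples.  Missing calls
    cannot prove discordance and are tolerated up to
    ``max_missing_fraction`` of cases per marker.  Runs shorter than
    ``min_markers`` are dropped.  Segments are reported per chromosome in
    position order.
    """
    if g.n_samples == 0:
        raise ValidationError("segment search requires at least one case")
    compatible, _state = _marker_compatibility(g.calls, max_missing_fraction)
    hom_concordant = (g.calls == 0) | (g.calls == 2)  # per case support

    segments: list[SharedSegment] = []
    for chrom in g.markers.chromosomes():
        idx = np.where(g.markers.chrom == chrom)[0]
        comp = compatible[idx]
        # maximal runs of True
        run_start = None
        for k in range(len(idx) + 1):
            inside = k < len(idx) and comp[k]
            if inside and run_start is None:
                run_start = k
            elif not inside and run_start is not None:
                first, last = idx[run_start], idx[k - 1]
                n = k - run_start
                if n >= min_markers:
                    segments.append(
                        _build_segment(
                            g, chrom, int(first), int(last), hom_concordant
                        )
                    )
                run_start = None
    return segments


def _build_segment(
    g: GenotypeMatrix,
    chrom: str,
    first: int,
    last: int,
    hom_concordant: np.ndarray,
) -> SharedSegment:
    interval = critical_interval_from_indices(first, last, g.markers)
    support = hom_concordant[:, first : last + 1].sum(axis=1)
    return SharedSegment(
        chromosome=chrom,
        first_marker_index=first,
        last_marker_index=last,
        n_markers=last - first + 1,
        interval=interval,
        support=support,
    )


def critical_interval_from_indices(
    first: int, last: int, markers: MarkerMap
) -> Interval:
    """Critical interval for a segment given by marker indices: from the
    first flanking marker left of the segment to the first flanking marker
    right of it (chromosome's first/last marker position when no flank
    exists), closed on both ends."""
    if not (0 <= first <= last < len(markers)):
        raise ValidationError("segment indices out of range")
    chrom = markers.chrom[first]
    if markers.chrom[last] != chrom:
        raise ValidationError("segment spans chromosomes")
    on_chrom = np.where(markers.chrom == chrom)[0]
    lo, hi = int(on_chrom[0]), int(on_chrom[-1])
    if not (lo <= first <= last <= hi):
        raise ValidationError("segment indices out of range")
    left = first - 1 if first > lo else first
    right = last + 1 if last < hi else last
    return Interval(
        str(chrom), int(markers.pos[left]), int(markers.pos[right])
    )


def critical_interval(segment: SharedSegment, markers: MarkerMap) -> Interval:
    """Critical interval of a segment: the span between the first flanking
    discordant markers on either side (see paper-style boundary rule)."""
    return critical_interval_from_indices(
        segment.first_marker_index, segment.last_marker_index, markers
    )


def rank_segments(
    segments: list[SharedSegment], assoc: pd.DataFrame | None = None
) -> list[SharedSegment]:
    """Order segments by the best contained association p-value (ascending),
    ties broken by marker count (descending) then by genomic position.

    Without association results the ordering falls back to marker count
    then position.  Deterministic for any input order.
    """

    def best_p(seg: SharedSegment) -> float:
        if assoc is None:
            return 1.0
        on = (
            (assoc["chromosome"].to_numpy() == seg.chromosome)
            & (assoc["position_bp"].to_numpy() >= seg.interval.start_bp)
            & (assoc["position_bp"].to_numpy() <= seg.interval.end_bp)
        )
        if not on.any():
            return 1.0
        return float(assoc.loc[on, "p_value"].min())

    return sorted(
        segments,
        key=lambda s: (
            best_p(s),
            -s.n_markers,
            s.chromosome,
            s.interval.start_bp,
        ),
    )


def segments_to_frame(segments: list[SharedSegment]) -> pd.DataFrame:
    cols = [
        "chromosome",
        "first_marker_index",
        "last_marker_index",
        "n_markers",
        "interval_start_bp",
        "interval_end_bp",
        "interval_kb",
    ]
    return pd.DataFrame([s.to_row() for s in segments], columns=cols)
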