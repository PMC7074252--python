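"""Synthetic breed-population generator.

Emulates the data a recessive-disease mapping study in a closed dog breed
rests on: a founder bottleneck followed by a few generations of random
mating with recombination produces long-range LD and long autozygous
haplotypes; one founder haplotype carries a causal alt allele embedded in
an identity-by-descent (IBD) segment that every affected individual
carries in two copies; an array tier (marker subset with missingness), a
sequence tier (called genotypes at all simulated sites for a couple of
sequenced cases), and a large control genome panel constructed from the
non-carrier founder pool, hence guaranteed free of the causal allele.

Two deliberate simplifications keep the truth auditable:

* gametes that transmit the causal allele inherit a core IBD segment of
  the configured length intact (crossovers inside it are resolved by
  copying the carrier parent's whole segment); the recorded truth interval
  is the *realized* region over which all true cases are homozygous and
  concordant at the sequence tier, which contains that core and extends
  beyond it by whatever sharing recombination left standing;
* the control panel's founder pool contains the ancestral, mutation-free
  version of the causal founder haplotype, so every standing allele of the
  study population is represented in the panel and the causal variant
  (plus any planted neutral ones) is the only allele private to the cases.

Sequencing noise is not modelled: the cascade consumes called genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import (
    GenotypeMatrix,
    Interval,
    MarkerMap,
    TranscriptModel,
    ValidationError,
    VariantSet,
    make_sample_table,
)
from .varannot import annotate

_NUCS = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


class InfeasibleSimulation(RuntimeError):
    """The configured cohort cannot be realized (e.g. not enough causal
    homozygotes can be produced within the attempt budget)."""


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults mirror the mapped cohort: 14 array-genotyped cases and 29
    controls, 2 sequenced cases, and a 654-genome control panel.  The
    genome is scaled down to 2 chromosomes of 50 Mb with 4,000 array
    markers each (12.5 kb spacing, about the density of a 220k canine
    array) drawn from a 3x denser sequence tier; the guaranteed IBD core
    is 1 Mb (breed LD spans megabases).  Founder pool of 8 haplotypes and
    24 generations of random mating at 1 cM/Mb: the mutation segregates in
    several related breeds, so it predates breed formation by a few dozen
    generations, and that meiotic depth is what erodes the shared
    haplotype to the roughly megabase scale the mapping resolves.
    Residual array missingness is 0.5% per call (BeadChips deliver >99%
    call rates once low-quality samples are dropped).
    """

    seed: int = 0
    n_founder_haplotypes: int = 8
    n_cases: int = 14
    n_controls: int = 29
    n_sequenced_cases: int = 2
    n_markers_per_chromosome: int = 4000
    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    causal_chromosome: str = "1"
    causal_position_bp: int = 25_000_000
    ibd_segment_length_bp: int = 1_000_000
    missing_rate: float = 0.005
    phenotype_error_rate: float = 0.0
    n_control_genomes: int = 654
    n_neutral_private_variants: int = 1
    recombination_rate_per_bp: float = 1e-8
    n_generations: int = 24
    population_size: int = 250
    sequence_site_factor: int = 3
    max_attempts_per_case: int = 200
    breed: str = "GSP-sim"

    def __post_init__(self) -> None:
        for name in ("missing_rate", "phenotype_error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not (1 <= self.causal_position_bp <= self.chromosome_length_bp):
            raise ValidationError("causal position outside its chromosome")
        if self.ibd_segment_length_bp < 1:
            raise ValidationError("ibd_segment_length_bp must be positive")
        if self.n_sequenced_cases > self.n_cases:
            raise ValidationError("more sequenced cases than cases")

    @property
    def chromosome_labels(self) -> list[str]:
        labels = [self.causal_chromosome]
        k = 1
        while len(labels) < self.n_chromosomes:
            if str(k) not in labels:
                labels.append(str(k))
            k += 1
        return labels

    @property
    def core_interval(self) -> Interval:
        """The forced IBD core around the causal position; the realized
        truth interval recorded in the study is at least this wide."""
        half = self.ibd_segment_length_bp // 2
        return Interval(
            self.causal_chromosome,
            max(1, self.causal_position_bp - half),
            min(
                self.chromosome_length_bp, self.causal_position_bp + half
            ),
        )


@dataclass
class TruthRecord:
    causal_chromosome: str
    causal_position_bp: int
    causal_ref: str
    causal_alt: str
    ibd_interval: Interval
    phenotype_error_samples: list[str]
    planted_private: list[tuple[str, int, str, str]] = field(
        default_factory=list
    )


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix  # array tier
    samples: pd.DataFrame
    case_variants: list[VariantSet]  # one per sequenced case
    cohort_variants: VariantSet  # all study samples, sequence tier
    panel_variants: VariantSet  # control genome panel
    transcript: TranscriptModel
    truth: TruthRecord
    config: SimConfig


# ---------------------------------------------------------------------------
# Haplotype machinery
# ---------------------------------------------------------------------------


def _sample_positions(
    rng: np.random.Generator, n: int, length: int, include: list[int]
) -> np.ndarray:
    """n sorted unique positions in [1, length], forcing ``include`` in."""
    pool = set(include)
    while len(pool) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(pool)))
        pool.update(int(x) for x in draw)
    free = np.array(sorted(pool - set(include)), dtype=np.int64)
    pick = rng.choice(len(free), size=n - len(include), replace=False)
    out = np.concatenate(
        [free[np.sort(pick)], np.array(include, dtype=np.int64)]
    )
    return np.sort(out)


def _meiosis(
    rng: np.random.Generator,
    h1: np.ndarray,
    h2: np.ndarray,
    positions: np.ndarray,
    length: int,
    rate: float,
    segment_sites: np.ndarray | None,
    causal_idx: int | None,
) -> np.ndarray:
    """One gamete from a diploid parent on one chromosome.

    Poisson crossovers at uniform positions; if the gamete ends up carrying
    the causal allele, the full IBD segment is copied from the contributing
    parental haplotype so the segment travels intact.
    """
    n_x = rng.poisson(rate * length)
    start = rng.integers(0, 2)
    if n_x == 0:
        gamete = (h1 if start == 0 else h2).copy()
        source = np.full(len(positions), start)
    else:
        bps = np.sort(rng.integers(1, length + 1, size=n_x))
        source = (np.searchsorted(bps, positions, side="right") + start) % 2
        gamete = np.where(source == 0, h1, h2)
    if causal_idx is not None and gamete[causal_idx] == 1:
        donor = h1 if source[causal_idx] == 0 else h2
        gamete[segment_sites] = donor[segment_sites]
    return gamete


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Reference CDS without internal stops, ending in a stop codon."""
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_NUCS, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _build_transcript(cfg: SimConfig, rng: np.random.Generator) -> TranscriptModel:
    """A toy protein-coding gene inside the IBD segment whose CDS covers
    the causal position; the causal substitution is guaranteed missense
    (a CC-initial codon hit at its first base, C>A: Pro -> Thr)."""
    cds_len = 1500  # 500 codons
    causal_cds_pos = 1438  # first base of codon 480
    # + strand, single coding exon flanked by two UTR-bearing exons
    cds_start = cfg.causal_position_bp - (causal_cds_pos - 1)
    cds_end = cds_start + cds_len - 1
    exon2 = Interval(cfg.causal_chromosome, cds_start - 60, cds_end + 90)
    exon1 = Interval(
        cfg.causal_chromosome, exon2.start_bp - 500, exon2.start_bp - 300
    )
    exon3 = Interval(
        cfg.causal_chromosome, exon2.end_bp + 400, exon2.end_bp + 600
    )
    seq = list(_random_cds(rng, cds_len // 3))
    idx0 = causal_cds_pos - 1
    codon_start = (idx0 // 3) * 3
    seq[codon_start] = "C"
    seq[codon_start + 1] = "C"
    seq[idx0] = "C"  # idx0 == codon_start (offset 0)
    return TranscriptModel(
        gene="SIMGENE1",
        transcript_id="SIMT1.1",
        protein_id="SIMP1.1",
        chromosome=cfg.causal_chromosome,
        strand="+",
        exons=[exon1, exon2, exon3],
        cds_start_bp=cds_start,
        cds_end_bp=cds_end,
        cds_sequence="".join(seq),
    )


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def simulate_study(cfg: SimConfig | None = None) -> SimulatedStudy:
    """Gene-drop a bottlenecked breed population and assemble all study
    tiers.  Deterministic given ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.chromosome_labels
    n_seq = cfg.n_markers_per_chromosome * cfg.sequence_site_factor
    length = cfg.chromosome_length_bp

    # --- sites, allele labels, founder haplotypes
    positions: dict[str, np.ndarray] = {}
    for c in labels:
        include = (
            [cfg.causal_position_bp] if c == cfg.causal_chromosome else []
        )
        positions[c] = _sample_positions(rng, n_seq, length, include)
    causal_idx = int(
        np.searchsorted(
            positions[cfg.causal_chromosome], cfg.causal_position_bp
        )
    )
    ref_alleles: dict[str, np.ndarray] = {}
    alt_alleles: dict[str, np.ndarray] = {}
    for c in labels:
        r = rng.integers(0, 4, size=n_seq)
        a = (r + rng.integers(1, 4, size=n_seq)) % 4
        ref_alleles[c] = _NUCS[r].astype(object)
        alt_alleles[c] = _NUCS[a].astype(object)
    ref_alleles[cfg.causal_chromosome][causal_idx] = "C"
    alt_alleles[cfg.causal_chromosome][causal_idx] = "A"

    founders: dict[str, np.ndarray] = {}
    for c in labels:
        p = rng.uniform(0.1, 0.9, size=n_seq)
        founders[c] = (
            rng.random((cfg.n_founder_haplotypes, n_seq)) < p
        ).astype(np.int8)
    # founder 0 carries the causal allele on an otherwise ordinary
    # haplotype; the mutation-free (ancestral) copy of that haplotype goes
    # into the panel's founder pool, so the causal allele is the study
    # population's only panel-absent allele
    core_iv = cfg.core_interval
    cpos = positions[cfg.causal_chromosome]
    seg_sites = np.where(
        (cpos >= core_iv.start_bp) & (cpos <= core_iv.end_bp)
    )[0]
    fc = founders[cfg.causal_chromosome]
    fc[:, causal_idx] = 0
    fc[0, causal_idx] = 1

    # --- forward gene drop
    def meiosis(ind, c):
        seg = seg_sites if c == cfg.causal_chromosome else None
        ci = causal_idx if c == cfg.causal_chromosome else None
        return _meiosis(
            rng,
            ind[c][0],
            ind[c][1],
            positions[c],
            length,
            cfg.recombination_rate_per_bp,
            seg,
            ci,
        )

    def make_child(p1, p2):
        return {c: np.stack([meiosis(p1, c), meiosis(p2, c)]) for c in labels}

    cchrom = cfg.causal_chromosome

    def causal_dosage(ind) -> int:
        return int(ind[cchrom][0][causal_idx] + ind[cchrom][1][causal_idx])

    # gene drop, conditioned on survival of the causal allele: the study
    # exists only because the disease allele is still segregating, so a
    # drop in which drift loses it is rejected and redrawn (bounded)
    max_drops = 30
    for _drop in range(max_drops):
        pop = []
        for _ in range(cfg.population_size):
            pop.append(
                {
                    c: founders[c][
                        rng.integers(0, cfg.n_founder_haplotypes, size=2)
                    ].copy()
                    for c in labels
                }
            )
        for _ in range(cfg.n_generations):
            nxt = []
            for _ in range(cfg.population_size):
                i, j = rng.choice(cfg.population_size, size=2, replace=False)
                nxt.append(make_child(pop[i], pop[j]))
            pop = nxt
        carriers = [ind for ind in pop if causal_dosage(ind) >= 1]
        if len(carriers) >= 2:
            break
    else:
        raise InfeasibleSimulation(
            f"causal allele lost in {max_drops} consecutive gene drops; "
            "fewer than 2 carriers available to mate"
        )

    # --- sample cases (carrier x carrier offspring, homozygous required)
    cases = []
    budget = cfg.max_attempts_per_case * cfg.n_cases
    while len(cases) < cfg.n_cases:
        if budget <= 0:
            raise InfeasibleSimulation(
                f"could not realize {cfg.n_cases} causal homozygotes within "
                "the attempt budget"
            )
        budget -= 1
        i, j = rng.choice(len(carriers), size=2, replace=False)
        child = make_child(carriers[i], carriers[j])
        if causal_dosage(child) == 2:
            cases.append(child)

    # --- phenotype errors: mislabel a non-homozygote as case
    error_ids: list[str] = []
    err_mask = rng.random(cfg.n_cases) < cfg.phenotype_error_rate
    for k in np.where(err_mask)[0]:
        for _ in range(cfg.max_attempts_per_case):
            i, j = rng.choice(cfg.population_size, size=2, replace=False)
            child = make_child(pop[i], pop[j])
            if causal_dosage(child) < 2:
                cases[k] = child
                error_ids.append(f"case_{k + 1:03d}")
                break
        else:  # pragma: no cover - would need a near-fixed causal allele
            raise InfeasibleSimulation("could not draw a non-homozygote")

    # --- controls: unaffected, hence not homozygous for the causal allele
    controls = []
    budget = cfg.max_attempts_per_case * max(cfg.n_controls, 1)
    while len(controls) < cfg.n_controls:
        if budget <= 0:
            raise InfeasibleSimulation("could not draw enough controls")
        budget -= 1
        i, j = rng.choice(cfg.population_size, size=2, replace=False)
        child = make_child(pop[i], pop[j])
        if causal_dosage(child) < 2:
            controls.append(child)

    individuals = cases + controls
    sample_ids = [f"case_{k + 1:03d}" for k in range(cfg.n_cases)] + [
        f"control_{k + 1:03d}" for k in range(cfg.n_controls)
    ]
    phenotypes = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    samples = make_sample_table(
        sample_ids, [cfg.breed] * len(sample_ids), phenotypes
    )

    # --- sequence tier: dosages at every site for every study sample
    dosage_blocks = []
    chrom_col, pos_col, ref_col, alt_col = [], [], [], []
    for c in labels:
        block = np.stack(
            [ind[c][0] + ind[c][1] for ind in individuals]
        ).T.astype(np.int8)  # (n_sites, n_samples)
        dosage_blocks.append(block)
        chrom_col.append(np.full(n_seq, c, dtype=object))
        pos_col.append(positions[c])
        ref_col.append(ref_alleles[c])
        alt_col.append(alt_alleles[c])
    cohort = VariantSet(
        sample_ids,
        np.concatenate(chrom_col),
        np.concatenate(pos_col),
        np.concatenate(ref_col),
        np.concatenate(alt_col),
        np.vstack(dosage_blocks),
    )

    # --- array tier: every sequence_site_factor-th site, causal excluded
    array_rows = []
    offset = 0
    for c in labels:
        take = np.arange(0, n_seq, cfg.sequence_site_factor)
        if c == cfg.causal_chromosome:
            take = take[take != causal_idx]
        array_rows.append(take + offset)
        offset += n_seq
    array_rows = np.concatenate(array_rows)
    markers = MarkerMap(
        [
            f"m_{cohort.chrom[i]}_{cohort.pos[i]}"
            for i in array_rows
        ],
        cohort.chrom[array_rows],
        cohort.pos[array_rows],
    )
    calls = cohort.gt[array_rows, :].T.copy()
    miss = rng.random(calls.shape) < cfg.missing_rate
    calls[miss] = -1
    genotypes = GenotypeMatrix(
        sample_ids,
        markers,
        calls,
        [
            (str(cohort.ref[i]), str(cohort.alt[i]))
            for i in array_rows
        ],
    )

    # --- sequenced cases and control panel
    sequenced = [
        cohort.subset_samples([sample_ids[k]])
        for k in range(cfg.n_sequenced_cases)
    ]

    panel_blocks = []
    panel_pool = {c: founders[c].copy() for c in labels}
    panel_pool[cchrom][0, causal_idx] = 0  # ancestral, mutation-free copy
    for c in labels:
        haps = np.empty((2 * cfg.n_control_genomes, n_seq), dtype=np.int8)
        for h in range(2 * cfg.n_control_genomes):
            i, j = rng.choice(cfg.n_founder_haplotypes, size=2, replace=True)
            haps[h] = _meiosis(
                rng,
                panel_pool[c][i],
                panel_pool[c][j],
                positions[c],
                length,
                cfg.recombination_rate_per_bp,
                None,
                None,
            )
        panel_blocks.append((haps[0::2] + haps[1::2]).T.astype(np.int8))
    panel = VariantSet(
        [f"panel_{k + 1:04d}" for k in range(cfg.n_control_genomes)],
        cohort.chrom.copy(),
        cohort.pos.copy(),
        cohort.ref.copy(),
        cohort.alt.copy(),
        np.vstack(panel_blocks),
    )
    if (panel.gt[np.concatenate(chrom_col) == cchrom][causal_idx] > 0).any():
        raise AssertionError("control panel carries the causal allele")

    transcript = _build_transcript(cfg, rng)
    truth_iv = _realized_shared_interval(
        cohort, sample_ids, phenotypes, error_ids, cchrom, causal_idx, core_iv
    )
    truth = TruthRecord(
        causal_chromosome=cchrom,
        causal_position_bp=cfg.causal_position_bp,
        causal_ref="C",
        causal_alt="A",
        ibd_interval=truth_iv,
        phenotype_error_samples=error_ids,
    )
    study = SimulatedStudy(
        genotypes=genotypes,
        samples=samples,
        case_variants=sequenced,
        cohort_variants=cohort,
        panel_variants=panel,
        transcript=transcript,
        truth=truth,
        config=cfg,
    )
    if cfg.n_neutral_private_variants > 0:
        study = plant_neutral_private_variants(
            study,
            cfg.n_neutral_private_variants,
            region=truth_iv,
            rng=rng,
        )
    return study


def _realized_shared_interval(
    cohort: VariantSet,
    sample_ids: list[str],
    phenotypes: list[str],
    error_ids: list[str],
    cchrom: str,
    causal_idx: int,
    core_iv: Interval,
) -> Interval:
    """The realized truth IBD interval: the maximal run of sequence sites
    around the causal site at which every true case is homozygous and all
    agree, bounded by the first discordant flanking sites.  Contains the
    forced core and whatever sharing recombination left beyond it."""
    true_cases = [
        i
        for i, (sid, phe) in enumerate(zip(sample_ids, phenotypes))
        if phe == "case" and sid not in error_ids
    ]
    if not true_cases:
        return core_iv
    rows = np.where(cohort.chrom == cchrom)[0]
    d = cohort.gt[np.ix_(rows, true_cases)]
    hom = ((d == 0) | (d == 2)).all(axis=1)
    concordant = (d == d[:, :1]).all(axis=1)
    ok = hom & concordant
    lo = causal_idx
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = causal_idx
    while hi < len(rows) - 1 and ok[hi + 1]:
        hi += 1
    left = lo - 1 if lo > 0 else lo
    right = hi + 1 if hi < len(rows) - 1 else hi
    return Interval(
        cchrom,
        int(cohort.pos[rows[left]]),
        int(cohort.pos[rows[right]]),
    )


# ---------------------------------------------------------------------------
# Neutral private variants
# ---------------------------------------------------------------------------


def plant_neutral_private_variants(
    study: SimulatedStudy,
    n: int,
    region: Interval | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """Insert ``n`` non-coding variants homozygous-alt in every sequenced
    case and absent from the control panel, at fresh positions inside
    ``region`` (default: the truth IBD interval)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return study
    region = region or study.truth.ibd_interval
    rng = rng or np.random.default_rng(study.config.seed + 7_000_003)
    taken = {
        (c, int(p))
        for c, p in zip(study.cohort_variants.chrom, study.cohort_variants.pos)
    }
    t = study.transcript
    new: list[tuple[str, int, str, str]] = []
    attempts = 0
    while len(new) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValidationError(
                f"region {region} too small to place {n} non-coding variants"
            )
        pos = int(rng.integers(region.start_bp, region.end_bp + 1))
        if (region.chromosome, pos) in taken:
            continue
        if (
            region.chromosome == t.chromosome
            and t.span.start_bp - 10 <= pos <= t.span.end_bp + 10
        ):
            continue  # keep clear of the gene: guaranteed non-coding
        r = int(rng.integers(0, 4))
        ref = str(_NUCS[r])
        alt = str(_NUCS[(r + int(rng.integers(1, 4))) % 4])
        taken.add((region.chromosome, pos))
        new.append((region.chromosome, pos, ref, alt))

    def extend(vs: VariantSet, dosage: np.ndarray) -> VariantSet:
        return VariantSet(
            vs.samples,
            np.concatenate([vs.chrom, [c for c, *_ in new]]),
            np.concatenate([vs.pos, [p for _, p, *_ in new]]),
            np.concatenate([vs.ref, [r for *_, r, _ in new]]),
            np.concatenate([vs.alt, [a for *_, a in new]]),
            np.vstack([vs.gt, dosage]),
        )

    case_ids = [vs.samples[0] for vs in study.case_variants]
    cohort_dos = np.zeros(
        (n, len(study.cohort_variants.samples)), dtype=np.int8
    )
    for sid in case_ids:
        cohort_dos[:, study.cohort_variants.samples.index(sid)] = 2
    new_cohort = extend(study.cohort_variants, cohort_dos)
    new_cases = [
        extend(vs, np.full((n, 1), 2, dtype=np.int8))
        for vs in study.case_variants
    ]
    truth = replace(
        study.truth,
        planted_private=study.truth.planted_private + new,
    )
    return replace(
        study,
        cohort_variants=new_cohort,
        case_variants=new_cases,
        truth=truth,
    )
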