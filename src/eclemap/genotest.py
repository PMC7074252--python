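"""Exact genotype-phenotype association on candidate variants and
multi-breed genotype tabulation.

The headline test collapses the case/control x genotype table under a
recessive coding (homozygous-alt versus everything else) and applies a
two-sided Fisher exact test.  The Fisher p-value is computed in log space
so that magnitudes around 1e-40 — the scale a near-perfect association in
a few hundred dogs produces — survive without underflow.  Dominant,
allelic and full-genotypic (2x3, exact enumeration with a seeded
Monte-Carlo fallback) codings are also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import MISSING, ValidationError

GENOTYPE_COLS = ["n_hom_ref", "n_het", "n_hom_alt"]

#: margin totals below this are reported but not tested on their own
MIN_MARGIN_COUNT = 5


@dataclass
class GenotypeCountTable:
    """Counts of hom-ref / het / hom-alt per (breed, phenotype) row."""

    counts: pd.DataFrame  # breed, phenotype, n_hom_ref, n_het, n_hom_alt,
    # n_missing, n

    def __post_init__(self) -> None:
        df = self.counts
        need = ["breed", "phenotype", *GENOTYPE_COLS, "n_missing", "n"]
        if list(df.columns) != need:
            raise ValidationError(f"count table columns must be {need}")
        if (df[GENOTYPE_COLS + ["n_missing"]] < 0).any().any():
            raise ValidationError("negative count")
        if not (df[GENOTYPE_COLS].sum(axis=1) == df["n"]).all():
            raise ValidationError("row totals do not match declared n")

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()

    def collapsed(
        self, breeds: list[str] | None = None
    ) -> pd.DataFrame:
        """Genotype counts summed per phenotype, optionally restricted to a
        breed subset."""
        df = self.counts
        if breeds is not None:
            missing = set(breeds) - set(df["breed"])
            if missing:
                raise ValidationError(f"breeds absent from table: {missing}")
            df = df[df["breed"].isin(breeds)]
        return df.groupby("phenotype")[GENOTYPE_COLS].sum()


@dataclass
class AssocTestResult:
    coding: str
    table: np.ndarray  # the contingency table actually tested
    p_value: float
    odds_ratio: float | None = None
    odds_ratio_corrected: bool = False


def tabulate_genotypes(
    calls: np.ndarray, sample_ids: list[str], samples: pd.DataFrame
) -> GenotypeCountTable:
    """Tabulate one variant's per-sample dosages by (breed, phenotype).

    Missing calls are tallied separately and excluded from the row n.
    Every sample with a call must appear in the metadata table.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if len(calls) != len(sample_ids):
        raise ValidationError("calls and sample ids differ in length")
    meta = samples.set_index("sample_id")
    rows: dict[tuple[str, str], list[int]] = {}
    for c, sid in zip(calls, sample_ids):
        if sid not in meta.index:
            raise ValidationError(f"sample {sid} has a call but no metadata")
        key = (meta.loc[sid, "breed"], meta.loc[sid, "phenotype"])
        row = rows.setdefault(key, [0, 0, 0, 0])
        if c == MISSING:
            row[3] += 1
        else:
            row[int(c)] += 1
    recs = []
    for (breed, phe), (hr, het, ha, miss) in sorted(rows.items()):
        recs.append(
            {
                "breed": breed,
                "phenotype": phe,
                "n_hom_ref": hr,
                "n_het": het,
                "n_hom_alt": ha,
                "n_missing": miss,
                "n": hr + het + ha,
            }
        )
    df = pd.DataFrame(
        recs,
        columns=["breed", "phenotype", *GENOTYPE_COLS, "n_missing", "n"],
    )
    return GenotypeCountTable(df)


# ---------------------------------------------------------------------------
# Fisher exact, 2x2, log-space
# ---------------------------------------------------------------------------


def _log_hypergeom(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(top-left cell = a) under fixed margins (r1, r2) x (c1, .)."""
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
        - (
            gammaln(r1 + r2 + 1)
            - gammaln(c1 + 1)
            - gammaln(r1 + r2 - c1 + 1)
        )
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sidedness: str = "two-sided"
) -> float:
    """Fisher exact test for the table [[a, b], [c, d]].

    Two-sided p sums the probabilities of every table with the observed
    margins whose probability does not exceed the observed one (relative
    tolerance 1e-7 on the comparison).  All probabilities are handled in
    log space, so p-values around 1e-40 come out finite and accurate.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValidationError("negative cell count")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValidationError("empty table")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logs = np.array([_log_hypergeom(int(k), r1, r2, c1) for k in ks])
    obs = logs[ks == a][0]
    if sidedness == "two-sided":
        inc = logs <= obs + math.log1p(1e-7)
    elif sidedness == "greater":
        inc = ks >= a
    elif sidedness == "less":
        inc = ks <= a
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    m = logs[inc].max()
    log_p = m + math.log(np.exp(logs[inc] - m).sum())
    return float(min(1.0, math.exp(log_p)))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Sample odds ratio; Haldane-Anscombe +0.5 in every cell when any cell
    is zero (flagged)."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c), corrected


# ---------------------------------------------------------------------------
# 2x3 genotypic exact test
# ---------------------------------------------------------------------------


def _fisher_2x3_exact(table: np.ndarray) -> float:
    """Exact conditional test on a 2x3 table by full enumeration over all
    tables with the observed margins (probability-mass two-sided rule)."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = int(table.sum())
    const = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1)

    def log_p(t00: int, t01: int) -> float:
        t02 = r[0] - t00 - t01
        t10, t11, t12 = c[0] - t00, c[1] - t01, c[2] - t02
        cells = np.array([t00, t01, t02, t10, t11, t12])
        if (cells < 0).any():
            return -np.inf
        return float(const - gammaln(cells + 1).sum())

    obs = log_p(int(table[0, 0]), int(table[0, 1]))
    logs = []
    for t00 in range(min(r[0], c[0]) + 1):
        for t01 in range(min(r[0] - t00, c[1]) + 1):
            lp = log_p(t00, t01)
            if lp > -np.inf and lp <= obs + math.log1p(1e-7):
                logs.append(lp)
    m = max(logs)
    return float(min(1.0, math.exp(m) * sum(math.exp(x - m) for x in logs)))


def _fisher_2x3_montecarlo(
    table: np.ndarray, n_draws: int, seed: int
) -> float:
    """Seeded Monte-Carlo estimate of the 2x3 exact p for large tables."""
    rng = np.random.default_rng(seed)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = int(table.sum())
    const = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1)

    def lp(t: np.ndarray) -> float:
        return float(const - gammaln(t + 1).sum())

    obs = lp(table)
    labels = np.repeat([0, 1, 2], c)
    hits = 0
    for _ in range(n_draws):
        rng.shuffle(labels)
        top = labels[: r[0]]
        t = np.array(
            [
                [(top == 0).sum(), (top == 1).sum(), (top == 2).sum()],
                [0, 0, 0],
            ]
        )
        t[1] = c - t[0]
        if lp(t) <= obs + math.log1p(1e-7):
            hits += 1
    return (hits + 1) / (n_draws + 1)


# ---------------------------------------------------------------------------
# Variant-level test
# ---------------------------------------------------------------------------


def test_variant(
    table: GenotypeCountTable,
    coding: str = "recessive",
    breeds: list[str] | None = None,
    min_margin: int = MIN_MARGIN_COUNT,
    enumeration_limit: int = 500,
    mc_draws: int = 200_000,
    seed: int = 0,
) -> AssocTestResult:
    """Exact association test on one variant's count table.

    Codings: ``recessive`` (hom-alt vs other, the default headline test
    for a recessive disease model), ``dominant`` (carrier vs hom-ref),
    ``allelic`` (allele counts), ``genotypic`` (full 2x3, exact
    enumeration when the grand total is at most ``enumeration_limit``,
    otherwise a seeded Monte-Carlo estimate).

    Rows from breed subsets whose phenotype margin is below ``min_margin``
    are refused when tested alone (single-case breeds are reported in the
    table but never tested by themselves).
    """
    collapsed = table.collapsed(breeds)
    for phe in ("case", "control"):
        if phe not in collapsed.index:
            raise ValidationError(f"no {phe} samples in the selected breeds")
    case = collapsed.loc["case"].to_numpy()
    ctrl = collapsed.loc["control"].to_numpy()
    if breeds is not None and (case.sum() < min_margin or ctrl.sum() < min_margin):
        raise ValidationError(
            f"phenotype margin below {min_margin} in breed subset; "
            "refusing a stand-alone test"
        )

    if coding == "recessive":
        t = np.array(
            [
                [case[2], case[0] + case[1]],
                [ctrl[2], ctrl[0] + ctrl[1]],
            ]
        )
    elif coding == "dominant":
        t = np.array(
            [
                [case[1] + case[2], case[0]],
                [ctrl[1] + ctrl[2], ctrl[0]],
            ]
        )
    elif coding == "allelic":
        t = np.array(
            [
                [2 * case[2] + case[1], 2 * case[0] + case[1]],
                [2 * ctrl[2] + ctrl[1], 2 * ctrl[0] + ctrl[1]],
            ]
        )
    elif coding == "genotypic":
        t = np.vstack([case[::-1], ctrl[::-1]])  # hom-alt, het, hom-ref
        if t.sum() <= enumeration_limit:
            p = _fisher_2x3_exact(t)
        else:
            p = _fisher_2x3_montecarlo(t, mc_draws, seed)
        return AssocTestResult(coding="genotypic", table=t, p_value=p)
    else:
        raise ValueError(f"unknown coding {coding!r}")

    p = fisher_exact_2x2(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    orv, corrected = odds_ratio_2x2(
        int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    )
    return AssocTestResult(
        coding=coding,
        table=t,
        p_value=p,
        odds_ratio=orv,
        odds_ratio_corrected=corrected,
    )
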