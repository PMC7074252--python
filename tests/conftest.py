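"""Shared fixtures.

Simulated studies are expensive enough to share: ``study_seed1`` is the
default-configuration study reused by cascade/annotation tests, and
``recovery50`` sweeps 50 default seeds once per session, recording for
each seed the truth interval, the top detected segment, the best
mixed-model marker and the cascade survivors.  ``small_sim_config`` is a
reduced-genome configuration (same demography, smaller map) for tests
where only the mechanics matter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eclemap import autozyg, gwas, simpop, varfilter
from eclemap.cli import run_gwas_stage


@pytest.fixture(scope="session")
def study_seed1() -> simpop.SimulatedStudy:
    return simpop.simulate_study(simpop.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim_config() -> simpop.SimConfig:
    """Default demography on a reduced genome (fast; HW/aggregation tests
    only need the process, not the full map)."""
    return simpop.SimConfig(
        seed=0,
        n_markers_per_chromosome=300,
        chromosome_length_bp=10_000_000,
        causal_position_bp=5_000_000,
        ibd_segment_length_bp=600_000,
        n_control_genomes=60,
        population_size=120,
        n_generations=12,
    )


@pytest.fixture(scope="session")
def recovery50():
    """Per-seed mapping outcomes over 50 default-configuration studies.

    For each seed: does the top-ranked shared segment's critical interval
    contain the causal position; does the best mixed-model marker fall in
    the truth interval; is the detected segment contained in the truth
    interval up to an array-resolution flank; does the planted causal
    variant survive the full cascade.
    """
    flank_bp = 150_000  # chance-concordance resolution of a 14-case array
    out = {
        "causal_in_ci": [],
        "best_marker_in_truth": [],
        "segment_contained": [],
        "causal_survives_cascade": [],
        "truth_kb": [],
    }
    for seed in range(50):
        s = simpop.simulate_study(simpop.SimConfig(seed=seed))
        tiv = s.truth.ibd_interval
        qc, K, assoc, allelic, diag = run_gwas_stage(
            s.genotypes, s.samples, gwas.QcConfig(), "centered-grm"
        )
        pheno = qc.samples.set_index("sample_id")["phenotype"]
        case_ids = [
            x for x in qc.genotypes.samples if pheno.loc[x] == "case"
        ]
        segs = autozyg.rank_segments(
            autozyg.find_shared_homozygous_segments(
                qc.genotypes.subset_samples(case_ids)
            ),
            assoc,
        )
        top = segs[0] if segs else None
        out["causal_in_ci"].append(
            top is not None
            and top.interval.contains(
                s.truth.causal_chromosome, s.truth.causal_position_bp
            )
        )
        best = assoc.loc[assoc["p_value"].idxmin()]
        out["best_marker_in_truth"].append(
            tiv.contains(str(best["chromosome"]), int(best["position_bp"]))
        )
        if top is None:
            out["segment_contained"].append(False)
        else:
            m = qc.genotypes.markers
            pos = m.pos[top.first_marker_index : top.last_marker_index + 1]
            out["segment_contained"].append(
                bool(
                    (
                        (pos >= tiv.start_bp - flank_bp)
                        & (pos <= tiv.end_bp + flank_bp)
                    ).all()
                )
            )
        panel = varfilter.ControlPanel.from_variant_sets([s.panel_variants])
        report = varfilter.run_cascade(
            s.case_variants, panel, tiv, [s.transcript]
        )
        causal_key = (
            s.truth.causal_chromosome,
            s.truth.causal_position_bp,
            s.truth.causal_ref,
            s.truth.causal_alt,
        )
        out["causal_survives_cascade"].append(
            causal_key in report.final_survivors
        )
        out["truth_kb"].append(tiv.length_kb)
    return out


@pytest.fixture()
def toy_matrix():
    """10 samples x 10 markers with one deliberate violation per QC rule.

    Expected removals (hand-enumerated; HWE floor 0.05 for the toy scale):
    sample s0 (all no-calls), marker mk1 (call rate 6/9 after s0 goes),
    mk2 (MAF 1/18), mk3 (all controls heterozygous, exact HWE p = 0.0216).
    """
    from eclemap.genio import GenotypeMatrix, MarkerMap, make_sample_table

    n, m = 10, 10
    calls = np.empty((n, m), dtype=np.int8)
    clean = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=np.int8)
    for j in (0, 6, 7, 8, 9):
        calls[:, j] = clean
    calls[:, 1] = [0, -1, -1, -1, 1, 2, 0, 1, 2, 0]  # marker call rate low
    calls[:, 2] = [0, 0, 0, 0, 0, 0, 0, 0, 0, 1]  # MAF 1/18
    calls[:, 3] = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]  # every control het
    calls[:, 4] = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]  # clean
    calls[:, 5] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 1]  # clean
    calls[0, :] = -1  # sample s0: call rate 0
    mm = MarkerMap(
        [f"mk{j}" for j in range(m)],
        np.array(["1"] * m, dtype=object),
        (np.arange(m) + 1) * 10_000,
    )
    g = GenotypeMatrix(
        [f"s{i}" for i in range(n)], mm, calls, [("A", "C")] * m
    )
    table = make_sample_table(
        g.samples,
        ["B"] * n,
        ["case"] * 2 + ["control"] * 8,
    )
    return g, table
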