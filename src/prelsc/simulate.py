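"""Synthetic-data generators for every stage of the pipeline.

Each generator is a pure function of its parameters and seed and reproduces
the statistical structure the corresponding analysis assumes:

* limiting-dilution cohorts under the single-hit Poisson model, on the
  standard six-dose transplantation schedule (10^7 … 10^2 cells, 7 mice per
  dose);
* stage-ordered expression matrices with planted gene sets following a
  rise-to-peak-then-fall trajectory (the DN3a-peaked shape of pathway-target
  expression during thymocyte differentiation) over flat background genes,
  with multiplicative log-normal noise;
* ChIP-seq peak placements at controlled offsets from TSSs, with decoy peaks
  outside the promoter window;
* RPKM tables with planted pairwise correlations (bivariate log-normal).

Defaults mirror the study design: dose schedule and 7 recipients per dose,
>1% positivity semantics, a 1.5-fold planted per-transition effect
comfortably above the 1.3-fold screening threshold, and ±2 kb promoter
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prelsc.errors import InputError
from prelsc.expression import DEFAULT_STAGES, StageExpressionMatrix
from prelsc.lda import DilutionCohort, TransplantRecord
from prelsc.regulome import Peak, PeakSet, TSSAnnotation

__all__ = [
    "DOSE_SCHEDULE",
    "N_PER_DOSE",
    "simulate_limiting_dilution",
    "simulate_transplant_records",
    "simulate_stage_expression",
    "simulate_tss",
    "simulate_peaks",
    "simulate_rpkm",
    "PlantedSet",
]

#: The transplantation dose schedule: 10^7 down to 10^2 cells per recipient.
DOSE_SCHEDULE: tuple[float, ...] = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2)
#: Recipients per dose.
N_PER_DOSE = 7


def simulate_limiting_dilution(
    true_frequency: float,
    doses: tuple[float, ...] = DOSE_SCHEDULE,
    n_per_dose: int = N_PER_DOSE,
    seed: int | None = None,
    genotype: str = "sim",
) -> DilutionCohort:
    """Simulate engraftment outcomes under the single-hit Poisson model.

    Each recipient at dose d is positive independently with probability
    ``1 - exp(-f * d)``.  ``true_frequency`` may be 0 (no stem cells: all
    recipients negative).
    """
    if true_frequency < 0:
        raise InputError("true_frequency must be non-negative")
    rng = np.random.default_rng(seed)
    n_positive = []
    for d in doses:
        p = -np.expm1(-true_frequency * d)
        n_positive.append(int(rng.binomial(n_per_dose, p)))
    return DilutionCohort(
        genotype=genotype,
        doses=tuple(float(d) for d in doses),
        n_tested=tuple([n_per_dose] * len(doses)),
        n_positive=tuple(n_positive),
    )


def simulate_transplant_records(
    frequencies: dict[str, float],
    doses: tuple[float, ...] = DOSE_SCHEDULE,
    n_per_dose: int = N_PER_DOSE,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-mouse transplant records for one or more genotypes.

    Positive mice get a reconstitution percentage drawn uniform(5, 90),
    negative mice uniform(0, 1) — only the >1% dichotomy matters downstream.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in sorted(frequencies):
        f = frequencies[genotype]
        if f < 0:
            raise InputError("frequencies must be non-negative")
        i = 0
        for d in doses:
            p = -np.expm1(-f * d)
            for _ in range(n_per_dose):
                positive = rng.random() < p
                pct = rng.uniform(5.0, 90.0) if positive else rng.uniform(0.0, 1.0)
                rows.append(
                    {
                        "mouse_id": f"{genotype}_{i:03d}",
                        "genotype": genotype,
                        "dose": int(d),
                        "reconstitution_pct": round(float(pct), 3),
                        "donor_cells": "",
                        "host_cells": "",
                    }
                )
                i += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlantedSet:
    """A gene set planted with a rise-to-peak-then-fall mean trajectory."""

    name: str
    n_genes: int
    peak_stage: str = "DN3a"
    effect: float = 1.5  # per-transition fold on the rising limb
    fall: float = 0.5  # per-transition fold after the peak


def simulate_stage_expression(
    n_genes: int = 2000,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    planted_sets: tuple[PlantedSet, ...] = (PlantedSet("planted", 50),),
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    n_replicates: int = 1,
    seed: int | None = None,
) -> tuple[StageExpressionMatrix, dict[str, list[str]]]:
    """Stage-ordered expression with planted trajectories over flat background.

    Planted genes multiply by ``effect`` at each transition up to
    ``peak_stage`` and by ``fall`` at each transition after it; background
    genes are flat at ``baseline``.  Noise is multiplicative log-normal with
    standard deviation ``noise_sd`` on the natural-log scale, independent per
    gene × column.  Returns the matrix and the truth map (set name → gene ids).
    """
    if len(stages) < 2:
        raise InputError("need at least two stages")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    n_planted_total = sum(ps.n_genes for ps in planted_sets)
    if n_planted_total > n_genes:
        raise InputError("planted sets exceed n_genes")
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    truth: dict[str, list[str]] = {}
    means = np.full((n_genes, len(stages)), baseline, dtype=float)
    cursor = 0
    for ps in planted_sets:
        if ps.peak_stage not in stages:
            raise InputError(f"peak stage {ps.peak_stage!r} not in stages")
        idx = slice(cursor, cursor + ps.n_genes)
        truth[ps.name] = genes[idx]
        peak = stages.index(ps.peak_stage)
        # trajectory: multiply by effect up to the peak, by fall afterwards
        traj = [baseline]
        for j in range(1, len(stages)):
            factor = ps.effect if j <= peak else ps.fall
            traj.append(traj[-1] * factor)
        means[idx, :] = np.array(traj)
        cursor += ps.n_genes

    cols: list[str] = []
    data = []
    for s in stages:
        for r in range(n_replicates):
            cols.append(s if n_replicates == 1 else f"{s}.{r + 1}")
    replicate_map = {
        s: [c for c in cols if c == s or c.startswith(f"{s}.")] for s in stages
    }
    stage_of_col = {c: c.split(".")[0] for c in cols}
    values = np.empty((n_genes, len(cols)))
    for j, c in enumerate(cols):
        mu = means[:, stages.index(stage_of_col[c])]
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
        values[:, j] = mu * np.exp(noise)
    matrix = StageExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        tuple(stages),
        replicate_map,
    )
    return matrix, truth


def simulate_tss(
    n_genes: int = 100,
    chrom: str = "chr1",
    spacing: int = 50_000,
    seed: int | None = None,
) -> TSSAnnotation:
    """Evenly spaced TSSs with random strands on one chromosome."""
    rng = np.random.default_rng(seed)
    ann = TSSAnnotation()
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(f"g{i:05d}", chrom, spacing * (i + 1), strand)
    return ann


def simulate_peaks(
    tss: TSSAnnotation,
    target_genes: list[str],
    window: int = 2000,
    decoy_genes: list[str] | None = None,
    decoy_offset: int | None = None,
    peak_width: int = 200,
    regulator: str = "TF",
    seed: int | None = None,
) -> PeakSet:
    """Peaks inside the promoter window for targets, outside it for decoys.

    Target peaks are centred within ``|offset| ≤ window − peak_width`` of the
    TSS so the whole peak stays inside the window; decoy peaks start at least
    ``decoy_offset`` (default ``2 * window``) past the window edge.
    """
    rng = np.random.default_rng(seed)
    if decoy_offset is None:
        decoy_offset = 2 * window
    peaks: list[Peak] = []
    for g in target_genes:
        if g not in tss.tss:
            raise InputError(f"target gene {g!r} not in annotation")
        chrom, pos, _ = tss.tss[g]
        max_off = max(window - peak_width, 0)
        center = pos + int(rng.integers(-max_off, max_off + 1))
        start = max(center - peak_width // 2, 0)
        peaks.append(Peak(chrom, start, start + peak_width))
    for g in decoy_genes or []:
        if g not in tss.tss:
            raise InputError(f"decoy gene {g!r} not in annotation")
        chrom, pos, _ = tss.tss[g]
        start = pos + window + decoy_offset
        peaks.append(Peak(chrom, start, start + peak_width))
    return PeakSet(regulator=regulator, source="simulated", peaks=peaks)


def simulate_rpkm(
    n_samples: int = 12,
    correlated_pairs: dict[tuple[str, str], float] | None = None,
    n_background_genes: int = 20,
    mean_log2: float = 5.0,
    sd_log2: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Samples × genes RPKM table with planted pairwise correlations.

    Each planted pair is drawn from a bivariate normal on the log2 scale with
    the target correlation, then exponentiated; background genes are
    independent log-normal.
    """
    rng = np.random.default_rng(seed)
    if correlated_pairs is None:
        correlated_pairs = {("geneA", "geneB"): 0.8}
    data: dict[str, np.ndarray] = {}
    for (ga, gb), rho in correlated_pairs.items():
        if not -1.0 <= rho <= 1.0:
            raise InputError(f"correlation for ({ga}, {gb}) must be in [-1, 1]")
        cov = sd_log2**2 * np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([mean_log2, mean_log2], cov, size=n_samples)
        data[ga] = 2.0 ** xy[:, 0]
        data[gb] = 2.0 ** xy[:, 1]
    for i in range(n_background_genes):
        data[f"bg{i:03d}"] = 2.0 ** rng.normal(mean_log2, sd_log2, size=n_samples)
    index = [f"sample{i + 1:02d}" for i in range(n_samples)]
    return pd.DataFrame(data, index=index)
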