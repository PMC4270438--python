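"""Gene-set statistics over the thymocyte differentiation trajectory.

Four families of operations:

* **trajectory profiles** — the percentage of a gene set exceeding a linear
  fold-change threshold (default >1.3, strict) at each adjacent stage
  transition, against the transcriptome-wide background;
* **GSEA** — the weighted Kolmogorov–Smirnov running-sum enrichment score of
  a gene set in a ranked list, with gene-label permutation p-values
  (exhaustive enumeration when the number of placements is small) and BH
  FDR across a collection;
* **overlap enrichment** — one-sided hypergeometric tests of a query set
  against a signature compendium with BH adjustment;
* the **candidate intersection filter** — the reproducible form of the
  pipeline that reduces a regulator-bound, pathway-responsive gene list to
  the handful of self-renewal candidates: binding ∩ responsiveness, a
  fold-change gate at a named transition, membership in self-renewal
  resources, and an optional high-expression exclusion at a refractory
  stage (the rule that removes Bcl6-like genes peaking in DP cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from prelsc.errors import InputError
from prelsc.expression import StageExpressionMatrix, TransitionFC
from prelsc.regulome import TFSignature

__all__ = [
    "GeneSet",
    "TrajectoryProfile",
    "EnrichmentResult",
    "FilterReport",
    "FilterStep",
    "StageExclusionRule",
    "trajectory_profile",
    "candidate_filter",
    "gsea",
    "gsea_collection",
    "overlap_enrichment",
    "read_gmt",
    "write_gmt_sets",
    "FOLD_THRESHOLD",
]

#: Default per-transition fold-change threshold; "up-regulated" means
#: strictly greater than this on the linear scale.
FOLD_THRESHOLD = 1.3


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TrajectoryProfile:
    """Percent of a gene set up-regulated at each transition, vs background."""

    transitions: tuple[str, ...]
    pct_up: pd.Series
    background_pct_up: pd.Series
    n_set: int
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pct_up": self.pct_up, "background_pct_up": self.background_pct_up}
        )


def trajectory_profile(
    gene_set: GeneSet, fc: TransitionFC, threshold: float = FOLD_THRESHOLD
) -> TrajectoryProfile:
    """Fraction (in %) of set members with fc > threshold at each transition.

    The denominator is the set's overlap with the expression universe
    (detected members only); the background is the same statistic over the
    whole universe.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    members = fc.genes.intersection(pd.Index(gene_set.genes))
    if len(members) == 0:
        raise InputError(
            f"gene set {gene_set.name!r} has no members in the expression universe"
        )
    sub = fc.fc.loc[members]
    pct = 100.0 * (sub > threshold).mean(axis=0)
    bg = 100.0 * (fc.fc > threshold).mean(axis=0)
    return TrajectoryProfile(
        transitions=fc.transitions,
        pct_up=pct,
        background_pct_up=bg,
        n_set=len(members),
        n_background=len(fc.genes),
    )


# ---------------------------------------------------------------------------
# Candidate intersection filter


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_input: int
    n_output: int
    survivors: frozenset[str]


@dataclass
class FilterReport:
    """Ordered record of genes surviving each candidate-filter step.

    Survivor sets are nested: each step's survivors are a subset of the
    previous step's (asserted on construction).
    """

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, n_input: int, survivors: set[str]) -> None:
        survivors = frozenset(survivors)
        if self.steps and not survivors <= self.steps[-1].survivors:
            raise AssertionError(
                f"filter step {name!r} produced genes outside the previous step"
            )
        self.steps.append(FilterStep(name, n_input, len(survivors), survivors))

    @property
    def survivors(self) -> frozenset[str]:
        return self.steps[-1].survivors if self.steps else frozenset()

    @property
    def counts(self) -> list[int]:
        return [s.n_output for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "n_input": s.n_input,
                    "n_output": s.n_output,
                    "survivors": ",".join(sorted(s.survivors)),
                }
                for s in self.steps
            ]
        )


@dataclass(frozen=True)
class StageExclusionRule:
    """Drop genes highly expressed at a reprogramming-refractory stage.

    A gene is excluded when its mean expression at ``stage`` is at least
    ``fraction_of_max`` of its own trajectory maximum — the reproducible form
    of ruling out a candidate because it stays high in DP cells.
    """

    stage: str
    fraction_of_max: float = 0.8

    def excluded(self, matrix: StageExpressionMatrix, genes: set[str]) -> set[str]:
        if self.stage not in matrix.stages:
            raise InputError(f"exclusion stage {self.stage!r} not in matrix stages")
        means = matrix.stage_means()
        present = [g for g in genes if g in means.index]
        out = set()
        for g in present:
            row = means.loc[g]
            if row[self.stage] >= self.fraction_of_max * row.max():
                out.add(g)
        return out


def candidate_filter(
    bound: TFSignature,
    responsive: GeneSet,
    fc: TransitionFC,
    transition: str,
    resources: list[GeneSet],
    threshold: float = FOLD_THRESHOLD,
    exclusion: StageExclusionRule | None = None,
    expression: StageExpressionMatrix | None = None,
) -> FilterReport:
    """Candidate-gene intersection pipeline.

    1. regulator-bound ∩ pathway-responsive genes;
    2. genes with fc > threshold at the named transition (strict);
    3. genes present in the union of self-renewal resources;
    4. (optional) drop genes failing the stage-exclusion rule.
    """
    if transition not in fc.transitions:
        raise InputError(
            f"unknown transition {transition!r}; available: {list(fc.transitions)}"
        )
    report = FilterReport()

    step1 = set(bound.genes) & set(responsive.genes)
    report.add("bound ∩ responsive", len(bound.genes), step1)

    in_universe = step1 & set(fc.genes)
    rising = {g for g in in_universe if fc.fc.loc[g, transition] > threshold}
    report.add(f"fc > {threshold} at {transition}", len(step1), rising)

    resource_union: set[str] = set()
    for r in resources:
        resource_union |= set(r.genes)
    step3 = rising & resource_union
    report.add("in self-renewal resources", len(rising), step3)

    if exclusion is not None:
        if expression is None:
            raise InputError("stage exclusion requires the expression matrix")
        dropped = exclusion.excluded(expression, step3)
        report.add(
            f"not high at {exclusion.stage}", len(step3), step3 - dropped
        )
    return report


# ---------------------------------------------------------------------------
# GSEA


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    p: float
    fdr: float | None
    n_hits: int
    n_perm_used: int
    exhaustive: bool


def _running_sum_es(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed extremum of the weighted KS running sum over a ranked list."""
    n = in_set.size
    n_hits = int(in_set.sum())
    n_miss = n - n_hits
    if n_hits == 0 or n_miss == 0:
        raise InputError("gene set must be a strict non-empty subset of the ranking")
    if weight == 0:
        hit_w = np.where(in_set, 1.0, 0.0)
    else:
        hit_w = np.where(in_set, np.abs(scores) ** weight, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores exactly zero; fall back to uniform increments
        hit_w = np.where(in_set, 1.0, 0.0)
        denom = float(n_hits)
    steps = hit_w / denom - np.where(in_set, 0.0, 1.0 / n_miss)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(
    ranking: pd.Series,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Enrichment of a gene set in a score-ranked list.

    ``ranking`` maps gene → score; it is sorted by decreasing score
    internally.  Hit increments are proportional to |score|^weight_exponent
    (normalized over hits); miss decrements are uniform.  ES is the running
    sum's extremum (|ES| ≤ 1).

    Significance is by gene-label permutation: random same-size subsets of
    the universe.  When the number of distinct placements C(N, k) does not
    exceed ``n_perm`` all placements are enumerated and the p-value is exact
    (the observed placement is one of them); otherwise ``n_perm`` random
    subsets are drawn and p uses the add-one estimator.  One-sided in the
    direction of the observed ES.
    """
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    universe = ranking.index
    hits = universe.intersection(pd.Index(gene_set.genes))
    if len(hits) == 0:
        raise InputError(f"gene set {gene_set.name!r} has no overlap with the ranking")
    if len(hits) == len(universe):
        raise InputError("gene set covers the whole ranking; ES undefined")
    scores = ranking.to_numpy(dtype=float)
    in_set = universe.isin(set(hits)).astype(bool)
    es_obs = _running_sum_es(in_set, scores, weight_exponent)

    n, k = len(universe), len(hits)
    n_placements = math.comb(n, k)
    if n_placements <= n_perm:
        null = np.empty(n_placements)
        for i, combo in enumerate(combinations(range(n), k)):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            null[i] = _running_sum_es(mask, scores, weight_exponent)
        if es_obs >= 0:
            p = float(np.mean(null >= es_obs))
        else:
            p = float(np.mean(null <= es_obs))
        return EnrichmentResult(
            gene_set.name, es_obs, p, None, k, n_placements, exhaustive=True
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        null[i] = _running_sum_es(mask, scores, weight_exponent)
    if es_obs >= 0:
        extreme = int(np.sum(null >= es_obs))
    else:
        extreme = int(np.sum(null <= es_obs))
    p = (extreme + 1) / (n_perm + 1)
    return EnrichmentResult(gene_set.name, es_obs, p, None, k, n_perm, exhaustive=False)


def gsea_collection(
    ranking: pd.Series,
    gene_sets: list[GeneSet],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """GSEA over a collection with BH FDR across all sets tested together."""
    rows = []
    for i, gs in enumerate(gene_sets):
        res = gsea(
            ranking,
            gs,
            weight_exponent=weight_exponent,
            n_perm=n_perm,
            seed=None if seed is None else seed + i,
        )
        rows.append(
            {"set": res.name, "es": res.es, "p": res.p, "n_hits": res.n_hits}
        )
    df = pd.DataFrame(rows).set_index("set")
    df["fdr"] = false_discovery_control(df["p"].to_numpy(), method="bh")
    return df.sort_values("p", kind="stable")


# ---------------------------------------------------------------------------
# Hypergeometric overlap


def overlap_enrichment(
    query: GeneSet,
    compendium: list[GeneSet],
    universe_size: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric overlap of a query set against a compendium.

    For each compendium set of size K, with query size q and overlap x in a
    universe of M genes, p = P(X ≥ x) for X ~ Hypergeom(M, K, q).  BH
    adjustment across the compendium; ``enriched`` is adjusted p strictly
    below ``alpha``.
    """
    q = len(query.genes)
    if q > universe_size:
        raise InputError("query larger than the universe")
    rows = []
    for gs in compendium:
        k = len(gs.genes)
        if k > universe_size:
            raise InputError(f"compendium set {gs.name!r} larger than the universe")
        x = len(query.genes & gs.genes)
        p = float(hypergeom.sf(x - 1, universe_size, k, q))
        rows.append({"set": gs.name, "set_size": k, "overlap": x, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    df["p_adj"] = false_discovery_control(df["p"].to_numpy(), method="bh")
    df["enriched"] = df["p_adj"] < alpha
    return df.sort_values("p", kind="stable")


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSet]:
    """Read GMT: name <tab> description/category <tab> gene1 <tab> gene2 ..."""
    sets = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs ≥3 fields")
            name, category = fields[0], fields[1] or None
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise InputError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, genes=genes, category=category))
    return sets


def write_gmt_sets(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write(
                "\t".join([gs.name, gs.category or ""] + sorted(gs.genes)) + "\n"
            )
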