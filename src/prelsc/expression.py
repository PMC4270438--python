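"""Stage-ordered expression matrices and differential expression.

Covers the expression-side primitives of the pipeline:

* :class:`StageExpressionMatrix` — genes × ordered thymocyte differentiation
  stages (ETP, DN2, DN3a, DN3b, DN4, DP, ...), linear-scale intensities,
  optionally with replicate columns per stage;
* per-transition linear fold changes (later stage / earlier stage);
* Rank Products differential expression (Breitling): per-comparison
  fold-change ranks, geometric-mean rank product, and a permutation-based
  per-gene probability of false positive (pfp), up and down analysed
  separately;
* a detection filter replacing probe-level absent/present calls with an
  intensity floor;
* ΔΔCt relative quantification and RPKM correlation utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from prelsc.errors import InputError

__all__ = [
    "StageExpressionMatrix",
    "TransitionFC",
    "RankProductsResult",
    "transition_fold_changes",
    "rank_products",
    "detection_filter",
    "delta_delta_ct",
    "rpkm_correlate",
    "read_stage_matrix",
    "read_rpkm_table",
]

DEFAULT_STAGES = ("ETP", "DN2", "DN3a", "DN3b", "DN4", "DP")


@dataclass
class StageExpressionMatrix:
    """Linear-scale expression for genes across ordered differentiation stages.

    ``values`` has one column per data column; ``replicate_map`` maps each
    stage label to its column names (a single column per stage when there are
    no replicates).  Stage order is explicit and immutable within an analysis.
    """

    values: pd.DataFrame  # genes x columns
    stages: tuple[str, ...]
    replicate_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene ids: {list(dupes)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InputError("expression values must be finite")
        self.stages = tuple(self.stages)
        if not self.replicate_map:
            missing = [s for s in self.stages if s not in self.values.columns]
            if missing:
                raise InputError(f"stages missing from matrix columns: {missing}")
            self.replicate_map = {s: [s] for s in self.stages}
        else:
            for s in self.stages:
                cols = self.replicate_map.get(s, [])
                if not cols:
                    raise InputError(f"stage {s!r} has no replicate columns")
                absent = [c for c in cols if c not in self.values.columns]
                if absent:
                    raise InputError(f"replicate columns absent from matrix: {absent}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def stage_means(self) -> pd.DataFrame:
        """Per-stage replicate means, genes × stages, in stage order."""
        return pd.DataFrame(
            {s: self.values[self.replicate_map[s]].mean(axis=1) for s in self.stages}
        )

    def subset(self, genes) -> "StageExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(genes))
        return StageExpressionMatrix(
            self.values.loc[keep], self.stages, dict(self.replicate_map)
        )


@dataclass
class TransitionFC:
    """Per-gene linear fold change at each adjacent stage transition.

    ``fc`` is genes × transitions with columns like ``"ETP->DN2"``; values are
    mean(later stage)/mean(earlier stage) and strictly positive.
    """

    fc: pd.DataFrame
    transitions: tuple[str, ...]

    @property
    def genes(self) -> pd.Index:
        return self.fc.index


def transition_label(a: str, b: str) -> str:
    return f"{a}->{b}"


def transition_fold_changes(m: StageExpressionMatrix) -> TransitionFC:
    """Linear fold change per gene at each adjacent transition.

    Replicate columns are averaged per stage before taking the ratio; a zero
    or negative stage mean is an error (the offending gene is named).
    """
    if len(m.stages) < 2:
        raise InputError("need at least two stages for transitions")
    means = m.stage_means()
    nonpos = means.columns[(means <= 0).any(axis=0)]
    if len(nonpos):
        genes = means.index[(means[nonpos] <= 0).any(axis=1)]
        raise InputError(
            f"non-positive stage mean for gene(s) {list(genes[:5])} "
            f"at stage(s) {list(nonpos)}; apply a detection filter first"
        )
    labels = tuple(
        transition_label(a, b) for a, b in zip(m.stages[:-1], m.stages[1:])
    )
    fc = pd.DataFrame(
        {
            lab: means[b] / means[a]
            for lab, (a, b) in zip(labels, zip(m.stages[:-1], m.stages[1:]))
        }
    )
    return TransitionFC(fc=fc, transitions=labels)


@dataclass
class RankProductsResult:
    """Rank Products statistics for one direction (up or down).

    ``rank_product`` is the geometric mean across comparisons of each gene's
    within-comparison fold-change rank (1 = most changed in the tested
    direction).  ``pfp`` is the permutation estimate of the expected number of
    false positives at or above each gene's rank product, divided by the
    gene's position in the sorted list.
    """

    table: pd.DataFrame  # columns: rank_product, E, pfp, position
    direction: str
    n_perm: int

    def significant(self, pfp_threshold: float = 0.01) -> pd.Index:
        """Genes with pfp strictly below the threshold."""
        return self.table.index[self.table["pfp"] < pfp_threshold]


def _rank_product(log_ratios: np.ndarray, direction: str) -> np.ndarray:
    """Geometric-mean rank across comparison columns; rank 1 = most extreme."""
    signed = -log_ratios if direction == "up" else log_ratios
    ranks = np.apply_along_axis(rankdata, 0, signed)
    return np.exp(np.mean(np.log(ranks), axis=1))


def rank_products(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    direction: str = "up",
) -> RankProductsResult:
    """Rank Products differential expression, one direction at a time.

    All ``n_a × n_b`` pairwise replicate comparisons contribute a fold-change
    ranking; the rank product is the geometric mean of a gene's ranks.  The
    null distribution is obtained by permuting gene labels independently
    within each replicate array and recomputing every comparison's ranks —
    this preserves the correlation between comparisons that share an array —
    and

        pfp(g) = E(g) / position(g),

    where ``E(g)`` is the average number of null rank products at least as
    extreme as gene g's and ``position`` is g's 1-based rank-product order.

    ``direction="up"`` tests for genes higher in ``group_a`` than ``group_b``.
    """
    if direction not in ("up", "down"):
        raise InputError("direction must be 'up' or 'down'")
    if not group_a.index.equals(group_b.index):
        if set(group_a.index) == set(group_b.index):
            group_b = group_b.loc[group_a.index]
        else:
            raise InputError("group_a and group_b must share the same gene universe")
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    if group_a.shape[1] < 1 or group_b.shape[1] < 1:
        raise InputError("each group needs at least one replicate column")

    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise InputError("expression values must be strictly positive (linear scale)")
    n_genes = a.shape[0]
    # all pairwise log ratios, genes x (n_a * n_b) comparisons
    log_ratios = (
        np.log(a)[:, :, None] - np.log(b)[:, None, :]
    ).reshape(n_genes, -1)
    n_comp = log_ratios.shape[1]

    rp_obs = _rank_product(log_ratios, direction)
    order = np.argsort(rp_obs, kind="stable")
    position = np.empty(n_genes, dtype=float)
    position[order] = np.arange(1, n_genes + 1)

    rng = np.random.default_rng(seed)
    # Null: permute gene labels within each array, recompute all comparisons.
    ka, kb = a.shape[1], b.shape[1]
    loga, logb = np.log(a), np.log(b)
    base = np.broadcast_to(np.arange(n_genes), (n_perm, 1, n_genes))
    perm_a = rng.permuted(np.broadcast_to(base, (n_perm, ka, n_genes)).copy(), axis=2)
    perm_b = rng.permuted(np.broadcast_to(base, (n_perm, kb, n_genes)).copy(), axis=2)
    # A[p, j, g] = loga[perm_a[p, j, g], j]
    A = np.take_along_axis(loga.T[None, :, :], perm_a, axis=2)
    B = np.take_along_axis(logb.T[None, :, :], perm_b, axis=2)
    null_lr = A[:, :, None, :] - B[:, None, :, :]  # (perm, ka, kb, genes)
    signed = -null_lr if direction == "up" else null_lr
    null_ranks = rankdata(signed, axis=-1)
    null_rp = np.exp(
        np.mean(np.log(null_ranks), axis=(1, 2))
    ).ravel()  # (perm, genes) -> pooled
    null_rp.sort()
    # E(g): expected count of null genes with RP <= RP_g, per permutation.
    counts = np.searchsorted(null_rp, rp_obs, side="right")
    E = counts / n_perm
    pfp = E / position

    table = pd.DataFrame(
        {"rank_product": rp_obs, "E": E, "pfp": pfp, "position": position.astype(int)},
        index=group_a.index,
    ).sort_values("rank_product", kind="stable")
    return RankProductsResult(table=table, direction=direction, n_perm=n_perm)


def detection_filter(
    m: StageExpressionMatrix,
    floor: float,
    conditions: list[list[str]] | None = None,
) -> StageExpressionMatrix:
    """Drop genes undetected in every condition (intensity-floor filter).

    A gene is kept iff its mean expression strictly exceeds ``floor`` in at
    least one condition.  ``conditions`` is a list of stage-label groups;
    by default each stage is its own condition.  Order-preserving and
    idempotent; may return an empty matrix.
    """
    if floor <= 0:
        raise InputError("floor must be positive")
    if conditions is None:
        conditions = [[s] for s in m.stages]
    keep = pd.Series(False, index=m.genes)
    for group in conditions:
        cols: list[str] = []
        for s in group:
            cols.extend(m.replicate_map.get(s, [s]))
        keep |= m.values[cols].mean(axis=1) > floor
    return StageExpressionMatrix(
        m.values.loc[keep], m.stages, dict(m.replicate_map)
    )


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-ΔΔCt with a reference gene (e.g. β-actin).

    ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,ctrl − Ct_ref,ctrl).
    """
    for ct in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise InputError("all Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def rpkm_correlate(
    table: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> float:
    """Pearson correlation of two genes across samples of an RPKM table.

    ``table`` is samples × genes.  With ``log_transform`` the values are
    log2(x + pseudocount)-transformed first, matching the usual treatment of
    RPKM data before correlation.
    """
    for g in (gene_a, gene_b):
        if g not in table.columns:
            raise InputError(f"gene {g!r} not in RPKM table")
    if len(table) < 3:
        raise InputError("need at least 3 samples to correlate")
    x = table[gene_a].to_numpy(dtype=float)
    y = table[gene_b].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise InputError("zero variance in one of the genes; correlation undefined")
    if gene_a == gene_b:
        return 1.0
    return float(pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# TSV I/O


def read_stage_matrix(path, stages: tuple[str, ...] | list[str]) -> StageExpressionMatrix:
    """Read a genes × columns TSV; columns named ``stage`` or ``stage.rep``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    replicate_map: dict[str, list[str]] = {s: [] for s in stages}
    for col in df.columns:
        stage = col.split(".")[0]
        if stage in replicate_map:
            replicate_map[stage].append(col)
    empty = [s for s in stages if not replicate_map[s]]
    if empty:
        raise InputError(f"no columns found for stage(s): {empty}")
    return StageExpressionMatrix(df, tuple(stages), replicate_map)


def read_rpkm_table(path) -> pd.DataFrame:
    """Read a samples × genes RPKM TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
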