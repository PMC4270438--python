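"""Independent brute-force oracles used by the test suite.

Every function here re-derives an expected value from first principles
(enumeration, closed form, or an all-pairs scan), deliberately sharing no
code with the implementation it checks.
"""

import itertools
import math

import numpy as np


def single_dose_mle(n_neg: int, n_tested: int, dose: float) -> float:
    """Closed-form single-dose frequency: f = -ln(n_neg / n) / d."""
    return -math.log(n_neg / n_tested) / dose


def grid_search_mle(cohort, lo: float = 1e-7, hi: float = 1e-1, n: int = 100_000) -> float:
    """Dense grid argmax of the single-hit binomial log-likelihood."""
    grid = np.logspace(math.log10(lo), math.log10(hi), n)
    best_f, best_ll = grid[0], -np.inf
    for f in grid:
        ll = 0.0
        for d, nt, k in zip(cohort.doses, cohort.n_tested, cohort.n_positive):
            p_neg = math.exp(-f * d)
            if k > 0:
                if p_neg >= 1.0:
                    ll = -np.inf
                    break
                ll += k * math.log(1 - p_neg)
            ll += (nt - k) * (-f * d)
        if ll > best_ll:
            best_f, best_ll = f, ll
    return best_f


def rank_product_exact_E(rp_values, a, b):
    """Exact expected null counts for a 1-vs-2 replicate Rank Products design.

    Enumerates the array-label-permutation null: both comparisons share the
    single first-group array, so conditionally on its permutation the two
    ranks of a gene are independent; E(g) = n * P(r1 * r2 <= RP_g^2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    la = np.log(a[:, 0])
    lbs = [np.log(b[:, j]) for j in range(2)]
    perms = list(itertools.permutations(range(n)))
    joint = np.zeros((n, n))
    for pa in perms:
        ga = la[list(pa)]
        conds = []
        for lb in lbs:
            counts = np.zeros(n)
            for pb in perms:
                ratios = ga - lb[list(pb)]
                rank = 1 + int(np.sum(ratios > ratios[0]))  # rank 1 = most up
                counts[rank - 1] += 1
            conds.append(counts / len(perms))
        joint += np.outer(conds[0], conds[1])
    joint /= len(perms)
    uv = np.outer(np.arange(1, n + 1), np.arange(1, n + 1))
    return np.array(
        [n * joint[uv <= rp**2 * (1 + 1e-12)].sum() for rp in np.asarray(rp_values)]
    )


def ks_running_sum_es(order_in_set) -> float:
    """Classic uniform-weight KS running-sum enrichment statistic."""
    n_hit = sum(order_in_set)
    n_miss = len(order_in_set) - n_hit
    best = run = 0.0
    for is_hit in order_in_set:
        run += 1.0 / n_hit if is_hit else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def gsea_enumeration(universe, set_size):
    """All C(N, k) hit placements and their KS enrichment statistics."""
    n = len(universe)
    out = []
    for combo in itertools.combinations(range(n), set_size):
        mask = [i in combo for i in range(n)]
        out.append((combo, ks_running_sum_es(mask)))
    return out


def hypergeom_tail(x: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= x) by the direct factorial formula."""
    total = 0.0
    for k in range(x, min(set_size, query) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, query - k)
            / math.comb(universe, query)
        )
    return total


def peak_targets_brute_force(peaks, tss, window: int) -> set:
    """All-pairs nearest-edge distance scan for promoter-window assignment."""
    hit = set()
    for gene, (chrom, pos, _strand) in tss.tss.items():
        for p in peaks.peaks:
            if p.chrom != chrom:
                continue
            if p.start > pos:
                dist = p.start - pos
            elif p.end - 1 < pos:
                dist = pos - (p.end - 1)
            else:
                dist = 0
            if dist <= window:
                hit.add(gene)
                break
    return hit


def lognormal_fc_tail(noise_sd: float, threshold: float) -> float:
    """P(exp(e2 - e1) > t) for independent e ~ N(0, sd)."""
    from scipy.stats import norm

    return float(1 - norm.cdf(math.log(threshold) / (noise_sd * math.sqrt(2))))
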