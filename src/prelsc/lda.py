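"""Single-hit Poisson limiting-dilution analysis and repopulation metrics.

The single-hit model assumes a transplanted inoculum of ``d`` cells engrafts
iff it contains at least one functional stem cell, so that with stem-cell
frequency ``f`` (stem cells per transplanted cell)

    P(recipient negative | dose d) = exp(-f * d).

Given a dilution cohort — per-dose counts of tested and engrafted recipients —
the frequency is estimated by maximum likelihood on the per-dose binomial
counts, with a profile-likelihood confidence interval (chi-square(1) cutoff),
the standard practice of ELDA-type limiting-dilution software.

Competitive-repopulation metrics follow the Harrison convention:

* RU  (repopulating units)  = donor-derived cells / competitor host cells,
* CRU (competitive repopulating units) = stem-cell content of an inoculum,
  here ``N * f_hat`` for an inoculum of ``N`` cells,
* MAS (mean activity of stem cells) = RU / CRU, the per-stem-cell output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm

from prelsc.errors import BoundaryError, InputError

__all__ = [
    "TransplantRecord",
    "DilutionCohort",
    "FrequencyEstimate",
    "RepopulationMetrics",
    "score_positive",
    "fit_single_hit",
    "frequency_ratio",
    "compute_RU",
    "compute_CRU",
    "compute_MAS",
    "fold_expansion",
    "serial_amplification",
    "cohorts_from_records",
    "read_transplant_records",
]

# Search bounds for the per-cell frequency (stem cells per transplanted cell).
F_MIN = 1e-9
F_MAX = 1.0

#: Default engraftment threshold: "positive" means strictly more than 1%
#: donor-derived T-lineage reconstitution.
POSITIVITY_THRESHOLD_PCT = 1.0


@dataclass(frozen=True)
class TransplantRecord:
    """One recipient mouse in a transplantation experiment.

    ``donor_cells``/``host_cells`` are the absolute donor-derived and
    competitor host cell counts in the recipient thymus, used for RU; they
    are optional because dilution cohorts only need the positivity call.
    """

    mouse_id: str
    genotype: str
    dose: int
    reconstitution_pct: float
    donor_cells: float | None = None
    host_cells: float | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise InputError(f"dose must be positive, got {self.dose}")
        if not 0.0 <= self.reconstitution_pct <= 100.0:
            raise InputError(
                f"reconstitution_pct must be in [0, 100], got {self.reconstitution_pct}"
            )
        if self.host_cells is not None and self.host_cells <= 0:
            raise InputError("host_cells must be positive when given")
        if self.donor_cells is not None and self.donor_cells < 0:
            raise InputError("donor_cells must be non-negative when given")


@dataclass(frozen=True)
class DilutionCohort:
    """Per-dose tested/positive counts for one genotype.

    Doses must be strictly positive and unique; ``0 <= n_positive <= n_tested``
    at every dose.
    """

    genotype: str
    doses: tuple[float, ...]
    n_tested: tuple[int, ...]
    n_positive: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n_tested) == len(self.n_positive)):
            raise InputError("doses, n_tested and n_positive must have equal length")
        if len(set(self.doses)) != len(self.doses):
            raise InputError("doses must be unique")
        for d, n, k in zip(self.doses, self.n_tested, self.n_positive):
            if d <= 0:
                raise InputError(f"doses must be positive, got {d}")
            if n < 0 or not 0 <= k <= n:
                raise InputError(f"need 0 <= n_positive <= n_tested at dose {d}")

    @property
    def total_tested(self) -> int:
        return int(sum(self.n_tested))

    @property
    def total_positive(self) -> int:
        return int(sum(self.n_positive))

    def scaled(self, c: float) -> "DilutionCohort":
        """Return the same cohort with every dose multiplied by ``c > 0``."""
        if c <= 0:
            raise InputError("scale factor must be positive")
        return DilutionCohort(
            self.genotype,
            tuple(d * c for d in self.doses),
            self.n_tested,
            self.n_positive,
        )


@dataclass(frozen=True)
class FrequencyEstimate:
    """Maximum-likelihood stem-cell frequency with profile-likelihood CI.

    ``boundary`` is ``None`` for interior estimates, ``"all_negative"`` when
    no recipient engrafted (``f_hat = 0``, upper bound only) and
    ``"all_positive"`` when every recipient engrafted (``f_hat`` pinned at the
    upper search bound, lower bound only).
    """

    f_hat: float
    ci_low: float
    ci_high: float
    level: float
    boundary: str | None
    loglik: float
    genotype: str = ""

    @property
    def frequency_denominator(self) -> float:
        """1/f_hat, i.e. 'one pre-LSC per this many cells'."""
        if self.f_hat <= 0:
            raise BoundaryError("frequency is zero; denominator undefined")
        return 1.0 / self.f_hat

    def cru(self, inoculum: float) -> float:
        """Competitive repopulating units contained in an inoculum of N cells."""
        if inoculum <= 0:
            raise InputError("inoculum must be positive")
        return inoculum * self.f_hat


@dataclass(frozen=True)
class RepopulationMetrics:
    RU: float
    CRU: float
    MAS: float

    def __post_init__(self) -> None:
        if self.RU < 0 or self.CRU < 0 or self.MAS < 0:
            raise InputError("repopulation metrics must be non-negative")


def score_positive(
    reconstitution_pct: float, threshold_pct: float = POSITIVITY_THRESHOLD_PCT
) -> bool:
    """True iff T-lineage reconstitution strictly exceeds the threshold (default 1%)."""
    if not 0.0 <= reconstitution_pct <= 100.0:
        raise InputError(
            f"reconstitution_pct must be in [0, 100], got {reconstitution_pct}"
        )
    return reconstitution_pct > threshold_pct


def _loglik(f: float, cohort: DilutionCohort) -> float:
    """Binomial log-likelihood (up to the constant binomial coefficients)."""
    ll = 0.0
    for d, n, k in zip(cohort.doses, cohort.n_tested, cohort.n_positive):
        if n == 0:
            continue
        fd = f * d
        # P(negative) = exp(-fd); use expm1 for small fd accuracy.
        if k > 0:
            p_pos = -math.expm1(-fd)
            if p_pos <= 0.0:
                return -math.inf
            ll += k * math.log(p_pos)
        ll += -(n - k) * fd
    return ll


def _score(f: float, cohort: DilutionCohort) -> float:
    """d loglik / d f; strictly decreasing in f (the log-likelihood is concave)."""
    s = 0.0
    for d, n, k in zip(cohort.doses, cohort.n_tested, cohort.n_positive):
        if n == 0:
            continue
        fd = f * d
        if k > 0 and fd < 700:  # beyond 700 the term underflows to 0
            # k * d * exp(-fd) / (1 - exp(-fd))
            s += k * d / math.expm1(fd)
        s -= (n - k) * d
    return s


def fit_single_hit(cohort: DilutionCohort, level: float = 0.95) -> FrequencyEstimate:
    """Fit the single-hit Poisson model to a dilution cohort.

    The MLE solves the score equation by bracketed root-finding on
    ``[F_MIN, F_MAX]`` (the log-likelihood is concave, so the root is the
    unique maximum).  The CI inverts the likelihood-ratio statistic at the
    chi-square(1) quantile for ``level``.
    """
    if not 0 < level < 1:
        raise InputError(f"confidence level must be in (0, 1), got {level}")
    if cohort.total_tested == 0:
        raise InputError("cohort has zero tested recipients")

    if cohort.total_positive == 0:
        # Likelihood maximized at f = 0 (boundary).
        cutoff = chi2.ppf(level, df=1) / 2.0
        sum_nd = sum(n * d for d, n in zip(cohort.doses, cohort.n_tested))
        return FrequencyEstimate(
            f_hat=0.0,
            ci_low=0.0,
            ci_high=cutoff / sum_nd,  # ll(f) = -f * sum(n*d) = -cutoff
            level=level,
            boundary="all_negative",
            loglik=0.0,
            genotype=cohort.genotype,
        )

    all_positive = all(
        k == n for n, k in zip(cohort.n_tested, cohort.n_positive) if n > 0
    )
    if all_positive:
        f_hat = F_MAX
        ll_max = _loglik(f_hat, cohort)
        ci_low = _profile_bound(cohort, f_hat, ll_max, level, side="lower")
        return FrequencyEstimate(
            f_hat=f_hat,
            ci_low=ci_low,
            ci_high=f_hat,
            level=level,
            boundary="all_positive",
            loglik=ll_max,
            genotype=cohort.genotype,
        )

    s_lo, s_hi = _score(F_MIN, cohort), _score(F_MAX, cohort)
    if s_lo <= 0:  # optimum below the search floor
        f_hat = F_MIN
    elif s_hi >= 0:  # should not happen once all-positive is excluded
        f_hat = F_MAX
    else:
        f_hat = brentq(
            _score, F_MIN, F_MAX, args=(cohort,), xtol=1e-300, rtol=1e-15, maxiter=200
        )
    ll_max = _loglik(f_hat, cohort)
    ci_low = _profile_bound(cohort, f_hat, ll_max, level, side="lower")
    ci_high = _profile_bound(cohort, f_hat, ll_max, level, side="upper")
    return FrequencyEstimate(
        f_hat=f_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        boundary=None,
        loglik=ll_max,
        genotype=cohort.genotype,
    )


def _profile_bound(
    cohort: DilutionCohort, f_hat: float, ll_max: float, level: float, side: str
) -> float:
    """One profile-likelihood bound: ll(f) = ll_max - chi2(1, level)/2.

    Solved on the log-f axis for numerical stability; clamped to the search
    bounds when the likelihood never drops below the cutoff inside them.
    """
    cutoff = chi2.ppf(level, df=1) / 2.0

    def g(logf: float) -> float:
        return _loglik(math.exp(logf), cohort) - (ll_max - cutoff)

    log_fhat = math.log(f_hat)
    if side == "lower":
        lo = math.log(F_MIN)
        if g(lo) >= 0:
            return F_MIN
        return math.exp(brentq(g, lo, log_fhat, xtol=1e-13, maxiter=200))
    hi = math.log(F_MAX)
    if g(hi) >= 0:
        return F_MAX
    return math.exp(brentq(g, log_fhat, hi, xtol=1e-13, maxiter=200))


@dataclass(frozen=True)
class RatioEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    level: float


def frequency_ratio(
    a: FrequencyEstimate, b: FrequencyEstimate, level: float | None = None
) -> RatioEstimate:
    """Fold-change ``a.f_hat / b.f_hat`` with a combined confidence interval.

    Each profile interval is converted to a standard error on the log scale
    (half-width over the normal quantile); the two are combined in quadrature,
    treating the cohorts as independent.
    """
    for est in (a, b):
        if est.boundary is not None or est.f_hat <= 0:
            raise BoundaryError(
                "frequency ratio undefined at boundary "
                f"(genotype={est.genotype!r}, boundary={est.boundary})"
            )
    if level is None:
        if a.level != b.level:
            raise InputError("estimates have different confidence levels; pass level=")
        level = a.level
    z = norm.ppf(0.5 + level / 2.0)
    # CI bounds clamped at the search floor would give a spurious zero SE.
    se_a = (math.log(a.ci_high) - math.log(max(a.ci_low, F_MIN))) / (2 * z)
    se_b = (math.log(b.ci_high) - math.log(max(b.ci_low, F_MIN))) / (2 * z)
    log_ratio = math.log(a.f_hat) - math.log(b.f_hat)
    half = z * math.hypot(se_a, se_b)
    return RatioEstimate(
        ratio=math.exp(log_ratio),
        ci_low=math.exp(log_ratio - half),
        ci_high=math.exp(log_ratio + half),
        level=level,
    )


def compute_RU(donor_cells: float, host_cells: float) -> float:
    """Repopulating units: donor-derived cells per competitor host cell."""
    if host_cells <= 0:
        raise InputError("host_cells must be positive")
    if donor_cells < 0:
        raise InputError("donor_cells must be non-negative")
    return donor_cells / host_cells


def compute_CRU(freq: FrequencyEstimate, inoculum: float) -> float:
    """CRU of an inoculum of ``inoculum`` cells at the fitted frequency."""
    return freq.cru(inoculum)


def compute_MAS(ru: float, freq: FrequencyEstimate, inoculum: float) -> RepopulationMetrics:
    """Mean activity of stem cells: MAS = RU / CRU."""
    if freq.boundary is not None or freq.f_hat <= 0:
        raise BoundaryError("MAS undefined for a boundary frequency estimate")
    if ru < 0:
        raise InputError("RU must be non-negative")
    cru = freq.cru(inoculum)
    return RepopulationMetrics(RU=ru, CRU=cru, MAS=ru / cru)


def fold_expansion(input_count: float, output_count: float) -> float:
    """Output/input cell ratio for one expansion round."""
    if input_count <= 0:
        raise InputError("input_count must be positive")
    if output_count < 0:
        raise InputError("output_count must be non-negative")
    return output_count / input_count


def serial_amplification(rounds: Sequence[float]) -> float:
    """Cumulative fold amplification over serial rounds (product of folds)."""
    folds = list(rounds)
    if any(r <= 0 for r in folds):
        raise InputError("every per-round fold must be positive")
    return float(np.prod(folds)) if folds else 1.0


# ---------------------------------------------------------------------------
# Record-level I/O

RECORD_COLUMNS = [
    "mouse_id",
    "genotype",
    "dose",
    "reconstitution_pct",
    "donor_cells",
    "host_cells",
]


def read_transplant_records(path) -> pd.DataFrame:
    """Read a transplant-record TSV (see :data:`RECORD_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RECORD_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise InputError(f"records file missing required columns: {missing}")
    for col in ("donor_cells", "host_cells"):
        if col not in df.columns:
            df[col] = np.nan
    bad = df[(df["reconstitution_pct"] < 0) | (df["reconstitution_pct"] > 100)]
    if len(bad):
        raise InputError(
            f"reconstitution_pct outside [0, 100] for mice: {list(bad['mouse_id'])}"
        )
    if (df["dose"] <= 0).any():
        raise InputError("all doses must be positive")
    return df


def cohorts_from_records(
    records: pd.DataFrame, threshold_pct: float = POSITIVITY_THRESHOLD_PCT
) -> dict[str, DilutionCohort]:
    """Aggregate per-mouse records into per-genotype dilution cohorts."""
    cohorts: dict[str, DilutionCohort] = {}
    for genotype, grp in records.groupby("genotype", sort=True):
        doses = sorted(grp["dose"].unique())
        n_tested, n_positive = [], []
        for d in doses:
            sub = grp[grp["dose"] == d]
            n_tested.append(len(sub))
            n_positive.append(
                int(sum(score_positive(p, threshold_pct) for p in sub["reconstitution_pct"]))
            )
        cohorts[str(genotype)] = DilutionCohort(
            str(genotype), tuple(float(d) for d in doses), tuple(n_tested), tuple(n_positive)
        )
    return cohorts


def pairwise_ratios(
    estimates: dict[str, FrequencyEstimate]
) -> list[tuple[str, str, RatioEstimate]]:
    """All pairwise frequency ratios among non-boundary estimates."""
    out = []
    usable = {g: e for g, e in estimates.items() if e.boundary is None and e.f_hat > 0}
    for ga, gb in combinations(sorted(usable), 2):
        out.append((ga, gb, frequency_ratio(usable[ga], usable[gb])))
    return out
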