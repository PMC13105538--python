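r"""Disproportionality statistics and four-method concordance signal calling.

For each drug–event pair a 2×2 contingency table is formed over de-duplicated
reports::

                event      no event
    drug          a            b
    other drugs   c            d

with N = a+b+c+d and expected count E = (a+b)(a+c)/N under independence.
Four statistics are computed:

* **PRR** — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with a chi-square
  statistic (Yates-corrected by default).
* **ROR** — reporting odds ratio ad/bc with a Wald 95% CI on the log scale.
* **BCPNN IC** — information component log2 of the shrunk observed/expected
  ratio; the reporting rate ratio has posterior Gamma(a + 1/2, E + 1/2) and
  IC025 is the exact 2.5th posterior percentile on the log2 scale.
* **MGPS EBGM/EB05** — DuMouchel's gamma–Poisson shrinker: counts are Poisson
  with mean lambda*E and lambda has a two-component gamma mixture prior fit by
  maximum marginal likelihood over all pairs; EBGM is the posterior geometric
  mean of lambda and EB05 its 5th posterior percentile.

A pair is a **key signal** only when all four methods pass their thresholds
(PRR >= 2 & chi2 >= 4 & a >= 3; ROR025 > 1; IC025 > 0; EB05 >= 2) — concordance
across methods is the false-positive control.  Statistics undefined on sparse
tables (zero margins or cells) are carried as NaN with their flag False, never
as exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .cohort import Cohort
from .faers_io import ReportStore

__all__ = [
    "ContingencyTable",
    "MgpsPrior",
    "MgpsConvergenceError",
    "SignalScores",
    "SignalMatrix",
    "Thresholds",
    "build_contingency",
    "contingency_tables",
    "prr_stats",
    "ror_stats",
    "bcpnn_stats",
    "nb_mixture_loglik",
    "fit_mgps_prior",
    "mgps_score",
    "call_signal",
    "compute_scores",
    "rank_signals",
    "signal_matrix",
]

Z975 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug/event report counts with margin total N and expected count E."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.N == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.N


def build_contingency(universe: ReportStore, cohort: Cohort, pt: str) -> ContingencyTable:
    """Count reports by (in cohort) × (contains PT); a PT counts once per report."""
    cohort_ids = {r.primaryid for r in cohort.reports}
    universe_ids = {r.primaryid for r in universe.reports}
    if not cohort_ids <= universe_ids:
        raise ValueError("cohort is not a subset of the universe")
    a = b = c = d = 0
    for rec in universe.reports:
        has_pt = pt in rec.events
        if rec.primaryid in cohort_ids:
            a, b = (a + 1, b) if has_pt else (a, b + 1)
        else:
            c, d = (c + 1, d) if has_pt else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def contingency_tables(
    universe: ReportStore, cohort: Cohort, pts: Sequence[str] | None = None
) -> dict[str, ContingencyTable]:
    """All 2×2 tables for one cohort at once via an inverted PT index.

    Equivalent to calling :func:`build_contingency` per PT but linear in the
    corpus size.  ``pts=None`` means every PT observed in the universe.
    """
    cohort_ids = {r.primaryid for r in cohort.reports}
    universe_ids = set()
    pt_index: dict[str, set[str]] = {}
    for rec in universe.reports:
        universe_ids.add(rec.primaryid)
        for pt in rec.events:
            pt_index.setdefault(pt, set()).add(rec.primaryid)
    if not cohort_ids <= universe_ids:
        raise ValueError("cohort is not a subset of the universe")
    n_total, n_cohort = len(universe_ids), len(cohort_ids)
    wanted = list(pt_index) if pts is None else list(pts)
    out = {}
    for pt in wanted:
        hits = pt_index.get(pt, set())
        a = len(hits & cohort_ids)
        c = len(hits) - a
        out[pt] = ContingencyTable(a, n_cohort - a, c, n_total - n_cohort - c)
    return out


# --- frequentist statistics ----------------------------------------------


def prr_stats(t: ContingencyTable, correction: str = "yates") -> tuple[float, float]:
    """PRR and its chi-square statistic; NaN where a margin is zero.

    chi2 = N(|ad - bc| - y)^2 / [(a+b)(c+d)(a+c)(b+d)], y = 0 (``"pearson"``)
    or N/2 (``"yates"``, with the numerator base floored at zero).
    """
    if correction not in ("pearson", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d, N = t.a, t.b, t.c, t.d, t.N
    prr = np.nan
    if a + b > 0 and c + d > 0 and c > 0:
        prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return prr, np.nan
    base = abs(a * d - b * c)
    if correction == "yates":
        base = max(base - N / 2.0, 0.0)
    chi2 = N * base * base / denom
    return prr, chi2


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """ROR with Wald 95% CI; any zero cell leaves all three NaN."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return np.nan, np.nan, np.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z975 * se)
    hi = math.exp(math.log(ror) + Z975 * se)
    return ror, lo, hi


# --- BCPNN ----------------------------------------------------------------


def bcpnn_stats(t: ContingencyTable, method: str = "exact") -> tuple[float, float]:
    """Information component IC and its 2.5% credible lower bound IC025.

    Shrinkage observed/expected formulation: the rate ratio has posterior
    Gamma(shape a + 1/2, rate E + 1/2), so IC = log2[(a+1/2)/(E+1/2)] and the
    exact IC025 is the log2 of the posterior 2.5th percentile.  ``method=
    "two_sigma"`` instead returns IC minus twice the posterior SD of log2(rate),
    a normal-approximation variant kept for compatibility.
    """
    shape = t.a + 0.5
    rate = t.E + 0.5
    ic = math.log2(shape / rate)
    if method == "exact":
        q = stats.gamma.ppf(0.025, shape, scale=1.0 / rate)
        ic025 = math.log2(q)
    elif method == "two_sigma":
        sd_log2 = math.sqrt(special.polygamma(1, shape)) / math.log(2)
        ic025 = ic - 2.0 * sd_log2
    else:
        raise ValueError(f"unknown BCPNN method {method!r}")
    return ic, ic025


# --- MGPS -----------------------------------------------------------------


class MgpsConvergenceError(RuntimeError):
    """Raised when no optimisation restart converges; carries best-so-far."""

    def __init__(self, message: str, best: "MgpsPrior | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Component i is Gamma(shape alpha_i, rate beta_i); p is the weight of
    component 1; loglik is the attained marginal log-likelihood.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    loglik: float = np.nan

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must be in (0,1), got {self.p}")

    @property
    def prior_mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2


#: DuMouchel's conventional starting point (alpha1, beta1, alpha2, beta2, p)
MGPS_CONVENTIONAL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _log_nb(a: np.ndarray, alpha: float, beta: float, E: np.ndarray) -> np.ndarray:
    """log NB(a; alpha, beta, E): marginal of Poisson(lambda E), lambda~Gamma."""
    return (
        special.gammaln(alpha + a) - special.gammaln(a + 1.0) - special.gammaln(alpha)
        + alpha * (np.log(beta) - np.log(beta + E))
        + a * (np.log(E) - np.log(beta + E))
    )


def nb_mixture_loglik(
    a: np.ndarray, E: np.ndarray,
    alpha1: float, beta1: float, alpha2: float, beta2: float, p: float,
) -> float:
    """Marginal log-likelihood of counts under the two-component mixture."""
    l1 = np.log(p) + _log_nb(a, alpha1, beta1, E)
    l2 = np.log1p(-p) + _log_nb(a, alpha2, beta2, E)
    return float(np.logaddexp(l1, l2).sum())


def _unpack(x: np.ndarray) -> tuple[float, float, float, float, float]:
    a1, b1, a2, b2 = np.exp(np.clip(x[:4], -30, 30))
    p = float(special.expit(np.clip(x[4], -30, 30)))
    return float(a1), float(b1), float(a2), float(b2), p


def fit_mgps_prior(
    tables: Iterable[ContingencyTable] | tuple[np.ndarray, np.ndarray],
    include_zeros: bool = False,
    n_restarts: int = 3,
    seed: int = 0,
    maxiter: int = 5000,
) -> MgpsPrior:
    """Fit the mixture hyperparameters by maximum marginal likelihood.

    ``tables`` is either an iterable of :class:`ContingencyTable` or a
    pre-extracted ``(a, E)`` array pair.  Default scope keeps pairs with
    a >= 1 (``include_zeros=True`` keeps the whole grid).  Optimisation is
    Nelder-Mead in unconstrained space (log shapes/rates, logit weight),
    multi-started from DuMouchel's conventional point plus seeded random
    perturbations; the best converged optimum wins.
    """
    if isinstance(tables, tuple):
        a_arr, e_arr = (np.asarray(x, dtype=float) for x in tables)
    else:
        tl = list(tables)
        a_arr = np.array([t.a for t in tl], dtype=float)
        e_arr = np.array([t.E for t in tl], dtype=float)
    keep = e_arr > 0
    if not include_zeros:
        keep &= a_arr >= 1
    a_arr, e_arr = a_arr[keep], e_arr[keep]
    if a_arr.size < 2:
        raise ValueError("need at least 2 pairs with a >= 1 (and E > 0) to fit the prior")

    def nll(x: np.ndarray) -> float:
        a1, b1, a2, b2, p = _unpack(x)
        return -nb_mixture_loglik(a_arr, e_arr, a1, b1, a2, b2, p)

    s = MGPS_CONVENTIONAL_START
    x0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]), math.log(s[3]),
                   special.logit(s[4])])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(scale=0.7, size=5) for _ in range(n_restarts)]
    best: optimize.OptimizeResult | None = None
    best_any: optimize.OptimizeResult | None = None
    for start in starts:
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"maxiter": maxiter, "maxfev": maxiter,
                                         "xatol": 1e-6, "fatol": 1e-9})
        if not res.success:
            # the likelihood can have a long flat ridge (a component drifting
            # toward a point mass); accept the point as stationary if a
            # restarted simplex no longer improves it meaningfully
            polish = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": maxiter // 2, "maxfev": maxiter // 2,
                         "xatol": 1e-6, "fatol": 1e-9})
            if polish.fun <= res.fun:
                improved = (res.fun - polish.fun) / max(abs(polish.fun), 1.0)
                polish.success = polish.success or improved < 1e-7
                res = polish
        if best_any is None or res.fun < best_any.fun:
            best_any = res
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        assert best_any is not None
        a1, b1, a2, b2, p = _unpack(best_any.x)
        raise MgpsConvergenceError(
            f"no restart converged after {len(starts)} starts "
            f"(best objective {best_any.fun:.6g}: {best_any.message})",
            best=MgpsPrior(a1, b1, a2, b2, p, loglik=-best_any.fun))
    a1, b1, a2, b2, p = _unpack(best.x)
    return MgpsPrior(a1, b1, a2, b2, p, loglik=-float(best.fun))


def _posterior_weight(a: float, E: float, prior: MgpsPrior) -> float:
    """Q = P(component 1 | a): posterior mixture weight."""
    aa = np.array([a], dtype=float)
    ee = np.array([E], dtype=float)
    l1 = math.log(prior.p) + float(_log_nb(aa, prior.alpha1, prior.beta1, ee)[0])
    l2 = math.log1p(-prior.p) + float(_log_nb(aa, prior.alpha2, prior.beta2, ee)[0])
    m = max(l1, l2)
    w1 = math.exp(l1 - m)
    return w1 / (w1 + math.exp(l2 - m))


def mgps_score(t: ContingencyTable, prior: MgpsPrior,
               quantile_tol: float = 1e-8) -> tuple[float, float]:
    """EBGM and EB05 under the fitted prior; E = 0 leaves both NaN.

    Posterior: lambda | a ~ Q Gamma(alpha1+a, beta1+E) + (1-Q) Gamma(alpha2+a,
    beta2+E).  EBGM = exp(E[log lambda]) via digamma; EB05 is the posterior
    5th percentile found by bracketed root-finding on the mixture CDF.
    """
    a, E = t.a, t.E
    if E <= 0:
        return np.nan, np.nan
    Q = _posterior_weight(a, E, prior)
    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E
    mean_log = Q * (special.digamma(s1) - math.log(r1)) \
        + (1 - Q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return (Q * stats.gamma.cdf(x, s1, scale=1.0 / r1)
                + (1 - Q) * stats.gamma.cdf(x, s2, scale=1.0 / r2))

    q1 = stats.gamma.ppf(0.05, s1, scale=1.0 / r1)
    q2 = stats.gamma.ppf(0.05, s2, scale=1.0 / r2)
    lo, hi = min(q1, q2), max(q1, q2)
    if hi - lo < quantile_tol:  # components coincide
        return ebgm, float(lo)
    # the mixture quantile lies between the component quantiles; widen the
    # bracket slightly to absorb CDF rounding at the endpoints
    lo *= 0.5
    hi *= 2.0
    for _ in range(60):
        if cdf(lo) < 0.05:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf(hi) > 0.05:
            break
        hi *= 2.0
    eb05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi,
                           xtol=quantile_tol, rtol=8.9e-16)
    return ebgm, float(eb05)


# --- concordance calling --------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """The four predefined signal criteria (defaults are the study's)."""

    prr_min: float = 2.0
    chi2_min: float = 4.0
    min_reports: int = 3
    ror_lo_min: float = 1.0   # strict >
    ic025_min: float = 0.0    # strict >
    eb05_min: float = 2.0     # >=


@dataclass
class SignalScores:
    """All four disproportionality estimates for one drug–event pair."""

    a: int
    prr: float = np.nan
    chi2: float = np.nan
    ror: float = np.nan
    ror_lo: float = np.nan
    ror_hi: float = np.nan
    ic: float = np.nan
    ic025: float = np.nan
    ebgm: float = np.nan
    eb05: float = np.nan
    prr_flag: bool = False
    ror_flag: bool = False
    ic_flag: bool = False
    ebgm_flag: bool = False
    key: bool = False


def call_signal(scores: SignalScores, thresholds: Thresholds = Thresholds()) -> SignalScores:
    """Set the per-method flags and the four-way concordance key flag.

    An undefined (NaN) statistic fails its criterion; flags are monotone in
    each statistic.
    """
    th = thresholds
    prr_flag = bool(scores.prr >= th.prr_min and scores.chi2 >= th.chi2_min
                    and scores.a >= th.min_reports)
    ror_flag = bool(scores.ror_lo > th.ror_lo_min)
    ic_flag = bool(scores.ic025 > th.ic025_min)
    ebgm_flag = bool(scores.eb05 >= th.eb05_min)
    return replace(scores, prr_flag=prr_flag, ror_flag=ror_flag, ic_flag=ic_flag,
                   ebgm_flag=ebgm_flag,
                   key=prr_flag and ror_flag and ic_flag and ebgm_flag)


def compute_scores(
    t: ContingencyTable,
    prior: MgpsPrior,
    thresholds: Thresholds = Thresholds(),
    chi2_correction: str = "yates",
    bcpnn_method: str = "exact",
) -> SignalScores:
    """Convenience: all four methods plus concordance calling for one table."""
    prr, chi2 = prr_stats(t, correction=chi2_correction)
    ror, lo, hi = ror_stats(t)
    ic, ic025 = bcpnn_stats(t, method=bcpnn_method)
    ebgm, eb05 = mgps_score(t, prior)
    return call_signal(
        SignalScores(a=t.a, prr=prr, chi2=chi2, ror=ror, ror_lo=lo, ror_hi=hi,
                     ic=ic, ic025=ic025, ebgm=ebgm, eb05=eb05),
        thresholds)


def rank_signals(
    scores: Mapping[str, SignalScores], by: str = "count", k: int = 10
) -> list[str]:
    """Top-k key signals by report count or EBGM.

    Ties break by the other field descending, then PT lexicographic, making
    the ordering fully deterministic.
    """
    if by not in ("count", "ebgm"):
        raise ValueError(f"unknown ranking field {by!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    keyed = [(pt, s) for pt, s in scores.items() if s.key]

    def sort_key(item: tuple[str, SignalScores]):
        pt, s = item
        primary = s.a if by == "count" else s.ebgm
        secondary = s.ebgm if by == "count" else s.a
        return (-primary, -(secondary if np.isfinite(secondary) else -np.inf), pt)

    return [pt for pt, _ in sorted(keyed, key=sort_key)][:k]


@dataclass
class SignalMatrix:
    """Binary drug × PT matrix of key-signal flags."""

    drugs: list[str]
    pts: list[str]
    values: np.ndarray  # bool, shape (n_drugs, n_pts)

    def signal_set(self, drug: str) -> frozenset[str]:
        i = self.drugs.index(drug)
        return frozenset(pt for j, pt in enumerate(self.pts) if self.values[i, j])

    @property
    def set_sizes(self) -> dict[str, int]:
        return {d: int(self.values[i].sum()) for i, d in enumerate(self.drugs)}


def signal_matrix(per_drug_scores: Mapping[str, Mapping[str, SignalScores]]) -> SignalMatrix:
    """Assemble the binary key-signal matrix; columns = union of key PTs.

    Drugs with no key signals keep an all-false row so the drug panel stays
    intact downstream.
    """
    drugs = list(per_drug_scores)
    pts = sorted({pt for sc in per_drug_scores.values()
                  for pt, s in sc.items() if s.key})
    vals = np.zeros((len(drugs), len(pts)), dtype=bool)
    col = {pt: j for j, pt in enumerate(pts)}
    for i, d in enumerate(drugs):
        for pt, s in per_drug_scores[d].items():
            if s.key:
                vals[i, col[pt]] = True
    return SignalMatrix(drugs=drugs, pts=pts, values=vals)
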