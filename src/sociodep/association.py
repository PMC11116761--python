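"""Dyadic association indices and null-model tests.

Associations are measured with the Simple Ratio Index (SRI): for a dyad
(i, j) over a set of sampling periods,

    SRI = x / (x + y_i + y_j + y_AB)

where x counts periods with i and j associated, y_i / y_j periods with
only one of them present, and y_AB periods with both present but not
together.  Under the gambit of the group all individuals photographed in
the same sighting are taken as associated.

Two sampling periods are supported:

``sighting``
    each sighting is a period; individuals are associated iff in the same
    sighting, so y_AB = 0.
``day``
    each UTC calendar date is a period; individuals are associated on a
    day iff they shared at least one sighting that day; both sighted the
    same day in different sightings counts in y_AB.

The preferred/avoided-association null model is a data-stream permutation:
a sequential chain of 2x2 checkerboard swaps on the group-by-individual
incidence, restricted to groups recorded on the same day, which preserves
group sizes and individual sighting frequencies exactly.  Day-level SRI
summary statistics (CV, SD, SD of nonzero values) are recorded along the
chain; an observed statistic in the upper tail indicates preferred
association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .sightings_io import Dataset

logger = logging.getLogger(__name__)

STATISTICS = ("cv_sri", "sd_sri", "sd_nonzero_sri")


# ---------------------------------------------------------------------------
# Association matrices
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Symmetric dyadic SRI values with their numerators and denominators."""

    ids: list[str]
    x: np.ndarray                 # periods associated
    d: np.ndarray                 # denominator = periods with i or j present
    n_periods: np.ndarray         # per-individual period count
    y_both_separate: np.ndarray   # periods with both present, not together
    sampling_period: str
    n_total_periods: int

    @property
    def sri(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(self.d > 0, self.x / np.maximum(self.d, 1), 0.0)
        np.fill_diagonal(s, 0.0)
        return s

    @property
    def n(self) -> int:
        return len(self.ids)

    def dyads(self) -> pd.DataFrame:
        """Long-format dyad table (upper triangle)."""
        iu, ju = np.triu_indices(self.n, k=1)
        sri = self.sri
        return pd.DataFrame({
            "i": [self.ids[a] for a in iu],
            "j": [self.ids[b] for b in ju],
            "x": self.x[iu, ju].astype(int),
            "d": self.d[iu, ju].astype(int),
            "sri": sri[iu, ju],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)

    def subset(self, ids: list[str]) -> "AssociationMatrix":
        pos = [self.ids.index(i) for i in ids]
        ix = np.ix_(pos, pos)
        return AssociationMatrix(list(ids), self.x[ix], self.d[ix],
                                 self.n_periods[pos], self.y_both_separate[ix],
                                 self.sampling_period, self.n_total_periods)


def _group_structure(ds: Dataset):
    """Group-by-individual incidence with day labels.

    Returns (ids, B, day_codes) where B is a boolean groups x individuals
    matrix (one row per non-empty sighting) and day_codes maps each group
    to its UTC date code.
    """
    ids = ds.individual_ids
    pos = {v: k for k, v in enumerate(ids)}
    rows, days = [], []
    for s in sorted(ds.sightings, key=lambda s: (s.start_time, s.sighting_id)):
        if not s.individual_ids:
            continue
        r = np.zeros(len(ids), dtype=bool)
        r[[pos[i] for i in s.individual_ids]] = True
        rows.append(r)
        days.append(s.date)
    B = np.array(rows, dtype=bool)
    day_codes = pd.factorize(pd.Series(days), sort=True)[0]
    return ids, B, day_codes


def _counts_from_groups(B: np.ndarray, day_codes: np.ndarray, by_day: bool):
    """(x, d, n, y_AB, n_periods_total) at sighting or day sampling period."""
    Bf = B.astype(np.float64)
    if not by_day:
        x = Bf.T @ Bf
        n = B.sum(axis=0).astype(np.float64)
        d = n[:, None] + n[None, :] - x
        y_ab = np.zeros_like(x)
        total = B.shape[0]
    else:
        n_days = int(day_codes.max()) + 1 if len(day_codes) else 0
        N = B.shape[1]
        together = np.zeros((N, N))
        present = np.zeros((n_days, N), dtype=bool)
        for dcode in range(n_days):
            Bd = Bf[day_codes == dcode]
            together += ((Bd.T @ Bd) > 0)
            present[dcode] = B[day_codes == dcode].any(axis=0)
        Pf = present.astype(np.float64)
        both = Pf.T @ Pf
        n = present.sum(axis=0).astype(np.float64)
        x = together
        d = n[:, None] + n[None, :] - both
        y_ab = both - together
        total = n_days
    np.fill_diagonal(x, 0.0)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(y_ab, 0.0)
    return x, d, n, y_ab, total


def compute_sri(ds: Dataset, sampling_period: str = "sighting") -> AssociationMatrix:
    if sampling_period not in ("sighting", "day"):
        raise ValueError(f"unknown sampling period {sampling_period!r}")
    ids, B, day_codes = _group_structure(ds)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    x, d, n, y_ab, total = _counts_from_groups(B, day_codes, sampling_period == "day")
    return AssociationMatrix(ids, x, d, n, y_ab, sampling_period, total)


# ---------------------------------------------------------------------------
# Data-stream permutation test
# ---------------------------------------------------------------------------

def _sri_statistic(sri: np.ndarray, statistic: str) -> float:
    iu = np.triu_indices(sri.shape[0], k=1)
    v = sri[iu]
    if statistic == "cv_sri":
        m = v.mean()
        return float(v.std() / m) if m > 0 else 0.0
    if statistic == "sd_sri":
        return float(v.std())
    if statistic == "sd_nonzero_sri":
        nz = v[v > 0]
        return float(nz.std()) if nz.size else 0.0
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    permuted: np.ndarray
    p_value: float
    n_permutations: int
    trials_per_permutation: int
    seed: int | None
    n_successful_swaps: int
    testable: bool = True

    @property
    def mean_permuted(self) -> float:
        return float(self.permuted.mean()) if self.permuted.size else float("nan")


def daily_swap_chain(B: np.ndarray, day_codes: np.ndarray, n_steps: int,
                     trials_per_step: int, rng: np.random.Generator
                     ) -> Iterator[tuple[np.ndarray, int]]:
    """Sequential checkerboard-swap chain on the incidence matrix.

    Each step attempts ``trials_per_step`` 2x2 swaps between two groups of
    the same day (move i from g1 to g2 and j from g2 to g1, requiring
    i in g1 only and j in g2 only) and yields ``(B, n_ok)`` where B is the
    *live* in-place-updated matrix.  Row sums (group sizes) and column sums
    (individual sighting frequencies) — per day and overall — are invariant.
    """
    days, counts = np.unique(day_codes, return_counts=True)
    eligible = days[counts >= 2]
    if eligible.size == 0:
        return
    groups_of_day = {d: np.flatnonzero(day_codes == d) for d in eligible}
    for _ in range(n_steps):
        ok = 0
        for _ in range(trials_per_step):
            d = eligible[rng.integers(eligible.size)]
            gs = groups_of_day[d]
            a, b = rng.choice(gs.size, size=2, replace=False)
            g1, g2 = gs[a], gs[b]
            only1 = np.flatnonzero(B[g1] & ~B[g2])
            only2 = np.flatnonzero(B[g2] & ~B[g1])
            if only1.size == 0 or only2.size == 0:
                continue
            i = only1[rng.integers(only1.size)]
            j = only2[rng.integers(only2.size)]
            B[g1, i] = False
            B[g2, i] = True
            B[g2, j] = False
            B[g1, j] = True
            ok += 1
        yield B, ok


def permutation_test(ds: Dataset, statistic: str = "cv_sri",
                     n_permutations: int = 10_000,
                     trials_per_permutation: int = 10,
                     seed: int | None = None,
                     two_sided: bool = False) -> PermutationResult:
    """Test for non-random association by permuting daily association data.

    The chain starts at the observed data (no burn-in discard); after each
    block of ``trials_per_permutation`` attempted swaps the day-level SRI
    statistic is recorded.  p = proportion of permuted values >= observed
    (doubled and capped for the optional two-sided mode).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    ids, B, day_codes = _group_structure(ds)
    x, d, n, y_ab, _ = _counts_from_groups(B, day_codes, by_day=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(d > 0, x / np.maximum(d, 1), 0.0)
    observed = _sri_statistic(sri, statistic)

    days, counts = np.unique(day_codes, return_counts=True)
    if not (counts >= 2).any():
        warnings.warn("no day holds two groups: association data not permutable")
        return PermutationResult(statistic, observed, np.empty(0), 1.0,
                                 n_permutations, trials_per_permutation, seed, 0,
                                 testable=False)

    rng = np.random.default_rng(seed)
    Bw = B.copy()
    permuted = np.empty(n_permutations)
    n_ok = 0
    # day-presence margins are swap-invariant: d and n stay fixed; only the
    # per-day co-membership counts (x) move, so `together` is recomputed per
    # recorded step (cheap at these matrix sizes).
    n_days = int(day_codes.max()) + 1
    day_rows = [np.flatnonzero(day_codes == dc) for dc in range(n_days)]
    chain = daily_swap_chain(Bw, day_codes, n_permutations,
                             trials_per_permutation, rng)
    for k, (Bcur, ok) in enumerate(chain):
        n_ok += ok
        together = np.zeros_like(x)
        for dc in range(n_days):
            Bd = Bcur[day_rows[dc]].astype(np.float64)
            together += ((Bd.T @ Bd) > 0)
        np.fill_diagonal(together, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sri_p = np.where(d > 0, together / np.maximum(d, 1), 0.0)
        permuted[k] = _sri_statistic(sri_p, statistic)
    if n_ok == 0:
        warnings.warn("no swappable 2x2 configuration found: untestable")
        return PermutationResult(statistic, observed, permuted, 1.0,
                                 n_permutations, trials_per_permutation, seed, 0,
                                 testable=False)
    p_high = float(np.mean(permuted >= observed))
    if two_sided:
        p_low = float(np.mean(permuted <= observed))
        p = min(1.0, 2.0 * min(p_high, p_low))
    else:
        p = p_high
    return PermutationResult(statistic, observed, permuted, p, n_permutations,
                             trials_per_permutation, seed, n_ok)


# ---------------------------------------------------------------------------
# Mantel test (platform comparison)
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    n_individuals: int
    method: str = "spearman"


def mantel_test(m1: AssociationMatrix, m2: AssociationMatrix,
                n_permutations: int = 10_000,
                seed: int | None = None) -> MantelResult:
    """Spearman matrix correlation with a row/column relabelling null.

    Matrices are restricted to their common individuals; the one-sided
    p-value is for positive association between the two matrices.
    """
    common = sorted(set(m1.ids) & set(m2.ids))
    if len(common) < 3:
        raise ValueError("need at least 3 common individuals")
    A = m1.subset(common).sri
    Bm = m2.subset(common).sri
    n = len(common)
    iu = np.triu_indices(n, k=1)
    ra = stats.rankdata(A[iu])
    rng = np.random.default_rng(seed)

    def spear(vb):
        rb = stats.rankdata(vb)
        if ra.std() == 0 or rb.std() == 0:
            return 0.0
        return float(np.corrcoef(ra, rb)[0, 1])

    r_obs = spear(Bm[iu])
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if spear(Bm[np.ix_(p, p)][iu]) >= r_obs:
            count += 1
    p_value = (count + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p_value, n_permutations, n)


# ---------------------------------------------------------------------------
# Social differentiation (beta-binomial maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class SocialDifferentiation:
    S: float
    se_S: float
    r: float
    se_r: float
    H: float
    power: float            # S^2 * H
    a: float
    b: float
    degenerate: bool
    h_measure: str


def _betabinom_nll(log_ab, x, d):
    a, b = np.exp(log_ab)
    return -np.sum(special.betaln(x + a, d - x + b) - special.betaln(a, b))


def _fit_beta(x, d):
    p = x / d
    m = float(np.clip(p.mean(), 1e-4, 1 - 1e-4))
    v = float(p.var())
    if v > 1e-8 and v < m * (1 - m):
        t = m * (1 - m) / v - 1.0
    else:
        t = 2.0
    x0 = np.log(np.clip([m * t, (1 - m) * t], 1e-3, 1e3))
    # box on log(a), log(b): the no-true-variation limit sends a, b to
    # infinity, where the likelihood is flat — the bound makes that case a
    # clean boundary solution instead of a non-convergence
    res = optimize.minimize(_betabinom_nll, x0, args=(x, d), method="L-BFGS-B",
                            bounds=[(-9.0, 14.0)] * 2,
                            options={"maxiter": 500, "ftol": 1e-12})
    if not res.success:
        raise RuntimeError(f"beta-binomial fit did not converge: {res.message}")
    return np.exp(res.x)


def _cv_beta(a, b):
    return float(np.sqrt(b / (a * (a + b + 1.0))))


def _posterior_r(a, b, d, rng, n_sim=50):
    """Correlation of true and estimated indices by simulation under the fit."""
    trues, ests = [], []
    for _ in range(n_sim):
        p = rng.beta(a, b, size=d.size)
        xs = rng.binomial(d.astype(int), p)
        trues.append(p)
        ests.append(xs / d)
    t = np.concatenate(trues)
    e = np.concatenate(ests)
    if t.std() == 0 or e.std() == 0:
        return 0.0
    return float(np.corrcoef(t, e)[0, 1])


def social_differentiation(am: AssociationMatrix, seed: int | None = None,
                           n_boot: int = 200, n_sim: int = 50,
                           h_measure: str = "mean_denominator") -> SocialDifferentiation:
    """Estimate social differentiation S and estimation power r.

    A two-parameter beta distribution of true dyadic association indices is
    fitted by maximising the beta-binomial marginal likelihood of the
    observed (x, d) pairs; S is the CV of the fitted beta, r the Pearson
    correlation of true and estimated indices under posterior simulation,
    and standard errors come from a nonparametric bootstrap over dyads.
    H is an association-count measure (mean dyadic denominator by default,
    or mean associations per individual); S^2 x H indexes the power of the
    permutation test.
    """
    iu = np.triu_indices(am.n, k=1)
    x = am.x[iu]
    d = am.d[iu]
    keep = d > 0
    if not keep.any():
        raise ValueError("no dyads with nonzero denominator")
    x, d = x[keep], d[keep]
    rng = np.random.default_rng(seed)

    a, b = _fit_beta(x, d)
    S = _cv_beta(a, b)
    r = _posterior_r(a, b, d, rng, n_sim=n_sim)

    degenerate = bool(np.all(x / d == (x / d)[0]) or S < 1e-3)
    if degenerate:
        logger.warning("social_differentiation: no detectable true variation (S=%.3g)", S)

    S_boot, r_boot = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            ab_, bb_ = _fit_beta(x[idx], d[idx])
        except RuntimeError:
            continue
        S_boot.append(_cv_beta(ab_, bb_))
        r_boot.append(_posterior_r(ab_, bb_, d[idx], rng, n_sim=max(3, n_sim // 10)))
    se_S = float(np.std(S_boot)) if S_boot else float("nan")
    se_r = float(np.std(r_boot)) if r_boot else float("nan")

    if h_measure == "mean_denominator":
        H = float(d.mean())
    elif h_measure == "mean_associations_per_individual":
        xs = am.x.copy()
        np.fill_diagonal(xs, 0.0)
        H = float(xs.sum(axis=1).mean())
    else:
        raise ValueError(f"unknown h_measure {h_measure!r}")
    return SocialDifferentiation(S, se_S, r, se_r, H, S * S * H,
                                 float(a), float(b), degenerate, h_measure)
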