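"""Four-family normal-mixture likelihood and its EM maximisation.

Each F2 individual's phenotype is modelled as a mixture over the four
ordered QTL configurations,

    y_ti ~ sum_k  w_tik * N(mu_tk, sigma2),

where ``w_tik`` are the marker-conditional configuration priors, ``mu_tk``
is the genotypic value of configuration k in mating type t (a linear
function of the 16 genetic effects), and a single residual variance is
shared across all 16 cells.  Arbitrary subsets of the 15 non-mean effects
may be constrained to zero; the M-step then solves a weighted least-squares
problem over the free design columns.  Nested fits are compared by
chi-square likelihood-ratio tests, which drive the standard hierarchy of
six imprinting tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .design import (DESIGN_MATRIX, EFFECT_NAMES, NON_MEAN_EFFECTS,
                     EffectVector)
from .linkage import MISSING, MarkerMap, configuration_priors_batch

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class CrossDataset:
    """Marker map, genotypes and one phenotype for the four reciprocal F2 families.

    ``family`` holds 0-based mating-type indices (0..3) per individual;
    ``genotypes`` is a DataFrame (individuals x markers) of unordered
    genotype strings ``11/12/22`` with ``NA`` for missing.
    """

    marker_map: MarkerMap
    family: np.ndarray
    phenotype: np.ndarray
    genotypes: pd.DataFrame
    individual: np.ndarray | None = None

    def __post_init__(self):
        self.family = np.asarray(self.family, dtype=int)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.phenotype)
        if len(self.family) != n or len(self.genotypes) != n:
            raise ValueError("family, phenotype and genotypes must have equal length")
        if not np.all(np.isfinite(self.phenotype)):
            raise ValueError("phenotypes must be finite")
        if self.family.min() < 0 or self.family.max() > 3:
            raise ValueError("family indices must be in 0..3")
        missing = set(self.genotypes.columns) - set(self.marker_map.marker_names)
        if missing:
            raise ValueError(f"markers absent from the map: {sorted(missing)}")
        if self.individual is None:
            self.individual = np.arange(1, n + 1)

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def family_sizes(self) -> np.ndarray:
        return np.bincount(self.family, minlength=4)

    def priors_at(self, chromosome: str, pos_cm: float) -> np.ndarray:
        """Configuration priors (n x 4) for a QTL at ``pos_cm`` on ``chromosome``."""
        iv = self.marker_map.interval_at(chromosome, pos_cm)
        left = self.genotypes[iv.left_marker].to_numpy(dtype=object) \
            if iv.left_marker in self.genotypes else np.full(self.n, MISSING, dtype=object)
        right = self.genotypes[iv.right_marker].to_numpy(dtype=object) \
            if iv.right_marker in self.genotypes else np.full(self.n, MISSING, dtype=object)
        return configuration_priors_batch(left, right, iv.r1, iv.r2)


# ---------------------------------------------------------------------------
# Constraints and test definitions
# ---------------------------------------------------------------------------

#: Null-hypothesis constraint sets of the six-level imprinting test hierarchy.
#: Test 1: all imprinting-related terms (13 df); Test 2: F1-expressed
#: imprinting (3 df); Test 3: F2-expressed imprinting and all cross-generation
#: interactions (10 df); Tests 4-6: the three interaction blocks (3 df each).
STANDARD_TESTS: dict[int, frozenset[str]] = {
    1: frozenset({"i1m", "i1p", "i1mp", "i2",
                  "i1m_a", "i1m_d", "i1m_i2",
                  "i1p_a", "i1p_d", "i1p_i2",
                  "i1mp_a", "i1mp_d", "i1mp_i2"}),
    2: frozenset({"i1m", "i1p", "i1mp"}),
    3: frozenset({"i2",
                  "i1m_a", "i1m_d", "i1m_i2",
                  "i1p_a", "i1p_d", "i1p_i2",
                  "i1mp_a", "i1mp_d", "i1mp_i2"}),
    4: frozenset({"i1m_a", "i1m_d", "i1m_i2"}),
    5: frozenset({"i1p_a", "i1p_d", "i1p_i2"}),
    6: frozenset({"i1mp_a", "i1mp_d", "i1mp_i2"}),
}

#: Constraint set of the QTL-existence null: all 16 cell means equal.
EXISTENCE_CONSTRAINTS: frozenset[str] = frozenset(NON_MEAN_EFFECTS)


def standard_test_constraints(test: int | str) -> frozenset[str]:
    """Constraint set for a numbered test (1-6), ``"existence"``, or one effect."""
    if isinstance(test, int):
        if test not in STANDARD_TESTS:
            raise ValueError(f"unknown test id {test}; expected 1..6")
        return STANDARD_TESTS[test]
    if test == "existence":
        return EXISTENCE_CONSTRAINTS
    if test in NON_MEAN_EFFECTS:
        return frozenset({test})
    raise ValueError(f"unknown test or effect name {test!r}")


def validate_constraints(constraints: Iterable[str]) -> frozenset[str]:
    cs = frozenset(constraints)
    if "mu" in cs:
        raise ValueError("the overall mean may not be constrained to zero")
    unknown = cs - set(NON_MEAN_EFFECTS)
    if unknown:
        raise ValueError(f"unknown effect names in constraints: {sorted(unknown)}")
    return cs


# ---------------------------------------------------------------------------
# Likelihood and EM
# ---------------------------------------------------------------------------

def mixture_loglik(y: np.ndarray, family: np.ndarray, priors: np.ndarray,
                   means: np.ndarray, sigma2: float) -> float:
    """Observed-data log-likelihood of the four-family normal mixture.

    ``means`` is the 4x4 genotypic-value matrix; the same residual variance
    applies to every cell.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    y = np.asarray(y, dtype=float)
    M = np.asarray(means, dtype=float).reshape(4, 4)[np.asarray(family, dtype=int)]
    logdens = -0.5 * ((y[:, None] - M) ** 2) / sigma2 - 0.5 * (_LOG_2PI + np.log(sigma2))
    with np.errstate(divide="ignore"):
        logw = np.where(priors > 0, np.log(np.maximum(priors, 1e-300)), -np.inf)
    a = logw + logdens
    amax = a.max(axis=1)
    return float(np.sum(amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))))


@dataclass
class ModelFit:
    """A converged (or best-iterate) maximum-likelihood mixture fit."""

    effects: EffectVector
    sigma2: float
    loglik: float
    constraints: frozenset[str]
    n_iter: int
    converged: bool
    n_obs: int
    trace: list[float] | None = None

    @property
    def n_free_effects(self) -> int:
        return 16 - len(self.constraints)

    @property
    def means(self) -> np.ndarray:
        from .design import effects_to_means
        return effects_to_means(self.effects)

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.to_dict(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "constraints": sorted(self.constraints),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _em_single_start(y, fam, logw, priors, Xf, mu0, s2_0, tol, max_iter):
    """One EM run from a given initial cell-mean vector; returns best iterate."""
    n = len(y)
    mu_cells = np.asarray(mu0, dtype=float).copy()
    s2 = s2_0
    loglik = -np.inf
    converged = False
    it = 0
    beta_f = np.zeros(Xf.shape[1])
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        # E-step: posteriors over configurations, in log space for stability
        M = mu_cells.reshape(4, 4)[fam]
        a = logw - 0.5 * ((y[:, None] - M) ** 2) / s2 - 0.5 * (_LOG_2PI + np.log(s2))
        amax = a.max(axis=1)
        lse = amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))
        new_loglik = float(lse.sum())
        trace.append(new_loglik)
        P = np.exp(a - lse[:, None])
        # M-step: weighted least squares over the free design columns
        cell_idx = fam * 4
        W = np.zeros(16)
        S = np.zeros(16)
        for k in range(4):
            W += np.bincount(cell_idx + k, weights=P[:, k], minlength=16)
            S += np.bincount(cell_idx + k, weights=P[:, k] * y, minlength=16)
        A = Xf.T @ (W[:, None] * Xf)
        b = Xf.T @ S
        try:
            beta_f = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_f = np.linalg.lstsq(A, b, rcond=None)[0]
        mu_cells = Xf @ beta_f
        M = mu_cells.reshape(4, 4)[fam]
        s2 = float(np.sum(P * (y[:, None] - M) ** 2) / n)
        s2 = max(s2, 1e-12)
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    # final likelihood at the returned parameters
    final_ll = mixture_loglik(y, fam, priors, mu_cells.reshape(4, 4), s2)
    return beta_f, mu_cells, s2, final_ll, it, converged, trace


def em_fit(data: CrossDataset | None, priors: np.ndarray,
           constraints: Iterable[str] = (), *,
           y: np.ndarray | None = None, family: np.ndarray | None = None,
           tol: float = 1e-8, max_iter: int = 2000,
           n_random_starts: int = 4, seed: int | np.random.Generator | None = 0,
           ) -> ModelFit:
    """Maximum-likelihood fit of the mixture model by EM.

    Parameters
    ----------
    data
        Dataset supplying phenotypes and family indices; alternatively pass
        ``y`` and ``family`` arrays directly with ``data=None``.
    priors
        (n x 4) marker-conditional configuration probabilities.
    constraints
        Effect names forced to zero (never ``mu``).
    n_random_starts
        Seeded random restarts added to the deterministic start (the
        single-normal fit perturbed by +-0.5 SD per cell); the best
        log-likelihood across starts is reported.
    """
    if data is not None:
        y = data.phenotype
        fam = data.family
    else:
        y = np.asarray(y, dtype=float)
        fam = np.asarray(family, dtype=int)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (len(y), 4):
        raise ValueError(f"priors must have shape ({len(y)}, 4)")
    cs = validate_constraints(constraints)
    free = [i for i, nm in enumerate(EFFECT_NAMES) if nm not in cs]
    Xf = DESIGN_MATRIX[:, free]

    # non-identifiability guard: a family-specific contrast with no data
    fam_sizes = np.bincount(fam, minlength=4)
    if np.any(fam_sizes == 0) and len(free) > 1:
        needed = {"i1m", "i1p", "i1mp"} - cs
        if needed:
            raise ValueError(
                "empty family with free F1-imprinting parameters: "
                f"families sized {fam_sizes.tolist()} cannot identify {sorted(needed)}")

    with np.errstate(divide="ignore"):
        logw = np.where(priors > 0, np.log(np.maximum(priors, 1e-300)), -np.inf)

    ybar = float(np.mean(y))
    s2_0 = float(np.var(y))
    s2_0 = max(s2_0, 1e-12)
    sd = np.sqrt(s2_0)

    # all 15 effects constrained -> the single-normal MLE, no EM needed
    if len(free) == 1:
        eff = EffectVector.from_array(
            np.array([ybar] + [0.0] * 15))
        ll = mixture_loglik(y, fam, priors, np.full((4, 4), ybar), s2_0)
        return ModelFit(effects=eff, sigma2=s2_0, loglik=ll,
                        constraints=cs, n_iter=0, converged=True, n_obs=len(y))

    # deterministic start: null fit perturbed +-0.5 SD alternating by cell
    signs = np.where(np.arange(16) % 2 == 0, 1.0, -1.0)
    starts = [ybar + 0.5 * sd * signs]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(ybar + 0.5 * sd * rng.standard_normal(16))

    # short-run / long-run strategy: burn each start in briefly, then run
    # only the most promising one to full convergence
    burn_in = min(25, max_iter)
    short = [
        _em_single_start(y, fam, logw, priors, Xf, mu0, s2_0, tol, burn_in)
        for mu0 in starts
    ]
    best_short = max(short, key=lambda r: r[3])
    if best_short[5]:  # already converged during burn-in
        beta_f, mu_cells, s2, ll, it, converged, trace = best_short
    else:
        beta_f, mu_cells, s2, ll, it, converged, trace = _em_single_start(
            y, fam, logw, priors, Xf, best_short[1], best_short[2], tol, max_iter)
        trace = list(best_short[6]) + trace

    beta = np.zeros(16)
    beta[free] = beta_f
    return ModelFit(effects=EffectVector.from_array(beta), sigma2=s2,
                    loglik=ll, constraints=cs, n_iter=it,
                    converged=converged, n_obs=len(y), trace=trace)


# ---------------------------------------------------------------------------
# Likelihood-ratio testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """A chi-square likelihood-ratio test between nested mixture fits."""

    name: str
    lr: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return {"name": self.name, "LR": self.lr, "df": self.df, "pvalue": self.pvalue}


def likelihood_ratio_test(fit_null: ModelFit, fit_full: ModelFit,
                          name: str = "LRT") -> TestResult:
    """LR = 2(logL_full - logL_null), chi-square with df = extra free effects."""
    if not fit_null.constraints > fit_full.constraints:
        raise ValueError("null constraints must strictly contain the full model's")
    df = len(fit_null.constraints) - len(fit_full.constraints)
    lr = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0
    return TestResult(name=name, lr=lr, df=df, pvalue=p)
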