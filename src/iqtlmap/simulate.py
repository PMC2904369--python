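"""Synthetic reciprocal-F2 crosses and the power / type-I-error study.

The generator emulates the study design the model targets: four reciprocal
F2 families descended from two inbred lines, fully heterozygous phase-known
F1 parents, multi-marker chromosomes with crossovers sampled independently
per interval (Haldane, no interference), a single biallelic QTL hidden
between markers, and phenotypes equal to the genotypic value of the
individual's (mating type, ordered configuration) cell plus normal noise
scaled to a target heritability.

The reference simulation places 10 evenly spaced markers on a 200 cM
linkage group with the QTL 35 cM from the left end; three effect scenarios
(full imprinting, F1-only imprinting, no imprinting) drive the power and
false-positive-rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import EffectVector, effects_to_means, genetic_variance
from .emfit import (CrossDataset, ModelFit, TestResult, em_fit,
                    likelihood_ratio_test, standard_test_constraints)
from .linkage import MarkerMap, haldane_r


def default_map(n_markers: int = 10, length_cm: float = 200.0,
                chromosome: str = "1") -> MarkerMap:
    """Evenly spaced markers spanning one linkage group (endpoints included)."""
    pos = np.linspace(0.0, length_cm, n_markers)
    names = [f"M{i + 1}" for i in range(n_markers)]
    return MarkerMap.from_table(names, [chromosome] * n_markers, pos)


# Reference truth for the simulation study: all 15 effects present.
_SCENARIO_I = EffectVector(
    mu=0.0, i1m=0.15, i1p=0.15, i1mp=0.1, a=0.3, d=0.6, i2=0.2,
    i1m_a=0.04, i1m_d=0.04, i1m_i2=0.04,
    i1p_a=0.04, i1p_d=0.04, i1p_i2=0.04,
    i1mp_a=0.04, i1mp_d=0.04, i1mp_i2=0.04,
)


def scenario_effects(scenario: str) -> EffectVector:
    """Effect vectors of the three study scenarios.

    * ``I``   -- all 15 effects nonzero (full transgenerational imprinting);
    * ``II``  -- F2-expressed imprinting and every cross-generation
      interaction zeroed (imprinting confined to the F1);
    * ``III`` -- only additive (0.3) and dominance (0.6) effects (no
      imprinting of any kind; the type-I-error scenario).
    """
    if scenario == "I":
        return _SCENARIO_I
    if scenario == "II":
        zeroed = {"i2", "i1m_a", "i1m_d", "i1m_i2", "i1p_a", "i1p_d",
                  "i1p_i2", "i1mp_a", "i1mp_d", "i1mp_i2"}
        d = _SCENARIO_I.to_dict()
        for k in zeroed:
            d[k] = 0.0
        return EffectVector.from_dict(d)
    if scenario == "III":
        return EffectVector(a=0.3, d=0.6)
    raise ValueError(f"unknown scenario {scenario!r}; expected 'I', 'II' or 'III'")


def residual_variance_for_heritability(effects: EffectVector, h2: float) -> float:
    """Residual variance making the genotypic values explain a fraction h2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    vg = genetic_variance(effects)
    if vg <= 0.0:
        raise ValueError("genetic variance is zero; heritability undefined")
    return vg * (1.0 - h2) / h2


@dataclass(frozen=True)
class SimulationScenario:
    """Complete specification of one simulated cross."""

    marker_map: MarkerMap
    qtl_chromosome: str
    qtl_pos: float
    effects: EffectVector
    h2: float
    n_per_family: int
    name: str = "custom"

    def __post_init__(self):
        pos = self.marker_map.positions[self.qtl_chromosome]
        if not pos[0] <= self.qtl_pos <= pos[-1]:
            raise ValueError("QTL position must lie inside the mapped chromosome")
        if self.n_per_family < 1:
            raise ValueError("n_per_family must be >= 1")

    @classmethod
    def reference(cls, scenario: str = "I", n_per_family: int = 300,
                  h2: float = 0.1) -> "SimulationScenario":
        """The 200 cM / 10-marker study design with the QTL at 35 cM."""
        return cls(marker_map=default_map(), qtl_chromosome="1", qtl_pos=35.0,
                   effects=scenario_effects(scenario), h2=h2,
                   n_per_family=n_per_family, name=scenario)


@dataclass
class SimulatedCross:
    """A synthetic dataset plus the hidden truth used by oracle checks."""

    data: CrossDataset
    true_config: np.ndarray          # ordered configuration index 0..3 per individual
    maternal_gametes: np.ndarray     # (n, n_loci) 0/1 grandparental-line labels
    paternal_gametes: np.ndarray
    genetic_values: np.ndarray
    scenario: SimulationScenario


def _simulate_gametes(n: int, loci_pos: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample n gametes along ordered loci by per-interval crossover draws.

    Returns 0/1 grandparental-line labels; label 0 is the line carrying
    marker allele 1 and QTL allele A.
    """
    L = len(loci_pos)
    out = np.empty((n, L), dtype=np.int8)
    out[:, 0] = rng.integers(0, 2, size=n)
    r = haldane_r(np.diff(loci_pos))
    switches = rng.random((n, L - 1)) < r
    out[:, 1:] = switches
    return np.cumsum(out, axis=1, dtype=np.int64).astype(np.int8) % 2


def simulate_cross(scenario: SimulationScenario,
                   seed: int | np.random.Generator = 0) -> SimulatedCross:
    """Simulate the four reciprocal F2 families under the scenario.

    Each individual draws one maternal and one paternal F1 gamete over the
    QTL chromosome's loci (markers plus the hidden QTL); other chromosomes,
    if present in the map, segregate independently of the phenotype.
    The phenotype is the (mating type, configuration) genotypic value plus
    N(0, sigma2) residual noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = scenario.marker_map
    n = scenario.n_per_family
    N = 4 * n
    family = np.repeat(np.arange(4), n)

    means = effects_to_means(scenario.effects)
    sigma2 = residual_variance_for_heritability(scenario.effects, scenario.h2)

    geno_cols: dict[str, np.ndarray] = {}
    true_config = np.empty(N, dtype=np.int8)
    mat_store = pat_store = None

    for chrom in m.chromosomes:
        mpos = m.positions[chrom]
        mnames = m.names[chrom]
        if chrom == scenario.qtl_chromosome:
            # insert a QTL slot; a zero-length interval (QTL at a marker) is fine
            qtl_idx = int(np.searchsorted(mpos, scenario.qtl_pos))
            loci = np.insert(mpos, qtl_idx, scenario.qtl_pos)
        else:
            loci, qtl_idx = mpos, None
        mat = _simulate_gametes(N, loci, rng)
        pat = _simulate_gametes(N, loci, rng)
        marker_cols = [i for i in range(len(loci)) if i != qtl_idx]
        for name, col in zip(mnames, marker_cols):
            alleles = np.sort(np.stack([mat[:, col], pat[:, col]], axis=1), axis=1)
            geno_cols[name] = np.array(
                [f"{a + 1}{b + 1}" for a, b in alleles], dtype=object)
        if qtl_idx is not None:
            # line 0 carries QTL allele A; configuration index 2*m + p
            true_config[:] = 2 * mat[:, qtl_idx] + pat[:, qtl_idx]
            mat_store, pat_store = mat, pat

    g = means[family, true_config]
    y = g + rng.normal(0.0, np.sqrt(sigma2), size=N)

    data = CrossDataset(
        marker_map=m, family=family, phenotype=y,
        genotypes=pd.DataFrame(geno_cols, columns=list(m.marker_names)),
    )
    return SimulatedCross(data=data, true_config=true_config,
                          maternal_gametes=mat_store, paternal_gametes=pat_store,
                          genetic_values=g, scenario=scenario)


# ---------------------------------------------------------------------------
# Power / type-I-error study
# ---------------------------------------------------------------------------

@dataclass
class PowerStudyResult:
    """Rejection rates and (optionally) effect estimates across replicates."""

    scenario: str
    n_per_family: int
    h2: float
    reps: int
    alpha: float
    rejections: dict[int, int]            # test id -> count of rejections
    estimates: pd.DataFrame | None = None  # replicate x effect, full-model MLEs
    sigma2_estimates: np.ndarray | None = None

    @property
    def percent(self) -> dict[int, float]:
        return {t: 100.0 * c / self.reps for t, c in self.rejections.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"test": t, "rejections": c, "reps": self.reps,
                 "percent": 100.0 * c / self.reps}
                for t, c in sorted(self.rejections.items())]
        return pd.DataFrame(rows)


def fit_tests_at_position(data: CrossDataset, chromosome: str, pos_cm: float,
                          tests: Sequence[int] = (1, 2, 3, 4, 5, 6), *,
                          em_kwargs: dict | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[ModelFit, dict[int, TestResult]]:
    """Fit the full model once and each requested constrained model at a position.

    Returns the full fit and a dict of test id -> TestResult.
    """
    em_kwargs = dict(em_kwargs or {})
    if rng is not None:
        em_kwargs.setdefault("seed", rng)
    priors = data.priors_at(chromosome, pos_cm)
    full = em_fit(data, priors, (), **em_kwargs)
    results: dict[int, TestResult] = {}
    for t in tests:
        null = em_fit(data, priors, standard_test_constraints(t), **em_kwargs)
        results[t] = likelihood_ratio_test(null, full, name=f"Test {t}")
    return full, results


def run_power_study(scenario: str = "I", n_per_family: int = 300,
                    h2: float = 0.1, reps: int = 100, alpha: float = 0.05,
                    seed: int = 0, tests: Sequence[int] = (1, 2, 3, 4, 5, 6),
                    collect_estimates: bool = False,
                    em_kwargs: dict | None = None) -> PowerStudyResult:
    """Monte-Carlo power / type-I-error study at the true QTL position.

    Each replicate simulates the reference 200 cM cross, fits the full and
    the requested constrained models by EM at the true QTL position, and
    rejects a test when its chi-square p-value falls below ``alpha``.
    """
    if reps < 20:
        raise ValueError("reps must be >= 20 for a meaningful rate")
    base = SimulationScenario.reference(scenario, n_per_family, h2)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(reps)
    rejections = {t: 0 for t in tests}
    est_rows = []
    s2_rows = []
    from .design import EFFECT_NAMES
    for rep in range(reps):
        rng = np.random.default_rng(child_seeds[rep])
        sim = simulate_cross(base, rng)
        full, results = fit_tests_at_position(
            sim.data, base.qtl_chromosome, base.qtl_pos, tests,
            em_kwargs=em_kwargs, rng=rng)
        for t in tests:
            if results[t].pvalue < alpha:
                rejections[t] += 1
        if collect_estimates:
            est_rows.append(full.effects.to_dict())
            s2_rows.append(full.sigma2)
    estimates = pd.DataFrame(est_rows, columns=list(EFFECT_NAMES)) if collect_estimates else None
    return PowerStudyResult(
        scenario=scenario, n_per_family=n_per_family, h2=h2, reps=reps,
        alpha=alpha, rejections=rejections, estimates=estimates,
        sigma2_estimates=np.asarray(s2_rows) if collect_estimates else None)


def run_estimation_study(n_per_family: int = 500, h2: float = 0.4,
                         reps: int = 100, seed: int = 0,
                         em_kwargs: dict | None = None) -> pd.DataFrame:
    """Replicate full-model MLEs under the full-imprinting truth.

    Returns a DataFrame of per-replicate effect estimates whose column means
    and SDs reproduce the estimation table of the simulation study.
    """
    res = run_power_study("I", n_per_family, h2, reps=reps, seed=seed,
                          tests=(), collect_estimates=True, em_kwargs=em_kwargs)
    return res.estimates
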