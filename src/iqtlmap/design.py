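"""Reciprocal-F2 mating design and the 16-parameter genotypic-value decomposition.

A reciprocal F2 design starts from two inbred lines (alleles ``A`` and ``a``
at a putative imprinted QTL).  Reciprocal F1 crosses produce the two ordered
heterozygotes ``Aa`` (A maternal) and ``aA`` (A paternal), which in turn are
intercrossed in all four mother x father combinations ("mating types").
Within every mating type the F2 segregates the four ordered configurations
``AA, Aa, aA, aa`` (maternal allele written first), giving 16 genotypic-value
cells in total.

The 16 cell means are decomposed into 16 orthogonal genetic effects:

* ``mu`` -- overall mean of the 16 cells;
* ``i1m``, ``i1p`` -- imprinting expressed by the F1 mother / father
  (contrast between the two reciprocal F1 configurations in each parental
  role), and their interaction ``i1mp``;
* ``a``, ``d``, ``i2`` -- additive, dominance and imprinting effects
  expressed in the F2 generation;
* nine cross-generation interactions between the F1 imprinting terms and
  the F2 terms (``i1m_a`` ... ``i1mp_i2``).

The coding is +-1/0 and fully orthogonal, so the decomposition is its own
closed-form inverse and ``mu`` is always the unweighted mean of the cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

#: Ordered QTL configurations, maternal allele first.  Index k = 0..3.
CONFIGS: tuple[str, ...] = ("AA", "Aa", "aA", "aa")

#: Mating types as (mother F1 configuration, father F1 configuration).
#: Index t = 0..3.
MATING_TYPES: tuple[tuple[str, str], ...] = (
    ("Aa", "Aa"),
    ("Aa", "aA"),
    ("aA", "Aa"),
    ("aA", "aA"),
)

#: Effect names in design-matrix column order.
EFFECT_NAMES: tuple[str, ...] = (
    "mu",
    "i1m", "i1p", "i1mp",
    "a", "d", "i2",
    "i1m_a", "i1m_d", "i1m_i2",
    "i1p_a", "i1p_d", "i1p_i2",
    "i1mp_a", "i1mp_d", "i1mp_i2",
)

#: Names of the 15 non-mean effects.
NON_MEAN_EFFECTS: tuple[str, ...] = EFFECT_NAMES[1:]

# F2 configuration scores: additive, dominance (homozygotes scored -1 so the
# column stays orthogonal to the mean), and parent-of-origin contrast.
_Z_A = {"AA": 1.0, "Aa": 0.0, "aA": 0.0, "aa": -1.0}
_Z_D = {"AA": -1.0, "Aa": 1.0, "aA": 1.0, "aa": -1.0}
_Z_I = {"AA": 0.0, "Aa": 1.0, "aA": -1.0, "aa": 0.0}


@dataclass(frozen=True)
class EffectVector:
    """The 16 genetic-effect parameters, in phenotype units."""

    mu: float = 0.0
    i1m: float = 0.0
    i1p: float = 0.0
    i1mp: float = 0.0
    a: float = 0.0
    d: float = 0.0
    i2: float = 0.0
    i1m_a: float = 0.0
    i1m_d: float = 0.0
    i1m_i2: float = 0.0
    i1p_a: float = 0.0
    i1p_d: float = 0.0
    i1p_i2: float = 0.0
    i1mp_a: float = 0.0
    i1mp_d: float = 0.0
    i1mp_i2: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EFFECT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "EffectVector":
        vals = np.asarray(list(arr), dtype=float)
        if vals.shape != (16,):
            raise ValueError(f"expected 16 effects, got shape {vals.shape}")
        return cls(**dict(zip(EFFECT_NAMES, vals)))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "EffectVector":
        unknown = set(d) - set(EFFECT_NAMES)
        if unknown:
            raise ValueError(f"unknown effect names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in EFFECT_NAMES}

    def __len__(self) -> int:
        return 16


def build_design_matrix() -> np.ndarray:
    """Return the 16x16 design matrix mapping effects to genotypic values.

    Rows are indexed (t, k) mating-type-major; columns follow
    :data:`EFFECT_NAMES`.  Row entries are
    ``[1, x_m, x_p, x_m*x_p, z_a, z_d, z_i, x_m*z, x_p*z, x_m*x_p*z]``
    with ``x_m = +1`` when the mother is ``Aa`` (else -1), ``x_p`` likewise
    for the father, and z-scores from the F2 configuration.  All columns are
    pairwise orthogonal and non-mean columns sum to zero.
    """
    rows = []
    for mother, father in MATING_TYPES:
        xm = 1.0 if mother == "Aa" else -1.0
        xp = 1.0 if father == "Aa" else -1.0
        for cfg in CONFIGS:
            za, zd, zi = _Z_A[cfg], _Z_D[cfg], _Z_I[cfg]
            rows.append([
                1.0, xm, xp, xm * xp,
                za, zd, zi,
                xm * za, xm * zd, xm * zi,
                xp * za, xp * zd, xp * zi,
                xm * xp * za, xm * xp * zd, xm * xp * zi,
            ])
    return np.array(rows, dtype=float)


# Cached matrix and per-column squared norms (the design is fixed).
DESIGN_MATRIX: np.ndarray = build_design_matrix()
_COL_SQNORM: np.ndarray = (DESIGN_MATRIX ** 2).sum(axis=0)


def effects_to_means(effects: EffectVector) -> np.ndarray:
    """Genotypic values as a 4x4 array, rows = mating types, cols = configs."""
    beta = effects.to_array()
    if not np.all(np.isfinite(beta)):
        raise ValueError("effects must be finite")
    return (DESIGN_MATRIX @ beta).reshape(4, 4)


def means_to_effects(means: np.ndarray) -> EffectVector:
    """Exact inverse of :func:`effects_to_means`.

    With the orthogonal coding each effect is the normalised projection
    ``(column . mean-vector) / ||column||^2``.
    """
    m = np.asarray(means, dtype=float).reshape(16)
    if not np.all(np.isfinite(m)):
        raise ValueError("means must be finite")
    beta = (DESIGN_MATRIX.T @ m) / _COL_SQNORM
    return EffectVector.from_array(beta)


def genetic_variance(effects: EffectVector) -> float:
    """Variance of the 16 genotypic values, each cell weighted 1/16.

    Mendelian segregation makes the four configurations equally likely within
    a family; with equally sized families every cell carries weight 1/16 and,
    by orthogonality, the variance is the sum of ``beta_j^2 * mean(c_j^2)``
    over the non-mean columns.
    """
    mu_cells = effects_to_means(effects).ravel()
    return float(np.mean((mu_cells - mu_cells.mean()) ** 2))


def mating_type_index(mother: str, father: str) -> int:
    """0-based index of the mating type (mother configuration listed first)."""
    try:
        return MATING_TYPES.index((mother, father))
    except ValueError:
        raise ValueError(f"unknown mating type {mother}x{father}") from None


def config_index(config: str) -> int:
    """0-based index of an ordered configuration (maternal allele first)."""
    try:
        return CONFIGS.index(config)
    except ValueError:
        raise ValueError(f"unknown configuration {config!r}") from None
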