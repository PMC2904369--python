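"""Map-distance arithmetic and conditional QTL-configuration probabilities.

Interval mapping places a putative QTL between two flanking markers and
infers the (unobserved) ordered QTL configuration of each F2 individual from
its unordered marker genotypes.  Every F1 parent here is a complete
heterozygote with known linkage phase ``1-A-1 / 2-a-2`` inherited intact
from the inbred grandparents, so three-locus gamete probabilities follow
directly from the two recombination fractions flanking the QTL, and the
configuration posterior is obtained by enumerating ordered
(maternal gamete, paternal gamete) pairs consistent with the observed
genotypes.  Haldane's no-interference map function is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .design import CONFIGS

MISSING = "NA"
VALID_GENOTYPES = ("11", "12", "22")


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a distance in cM (Haldane, no interference)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0)) if d.ndim else float(
        0.5 * (1.0 - np.exp(-2.0 * float(d) / 100.0))
    )


def haldane_d(r: float) -> float:
    """Inverse Haldane map: cM distance for a recombination fraction."""
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


def kosambi_r(d_cm: float) -> float:
    """Kosambi map function (optional alternative allowing interference)."""
    d = float(d_cm)
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * np.tanh(2.0 * d / 100.0)


def kosambi_d(r: float) -> float:
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


MAP_FUNCTIONS = {"haldane": (haldane_r, haldane_d), "kosambi": (kosambi_r, kosambi_d)}


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker positions per chromosome.

    Positions are cM offsets; within a chromosome they must be strictly
    increasing.  ``chromosomes`` preserves input order.
    """

    chromosomes: tuple[str, ...]
    names: dict[str, tuple[str, ...]]       # chromosome -> marker names
    positions: dict[str, np.ndarray]        # chromosome -> cM positions

    def __post_init__(self):
        seen: set[str] = set()
        for chrom in self.chromosomes:
            nm, pos = self.names[chrom], self.positions[chrom]
            if len(nm) != len(pos):
                raise ValueError(f"chromosome {chrom}: names/positions length mismatch")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {chrom}: positions must be strictly increasing")
            dup = seen.intersection(nm)
            if dup or len(set(nm)) != len(nm):
                raise ValueError(f"duplicate marker names: {sorted(dup) or 'within chromosome'}")
            seen.update(nm)

    @classmethod
    def from_table(cls, names: Sequence[str], chroms: Sequence[str],
                   positions: Sequence[float]) -> "MarkerMap":
        order: list[str] = []
        by_chrom_names: dict[str, list[str]] = {}
        by_chrom_pos: dict[str, list[float]] = {}
        for n, c, p in zip(names, chroms, positions):
            c = str(c)
            if c not in by_chrom_names:
                order.append(c)
                by_chrom_names[c] = []
                by_chrom_pos[c] = []
            by_chrom_names[c].append(str(n))
            by_chrom_pos[c].append(float(p))
        return cls(
            chromosomes=tuple(order),
            names={c: tuple(v) for c, v in by_chrom_names.items()},
            positions={c: np.asarray(v, dtype=float) for c, v in by_chrom_pos.items()},
        )

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(n for c in self.chromosomes for n in self.names[c])

    def n_markers(self) -> int:
        return sum(len(self.names[c]) for c in self.chromosomes)

    def interval_at(self, chromosome: str, pos_cm: float) -> "IntervalPosition":
        """Flanking-marker interval containing ``pos_cm`` on a chromosome."""
        if chromosome not in self.positions:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        pos = self.positions[chromosome]
        if not pos[0] <= pos_cm <= pos[-1]:
            raise ValueError(
                f"position {pos_cm} cM outside map range "
                f"[{pos[0]}, {pos[-1]}] on chromosome {chromosome}")
        # right-closed search; a position at a marker belongs to the interval
        # whose left edge it is, except at the chromosome end
        i = int(np.searchsorted(pos, pos_cm, side="right")) - 1
        i = min(i, len(pos) - 2)
        return IntervalPosition(
            chromosome=chromosome,
            left_marker=self.names[chromosome][i],
            right_marker=self.names[chromosome][i + 1],
            left_pos=float(pos[i]),
            right_pos=float(pos[i + 1]),
            qtl_pos=float(pos_cm),
        )


@dataclass(frozen=True)
class IntervalPosition:
    """A putative QTL position between two flanking markers."""

    chromosome: str
    left_marker: str
    right_marker: str
    left_pos: float
    right_pos: float
    qtl_pos: float

    def __post_init__(self):
        if not self.left_pos <= self.qtl_pos <= self.right_pos:
            raise ValueError("QTL position outside the marker interval")

    @property
    def r1(self) -> float:
        """Recombination fraction left marker <-> QTL."""
        return haldane_r(self.qtl_pos - self.left_pos)

    @property
    def r2(self) -> float:
        """Recombination fraction QTL <-> right marker."""
        return haldane_r(self.right_pos - self.qtl_pos)

    @property
    def r(self) -> float:
        """Marker <-> marker recombination fraction (no interference)."""
        r1, r2 = self.r1, self.r2
        return r1 + r2 - 2.0 * r1 * r2


# ---------------------------------------------------------------------------
# Gamete and configuration probabilities
# ---------------------------------------------------------------------------

def gamete_distribution(r1: float, r2: float) -> np.ndarray:
    """Three-locus gamete probabilities for a phase-known F1 parent.

    Returns an array ``P[l, q, m]`` over left-marker allele ``l`` (0 for
    allele 1, 1 for allele 2), QTL allele ``q`` (0 for A, 1 for a) and
    right-marker allele ``m``.  The parent carries the intact grandparental
    haplotypes ``1-A-1`` and ``2-a-2``, so the table is identical for all
    four F1 parents regardless of their ordered configuration.
    """
    if not (0.0 <= r1 <= 0.5 and 0.0 <= r2 <= 0.5):
        raise ValueError("recombination fractions must lie in [0, 0.5]")
    P = np.empty((2, 2, 2), dtype=float)
    P[0, 0, 0] = P[1, 1, 1] = (1 - r1) * (1 - r2) / 2.0   # parental
    P[0, 0, 1] = P[1, 1, 0] = (1 - r1) * r2 / 2.0         # recombination right
    P[0, 1, 1] = P[1, 0, 0] = r1 * (1 - r2) / 2.0         # recombination left
    P[0, 1, 0] = P[1, 0, 1] = r1 * r2 / 2.0               # double recombinant
    return P


def _genotype_allele_counts(genotype: str) -> tuple[int, int] | None:
    """Unordered genotype -> sorted allele pair (0-based), or None if missing."""
    if genotype is None or genotype == MISSING:
        return None
    if genotype not in VALID_GENOTYPES:
        raise ValueError(f"invalid marker genotype {genotype!r}")
    return (int(genotype[0]) - 1, int(genotype[1]) - 1)


def configuration_priors(left: str, right: str, r1: float, r2: float) -> np.ndarray:
    """Posterior over the four ordered QTL configurations given flanking markers.

    Enumerates all ordered (maternal gamete, paternal gamete) haplotype
    pairs whose marker alleles are consistent with the unordered genotypes
    (a missing flank matches every allele), weights each pair by the product
    of independent maternal and paternal gamete probabilities and sums
    weights by the ordered configuration (maternal QTL allele first).
    Returns probabilities in :data:`iqtlmap.design.CONFIGS` order.
    """
    gl = _genotype_allele_counts(left)
    gr = _genotype_allele_counts(right)
    P = gamete_distribution(r1, r2)
    out = np.zeros(4, dtype=float)
    for lm, qm, rm in product((0, 1), repeat=3):
        pm = P[lm, qm, rm]
        if pm == 0.0:
            continue
        for lp, qp, rp in product((0, 1), repeat=3):
            pp = P[lp, qp, rp]
            if pp == 0.0:
                continue
            if gl is not None and tuple(sorted((lm, lp))) != gl:
                continue
            if gr is not None and tuple(sorted((rm, rp))) != gr:
                continue
            out[2 * qm + qp] += pm * pp
    total = out.sum()
    if total == 0.0:
        # impossible genotype class at these recombination fractions
        return np.full(4, 0.25)
    return out / total


def configuration_prior_table(r1: float, r2: float) -> dict[tuple[str, str], np.ndarray]:
    """Priors for every (left, right) unordered-genotype class, incl. missing."""
    classes = VALID_GENOTYPES + (MISSING,)
    return {
        (gl, gr): configuration_priors(gl, gr, r1, r2)
        for gl in classes for gr in classes
    }


def configuration_priors_batch(left: np.ndarray, right: np.ndarray,
                               r1: float, r2: float) -> np.ndarray:
    """Vectorised priors for arrays of genotype strings; returns (n, 4)."""
    table = configuration_prior_table(r1, r2)
    left = np.asarray(left, dtype=object)
    right = np.asarray(right, dtype=object)
    out = np.empty((len(left), 4), dtype=float)
    for gl in VALID_GENOTYPES + (MISSING,):
        for gr in VALID_GENOTYPES + (MISSING,):
            mask = (left == gl) & (right == gr)
            if mask.any():
                out[mask] = table[(gl, gr)]
    return out
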