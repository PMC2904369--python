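"""Genome scanning, permutation thresholds, peak calling and imprinting tests.

The existence of a QTL is tested at a grid of positions along every mapped
chromosome by the likelihood ratio of the full 16-parameter model against
the single-normal null (all 16 cell means equal).  Genome-wide significance
is calibrated by permutation: phenotypes are shuffled, the genome rescanned,
and the (1 - alpha) quantile of the maximum LR taken as threshold.  At
called peaks, the six-level hierarchy of imprinting tests dissects how the
parent-of-origin effect is expressed and transmitted across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import EffectVector
from .emfit import (EXISTENCE_CONSTRAINTS, CrossDataset, ModelFit, TestResult,
                    em_fit, likelihood_ratio_test, standard_test_constraints)


@dataclass
class ScanResult:
    """Existence-LR profile over the scan grid."""

    profile: pd.DataFrame          # columns: chromosome, pos_cM, LR
    fits: list[ModelFit]
    null_loglik: float
    step: float

    def max_lr(self) -> float:
        return float(self.profile["LR"].max())


@dataclass
class PeakCall:
    """A significant QTL peak with its imprinting-test dissection."""

    chromosome: str
    pos_cm: float
    left_marker: str
    right_marker: str
    lr: float
    effects: EffectVector | None = None
    sigma2: float | None = None
    tests: dict[str, TestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "pos_cM": self.pos_cm,
            "left_marker": self.left_marker,
            "right_marker": self.right_marker,
            "LR": self.lr,
            "effects": self.effects.to_dict() if self.effects else None,
            "sigma2": self.sigma2,
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
        }


def scan_grid(marker_map, step: float) -> list[tuple[str, float]]:
    """Scan positions: every marker plus every ``step`` cM within intervals."""
    if step <= 0:
        raise ValueError("step must be positive")
    grid: list[tuple[str, float]] = []
    for chrom in marker_map.chromosomes:
        pos = marker_map.positions[chrom]
        pts = [float(pos[0])]
        for left, right in zip(pos[:-1], pos[1:]):
            p = left + step
            while p < right - 1e-9:
                pts.append(float(p))
                p += step
            pts.append(float(right))
        grid.extend((chrom, p) for p in pts)
    return grid


def _existence_null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the single-normal fit (all 16 means equal), MLE sigma2."""
    n = len(y)
    s2 = max(float(np.var(y)), 1e-12)
    return float(-0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0))


def scan_genome(data: CrossDataset, step: float = 2.0, *,
                em_kwargs: dict | None = None,
                keep_fits: bool = False) -> ScanResult:
    """Existence-LR profile across the genome at ``step`` cM resolution.

    At each grid position the full mixture model is fitted by EM and
    compared with the position-independent single-normal null,
    LR = 2(logL_full - logL_null).
    """
    em_kwargs = dict(em_kwargs or {})
    null_ll = _existence_null_loglik(data.phenotype)
    rows = []
    fits: list[ModelFit] = []
    for chrom, pos in scan_grid(data.marker_map, step):
        priors = data.priors_at(chrom, pos)
        fit = em_fit(data, priors, (), **em_kwargs)
        lr = max(0.0, 2.0 * (fit.loglik - null_ll))
        rows.append({"chromosome": chrom, "pos_cM": pos, "LR": lr})
        if keep_fits:
            fits.append(fit)
    profile = pd.DataFrame(rows)
    return ScanResult(profile=profile, fits=fits, null_loglik=null_ll, step=step)


def permutation_threshold(data: CrossDataset, step: float = 2.0,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, within_family: bool = False,
                          em_kwargs: dict | None = None) -> float:
    """Genome-wide LR threshold from phenotype permutations.

    Phenotypes are shuffled jointly across all individuals by default,
    matching the existence null under which all 16 cell means (including
    between-family differences) are equal; ``within_family=True`` instead
    permutes within each family, preserving family means.  The threshold is
    the empirical (1 - alpha) quantile of the per-permutation maximum LR.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    y = data.phenotype
    for b in range(n_perm):
        if within_family:
            perm = np.empty_like(y)
            for t in range(4):
                idx = np.flatnonzero(data.family == t)
                perm[idx] = y[rng.permutation(idx)]
        else:
            perm = y[rng.permutation(len(y))]
        shuffled = CrossDataset(
            marker_map=data.marker_map, family=data.family,
            phenotype=perm, genotypes=data.genotypes)
        maxima[b] = scan_genome(shuffled, step, em_kwargs=em_kwargs).max_lr()
    return float(np.quantile(maxima, 1.0 - alpha))


def call_peaks(scan: ScanResult, threshold: float,
               min_separation: float = 30.0,
               marker_map=None) -> list[PeakCall]:
    """Local maxima of the LR profile above the genome-wide threshold.

    Two maxima on the same chromosome are distinct peaks only if they are
    at least ``min_separation`` cM apart AND the profile drops below the
    threshold between them; otherwise the higher (leftmost on ties) wins.
    """
    peaks: list[PeakCall] = []
    for chrom, sub in scan.profile.groupby("chromosome", sort=False):
        sub = sub.sort_values("pos_cM").reset_index(drop=True)
        above = sub["LR"].to_numpy() >= threshold
        if not above.any():
            continue
        # contiguous above-threshold runs -> one candidate peak each
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        candidates = []
        for start, stop in zip(edges[::2], edges[1::2]):
            chunk = sub.iloc[start:stop]
            i = int(chunk["LR"].to_numpy().argmax())   # argmax -> leftmost tie
            candidates.append((float(chunk["pos_cM"].iloc[i]),
                               float(chunk["LR"].iloc[i])))
        # merge runs closer than min_separation, keeping the higher LR
        merged: list[tuple[float, float]] = []
        for pos, lr in candidates:
            if merged and pos - merged[-1][0] < min_separation:
                if lr > merged[-1][1]:
                    merged[-1] = (pos, lr)
            else:
                merged.append((pos, lr))
        for pos, lr in merged:
            left = right = ""
            mm = marker_map
            if mm is not None:
                iv = mm.interval_at(chrom, pos)
                left, right = iv.left_marker, iv.right_marker
            peaks.append(PeakCall(chromosome=chrom, pos_cm=pos,
                                  left_marker=left, right_marker=right, lr=lr))
    return peaks


def imprinting_test_suite(data: CrossDataset, chromosome: str, pos_cm: float, *,
                          include_single_effects: bool = True,
                          em_kwargs: dict | None = None,
                          ) -> tuple[ModelFit, dict[str, TestResult]]:
    """Full six-level imprinting dissection at one position.

    Fits the full model once and reuses it against each constrained null:
    Tests 1-6 of the hierarchy and, optionally, every single non-mean effect.
    """
    em_kwargs = dict(em_kwargs or {})
    priors = data.priors_at(chromosome, pos_cm)
    full = em_fit(data, priors, (), **em_kwargs)
    results: dict[str, TestResult] = {}
    for t in (1, 2, 3, 4, 5, 6):
        null = em_fit(data, priors, standard_test_constraints(t), **em_kwargs)
        results[f"test{t}"] = likelihood_ratio_test(null, full, name=f"Test {t}")
    if include_single_effects:
        from .design import NON_MEAN_EFFECTS
        for name in NON_MEAN_EFFECTS:
            null = em_fit(data, priors, frozenset({name}), **em_kwargs)
            results[name] = likelihood_ratio_test(null, full, name=name)
    return full, results


def scan_and_call(data: CrossDataset, step: float = 2.0, n_perm: int = 1000,
                  alpha: float = 0.05, seed: int = 0,
                  min_separation: float = 30.0,
                  within_family: bool = False,
                  em_kwargs: dict | None = None,
                  ) -> tuple[ScanResult, float, list[PeakCall]]:
    """Scan, derive the permutation threshold, call peaks and test each peak."""
    scan = scan_genome(data, step, em_kwargs=em_kwargs)
    thr = permutation_threshold(data, step, n_perm, alpha, seed,
                                within_family=within_family, em_kwargs=em_kwargs)
    peaks = call_peaks(scan, thr, min_separation, marker_map=data.marker_map)
    for pk in peaks:
        full, tests = imprinting_test_suite(
            data, pk.chromosome, pk.pos_cm,
            include_single_effects=False, em_kwargs=em_kwargs)
        pk.effects = full.effects
        pk.sigma2 = full.sigma2
        pk.tests = tests
    return scan, thr, peaks
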