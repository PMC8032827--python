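"""Enrichment of protein clusters at annotated feature classes.

Fold increase is the observed base overlap between a cluster set and a
feature class divided by the overlap expected under random placement.
Two expectation modes are provided and labeled, because "expected for
random binding" admits both readings:

* ``analytic`` — the independence expectation ``|A| * |F| / G``;
* ``montecarlo`` — the mean overlap over random re-placements of the
  cluster set (:func:`npstools.coloc.monte_carlo_pvalue`), which also yields
  an empirical p-value.

A discrete feature is "bound" when a cluster overlaps it by at least
``min_overlap_bp`` (default 1 bp — the weakest defensible criterion, and a
surfaced parameter). Co-occupancy tables tabulate, per feature, which
proteins bind it, and report counts and percentages for every protein
combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coloc import fisher_colocalization_test, monte_carlo_pvalue, overlap_bases
from .genome import ClusterSet, FeatureSet, ValidationError

__all__ = ["FoldResult", "CooccupancyMatrix", "fold_increase", "bound_features", "cooccupancy"]


@dataclass(frozen=True)
class FoldResult:
    protein: str
    feature_class: str
    observed_overlap_bp: int
    expected_overlap_bp: float
    expectation_mode: str  # "analytic" | "montecarlo"
    fold: float
    fisher_p: float
    empirical_p: float | None = None
    n_iterations: int | None = None
    seed: int | None = None


def _flanked(features: FeatureSet, flank_bp: int) -> FeatureSet:
    if flank_bp == 0:
        return features
    from .genome import GenomicInterval

    out = []
    for fid, iv in features.features:
        start = max(0, iv.start - flank_bp)
        end = min(features.genome.length(iv.chrom), iv.end + flank_bp)
        out.append((fid, GenomicInterval(iv.chrom, start, end, iv.name)))
    return FeatureSet(features.class_label, features.genome, tuple(out))


def fold_increase(
    a: ClusterSet,
    features: FeatureSet,
    *,
    mode: str = "analytic",
    n_iterations: int = 1000,
    seed: int = 0,
    flank_bp: int = 0,
) -> FoldResult:
    """Fold increase of a protein's clusters at a feature class vs random binding.

    Computed on bases: observed is ``overlap_bases(A, footprint(F))``; the
    expectation depends on ``mode``. Fisher's one-tailed exact p accompanies
    the fold; ``montecarlo`` mode adds the empirical p.
    """
    if a.total_bases == 0 or len(features) == 0:
        raise ValidationError("undefined fold: empty cluster set or feature set")
    if mode not in ("analytic", "montecarlo"):
        raise ValueError("mode must be 'analytic' or 'montecarlo'")
    f_set = _flanked(features, flank_bp).as_cluster_set()
    observed = overlap_bases(a, f_set)
    fisher_p = fisher_colocalization_test(a, f_set)
    g = a.genome.total_length
    if mode == "analytic":
        expected = a.total_bases * f_set.total_bases / g
        return FoldResult(
            protein=a.protein,
            feature_class=features.class_label,
            observed_overlap_bp=observed,
            expected_overlap_bp=expected,
            expectation_mode=mode,
            fold=observed / expected,
            fisher_p=fisher_p,
        )
    null, emp_p = monte_carlo_pvalue(
        a, f_set, n_iterations=n_iterations, seed=seed, randomize="a"
    )
    expected = null.mean
    fold = observed / expected if expected > 0 else float("nan")
    return FoldResult(
        protein=a.protein,
        feature_class=features.class_label,
        observed_overlap_bp=observed,
        expected_overlap_bp=expected,
        expectation_mode=mode,
        fold=fold,
        fisher_p=fisher_p,
        empirical_p=emp_p,
        n_iterations=n_iterations,
        seed=int(seed),
    )


def bound_features(
    a: ClusterSet, features: FeatureSet, *, min_overlap_bp: int = 1
) -> tuple[list[str], int]:
    """Which discrete features the cluster set binds.

    A feature is bound iff its interval overlaps the cluster footprint by at
    least ``min_overlap_bp``. Returns (sorted ids, count).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    bound: list[str] = []
    for fid, iv in features.features:
        s, e = a.arrays(iv.chrom)
        if len(s) == 0:
            continue
        ov = np.minimum(e, iv.end) - np.maximum(s, iv.start)
        if int(np.clip(ov, 0, None).sum()) >= min_overlap_bp:
            bound.append(fid)
    return sorted(bound), len(bound)


@dataclass(frozen=True)
class CooccupancyMatrix:
    """Per-feature binding matrix plus per-combination tallies.

    ``matrix`` is a boolean DataFrame (feature ids x protein labels);
    ``combination_counts`` maps each protein combination — a tuple of bound
    proteins in column order, ``()`` for "none" — to the number of features
    with exactly that pattern. Percentages are raw reals over the feature
    count; display rounding is the caller's concern.
    """

    feature_class: str
    matrix: pd.DataFrame
    combination_counts: dict[tuple[str, ...], int]
    combination_percent: dict[tuple[str, ...], float]

    @property
    def n_features(self) -> int:
        return len(self.matrix)

    def bound_count(self, proteins: tuple[str, ...] | list[str]) -> int:
        """Features bound by *all* listed proteins (other proteins free)."""
        sub = self.matrix[list(proteins)]
        return int(sub.all(axis=1).sum())

    def bound_percent(self, proteins: tuple[str, ...] | list[str]) -> float:
        return 100.0 * self.bound_count(proteins) / self.n_features


def cooccupancy(
    sets: Mapping[str, ClusterSet], features: FeatureSet, *, min_overlap_bp: int = 1
) -> CooccupancyMatrix:
    """Multi-protein co-occupancy of a feature class.

    Builds the boolean bound matrix from :func:`bound_features` per protein
    and tallies every exact protein combination; combination counts sum to
    the number of features and percentages to 100.
    """
    if len(sets) < 1 or len(features) < 1:
        raise ValidationError("need at least one protein and one feature")
    labels = list(sets)
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate protein labels")
    cols = {}
    for label, cs in sets.items():
        ids, _ = bound_features(cs, features, min_overlap_bp=min_overlap_bp)
        bound_set = set(ids)
        cols[label] = [fid in bound_set for fid in features.ids]
    matrix = pd.DataFrame(cols, index=list(features.ids))
    counts: dict[tuple[str, ...], int] = {}
    for _, row in matrix.iterrows():
        combo = tuple(l for l in labels if row[l])
        counts[combo] = counts.get(combo, 0) + 1
    n = len(features)
    percent = {k: 100.0 * v / n for k, v in counts.items()}
    return CooccupancyMatrix(
        feature_class=features.class_label,
        matrix=matrix,
        combination_counts=counts,
        combination_percent=percent,
    )
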