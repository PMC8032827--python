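"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate a budding-yeast-scale dataset: a 16-chromosome,
~12 Mb genome carrying 71 replication-termination regions (TERs), one
~120 bp centromere per chromosome and 275 tRNA genes, plus protein cluster
sets with a controllable degree of co-localization with those features and
with each other.

Co-localization is induced by *anchoring*: a fraction ``f`` of clusters are
centered on feature midpoints (or on a partner protein's cluster midpoints)
with Gaussian positional jitter; the remaining ``1 - f`` are placed
uniformly. ``f = 0`` is the null of independent placement; ``f = 1`` with
zero jitter and clusters at least as long as their anchors binds every
anchor. This one interpretable knob creates exactly the base-overlap signal
the co-localization score measures.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ClusterSet, FeatureSet, GenomeDef, GenomicInterval, ValidationError
from .jm import JMRecord

__all__ = [
    "YEAST_CHROM_LENGTHS",
    "FeatureClassSpec",
    "DEFAULT_FEATURE_SPECS",
    "make_genome",
    "place_features",
    "make_cluster_set",
    "make_jm_records",
    "make_qpcr_table",
]

#: Chromosome lengths (bp) of the S. cerevisiae reference assembly
#: (sacCer3), totalling ~12.07 Mb over 16 chromosomes.
YEAST_CHROM_LENGTHS: tuple[tuple[str, int], ...] = (
    ("chrI", 230218), ("chrII", 813184), ("chrIII", 316620), ("chrIV", 1531933),
    ("chrV", 576874), ("chrVI", 270161), ("chrVII", 1090940), ("chrVIII", 562643),
    ("chrIX", 439888), ("chrX", 745751), ("chrXI", 666816), ("chrXII", 1078177),
    ("chrXIII", 924431), ("chrXIV", 784333), ("chrXV", 1091291), ("chrXVI", 948066),
)


def make_genome(
    *,
    chrom_lengths: tuple[tuple[str, int], ...] | None = None,
    n_chromosomes: int | None = None,
    total_length: int | None = None,
    randomize_lengths: bool = False,
    seed: int = 0,
) -> GenomeDef:
    """A synthetic genome; defaults to the 16 yeast chromosome lengths.

    ``n_chromosomes``/``total_length`` build an equal-split genome instead;
    ``randomize_lengths`` draws chromosome lengths from a Dirichlet split of
    the total (deterministic given ``seed``).
    """
    if chrom_lengths is not None:
        return GenomeDef(tuple(chrom_lengths))
    if n_chromosomes is None:
        n_chromosomes = 16
    if n_chromosomes < 1:
        raise ValidationError("need at least one chromosome")
    if total_length is None:
        total_length = sum(l for _, l in YEAST_CHROM_LENGTHS[:n_chromosomes])
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if randomize_lengths:
        rng = np.random.default_rng(seed)
        weights = rng.dirichlet(np.full(n_chromosomes, 5.0))
        lengths = np.maximum(1, np.round(weights * total_length).astype(np.int64))
    else:
        base = total_length // n_chromosomes
        lengths = np.full(n_chromosomes, base, dtype=np.int64)
        lengths[-1] += total_length - base * n_chromosomes
    return GenomeDef(tuple(zip(names, (int(x) for x in lengths))))


@dataclass(frozen=True)
class FeatureClassSpec:
    """How many elements of one annotation class to place, and how long."""

    class_label: str
    count: int
    min_len: int
    max_len: int
    one_per_chromosome: bool = False


#: Yeast-scale defaults: 71 TERs of ~5 kb, one ~120 bp CEN per chromosome,
#: 275 tRNA genes of 70-100 bp.
DEFAULT_FEATURE_SPECS: tuple[FeatureClassSpec, ...] = (
    FeatureClassSpec("TER", 71, 4000, 6000),
    FeatureClassSpec("CEN", 16, 110, 130, one_per_chromosome=True),
    FeatureClassSpec("tRNA", 275, 70, 100),
)


def place_features(
    genome: GenomeDef,
    specs: tuple[FeatureClassSpec, ...] = DEFAULT_FEATURE_SPECS,
    *,
    seed: int = 0,
    max_tries: int = 1000,
) -> dict[str, FeatureSet]:
    """Place non-overlapping features of each class on the genome.

    Features never overlap, within or across classes. Classes flagged
    ``one_per_chromosome`` (centromeres) get exactly one element per
    chromosome and require ``count == n_chromosomes``.
    """
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    chrom_lens = np.array([genome.length(c) for c in genome.names], dtype=np.float64)
    weights = chrom_lens / chrom_lens.sum()
    out: dict[str, FeatureSet] = {}

    def _try_place(chrom: str, length: int) -> tuple[int, int] | None:
        chrom_len = genome.length(chrom)
        if chrom_len < length:
            return None
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        for s, e in occupied[chrom]:
            if start < e and s < end:
                return None
        return start, end

    for spec in specs:
        if spec.one_per_chromosome and spec.count != len(genome.names):
            raise ValidationError(
                f"{spec.class_label}: one_per_chromosome requires count == "
                f"number of chromosomes ({len(genome.names)})"
            )
        feats: list[tuple[str, GenomicInterval]] = []
        width = len(str(spec.count))
        for idx in range(spec.count):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            placed = None
            for _ in range(max_tries):
                if spec.one_per_chromosome:
                    chrom = genome.names[idx]
                else:
                    chrom = genome.names[int(rng.choice(len(genome.names), p=weights))]
                placed = _try_place(chrom, length)
                if placed is not None:
                    break
            if placed is None:
                raise ValidationError(
                    f"could not place {spec.class_label} feature after {max_tries} tries "
                    "(feature density infeasible)"
                )
            start, end = placed
            occupied[chrom].append((start, end))
            fid = f"{spec.class_label}{idx + 1:0{width}d}"
            feats.append((fid, GenomicInterval(chrom, start, end, name=fid)))
        out[spec.class_label] = FeatureSet(spec.class_label, genome, tuple(feats))
    return out


def _anchor_midpoints(anchors: FeatureSet | ClusterSet) -> list[tuple[str, int]]:
    if isinstance(anchors, FeatureSet):
        return [(iv.chrom, (iv.start + iv.end) // 2) for _, iv in anchors.features]
    return [(iv.chrom, (iv.start + iv.end) // 2) for iv in anchors.intervals()]


def make_cluster_set(
    genome: GenomeDef,
    *,
    protein: str = "protein",
    n_clusters: int = 300,
    length_median: float = 1000.0,
    length_sigma: float = 0.5,
    min_length: int = 50,
    anchors: FeatureSet | ClusterSet | None = None,
    anchor_fraction: float = 0.0,
    jitter_sd: float = 200.0,
    seed: int = 0,
) -> ClusterSet:
    """A synthetic protein cluster set with controllable co-localization.

    Cluster lengths are log-normal (``length_median``, ``length_sigma`` on
    the log scale) — a heavy-tailed distribution typical of enrichment-domain
    widths. A fraction ``anchor_fraction`` of clusters is centered on the
    midpoints of ``anchors`` (features or a partner protein's clusters) plus
    Gaussian jitter of sd ``jitter_sd`` bp; the rest are placed uniformly,
    chromosomes weighted by length. Clusters are clipped to chromosome
    bounds and merged on construction.
    """
    if not 0 <= anchor_fraction <= 1:
        raise ValidationError("anchor_fraction must be in [0, 1]")
    if anchor_fraction > 0 and anchors is None:
        raise ValidationError("anchor_fraction > 0 requires anchors")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        min_length,
        np.round(rng.lognormal(np.log(length_median), length_sigma, n_clusters)).astype(np.int64),
    )
    n_anchored = int(round(anchor_fraction * n_clusters))
    mids = _anchor_midpoints(anchors) if anchors is not None else []
    chrom_lens = np.array([genome.length(c) for c in genome.names], dtype=np.float64)
    weights = chrom_lens / chrom_lens.sum()

    intervals: list[GenomicInterval] = []
    for i, length in enumerate(lengths):
        length = int(length)
        if i < n_anchored:
            chrom, mid = mids[int(rng.integers(0, len(mids)))]
            center = mid + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
            chrom_len = genome.length(chrom)
            length = min(length, chrom_len)
            start = int(round(center - length / 2))
            start = max(0, min(start, chrom_len - length))
        else:
            chrom = genome.names[int(rng.choice(len(genome.names), p=weights))]
            chrom_len = genome.length(chrom)
            length = min(length, chrom_len)
            start = int(rng.integers(0, chrom_len - length + 1))
        intervals.append(GenomicInterval(chrom, start, start + length))
    return ClusterSet.from_intervals(protein, intervals, genome)


# --- EM joint-molecule generator -------------------------------------------

_JM_DEFAULT_COUNTS: dict[str, int] = {
    "fork": 25, "bubble": 25, "reversed_fork": 25, "dHJ": 25, "hemicatenane": 25,
}


def make_jm_records(
    *,
    counts: dict[str, int] | None = None,
    genotype: str = "WT",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[JMRecord]:
    """Labeled EM molecule records whose geometry satisfies each category's
    defining rule exactly at ``noise_sigma = 0``.

    Branch lengths are drawn per category (nm, plausible EM scale of a few
    hundred to ~2000 nm) and then perturbed by multiplicative log-normal
    noise of parameter ``noise_sigma``:

    * ``fork`` — one 3-branch junction, arbitrary lengths;
    * ``bubble`` — two 3-branch junctions;
    * ``dHJ`` — two 4-branch junctions;
    * ``reversed_fork`` — daughter arms exactly equal, regressed arm
      strictly shorter, parental arm longer;
    * ``hemicatenane`` — branches (a, S-a, b, S-b): two filaments of the
      same total size S, with a, b chosen so no two branches are within the
      classifier's default 5% equality tolerance.
    """
    counts = dict(_JM_DEFAULT_COUNTS) if counts is None else counts
    rng = np.random.default_rng(seed)
    records: list[JMRecord] = []
    serial = 0

    def _noisy(vals: list[float]) -> tuple[float, ...]:
        if noise_sigma == 0:
            return tuple(vals)
        return tuple(float(v * rng.lognormal(0.0, noise_sigma)) for v in vals)

    for category, n in counts.items():
        for _ in range(n):
            serial += 1
            mid = f"{genotype}_{serial:04d}"
            if category == "fork":
                lengths = list(rng.uniform(200, 1500, 3))
                nj, nb = 1, 3
            elif category == "bubble":
                lengths = list(rng.uniform(200, 1500, 3))
                nj, nb = 2, 3
            elif category == "dHJ":
                lengths = list(rng.uniform(200, 1500, 4))
                nj, nb = 2, 4
            elif category == "reversed_fork":
                daughter = float(rng.uniform(500, 1200))
                regressed = daughter * float(rng.uniform(0.2, 0.85))
                parental = daughter * float(rng.uniform(1.2, 1.9))
                lengths = [daughter, daughter, parental, regressed]
                nj, nb = 1, 4
            elif category == "hemicatenane":
                total = float(rng.uniform(1200, 2400))
                a = total * float(rng.uniform(0.25, 0.35))
                b = total * float(rng.uniform(0.40, 0.47))
                lengths = [a, total - a, b, total - b]
                nj, nb = 1, 4
            else:
                raise ValidationError(f"unknown JM category {category!r}")
            order = rng.permutation(len(lengths))
            lengths = [lengths[k] for k in order]
            records.append(
                JMRecord(
                    molecule_id=mid,
                    genotype=genotype,
                    n_junctions=nj,
                    branch_lengths_nm=_noisy(lengths),
                    n_branches=nb,
                    true_category=category,
                )
            )
    return records


# --- qPCR generator ---------------------------------------------------------


def make_qpcr_table(
    *,
    true_percent_input: dict[tuple[str, str], float],
    replicates: int = 3,
    ct_input: float = 20.0,
    input_dilution: float = 0.01,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic ChIP-qPCR Ct table with known true enrichment.

    ``true_percent_input`` maps ``(target_region, strain)`` to the true
    percent input; IP Ct values are derived by inverting the
    dilution-corrected 2^(-dCt) formula and perturbed (with the input Ct)
    by Gaussian noise of sd ``ct_noise_sd`` cycles. Columns match the
    qPCR reader (``Ct_IP, Ct_input, input_dilution, true_percent_input``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (region, strain), pct in true_percent_input.items():
        if pct <= 0:
            raise ValidationError("true percent input must be > 0")
        ct_ip_true = ct_input - np.log2(input_dilution) - np.log2(pct / 100.0)
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "target_region": region,
                    "strain": strain,
                    "replicate": f"rep{rep}",
                    "Ct_IP": float(ct_ip_true + rng.normal(0.0, ct_noise_sd))
                    if ct_noise_sd > 0
                    else float(ct_ip_true),
                    "Ct_input": float(ct_input + rng.normal(0.0, ct_noise_sd))
                    if ct_noise_sd > 0
                    else float(ct_input),
                    "input_dilution": input_dilution,
                    "true_percent_input": pct,
                }
            )
    return pd.DataFrame(rows)
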