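"""Core data model: genomes, intervals, cluster sets and feature annotations.

All coordinates are 0-based, half-open (BED convention). An interval
``[start, end)`` covers ``end - start`` bases. Inputs recorded in 1-based
fully-closed coordinates must be converted at the reader
(:func:`npstools.io.read_bed` with ``one_based=True``); nothing downstream
ever sees 1-based coordinates.

A :class:`ClusterSet` holds one protein's chromatin-binding clusters —
maximal intervals of ChIP enrichment — as per-chromosome sorted, disjoint
interval arrays. Overlapping or book-ended input intervals are merged on
construction: clusters are maximal runs of enrichment, and adjacency of two
called intervals is an artifact of tiling resolution, not biology. Strand is
ignored throughout; cluster overlap is a strand-agnostic quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "GenomeDef",
    "GenomicInterval",
    "ClusterSet",
    "FeatureSet",
    "merge_intervals",
]


class ValidationError(ValueError):
    """An interval, genome or set violated a structural invariant."""


@dataclass(frozen=True)
class GenomeDef:
    """Named chromosomes with lengths; the universe for all interval math.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs. Names must be unique and lengths
        positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _sizes: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        sizes: dict[str, int] = {}
        for name, length in chroms:
            if length < 1:
                raise ValidationError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            if name in sizes:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            sizes[name] = length
        if not sizes:
            raise ValidationError("genome has no chromosomes")
        object.__setattr__(self, "_sizes", sizes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        """Total genome size in bp (sum of chromosome lengths)."""
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: object) -> bool:
        return chrom in self._sizes


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeDef) -> None:
        """Raise :class:`ValidationError` if the interval exceeds its chromosome."""
        chrom_len = genome.length(self.chrom)
        if self.end > chrom_len:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {chrom_len}"
            )


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals; overlapping or book-ended runs collapse."""
    if len(starts) == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlap or book-ended
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_intervals(
    raw: Iterable[GenomicInterval], genome: GenomeDef
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Validate, sort and merge raw intervals into per-chromosome arrays.

    Overlapping or book-ended (``end == next start``) intervals are merged.
    Returns a mapping ``chrom -> (starts, ends)`` with sorted, disjoint,
    non-adjacent intervals; chromosomes follow genome order and empty
    chromosomes are omitted.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in raw:
        iv.validate(genome)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.names:
        pairs = by_chrom.get(chrom)
        if not pairs:
            continue
        pairs.sort()
        starts = np.asarray([p[0] for p in pairs], dtype=np.int64)
        ends = np.asarray([p[1] for p in pairs], dtype=np.int64)
        out[chrom] = _merge_sorted(starts, ends)
    return out


@dataclass(frozen=True)
class ClusterSet:
    """One protein's chromatin-binding clusters on a genome.

    Intervals are stored per chromosome as sorted, pairwise-disjoint,
    non-adjacent ``(starts, ends)`` int64 arrays; construction via
    :meth:`from_intervals` merges any overlapping or book-ended input.
    """

    protein: str
    genome: GenomeDef
    _by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]] = field(hash=False)

    @classmethod
    def from_intervals(
        cls, protein: str, intervals: Iterable[GenomicInterval], genome: GenomeDef
    ) -> "ClusterSet":
        return cls(protein=protein, genome=genome, _by_chrom=merge_intervals(intervals, genome))

    @classmethod
    def from_arrays(
        cls,
        protein: str,
        genome: GenomeDef,
        by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
        *,
        merge: bool = True,
    ) -> "ClusterSet":
        """Build from per-chromosome arrays; set ``merge=False`` only for
        arrays already known sorted, disjoint and in-bounds."""
        if not merge:
            return cls(protein=protein, genome=genome, _by_chrom=dict(by_chrom))
        ivs = [
            GenomicInterval(chrom, int(s), int(e))
            for chrom, (ss, ee) in by_chrom.items()
            for s, e in zip(ss, ee)
        ]
        return cls.from_intervals(protein, ivs, genome)

    def per_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for chrom, (s, e) in self._by_chrom.items():
            yield chrom, s, e

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty))

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom, s, e in self.per_chrom():
            for a, b in zip(s, e):
                yield GenomicInterval(chrom, int(a), int(b))

    @property
    def total_bases(self) -> int:
        """Union footprint in bp; 0 for an empty set."""
        return int(sum((e - s).sum() for _, s, e in self.per_chrom()))

    @property
    def n_clusters(self) -> int:
        return int(sum(len(s) for _, s, _ in self.per_chrom()))


@dataclass(frozen=True)
class FeatureSet:
    """A labeled class of annotated elements (tRNA / CEN / TER / ARS / other).

    Features keep stable ids and their own (possibly overlapping) intervals;
    use :meth:`as_cluster_set` for base-level overlap arithmetic.
    """

    class_label: str
    genome: GenomeDef
    features: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        feats = tuple((str(i), iv) for i, iv in self.features)
        object.__setattr__(self, "features", feats)
        seen: set[str] = set()
        for fid, iv in feats:
            if fid in seen:
                raise ValidationError(f"duplicate feature id {fid!r}")
            seen.add(fid)
            iv.validate(self.genome)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.features)

    def as_cluster_set(self) -> ClusterSet:
        """The merged genomic footprint of the class, as a ClusterSet."""
        return ClusterSet.from_intervals(
            self.class_label, (iv for _, iv in self.features), self.genome
        )
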