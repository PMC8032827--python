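"""Readers and writers for the formats the pipeline touches.

Interchange formats are deliberately boring: chrom.sizes for genomes, BED3/
BED6 (0-based, half-open) for cluster sets and feature annotations, TSV for
qPCR Ct tables and EM molecule records, TSV/JSON for result tables.

BED written by other tools in the 1-based fully-closed dialect must be
declared as such (``one_based=True``); coordinates are converted on read and
nothing downstream sees 1-based positions. Feature class labels travel
either in the BED name column as ``class:id`` or in a side TSV with columns
``id, class``.

All readers validate against the governing genome and reject — never
clamp — out-of-bounds coordinates, reporting the offending file line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import ClusterSet, FeatureSet, GenomeDef, GenomicInterval
from .jm import JMRecord

__all__ = [
    "ParseError",
    "ReportTable",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_feature_classes",
    "read_qpcr_table",
    "read_jm_records",
    "write_jm_records",
]


class ParseError(ValueError):
    """A file could not be parsed; the message carries file and line."""


# --- chrom.sizes ------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    """Read a two-column (name, length) chrom.sizes file into a GenomeDef."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            name, raw_len = parts
            try:
                length = int(raw_len)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {raw_len!r}") from None
            if length < 1:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise ParseError(f"{path}: no chromosomes")
    return GenomeDef(tuple(chroms))


def write_chrom_sizes(genome: GenomeDef, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


# --- BED --------------------------------------------------------------------


def _parse_bed_line(
    line: str, lineno: int, path: str | Path, genome: GenomeDef, one_based: bool
) -> GenomicInterval | None:
    stripped = line.strip()
    if not stripped or stripped.startswith(("#", "track", "browser")):
        return None
    parts = stripped.split("\t") if "\t" in stripped else stripped.split()
    if len(parts) < 3:
        raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
    chrom = parts[0]
    if chrom not in genome:
        raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
    if one_based:
        start -= 1  # 1-based fully-closed -> 0-based half-open
    name = parts[3] if len(parts) >= 4 else None
    try:
        iv = GenomicInterval(chrom, start, end, name=name)
        iv.validate(genome)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None
    return iv


def read_bed(
    path: str | Path,
    genome: GenomeDef,
    *,
    one_based: bool = False,
    as_features: bool = False,
    label: str | None = None,
) -> ClusterSet | FeatureSet:
    """Read a BED3/BED6 file as a merged ClusterSet or an id-preserving FeatureSet.

    Comment, ``track`` and ``browser`` lines are skipped. As a FeatureSet the
    name column provides ids (``class:id`` names are split); missing names
    get positional ids. ``label`` names the protein (cluster mode) or the
    feature class (feature mode; default inferred from ``class:id`` names,
    else ``other``).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            iv = _parse_bed_line(line, lineno, path, genome, one_based)
            if iv is not None:
                intervals.append(iv)
    if not as_features:
        return ClusterSet.from_intervals(label or Path(path).stem, intervals, genome)
    feats: list[tuple[str, GenomicInterval]] = []
    classes: set[str] = set()
    for i, iv in enumerate(intervals):
        fid = iv.name if iv.name else f"feature{i + 1}"
        if ":" in fid:
            cls, fid = fid.split(":", 1)
            classes.add(cls)
        feats.append((fid, iv))
    if label is None:
        label = classes.pop() if len(classes) == 1 else "other"
    return FeatureSet(label, genome, tuple(feats))


def write_bed(obj: ClusterSet | FeatureSet, path: str | Path) -> None:
    """Write a ClusterSet (BED3) or FeatureSet (BED4, names ``class:id``)."""
    with open(path, "w") as fh:
        if isinstance(obj, FeatureSet):
            for fid, iv in obj.features:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{obj.class_label}:{fid}\n")
        else:
            for iv in obj.intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_feature_classes(
    path: str | Path,
    genome: GenomeDef,
    *,
    class_table: str | Path | None = None,
    one_based: bool = False,
) -> dict[str, FeatureSet]:
    """Read a BED of annotated elements and split it by feature class.

    The class comes from ``class:id`` BED names, or from a side TSV with
    columns ``id, class`` (which overrides); unclassified features land in
    ``other``.
    """
    fs = read_bed(path, genome, one_based=one_based, as_features=True, label="all")
    id_to_class: dict[str, str] = {}
    if class_table is not None:
        tbl = pd.read_csv(class_table, sep="\t", dtype=str)
        if not {"id", "class"} <= set(tbl.columns):
            raise ParseError(f"{class_table}: need columns 'id' and 'class'")
        id_to_class = dict(zip(tbl["id"], tbl["class"]))
    # re-read names to recover class prefixes discarded by read_bed
    by_class: dict[str, list[tuple[str, GenomicInterval]]] = {}
    with open(path) as fh:
        raw = [
            iv
            for lineno, line in enumerate(fh, start=1)
            if (iv := _parse_bed_line(line, lineno, path, genome, one_based)) is not None
        ]
    for i, iv in enumerate(raw):
        fid = iv.name if iv.name else f"feature{i + 1}"
        cls = "other"
        if ":" in fid:
            cls, fid = fid.split(":", 1)
        cls = id_to_class.get(fid, cls)
        by_class.setdefault(cls, []).append((fid, iv))
    return {cls: FeatureSet(cls, genome, tuple(feats)) for cls, feats in by_class.items()}


# --- qPCR and JM tables -----------------------------------------------------

_QPCR_COLUMNS = ["target_region", "strain", "replicate", "role", "Ct", "input_dilution"]


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR Ct TSV and pivot it to one row per replicate.

    Input columns: ``target_region, strain, replicate, role (IP | input |
    no_tag_IP), Ct, input_dilution``. Output columns match
    :func:`npstools.qpcr.percent_input_table` (``Ct_IP``, ``Ct_input``, ...).
    A ``no_tag_IP`` row shares its replicate's input Ct and comes back as an
    extra row with the strain suffixed ``/no_tag``.
    """
    tbl = pd.read_csv(path, sep="\t")
    missing = set(_QPCR_COLUMNS) - set(tbl.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_roles = set(tbl["role"]) - {"IP", "input", "no_tag_IP"}
    if bad_roles:
        raise ParseError(f"{path}: unknown roles {sorted(bad_roles)}")
    wide = tbl.pivot_table(
        index=["target_region", "strain", "replicate", "input_dilution"],
        columns="role",
        values="Ct",
    ).reset_index()
    wide.columns.name = None
    if "input" not in wide or wide["input"].isna().any():
        raise ParseError(f"{path}: every replicate needs an input Ct")
    rows = []
    for _, row in wide.iterrows():
        base = {
            "target_region": row["target_region"],
            "replicate": row["replicate"],
            "input_dilution": row["input_dilution"],
            "Ct_input": row["input"],
        }
        if "IP" in wide.columns and pd.notna(row.get("IP")):
            rows.append({**base, "strain": row["strain"], "Ct_IP": row["IP"]})
        if "no_tag_IP" in wide.columns and pd.notna(row.get("no_tag_IP")):
            rows.append({**base, "strain": f"{row['strain']}/no_tag", "Ct_IP": row["no_tag_IP"]})
    if not rows:
        raise ParseError(f"{path}: no IP measurements found")
    cols = ["target_region", "strain", "replicate", "input_dilution", "Ct_IP", "Ct_input"]
    return pd.DataFrame(rows)[cols]


_JM_COLUMNS = ["molecule_id", "genotype", "n_junctions", "n_branches"]


def read_jm_records(path: str | Path) -> list[JMRecord]:
    """Read EM molecule records from TSV (branch lengths in nm, blanks allowed)."""
    tbl = pd.read_csv(path, sep="\t")
    missing = set(_JM_COLUMNS) - set(tbl.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in tbl.iterrows():
        lengths = [
            float(row[c])
            for c in ("branch1_nm", "branch2_nm", "branch3_nm", "branch4_nm")
            if c in tbl.columns and pd.notna(row[c])
        ]
        true_cat = row.get("category_label")
        records.append(
            JMRecord(
                molecule_id=str(row["molecule_id"]),
                genotype=str(row["genotype"]),
                n_junctions=int(row["n_junctions"]),
                branch_lengths_nm=tuple(lengths),
                n_branches=int(row["n_branches"]),
                true_category=str(true_cat) if pd.notna(true_cat) else None,
            )
        )
    return records


def write_jm_records(records: list[JMRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "molecule_id": r.molecule_id,
            "genotype": r.genotype,
            "n_junctions": r.n_junctions,
        }
        for i in range(4):
            row[f"branch{i + 1}_nm"] = (
                round(r.branch_lengths_nm[i], 3) if i < len(r.branch_lengths_nm) else ""
            )
        row["n_branches"] = r.n_branches
        row["category_label"] = r.true_category or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- result tables ----------------------------------------------------------

_REPORT_COLUMNS = [
    "analysis",
    "proteins",
    "feature_class",
    "observed",
    "expected",
    "fold",
    "empirical_p",
    "fisher_p",
    "n_iterations",
    "seed",
]


@dataclass
class ReportTable:
    """Uniform result table for co-localization and enrichment analyses."""

    rows: list[dict]

    @classmethod
    def from_results(cls, results: list) -> "ReportTable":
        from .coloc import ColocResult
        from .enrichment import FoldResult

        rows = []
        for r in results:
            if isinstance(r, ColocResult):
                rows.append(
                    {
                        "analysis": "colocalization",
                        "proteins": f"{r.protein_a},{r.protein_b}",
                        "feature_class": "",
                        "observed": r.observed_overlap_bp,
                        "expected": r.expected_overlap_bp,
                        "fold": r.fold,
                        "empirical_p": r.empirical_p,
                        "fisher_p": r.fisher_p,
                        "n_iterations": r.n_iterations,
                        "seed": r.seed,
                    }
                )
            elif isinstance(r, FoldResult):
                rows.append(
                    {
                        "analysis": f"enrichment[{r.expectation_mode}]",
                        "proteins": r.protein,
                        "feature_class": r.feature_class,
                        "observed": r.observed_overlap_bp,
                        "expected": r.expected_overlap_bp,
                        "fold": r.fold,
                        "empirical_p": r.empirical_p,
                        "fisher_p": r.fisher_p,
                        "n_iterations": r.n_iterations,
                        "seed": r.seed,
                    }
                )
            else:
                raise TypeError(f"cannot tabulate {type(r).__name__}")
        return cls(rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_REPORT_COLUMNS)

    def write(self, path: str | Path, *, format: str = "tsv") -> None:
        """Write as TSV or JSON; floats carry 6 significant digits in both."""
        df = self.to_dataframe()

        def _fmt(x: object) -> object:
            if isinstance(x, float):
                return float(f"{x:.6g}")
            return x

        df = df.map(_fmt)
        if format == "tsv":
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        elif format == "json":
            with open(path, "w") as fh:
                json.dump(df.to_dict(orient="records"), fh, indent=1)
        else:
            raise ValueError(f"unknown format {format!r}")

    @classmethod
    def read(cls, path: str | Path, *, format: str = "tsv") -> "ReportTable":
        if format == "tsv":
            df = pd.read_csv(path, sep="\t")
            return cls(df.to_dict(orient="records"))
        with open(path) as fh:
            return cls(json.load(fh))
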