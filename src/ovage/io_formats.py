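"""Readers and writers for the formats the pipeline touches.

Coordinate contracts
--------------------
BED is 0-based half-open; GFF3 is 1-based inclusive.  Everything is held
internally as 0-based half-open (pyranges applies the GFF3 conversion on
read).  Count matrices are features x samples with non-negative integer
entries.  GMT lines are ``name<TAB>description<TAB>member...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.io
import scipy.sparse

logger = logging.getLogger("ovage")

FEATURE_KINDS = ("gene", "te_family", "mito")
AGE_GROUPS = ("young", "old")


class ParseError(ValueError):
    """A file violated its format contract; message carries the line number."""


class ValidationError(ValueError):
    """In-memory data violated a type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with a per-feature kind label.

    ``counts`` rows are features, columns are samples.  ``feature_kind``
    maps every feature id to one of :data:`FEATURE_KINDS`.
    """

    counts: pd.DataFrame
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValidationError("count matrix contains non-integer cells")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("count matrix contains negative entries")
        self.feature_kind = self.feature_kind.reindex(self.counts.index)
        if self.feature_kind.isna().any():
            missing = self.feature_kind.index[self.feature_kind.isna()][:3].tolist()
            raise ValidationError(f"features without a kind label: {missing}")
        bad = set(self.feature_kind.unique()) - set(FEATURE_KINDS)
        if bad:
            raise ValidationError(f"unknown feature kinds: {sorted(bad)}")
        # normalised axis names so round trips compare equal
        self.counts.index.name = "feature"
        self.counts.columns.name = None
        self.feature_kind.index.name = "feature"

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_kind(self, kind: str) -> "CountMatrix":
        keep = self.feature_kind[self.feature_kind == kind].index
        return CountMatrix(self.counts.loc[keep], self.feature_kind.loc[keep])


@dataclass
class SampleDesign:
    """Per-sample strain, age group and replicate index."""

    table: pd.DataFrame  # columns: sample, strain, age, replicate

    def __post_init__(self) -> None:
        required = {"sample", "strain", "age", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        bad_age = set(self.table["age"].unique()) - set(AGE_GROUPS)
        if bad_age:
            raise ValidationError(f"age groups must be in {AGE_GROUPS}, got {sorted(bad_age)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())

    def samples_for(self, strain: str, age: str) -> list[str]:
        t = self.table
        return t.loc[(t["strain"] == strain) & (t["age"] == age), "sample"].tolist()

    def validate_against(self, counts: CountMatrix, min_replicates: int = 2) -> None:
        design_samples = set(self.table["sample"])
        matrix_samples = set(counts.samples)
        if design_samples != matrix_samples:
            raise ValidationError(
                f"design/matrix sample mismatch: only-in-design={sorted(design_samples - matrix_samples)}, "
                f"only-in-matrix={sorted(matrix_samples - design_samples)}"
            )
        cell_sizes = self.table.groupby(["strain", "age"]).size()
        for strain in self.strains:
            for age in AGE_GROUPS:
                n = cell_sizes.get((strain, age), 0)
                if n < min_replicates:
                    raise ValidationError(
                        f"strain {strain!r} age {age!r} has {n} replicates (< {min_replicates})"
                    )


@dataclass
class GeneSet:
    """A named collection of feature ids (GMT semantics)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        self.members = tuple(dict.fromkeys(self.members))  # dedupe, keep order

    def restrict_to(self, universe: Iterable[str]) -> "GeneSet":
        """Drop members absent from ``universe``, warning about each loss."""
        universe = set(universe)
        kept = tuple(m for m in self.members if m in universe)
        dropped = [m for m in self.members if m not in universe]
        if dropped:
            logger.warning(
                "gene set %r: dropping %d unmatched members (e.g. %s)",
                self.name, len(dropped), dropped[:3],
            )
        return GeneSet(self.name, kept, self.description)


#: FeatureAnnotation is a DataFrame indexed by feature id with columns
#: chromosome, start, end (0-based half-open), strand, length (bp).
ANNOTATION_COLUMNS = ["chromosome", "start", "end", "strand", "length"]


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if annotation.index.has_duplicates:
        raise ValidationError("duplicate feature ids in annotation")
    if (annotation["start"] >= annotation["end"]).any():
        raise ValidationError("annotation has start >= end")
    if (annotation["length"] <= 0).any():
        raise ValidationError("annotation has non-positive feature length")
    return annotation


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    kind_map: Mapping[str, str] | None = None,
    default_kind: str = "gene",
    mtx_rows: str | Path | None = None,
    mtx_cols: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from TSV (features x samples, header row of
    sample ids) or MatrixMarket triplet plus row/column id files.

    ``kind_map`` assigns feature kinds; unlisted features get ``default_kind``.
    Non-integer or negative cells are rejected.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mtx_rows = Path(mtx_rows) if mtx_rows else path.with_suffix(".rows.txt")
        mtx_cols = Path(mtx_cols) if mtx_cols else path.with_suffix(".cols.txt")
        mat = scipy.io.mmread(path)
        rows = mtx_rows.read_text().split()
        cols = mtx_cols.read_text().split()
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        if mat.shape != (len(rows), len(cols)):
            raise ParseError(
                f"{path}: matrix is {mat.shape} but {len(rows)} row ids / {len(cols)} column ids given"
            )
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.isna().any() or df.isna().any().any():
            raise ParseError(f"{path}: missing cells (truncated file?)")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(f"{path}: non-numeric count for {bad[0]!r} in sample {col!r}")
    kinds = pd.Series(default_kind, index=df.index, dtype=object)
    if kind_map:
        for feat, kind in kind_map.items():
            if feat in kinds.index:
                kinds.loc[feat] = kind
    try:
        return CountMatrix(df, kinds)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts(path: str | Path, counts: CountMatrix) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="feature")


def read_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "strain": str, "age": str})
    if table.isna().any().any():
        raise ParseError(f"{path}: missing cells (truncated file?)")
    return SampleDesign(table)


def write_design(path: str | Path, design: SampleDesign) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intervals and annotation
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into a DataFrame (chromosome, start, end, name).

    Coordinates stay 0-based half-open.  Malformed rows raise
    :class:`ParseError` with the offending 1-based line number.
    """
    path = Path(path)
    # structural pass for precise error locations before handing to pyranges
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has {len(fields)} fields (<3)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    gr = pr.read_bed(str(path)).df
    out = gr.rename(columns={"Chromosome": "chromosome", "Start": "start", "End": "end", "Name": "name"})
    keep = [c for c in ("chromosome", "start", "end", "name") if c in out.columns]
    out = out[keep].copy()
    out["chromosome"] = out["chromosome"].astype(str)
    return out.reset_index(drop=True)


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    cols = ["chromosome", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> pd.DataFrame:
    """Read gene records from GFF3 into a FeatureAnnotation frame.

    GFF3 is 1-based inclusive on disk; the returned start/end are 0-based
    half-open.  Feature length is the ``length`` attribute when present
    (transcript length), otherwise the genomic span.
    """
    path = Path(path)
    gr = pr.read_gff3(str(path)).df
    if feature_types:
        gr = gr[gr["Feature"].isin(feature_types)]
    if "ID" not in gr.columns or gr["ID"].isna().any():
        raise ParseError(f"{path}: GFF3 gene records without ID attribute")
    ann = pd.DataFrame(
        {
            "chromosome": gr["Chromosome"].astype(str).to_numpy(),
            "start": gr["Start"].to_numpy(),
            "end": gr["End"].to_numpy(),
            "strand": gr["Strand"].astype(str).to_numpy() if "Strand" in gr else ".",
        },
        index=pd.Index(gr["ID"].astype(str), name="feature"),
    )
    if "length" in gr.columns:
        length = pd.to_numeric(gr["length"], errors="coerce").to_numpy()
        span = (ann["end"] - ann["start"]).to_numpy()
        ann["length"] = np.where(np.isnan(length), span, length).astype(np.int64)
    else:
        ann["length"] = (ann["end"] - ann["start"]).astype(np.int64)
    return validate_annotation(ann)


def write_gff3(path: str | Path, annotation: pd.DataFrame, source: str = "ovage") -> None:
    """Write a FeatureAnnotation frame as GFF3 gene records (1-based inclusive)."""
    validate_annotation(annotation)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat, row in annotation.iterrows():
            attrs = f"ID={feat};length={int(row['length'])}"
            fh.write(
                f"{row['chromosome']}\t{source}\tgene\t{int(row['start']) + 1}\t{int(row['end'])}\t.\t"
                f"{row.get('strand', '.')}\t.\t{attrs}\n"
            )


def annotation_to_bed(annotation: pd.DataFrame) -> pd.DataFrame:
    out = annotation[["chromosome", "start", "end"]].copy()
    out["name"] = annotation.index
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene sets and profiles
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            sets.append(GeneSet(fields[0], tuple(fields[2:]), description=fields[1]))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or ".", *s.members]) + "\n")


def read_stage_profiles(path: str | Path) -> pd.DataFrame:
    """Stage reference profiles: rows = panel genes, columns = stage labels."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: stage profiles need >=2 stages")
    if table.index.has_duplicates:
        raise ParseError(f"{path}: duplicate panel genes")
    if table.isna().any().any():
        raise ParseError(f"{path}: missing cells (truncated file?)")
    return table


def write_results(path: str | Path, table: pd.DataFrame, index: bool = True) -> None:
    """Write a results table as TSV with stable column order."""
    table.to_csv(path, sep="\t", index=index, float_format="%.6g")
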