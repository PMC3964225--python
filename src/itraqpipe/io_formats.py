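"""Tabular input/output for the iTRAQ biomarker pipeline.

All quantitative tables in the pipeline are plain CSV/TSV (RFC-4180,
UTF-8).  Missing ratios are encoded as *empty cells*, never as 0 or an
NA sentinel, because reporter ratios are strictly positive and a blank
in the source tables is a genuine "not quantified in this sample".
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CANCER = "cancer"
NORMAL = "normal"
GROUPS = (CANCER, NORMAL)

#: columns every peptide table must carry, in this order, followed by
#: one ratio column per non-reference channel (named by sample id)
PEPTIDE_BASE_COLUMNS = ("accession", "peptide", "confidence", "is_decoy")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


# ---------------------------------------------------------------------------
# ratio matrices
# ---------------------------------------------------------------------------

@dataclass
class RatioMatrix:
    """Proteins x samples table of reporter ratios to the pooled reference.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample.
        Cells are positive floats; missing ratios are NaN.
    groups
        Mapping of every sample id to ``"cancer"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dup}")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        bad = ~np.isnan(arr) & (arr <= 0)
        if bad.any():
            raise ValueError("ratios must be strictly positive")
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        for s, g in self.groups.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} for sample {s!r}")

    # -- accessors ----------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    @property
    def cancer_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == CANCER]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == NORMAL]

    def ratio(self, protein: str, sample: str) -> float:
        """Ratio for one cell; NaN when missing."""
        return float(self.values.at[protein, sample])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, proteins: Iterable[str]) -> "RatioMatrix":
        proteins = list(proteins)
        unknown = [p for p in proteins if p not in self.values.index]
        if unknown:
            raise KeyError(f"proteins not in matrix: {unknown}")
        return RatioMatrix(self.values.loc[proteins].copy(), dict(self.groups))


def infer_groups(sample_ids: Iterable[str]) -> dict[str, str]:
    """Map C*/T* prefixes to cancer and N* to normal.

    Used for the packaged fixture and for simulator output; external
    matrices should come with an explicit group map.
    """
    out: dict[str, str] = {}
    for s in sample_ids:
        head = s[:1].upper()
        if head in ("C", "T"):
            out[s] = CANCER
        elif head == "N":
            out[s] = NORMAL
        else:
            raise ValueError(f"cannot infer group from sample id {s!r}")
    return out


def read_ratio_matrix(path: str | Path,
                      group_map: Mapping[str, str] | None = None) -> RatioMatrix:
    """Read a protein x sample ratio matrix from CSV/TSV.

    First column holds protein ids, the header row holds sample ids and
    empty cells denote missing ratios.  ``group_map`` assigns each sample
    to cancer/normal; if omitted the C/N prefix convention is used.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#",
                     keep_default_na=False, na_values=[""])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric ratio cell in {path}: {exc}") from exc
    if group_map is None:
        groups = infer_groups(df.columns)
    else:
        absent = [s for s in df.columns if s not in group_map]
        if absent:
            raise ValueError(f"samples absent from group map: {absent}")
        groups = {s: group_map[s] for s in df.columns}
    return RatioMatrix(df, groups)


def write_ratio_matrix(matrix: RatioMatrix, path: str | Path,
                       header_lines: Iterable[str] = ()) -> None:
    """Write a matrix as CSV/TSV with blanks for missing cells."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep=_sep_for(path), index_label="protein",
                             na_rep="")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column sample,group sidecar file."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None,
                     names=["sample", "group"], comment="#",
                     skipinitialspace=True)
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample in group map")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups in map: {sorted(bad)}")
    return dict(zip(df["sample"].astype(str), df["group"]))


_FIXTURE_CACHE: RatioMatrix | None = None


def load_table1_fixture() -> RatioMatrix:
    """The packaged 55-protein x 20-sample discovery ratio matrix.

    Ten matched ccRCC (C1-C10) and normal-kidney (N1-N10) samples, each
    expressed as the iTRAQ ratio to a pooled-normal reference channel.
    Blanks are proteins not quantified in that sample.  The matrix is
    returned as a fresh copy each call; the underlying packaged data
    never changes.
    """
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        text = (resources.files("itraqpipe") / "data" / "table1_ratios.csv").read_text()
        df = pd.read_csv(io.StringIO(text), index_col=0,
                         keep_default_na=False, na_values=[""]).astype(float)
        _FIXTURE_CACHE = RatioMatrix(df, infer_groups(df.columns))
    return RatioMatrix(_FIXTURE_CACHE.values.copy(), dict(_FIXTURE_CACHE.groups))


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with per-channel reporter ratios.

    ``channel_ratios`` maps sample id -> ratio to the set's reference
    channel; a sample may be absent (not quantified for this peptide).
    Decoy (reverse-sequence) records are identification-only: they are
    excluded from all quantitation downstream.
    """

    accession: str
    sequence: str
    confidence: float
    is_decoy: bool
    channel_ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence {self.confidence} outside [0, 1] "
                f"for peptide {self.sequence!r}")
        for s, r in self.channel_ratios.items():
            if not np.isfinite(r) or r <= 0:
                raise ValueError(f"non-positive ratio {r} in channel {s!r}")


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide-level quantitation TSV.

    Mandatory columns ``accession, peptide, confidence, is_decoy`` are
    followed by one ratio column per non-reference channel.  Confidence
    outside [0, 1] is an error, not clipped.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#",
                     keep_default_na=False,
                     na_values=[""], dtype={"is_decoy": str})
    missing = [c for c in PEPTIDE_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    ratio_cols = [c for c in df.columns if c not in PEPTIDE_BASE_COLUMNS]
    records = []
    for _, row in df.iterrows():
        ratios = {c: float(row[c]) for c in ratio_cols if pd.notna(row[c])}
        records.append(PeptideRecord(
            accession=str(row["accession"]),
            sequence=str(row["peptide"]),
            confidence=float(row["confidence"]),
            is_decoy=_parse_bool(row["is_decoy"]),
            channel_ratios=ratios,
        ))
    return records


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path,
                        header_lines: Iterable[str] = ()) -> None:
    records = list(records)
    ratio_cols: list[str] = []
    for r in records:
        for s in r.channel_ratios:
            if s not in ratio_cols:
                ratio_cols.append(s)
    rows = []
    for r in records:
        row = {"accession": r.accession, "peptide": r.sequence,
               "confidence": r.confidence, "is_decoy": r.is_decoy}
        for s in ratio_cols:
            row[s] = r.channel_ratios.get(s, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(PEPTIDE_BASE_COLUMNS) + ratio_cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False, na_rep="")


def _parse_bool(value: object) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


# ---------------------------------------------------------------------------
# secretion annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_FLAGS = ("is_extracellular", "is_membrane_bound", "is_exosomal",
                    "signalp_secreted", "secretomep_secreted")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein secretion evidence flags consumed by the secretome rubric.

    The SignalP / SecretomeP verdicts and subcellular-location and
    exosome annotations are produced upstream (predictors, UniProt
    curation) and enter the pipeline as plain booleans.
    """

    protein_id: str
    is_extracellular: bool = False
    is_membrane_bound: bool = False
    is_exosomal: bool = False
    signalp_secreted: bool = False
    secretomep_secreted: bool = False


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#",
                     keep_default_na=False, dtype=str)
    if "protein_id" not in df.columns:
        raise ValueError("annotation table needs a protein_id column")
    missing = [c for c in ANNOTATION_FLAGS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing flags: {missing}")
    if df["protein_id"].duplicated().any():
        raise ValueError("duplicate protein_id in annotation table")
    return [
        AnnotationRecord(
            protein_id=row["protein_id"],
            **{flag: _parse_bool(row[flag]) for flag in ANNOTATION_FLAGS},
        )
        for _, row in df.iterrows()
    ]


def write_annotation_table(records: Iterable[AnnotationRecord],
                           path: str | Path) -> None:
    rows = [{"protein_id": r.protein_id,
             **{f: getattr(r, f) for f in ANNOTATION_FLAGS}} for r in records]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
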