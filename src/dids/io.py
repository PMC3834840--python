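"""Reading, validation and writing of expression matrices, label files and result tables.

The on-disk conventions are deliberately plain: a genes-by-samples matrix as
TSV or CSV with a header row of sample identifiers and gene identifiers in the
first column, and a two-column label file assigning every sample to the
``control`` or ``case`` group. DIDS consumes already-normalised continuous
values (typically log-scale intensities); no platform-specific parsing or
normalisation happens here.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupLabels",
    "read_matrix",
    "read_labels",
    "write_matrix",
    "write_results",
]


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of continuous expression values.

    Gene identifiers must be unique; values must be finite unless the caller
    explicitly opted into per-gene NA dropping downstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene identifiers: {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample identifiers: {sorted(dup)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class GroupLabels:
    """Partition of samples into a control group (n1) and a case group (n2)."""

    mapping: Mapping[str, str]  # sample_id -> "control" | "case"

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in ("control", "case")}
        if bad:
            raise ValueError(f"unrecognised group tokens: {sorted(bad)}")
        if not self.control_ids:
            raise ValueError("control group is empty; both groups must be non-empty")
        if not self.case_ids:
            raise ValueError("case group is empty; both groups must be non-empty")

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "control"]

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "case"]

    @property
    def n1(self) -> int:
        return len(self.control_ids)

    @property
    def n2(self) -> int:
        return len(self.case_ids)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check that the labels cover exactly the matrix's samples."""
        labelled = set(self.mapping)
        present = set(matrix.sample_ids)
        missing = present - labelled
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
        unknown = labelled - present
        if unknown:
            raise ValueError(f"labels refer to absent samples: {sorted(unknown)[:5]}")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_matrix(
    path: str | Path,
    delimiter: str | None = None,
    transpose: bool = False,
    drop_na: bool = False,
) -> ExpressionMatrix:
    """Parse a TSV/CSV expression matrix (gene IDs in the first column).

    Parameters
    ----------
    delimiter:
        Field separator; sniffed from the file when not given.
    transpose:
        Set for samples-in-rows files.
    drop_na:
        When False (default) any non-finite cell is an error; when True,
        non-finite cells are kept as NaN for gene-wise dropping downstream.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, header=0, float_precision="round_trip")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (delimiter {sep!r}?)")
    if transpose:
        frame = frame.T
    # pin down non-numeric cells with their file location
    bad_cols = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    for col in bad_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        original_na = frame[col].isna()
        bad_rows = frame.index[coerced.isna() & ~original_na]
        if len(bad_rows):
            # header is line 1, first data row is line 2
            line = frame.index.get_loc(bad_rows[0]) + 2
            raise ValueError(
                f"{path}, line {line}: non-numeric value "
                f"{frame.loc[bad_rows[0], col]!r} for gene {bad_rows[0]!r}, sample {col!r}"
            )
        frame[col] = coerced
    matrix = ExpressionMatrix.from_frame(frame)
    if not drop_na and not np.all(np.isfinite(matrix.values)):
        rows = np.where(~np.all(np.isfinite(matrix.values), axis=1))[0]
        names = [matrix.gene_ids[i] for i in rows[:5]]
        raise ValueError(
            f"{path}: non-finite values in genes {names}; "
            "remove them or pass drop_na/--drop-na to drop offending samples gene-wise"
        )
    return matrix


def write_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix in the same layout ``read_matrix`` expects; full precision."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def read_labels(
    path: str | Path,
    control_label: str = "control",
    case_label: str = "case",
    delimiter: str | None = None,
) -> GroupLabels:
    """Parse a two-column sample_id / group file into a :class:`GroupLabels`.

    ``control_label`` / ``case_label`` map the file's group tokens onto the
    canonical names; any other token is an error.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if list(frame.iloc[0]) == ["sample_id", "group"]:  # optional header
        frame = frame.iloc[1:]
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group), got {frame.shape[1]}")
    mapping: dict[str, str] = {}
    for _, (sample, group) in frame.iterrows():
        if sample in mapping:
            raise ValueError(f"{path}: sample {sample!r} labelled more than once")
        if group == control_label:
            mapping[sample] = "control"
        elif group == case_label:
            mapping[sample] = "case"
        else:
            raise ValueError(
                f"{path}: unrecognised group {group!r} for sample {sample!r} "
                f"(expected {control_label!r} or {case_label!r})"
            )
    return GroupLabels(mapping)


def write_labels(labels: GroupLabels, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for sample, group in labels.mapping.items():
            fh.write(f"{sample}{delimiter}{group}\n")


_RESULT_COLUMNS = [
    "gene_id", "direction", "n1", "n2", "k", "threshold",
    "score", "p_value", "p_bonferroni", "passed_filter", "rank",
]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write one TSV per table plus a run manifest; deterministic layout.

    Human tables carry 6 significant digits; a machine-readable sidecar
    (``*.full.json``-free — the TSV itself at full precision) is written next
    to each as ``<name>.fullprec.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        cols = [c for c in _RESULT_COLUMNS if c in table.columns]
        cols += [c for c in table.columns if c not in cols]
        table = table[cols]
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        full = out_dir / f"{name}.fullprec.tsv"
        table.to_csv(full, sep="\t", index=False, float_format="%.17g")
        written[name] = path
    if manifest is not None:
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written["manifest"] = mpath
    return written


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
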