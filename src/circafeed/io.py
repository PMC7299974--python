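"""Table readers/writers and the run manifest.

TSV is the canonical dialect (tab-separated, '.' decimal, UTF-8); CSV is
accepted on read, chosen by file extension. Writers emit a stable column
order and a leading ``#`` comment carrying the package version and seed;
readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .behavior import INTAKE_COLUMNS, VALID_UNITS
from .exceptions import EmptyInputError, SampleMismatchError, SchemaError
from .transcriptome import ExpressionMatrix

__all__ = [
    "read_intake_table",
    "write_table",
    "read_table",
    "read_expression",
    "write_expression",
    "RunManifest",
]

CPP_COLUMNS = ("animal_id", "phase", "t_conditioned", "t_opposite", "t_neutral")


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table, skipping '#' comment lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep(path), comment="#")


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> Path:
    """Write a table as TSV/CSV with a version/seed header comment."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# circafeed v{__version__}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep=_sep(path), index=False)
    return path


def read_intake_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format intake table.

    Required columns: animal_id, group, item, bin_start, bin_width, amount,
    unit. Units must be one of g/kcal/licks, amounts non-negative and bin
    widths positive; violations raise a :class:`SchemaError` naming the
    offending rows (1-based data row numbers).
    """
    df = read_table(path)
    missing = [c for c in INTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    bad_unit = ~df["unit"].isin(VALID_UNITS)
    if bad_unit.any():
        rows = (df.index[bad_unit] + 1).tolist()[:10]
        raise SchemaError(
            f"{path}: invalid unit in rows {rows} "
            f"(allowed: {', '.join(VALID_UNITS)})"
        )
    for col, ok in (("amount", df["amount"] >= 0), ("bin_width", df["bin_width"] > 0),
                    ("bin_start", df["bin_start"] >= 0)):
        bad = ~ok
        if bad.any():
            rows = (df.index[bad] + 1).tolist()[:10]
            raise SchemaError(f"{path}: invalid {col} in rows {rows}")
    return df


def read_cpp_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a CPP dwell-time table."""
    df = read_table(path)
    missing = [c for c in CPP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def read_expression(path_matrix: str | Path, path_meta: str | Path) -> ExpressionMatrix:
    """Read a gene x sample matrix and its sample-metadata table.

    The matrix has genes as rows (first column = gene identifier) and samples
    as columns; metadata needs columns sample and zt (replicate, tissue,
    genotype carried when present). Mismatched sample sets raise a join error.
    """
    mat = read_table(path_matrix)
    if mat.empty or mat.shape[1] < 2:
        raise EmptyInputError(f"{path_matrix}: empty expression matrix")
    mat = mat.set_index(mat.columns[0])
    meta = read_table(path_meta)
    if "sample" not in meta.columns or "zt" not in meta.columns:
        raise SchemaError(f"{path_meta}: metadata needs 'sample' and 'zt' columns")
    meta = meta.set_index("sample")
    if set(mat.columns) != set(meta.index):
        only_m = sorted(set(mat.columns) - set(meta.index))[:5]
        only_d = sorted(set(meta.index) - set(mat.columns))[:5]
        raise SampleMismatchError(
            f"sample sets differ (matrix-only: {only_m}, meta-only: {only_d})"
        )
    return ExpressionMatrix(values=mat, samples=meta)


def write_expression(
    matrix: ExpressionMatrix, path_matrix: str | Path, path_meta: str | Path,
    seed: int | None = None,
) -> None:
    """Write an ExpressionMatrix as a matrix TSV plus a metadata TSV."""
    write_table(matrix.values.rename_axis("gene").reset_index(), path_matrix, seed=seed)
    write_table(matrix.samples.rename_axis("sample").reset_index(), path_meta, seed=seed)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run.

    Holds the configuration snapshot, the seed, SHA-256 digests of every
    input file, the package version and a timestamp — enough to re-run the
    deterministic stages bit-identically.
    """

    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
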