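"""Tab-delimited readers and writers.

All matrices travel as TSV with a header row of sample ids and the feature
id in the first column; ``#``-prefixed lines before the header carry
provenance (currently the scale tag).  Floats are written with 12
significant digits so write -> read -> write is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TsvParseError",
    "ExpressionMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_table",
]

_FLOAT_FMT = "{:.12g}"


class TsvParseError(ValueError):
    """A TSV file did not parse; the message names the offending cell."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix with a processing-stage tag.

    ``scale_tag`` is one of raw / background-corrected / quantile-normalized
    / log2 (free-form tags are allowed for intermediate products).
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    @property
    def feature_ids(self):
        return self.data.index

    @property
    def sample_ids(self):
        return self.data.columns


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a matrix TSV; raises :class:`TsvParseError` naming bad cells."""
    path = Path(path)
    scale_tag = "raw"
    header: list[str] | None = None
    features: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#scale_tag="):
                    scale_tag = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if not header:
                    raise TsvParseError(f"{path}:{lineno}: header has no sample columns")
                continue
            if len(fields) != len(header) + 1:
                raise TsvParseError(
                    f"{path}:{lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            features.append(fields[0])
            vals = []
            for col, cell in enumerate(fields[1:], start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise TsvParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column "
                        f"{header[col - 1]!r}"
                    ) from None
            rows.append(vals)
    if header is None:
        raise TsvParseError(f"{path}: empty file")
    data = pd.DataFrame(rows, index=features, columns=header)
    return ExpressionMatrix(data=data, scale_tag=scale_tag)


def _format_value(v) -> str:
    f = float(v)
    if np.isnan(f):
        return "nan"
    return _FLOAT_FMT.format(f)


def write_expression_tsv(matrix: ExpressionMatrix | pd.DataFrame, path, scale_tag=None) -> None:
    """Write a matrix TSV (canonical formatting; round-trips losslessly)."""
    if isinstance(matrix, pd.DataFrame):
        matrix = ExpressionMatrix(data=matrix, scale_tag=scale_tag or "raw")
    elif scale_tag is not None:
        matrix = ExpressionMatrix(data=matrix.data, scale_tag=scale_tag)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#scale_tag={matrix.scale_tag}\n")
        fh.write("feature_id\t" + "\t".join(map(str, matrix.data.columns)) + "\n")
        for fid, row in zip(matrix.data.index, matrix.data.to_numpy()):
            fh.write(str(fid) + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Plain TSV writer for annotation/result tables."""
    df.to_csv(Path(path), sep="\t", index=index, float_format="%.12g")
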