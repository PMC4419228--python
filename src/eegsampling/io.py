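"""Readers and writers for the channel-file corpus layout and feature CSVs.

Corpus layout: ``<root>/<class_label>/*.txt``, one ASCII file per channel,
one amplitude sample per line. Blank lines and surrounding whitespace are
tolerated; there is no header. Feature matrices travel as CSV with the
fixed header ``class,channel,X_Mean,...,X_Max``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import ClassDataset, RunConfig, SignalRecord
from .errors import EmptyInputError, FormatError, RaggedDataError, SchemaError
from .features import MATRIX_COLUMNS

PathLike = Union[str, Path]


def read_channel_file(
    path: PathLike, channel_id: str, class_label: str
) -> SignalRecord:
    """Parse one channel file: one real amplitude per nonblank line."""
    path = Path(path)
    samples: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                samples.append(float(stripped))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: {stripped!r} is not a number"
                ) from None
    if not samples:
        raise EmptyInputError(f"{path}: no samples found")
    return SignalRecord(
        channel_id=channel_id, class_label=class_label, samples=np.array(samples)
    )


def read_class_directory(directory: PathLike, class_label: str) -> ClassDataset:
    """Read every ``*.txt`` channel file of one class, sorted by filename."""
    directory = Path(directory)
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise EmptyInputError(f"{directory}: no channel files (*.txt) found")
    records = [
        read_channel_file(f, channel_id=f.stem, class_label=class_label)
        for f in files
    ]
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        detail = ", ".join(f"{r.channel_id}:{len(r)}" for r in records)
        raise RaggedDataError(
            f"{directory}: channel files have unequal lengths ({detail})"
        )
    return ClassDataset(class_label=class_label, records=records)


def read_corpus(root: PathLike) -> list[ClassDataset]:
    """Read all class subdirectories of a corpus root, sorted by name."""
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise EmptyInputError(f"{root}: no class directories found")
    return [read_class_directory(d, class_label=d.name) for d in class_dirs]


def write_corpus(corpus: list[ClassDataset], root: PathLike) -> None:
    """Write datasets in the ``<root>/<class>/<channel>.txt`` layout."""
    root = Path(root)
    for ds in corpus:
        class_dir = root / ds.class_label
        class_dir.mkdir(parents=True, exist_ok=True)
        for rec in ds.records:
            out = class_dir / f"{rec.channel_id}.txt"
            np.savetxt(out, rec.samples, fmt="%.10g")


def write_feature_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a feature matrix as CSV in the canonical column order."""
    _check_schema(matrix.columns)
    matrix.loc[:, list(MATRIX_COLUMNS)].to_csv(
        path, index=False, float_format="%.12g"
    )


def read_feature_matrix(path: PathLike) -> pd.DataFrame:
    """Read a feature-matrix CSV, enforcing the canonical schema."""
    df = pd.read_csv(path, dtype={"class": str, "channel": str})
    _check_schema(df.columns)
    return df.loc[:, list(MATRIX_COLUMNS)]


def _check_schema(columns) -> None:
    have = list(columns)
    want = list(MATRIX_COLUMNS)
    missing = [c for c in want if c not in have]
    extra = [c for c in have if c not in want]
    if missing or extra:
        raise SchemaError(
            f"feature matrix schema mismatch: missing {missing}, extra {extra}"
        )


def load_config(path: PathLike, **overrides) -> RunConfig:
    """Load a flat YAML config file; keyword overrides win over file values."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a flat key-value mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)
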