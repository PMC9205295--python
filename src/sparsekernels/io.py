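"""Delimited-text readers/writers and run configuration.

Marker matrices are CSV/TSV with the line id in the first column and a
header of marker names; kernels are CSV with line-id row and column
labels; phenotypes are long CSV with Line, Env and one trait column.
Run configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .learners import ResponseSpec, infer_response_type


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_markers(path) -> pd.DataFrame:
    """Read a lines x markers matrix; first column is the line id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"marker file {path} has no marker columns")
    if df.isna().any().any():
        raise ValueError(f"marker file {path} contains missing entries")
    df.index.name = "Line"
    return df


def read_phenotypes(path):
    """Read a phenotype table and attach the inferred response type.

    Requires columns ``Line`` and ``Env`` plus exactly one trait column;
    duplicated (Line, Env) keys are an error.

    Returns ``(table, ResponseSpec)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("Line", "Env") if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks required column(s) {missing}")
    trait_cols = [c for c in df.columns if c not in ("Line", "Env")]
    if len(trait_cols) != 1:
        raise ValueError(
            f"phenotype file {path} must have exactly one trait column, "
            f"found {trait_cols}"
        )
    dup = df.duplicated(subset=["Line", "Env"])
    if dup.any():
        keys = df.loc[dup, ["Line", "Env"]].apply(tuple, axis=1).tolist()
        raise ValueError(f"duplicated (Line, Env) key(s): {keys[:5]}")
    if df[trait_cols[0]].isna().any():
        raise ValueError(f"trait column {trait_cols[0]!r} contains missing values")
    spec = infer_response_type(df[trait_cols[0]].to_numpy())
    return df, spec


def write_kernel(K, line_ids, path) -> None:
    pd.DataFrame(K, index=line_ids, columns=line_ids).to_csv(path)


def read_kernel(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"kernel file {path} is not square")
    df.columns = df.index
    return df


@dataclass
class RunConfig:
    """Serializable configuration of a CLI workflow run."""

    workflow: str = "benchmark"
    markers: str | None = None
    phenotypes: str | None = None
    kernel_file: str | None = None
    out_dir: str = "run"
    kernel: dict = field(default_factory=lambda: {"name": "linear"})
    sparse: dict | None = None
    models: list = field(default_factory=lambda: ["bayesian_gblup"])
    tune: dict | None = None
    master_seed: int = 0

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
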