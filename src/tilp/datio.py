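"""Expression-matrix and prior-knowledge input; ternary discretization.

Perturbation profiles arrive as a protein x condition matrix of
log2(treatment/control) ratios.  They are discretized to ternary states
{-1, 0, +1} with a fold-change threshold t > 1: a ratio rho maps to +1 when
rho >= log2(t), to -1 when rho <= -log2(t), and to 0 in between; missing
measurements stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 1.2


@dataclass
class LogRatioMatrix:
    """Protein x condition matrix of log2(treatment/control) ratios."""

    values: pd.DataFrame  # rows: protein ids, columns: condition ids; NaN = missing

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids in matrix rows")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate condition ids in matrix columns")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TernaryProfile:
    """Discretized states m[j, k] in {-1, 0, +1}; NaN marks missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("ternary profile entries must be in {-1, 0, 1} or missing")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def state(self, protein: str, condition: str) -> int | None:
        v = self.values.at[protein, condition]
        return None if pd.isna(v) else int(v)

    def observed_pairs(self) -> list[tuple[str, str, int]]:
        """All non-missing (protein, condition, state) triples."""
        out = []
        for j in self.values.index:
            for k in self.values.columns:
                v = self.values.at[j, k]
                if not pd.isna(v):
                    out.append((j, k, int(v)))
        return out


@dataclass(frozen=True)
class PriorRecord:
    condition: str
    node: str
    direction: int  # +1 up-regulated, -1 down-regulated


@dataclass
class PriorKnowledge:
    """Literature-derived compound targets: (condition, node, direction)."""

    records: list[PriorRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.direction not in (-1, 1):
                raise ValueError(f"prior direction must be +/-1, got {r.direction}")
            key = (r.condition, r.node)
            if key in seen:
                raise ValueError(f"duplicate prior for {key}")
            seen.add(key)

    def for_condition(self, condition: str) -> dict[str, int]:
        return {r.node: r.direction for r in self.records if r.condition == condition}

    def __len__(self) -> int:
        return len(self.records)

    @staticmethod
    def empty() -> "PriorKnowledge":
        return PriorKnowledge([])


def ternarize(matrix: LogRatioMatrix, threshold: float = DEFAULT_THRESHOLD) -> TernaryProfile:
    """Discretize log2 ratios at a fold-change threshold (inclusive bounds)."""
    if threshold <= 1:
        raise ValueError(f"fold-change threshold must exceed 1, got {threshold}")
    cut = np.log2(threshold)
    arr = matrix.values.to_numpy(dtype=float)
    out = np.where(arr >= cut, 1.0, np.where(arr <= -cut, -1.0, 0.0))
    out = np.where(np.isnan(arr), np.nan, out)
    return TernaryProfile(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def select_deps(profile: TernaryProfile) -> list[str]:
    """Differentially expressed proteins: non-zero in at least one condition."""
    arr = profile.values.to_numpy(dtype=float)
    mask = np.nansum(np.abs(np.nan_to_num(arr)), axis=1) > 0
    return [p for p, m in zip(profile.proteins, mask) if m]


def _collapse_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns sharing a condition id (log2 scale)."""
    if not df.columns.has_duplicates:
        return df
    return df.T.groupby(level=0, sort=False).mean().T


def read_matrix(path: str | Path, format: str | None = None) -> LogRatioMatrix:
    """Read a protein x condition matrix from TSV, CSV or GCT 1.3.

    GCT 1.3 layout: version line, a ``#rows #cols #rowmeta #colmeta``
    dimension line, then a table whose leading metadata rows/columns are
    dropped.  Replicate columns sharing a condition id are averaged.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "tsv"
    format = format.lower()
    if format == "gct":
        df = _read_gct(path)
    elif format in ("tsv", "txt", "csv"):
        sep = "," if format == "csv" else "\t"
        # keep duplicate condition headers verbatim (pandas would mangle
        # them to k1.1, breaking replicate detection)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
            df = pd.read_csv(fh, sep=sep, header=None, index_col=0)
        df.index.name = header[0]
        df.columns = header[1:]
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein rows: {dup}")
    df = _collapse_replicates(df.astype(float))
    return LogRatioMatrix(df)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (version line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rowmeta = int(dims[2]) if len(dims) > 2 else 0
        n_colmeta = int(dims[3]) if len(dims) > 3 else 0
        table = pd.read_csv(fh, sep="\t", index_col=0)
    # drop column-metadata rows and row-metadata columns
    data = table.iloc[n_colmeta:, n_rowmeta:]
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: GCT dimension mismatch: declared {(n_rows, n_cols)}, "
            f"found {data.shape}"
        )
    return data.astype(float)


_DIRECTION_TOKENS = {"up": 1, "+1": 1, "1": 1, "down": -1, "-1": -1, "−1": -1}


def read_prior(path: str | Path) -> PriorKnowledge:
    """Read a prior-knowledge TSV with columns condition, node, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("condition", "node", "direction"):
        if col not in df.columns:
            raise ValueError(f"{path}: prior table missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        token = str(row["direction"]).strip().lower()
        if token not in _DIRECTION_TOKENS:
            raise ValueError(f"{path}: unknown direction token {row['direction']!r}")
        records.append(
            PriorRecord(str(row["condition"]), str(row["node"]), _DIRECTION_TOKENS[token])
        )
    return PriorKnowledge(records)


def write_profile(profile: TernaryProfile, path: str | Path) -> None:
    df = profile.values
    # write ternary states as integers, keep missing cells empty
    formatted = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t")


def read_profile(path: str | Path) -> TernaryProfile:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return TernaryProfile(df)
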