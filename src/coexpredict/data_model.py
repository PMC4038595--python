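"""Typed containers and TSV readers/writers for expression data.

File formats are deliberately plain: tab-separated text, UTF-8.  The
expression matrix has a header row whose first column is ``id`` followed by
sample identifiers; probe maps and source-value tables are two-column TSV
without headers.  Row identifiers are opaque strings — the same container
holds probe-level and gene-level matrices.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coexpredict._util import atomic_write

logger = logging.getLogger(__name__)


class DataModelError(ValueError):
    """Malformed input data (duplicate ids, non-numeric cells, bad shapes)."""


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataModelError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A rows-by-samples table of RMA-scale (log2 intensity) expression values.

    Parameters
    ----------
    row_ids
        Ordered probe/gene identifiers, unique.
    sample_ids
        Ordered sample (array) identifiers, unique.
    values
        Real matrix of shape ``(len(row_ids), len(sample_ids))``.  NaN is
        rejected unless ``allow_nan=True`` (pairwise-complete analyses only).
    """

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    allow_nan: bool = False
    _row_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataModelError("values must be a 2-D array")
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise DataModelError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.sample_ids, "sample")
        if np.isinf(self.values).any():
            raise DataModelError("expression values must be finite")
        if not self.allow_nan and np.isnan(self.values).any():
            raise DataModelError(
                "expression values contain NaN (pass allow_nan=True for "
                "pairwise-complete analyses)"
            )
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, row_id: str) -> np.ndarray:
        """Return the value vector for one row (view, do not mutate)."""
        try:
            return self.values[self._row_index[row_id]]
        except KeyError:
            raise DataModelError(f"unknown row id: {row_id!r}") from None

    def sample_column(self, sample_id: str) -> dict[str, float]:
        """Return one sample as a row-id -> value mapping."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise DataModelError(f"unknown sample id: {sample_id!r}") from None
        return dict(zip(self.row_ids, self.values[:, j]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.row_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, allow_nan: bool = False) -> "ExpressionMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            allow_nan=allow_nan,
        )

    def save(self, path: str | Path) -> None:
        save_expression_matrix(self, path)


def load_expression_matrix(path: str | Path, allow_nan: bool = False) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    The first header cell must be ``id``; remaining header cells are sample
    ids; each following line is a row id and its decimal values.  Errors name
    the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataModelError(f"cannot parse {path}: {exc}") from exc
    if frame.index.name != "id":
        raise DataModelError(
            f"{path}: first header column must be 'id', got {frame.index.name!r}"
        )
    if frame.shape[1] == 0:
        raise DataModelError(f"{path}: no sample columns")
    row_ids = [str(i) for i in frame.index]
    sample_ids = [str(c) for c in frame.columns]
    _check_unique(row_ids, "row")
    _check_unique(sample_ids, "sample")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DataModelError(
                    f"{path}: non-numeric value {cell!r} at row "
                    f"{row_ids[i]!r}, column {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(row_ids, sample_ids, values, allow_nan=allow_nan)


def save_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (round-trips exactly)."""
    with atomic_write(path) as handle:
        handle.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, row_id in enumerate(matrix.row_ids):
            cells = "\t".join(repr(float(v)) for v in matrix.values[i])
            handle.write(f"{row_id}\t{cells}\n")


@dataclass
class ProbeGeneMap:
    """Probe-id -> gene-id mapping; a gene may own several probes."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        self.pairs = {str(p): str(g) for p, g in self.pairs.items()}

    def genes(self) -> set[str]:
        return set(self.pairs.values())

    def probes_of(self, gene: str) -> list[str]:
        return sorted(p for p, g in self.pairs.items() if g == gene)

    @classmethod
    def load(cls, path: str | Path) -> "ProbeGeneMap":
        pairs: dict[str, str] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataModelError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                probe, gene = parts
                if probe in pairs and pairs[probe] != gene:
                    raise DataModelError(
                        f"{path}:{lineno}: probe {probe!r} mapped to both "
                        f"{pairs[probe]!r} and {gene!r}"
                    )
                pairs[probe] = gene
        return cls(pairs)

    def save(self, path: str | Path) -> None:
        with atomic_write(path) as handle:
            for probe in sorted(self.pairs):
                handle.write(f"{probe}\t{self.pairs[probe]}\n")


def duplicate_probe_genes(pmap: ProbeGeneMap) -> list[tuple[str, set[str]]]:
    """Genes represented by two or more probes, sorted by gene id.

    Returns ``[(gene_id, {probe ids}), ...]``; genes with a single probe are
    omitted.
    """
    by_gene: dict[str, set[str]] = {}
    for probe, gene in pmap.pairs.items():
        by_gene.setdefault(gene, set()).add(probe)
    return [(g, probes) for g, probes in sorted(by_gene.items()) if len(probes) >= 2]


@dataclass
class SourceValues:
    """Gene-id -> expression value (RMA scale) table, insertion-ordered.

    The order of entries matters for single-pass prediction tie-breaking, so
    it is preserved from the input file / constructor.
    """

    entries: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for gene, value in self.entries.items():
            value = float(value)
            if not math.isfinite(value):
                raise DataModelError(f"non-finite value for gene {gene!r}")
            if str(gene) in clean:
                raise DataModelError(f"duplicate gene id: {gene!r}")
            clean[str(gene)] = value
        self.entries = clean

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def __contains__(self, gene: object) -> bool:
        return gene in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def keys(self):
        return self.entries.keys()

    def values(self):
        return self.entries.values()

    @classmethod
    def load(cls, path: str | Path) -> "SourceValues":
        entries: dict[str, float] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataModelError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                gene, raw = parts
                if gene in entries:
                    raise DataModelError(f"{path}:{lineno}: duplicate gene {gene!r}")
                try:
                    entries[gene] = float(raw)
                except ValueError:
                    raise DataModelError(
                        f"{path}:{lineno}: non-numeric value {raw!r}"
                    ) from None
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with atomic_write(path) as handle:
            for gene, value in self.entries.items():
                handle.write(f"{gene}\t{value!r}\n")


def as_value_dict(values: "SourceValues | Mapping[str, float]") -> dict[str, float]:
    """Normalize SourceValues or any mapping to a plain insertion-ordered dict."""
    if isinstance(values, SourceValues):
        return dict(values.entries)
    return {str(k): float(v) for k, v in values.items()}
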