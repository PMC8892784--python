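"""Data model and file I/O for around-the-clock expression studies.

The study design encoded here is a 3-group comparison — control (``C``),
shift worker (``W``), and shift worker with restricted feeding (``WRF``) —
sampled every 4 h across the 24-h day (Zeitgeber times ZT1..ZT21) with three
animals per group and timepoint, i.e. 54 samples.  Sample identity is carried
in the column labels of the expression table using the ``<group><animal>ZT<h>``
convention (e.g. ``WRF42ZT13``), so a plain TSV of fpkm values is
self-describing.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("circaheart")

GROUPS = ("C", "W", "WRF")

_LABEL_RE = re.compile(r"^(WRF|C|W)(\d+)ZT(\d+)$")


class ParseError(ValueError):
    """Raised when a sample label or input table cannot be parsed."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one animal/sample.

    ``replicate_index`` is not part of the label; it is assigned by ranking
    animal IDs within each (group, ZT) cell and is 1-based.
    """

    group: str
    animal_id: int
    zt: float
    replicate_index: int = 0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.animal_id <= 0:
            raise ValueError(f"animal_id must be positive, got {self.animal_id}")
        if not (0 <= self.zt < 24):
            raise ValueError(f"zt must lie in [0, 24), got {self.zt}")

    @property
    def label(self) -> str:
        return format_sample_label(self)


def parse_sample_label(label: str) -> SampleMeta:
    """Parse ``<group><animal>ZT<hour>`` into a :class:`SampleMeta`.

    >>> parse_sample_label("WRF42ZT13")
    SampleMeta(group='WRF', animal_id=42, zt=13.0, replicate_index=0)
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        # Identify the offending token for the error message.
        g = re.match(r"^([A-Za-z]+)", label.strip())
        token = g.group(1) if g else label
        raise ParseError(
            f"malformed sample label {label!r}: token {token!r} does not match "
            f"<GROUP><animal>ZT<hour> with GROUP in {GROUPS}"
        )
    group, animal, zt = m.group(1), int(m.group(2)), float(m.group(3))
    if not (0 <= zt < 24):
        raise ParseError(f"malformed sample label {label!r}: ZT hour {zt:g} outside [0, 24)")
    if animal <= 0:
        raise ParseError(f"malformed sample label {label!r}: animal id must be positive")
    return SampleMeta(group=group, animal_id=animal, zt=zt)


def format_sample_label(meta: SampleMeta) -> str:
    return f"{meta.group}{meta.animal_id}ZT{meta.zt:g}"


def assign_replicates(samples: Sequence[SampleMeta]) -> list[SampleMeta]:
    """Assign 1-based replicate indices within each (group, ZT) cell.

    Animals are ranked by ID so the assignment is deterministic; duplicate
    (group, animal) pairs are rejected.
    """
    seen = set()
    for s in samples:
        key = (s.group, s.animal_id)
        if key in seen:
            raise ValueError(f"duplicate animal {s.group}{s.animal_id} in sample set")
        seen.add(key)
    by_cell: dict[tuple, list[int]] = {}
    for i, s in enumerate(samples):
        by_cell.setdefault((s.group, s.zt), []).append(i)
    out = list(samples)
    for idxs in by_cell.values():
        for rank, i in enumerate(sorted(idxs, key=lambda j: samples[j].animal_id), start=1):
            s = samples[i]
            out[i] = SampleMeta(s.group, s.animal_id, s.zt, rank)
    return out


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid (fpkm scale) with sample metadata.

    ``data`` is a DataFrame indexed by gene ID whose columns are the sample
    labels, kept in file order.  Values are stored as given; no
    re-normalisation is applied anywhere downstream.
    """

    data: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self):
        if len(self.samples) != self.data.shape[1]:
            raise ValueError(
                f"{self.data.shape[1]} value columns but {len(self.samples)} sample records"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.any(vals < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.samples],
                "group": [s.group for s in self.samples],
                "animal_id": [s.animal_id for s in self.samples],
                "zt": [s.zt for s in self.samples],
                "replicate_index": [s.replicate_index for s in self.samples],
            }
        )

    def groups(self) -> list[str]:
        return sorted({s.group for s in self.samples}, key=GROUPS.index)

    def group_columns(self, group: str) -> list[int]:
        cols = [i for i, s in enumerate(self.samples) if s.group == group]
        if not cols:
            raise KeyError(f"group {group!r} absent from matrix")
        return cols

    def group_series(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) for one group: times (n,) and values (genes, n)."""
        cols = self.group_columns(group)
        times = np.array([self.samples[i].zt for i in cols], dtype=float)
        return times, self.values[:, cols]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], list(self.samples))


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV of genes (rows) x samples (columns; headers are labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene ID(s): {dupes[:5]}")
    samples = [parse_sample_label(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's str->float conversion is correctly rounded (exact round-trip)
            values[:, j] = df[col].to_numpy(dtype="U").astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(f"{path}: non-numeric value at gene {bad!r}, column {col!r}")
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(f"{path}: missing value at gene {df.index[i]!r}, column {df.columns[j]!r}")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(f"{path}: negative value at gene {df.index[i]!r}, column {df.columns[j]!r}")
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = df.index.name or "gene_id"
    logger.info("read %d genes x %d samples from %s", out.shape[0], out.shape[1], path)
    return ExpressionMatrix(out, assign_replicates(samples))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix back to TSV; read -> write round-trips values exactly."""
    df = matrix.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class ModuleSet:
    """Catalog of named, disjointly-intended gene modules with a null module.

    The null module (``M0`` by convention) collects genes unaffected by the
    disease process and serves as the reference for enrichment and
    distribution-shift tests.
    """

    modules: dict[str, frozenset[str]]
    null_module_id: str = "M0"

    def __post_init__(self):
        if self.null_module_id not in self.modules:
            raise ValueError(f"null module {self.null_module_id!r} missing from catalog")
        for mid, genes in self.modules.items():
            if not genes:
                raise ValueError(f"module {mid!r} is empty")
        self.modules = {k: frozenset(v) for k, v in self.modules.items()}

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    def __getitem__(self, mid: str) -> frozenset[str]:
        return self.modules[mid]

    def __len__(self) -> int:
        return len(self.modules)


@dataclass
class GeneSetPair:
    """Disease up/down gene lists (e.g. from ICM or DCM failing-heart cohorts)."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    label: str = ""

    def __post_init__(self):
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(f"up/down gene sets overlap: {sorted(overlap)[:5]}")


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read named gene sets from a 2-column TSV (set_id, gene_id) or GMT file.

    GMT lines are ``set_id<TAB>description<TAB>gene1<TAB>gene2...``; a file
    whose every line has exactly two fields is treated as the 2-column format.
    Duplicate members are collapsed; empty files and empty sets are rejected.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: no gene sets found (empty file)")
    rows = [ln.split("\t") for ln in lines]
    sets: dict[str, set[str]] = {}
    if all(len(r) == 2 for r in rows):
        for set_id, gene in rows:
            sets.setdefault(set_id, set()).add(gene)
    else:  # GMT
        for r in rows:
            if len(r) < 3:
                raise ParseError(f"{path}: GMT line for {r[0]!r} has no members")
            sets.setdefault(r[0], set()).update(g for g in r[2:] if g)
    for sid, members in sets.items():
        if not members:
            raise ParseError(f"{path}: set {sid!r} is empty")
    return {k: frozenset(v) for k, v in sets.items()}


def read_module_set(path: str | Path, null_module_id: str = "M0") -> ModuleSet:
    sets = read_gene_sets(path)
    if null_module_id not in sets:
        raise ParseError(f"{path}: null module {null_module_id!r} not present")
    return ModuleSet(dict(sets), null_module_id=null_module_id)


def read_gene_set_pair(path: str | Path, label: str = "",
                       up_id: str = "up", down_id: str = "down") -> GeneSetPair:
    sets = read_gene_sets(path)
    missing = [k for k in (up_id, down_id) if k not in sets]
    if missing:
        raise ParseError(f"{path}: expected sets named {missing} for an up/down pair")
    return GeneSetPair(sets[up_id], sets[down_id], label=label or Path(path).stem)


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write named gene sets as a sorted 2-column TSV (deterministic)."""
    with open(path, "w") as fh:
        for sid in sorted(sets):
            for gene in sorted(sets[sid]):
                fh.write(f"{sid}\t{gene}\n")


def write_manifest(path: str | Path, seed: int | None, parameters: Mapping) -> None:
    """Write a JSON run-manifest with package version, seed, and parameters."""
    from . import __version__

    manifest = {
        "package": "circaheart",
        "version": __version__,
        "seed": seed,
        "parameters": _jsonable(parameters),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in (sorted(obj) if isinstance(obj, (set, frozenset)) else obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else (logging.ERROR if quiet else logging.INFO)
    logging.basicConfig(level=level, stream=None, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
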