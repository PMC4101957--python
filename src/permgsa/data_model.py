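"""Domain types and I/O for expression matrices and gene set collections.

The canonical on-disk layout ("mavtn") is a delimited text matrix with
samples in columns: the first row carries the experimental condition (or a
continuous phenotype value) for each sample, and every following row is
``geneID<delim>value<delim>value...``.  GCT v1.2 + CLS and GMT readers are
provided for interoperability with the Broad file formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Phenotype",
    "ExpressionDataset",
    "GeneSetCollection",
    "ValidationReport",
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "validate",
    "clean",
]


@dataclass
class Phenotype:
    """Per-sample outcome: categorical group labels or a continuous value.

    For categorical phenotypes, ``groups`` preserves order of first
    appearance in the sample row; the first group is the reference used by
    Dunnett-style comparisons.
    """

    kind: str  # "categorical" | "continuous"
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        self.labels = np.asarray(self.labels)
        if self.kind == "categorical":
            self.labels = self.labels.astype(str)
            if len(self.groups) < 2:
                raise ValueError("categorical phenotype needs at least 2 groups")
            bad = [g for g, n in zip(self.groups, self.group_counts) if n < 2]
            if bad:
                raise ValueError(f"groups with fewer than 2 samples: {bad}")
        else:
            self.labels = self.labels.astype(float)
            if not np.all(np.isfinite(self.labels)):
                raise ValueError("continuous phenotype contains non-finite values")
            if len(np.unique(self.labels)) < 3:
                raise ValueError("continuous phenotype needs at least 3 distinct values")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def groups(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab))
        return list(seen)

    @property
    def group_counts(self) -> list[int]:
        labs = list(map(str, self.labels))
        return [labs.count(g) for g in self.groups]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def reference_group(self) -> str:
        if self.kind != "categorical":
            raise ValueError("reference group is defined only for categorical phenotypes")
        return self.groups[0]

    def group_indices(self) -> dict[str, np.ndarray]:
        labs = np.asarray([str(x) for x in self.labels])
        return {g: np.flatnonzero(labs == g) for g in self.groups}


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with one phenotype per sample."""

    values: np.ndarray  # (m_total, N)
    gene_ids: list[str]
    sample_ids: list[str]
    phenotype: Phenotype

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if n != len(self.sample_ids) or n != len(self.phenotype):
            raise ValueError("column count does not match samples/phenotype length")
        if len(set(self.gene_ids)) != m:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            self.sample_ids,
            self.phenotype,
        )


@dataclass
class GeneSetCollection:
    """Named binary memberships over a fixed gene universe (genes x sets)."""

    set_names: list[str]
    membership: np.ndarray  # (m_total, n_sets) of {0,1}

    def __post_init__(self) -> None:
        self.set_names = list(map(str, self.set_names))
        self.membership = np.asarray(self.membership)
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("membership matrix entries must be 0 or 1")
        self.membership = self.membership.astype(np.int8)
        if self.membership.ndim != 2 or self.membership.shape[1] != len(self.set_names):
            raise ValueError("membership shape does not match set names")
        small = [n for n, s in zip(self.set_names, self.sizes) if s < 2]
        if small:
            raise ValueError(f"gene sets must contain at least 2 genes: {small}")
        if not self.set_names:
            raise ValueError("empty gene set collection")

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def sizes(self) -> np.ndarray:
        return self.membership.sum(axis=0).astype(int)

    def members(self, name_or_idx) -> np.ndarray:
        """Row indices (into the gene universe) of one set's genes."""
        j = name_or_idx if isinstance(name_or_idx, (int, np.integer)) else self.set_names.index(name_or_idx)
        return np.flatnonzero(self.membership[:, j])


@dataclass
class ValidationReport:
    dropped_zero_variance_genes: list[str] = field(default_factory=list)
    dropped_small_sets: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.dropped_zero_variance_genes or self.dropped_small_sets or self.warnings)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def _split(line: str, delim) -> list[str]:
    return line.rstrip("\r\n").split(delim) if delim else line.split()


def _looks_categorical(tokens: list[str]) -> bool:
    """Auto rule: <= 10 distinct integer-like labels, every count >= 2."""
    distinct: dict[str, int] = {}
    for t in tokens:
        try:
            f = float(t)
            if f != int(f):
                return False
            key = str(int(f))
        except ValueError:
            key = t
        distinct[key] = distinct.get(key, 0) + 1
    return len(distinct) <= 10 and all(v >= 2 for v in distinct.values())


def _canon_labels(tokens: list[str]) -> list[str]:
    """Collapse '1.0' and '1' to the same categorical label."""
    out = []
    for t in tokens:
        try:
            f = float(t)
            out.append(str(int(f)) if f == int(f) else t)
        except ValueError:
            out.append(t)
    return out


def read_expression_table(
    path,
    layout: str = "mavtn",
    phenotype_kind: str = "auto",
) -> ExpressionDataset:
    """Read an expression matrix with its phenotype row.

    Parameters
    ----------
    path
        Delimited text file.  For ``layout="gct_cls"`` this is the GCT file;
        a companion ``.cls`` file with the same stem must sit next to it (or
        pass a tuple ``(gct_path, cls_path)``).
    layout
        ``"mavtn"`` (phenotype in row 1) or ``"gct_cls"``.
    phenotype_kind
        ``"categorical"``, ``"continuous"`` or ``"auto"``.
    """
    if layout == "gct_cls":
        if isinstance(path, tuple):
            gct_path, cls_path = map(Path, path)
        else:
            gct_path = Path(path)
            cls_path = gct_path.with_suffix(".cls")
        return _read_gct(gct_path, cls_path, phenotype_kind)
    if layout != "mavtn":
        raise ValueError(f"unknown layout {layout!r}")

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError("expression file needs a phenotype row and at least one gene row")
    delim = _sniff_delimiter(lines[0])
    gene_rows = [_split(ln, delim) for ln in lines[1:]]
    n = len(gene_rows[0]) - 1
    pheno_tokens = _split(lines[0], delim)
    if len(pheno_tokens) == n + 1:
        pheno_tokens = pheno_tokens[1:]  # leading label cell
    elif len(pheno_tokens) != n:
        raise ValueError(
            f"phenotype row has {len(pheno_tokens)} entries but gene rows imply {n} samples"
        )

    gene_ids, values = [], []
    for r, row in enumerate(gene_rows, start=2):
        if len(row) != n + 1:
            raise ValueError(f"row {r}: expected {n + 1} fields, got {len(row)}")
        gene_ids.append(row[0])
        vals = []
        for c, tok in enumerate(row[1:], start=2):
            try:
                vals.append(float(tok))
            except ValueError:
                raise ValueError(f"malformed numeric cell at row {r}, column {c}: {tok!r}") from None
        values.append(vals)

    phenotype = _build_phenotype(pheno_tokens, phenotype_kind)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    return ExpressionDataset(np.array(values), gene_ids, sample_ids, phenotype)


def _build_phenotype(tokens: list[str], kind: str) -> Phenotype:
    if kind == "auto":
        kind = "categorical" if _looks_categorical(tokens) else "continuous"
    if kind == "categorical":
        return Phenotype("categorical", np.array(_canon_labels(tokens)))
    try:
        vals = np.array([float(t) for t in tokens])
    except ValueError as e:
        raise ValueError(f"continuous phenotype has non-numeric entries: {e}") from None
    return Phenotype("continuous", vals)


def _read_gct(gct_path: Path, cls_path: Path, phenotype_kind: str) -> ExpressionDataset:
    lines = [ln for ln in gct_path.read_text().splitlines() if ln.strip()]
    if not lines[0].startswith("#1.2"):
        raise ValueError("GCT file must start with the #1.2 version line")
    m, n = map(int, lines[1].split()[:2])
    header = lines[2].split("\t")
    sample_ids = header[2:]
    if len(sample_ids) != n:
        raise ValueError("GCT header sample count does not match declared size")
    gene_ids, values = [], []
    for r, ln in enumerate(lines[3 : 3 + m], start=4):
        parts = ln.split("\t")
        gene_ids.append(parts[0])
        try:
            values.append([float(t) for t in parts[2:]])
        except ValueError as e:
            raise ValueError(f"malformed numeric cell in GCT row {r}: {e}") from None
    phenotype = _read_cls(cls_path, phenotype_kind)
    return ExpressionDataset(np.array(values), gene_ids, sample_ids, phenotype)


def _read_cls(cls_path: Path, phenotype_kind: str) -> Phenotype:
    lines = [ln for ln in Path(cls_path).read_text().splitlines() if ln.strip()]
    if lines[0].strip().lower().startswith("#numeric"):
        vals = [float(t) for t in lines[-1].split()]
        return Phenotype("continuous", np.array(vals))
    # categorical CLS: "<N> <k> 1" / "# name1 name2" / per-sample labels
    n, k = map(int, lines[0].split()[:2])
    names = lines[1].lstrip("#").split()
    tokens = lines[2].split()
    if len(tokens) != n:
        raise ValueError("CLS label row length does not match declared sample count")
    # labels may be 0-based indices into the name line, or the names themselves
    if all(t.isdigit() for t in tokens) and len(names) == k:
        order: dict[str, str] = {}
        for t in tokens:
            order.setdefault(t, names[int(t)] if int(t) < len(names) else t)
        tokens = [order[t] for t in tokens]
    if phenotype_kind == "continuous":
        raise ValueError("categorical CLS file cannot supply a continuous phenotype")
    return Phenotype("categorical", np.array(tokens))


def write_expression_table(data: ExpressionDataset, path, delimiter: str = "\t") -> None:
    """Write in mavtn layout; ``read_expression_table`` round-trips it."""
    with open(path, "w") as fh:
        labels = data.phenotype.labels
        if data.phenotype.kind == "continuous":
            row = delimiter.join(repr(float(v)) for v in labels)
        else:
            row = delimiter.join(map(str, labels))
        fh.write("phenotype" + delimiter + row + "\n")
        for gid, vals in zip(data.gene_ids, data.values):
            fh.write(gid + delimiter + delimiter.join(repr(float(v)) for v in vals) + "\n")


def read_gene_sets(path, format: str = "binary_matrix", universe: list[str] | None = None) -> GeneSetCollection:
    """Read gene sets as a 0/1 matrix or a GMT file, aligned to ``universe``.

    GMT genes absent from the universe are dropped with a warning; sets left
    with fewer than 2 genes are dropped and reported.
    """
    if format == "binary_matrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if universe is not None:
            if list(df.index) != list(universe):
                if set(df.index) == set(universe):
                    df = df.loc[list(universe)]
                else:
                    raise ValueError("gene set matrix rows do not match the gene universe")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary gene set matrix has entries outside {0,1}")
        return GeneSetCollection(list(df.columns), vals)

    if format != "gmt":
        raise ValueError(f"unknown gene set format {format!r}")
    if universe is None:
        raise ValueError("GMT reading requires the gene universe")
    pos = {g: i for i, g in enumerate(universe)}
    names, cols = [], []
    dropped: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs name, description and genes: {ln[:40]!r}")
        name, genes = parts[0], parts[2:]
        col = np.zeros(len(universe), dtype=np.int8)
        missing = []
        for g in genes:
            if g in pos:
                col[pos[g]] = 1
            else:
                missing.append(g)
        if missing:
            warnings.warn(f"set {name}: {len(missing)} gene(s) not in universe", stacklevel=2)
        if col.sum() < 2:
            dropped.append(name)
            continue
        names.append(name)
        cols.append(col)
    if not names:
        raise ValueError("no gene sets left after matching to the universe")
    gsc = GeneSetCollection(names, np.column_stack(cols))
    if dropped:
        warnings.warn(f"dropped sets with <2 matched genes: {dropped}", stacklevel=2)
    return gsc


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _zero_variance_mask(data: ExpressionDataset) -> np.ndarray:
    ph = data.phenotype
    if ph.kind == "categorical":
        pooled_ss = np.zeros(data.n_genes)
        for idx in ph.group_indices().values():
            sub = data.values[:, idx]
            pooled_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        return pooled_ss == 0.0
    return data.values.var(axis=1) == 0.0


def validate(data: ExpressionDataset, sets: GeneSetCollection) -> ValidationReport:
    """Report zero-variance genes and the sets that removing them would break.

    Zero variance means pooled within-group variance exactly 0 (categorical)
    or overall variance 0 (continuous).  Report-only; use :func:`clean` to
    apply the drops.
    """
    if sets.membership.shape[0] != data.n_genes:
        raise ValueError(
            f"gene set universe size {sets.membership.shape[0]} does not match "
            f"dataset gene count {data.n_genes}"
        )
    rep = ValidationReport()
    zv = _zero_variance_mask(data)
    rep.dropped_zero_variance_genes = [g for g, z in zip(data.gene_ids, zv) if z]
    if rep.dropped_zero_variance_genes:
        rep.warnings.append(
            f"{len(rep.dropped_zero_variance_genes)} gene(s) with zero variance dropped"
        )
        surviving_sizes = sets.membership[~zv].sum(axis=0)
        rep.dropped_small_sets = [
            n for n, s in zip(sets.set_names, surviving_sizes) if s < 2
        ]
        if rep.dropped_small_sets:
            rep.warnings.append(
                f"{len(rep.dropped_small_sets)} set(s) fell below 2 genes after cleaning"
            )
    return rep


def clean(
    data: ExpressionDataset, sets: GeneSetCollection
) -> tuple[ExpressionDataset, GeneSetCollection, ValidationReport]:
    """Apply :func:`validate`'s drops, returning cleaned copies + the report."""
    rep = validate(data, sets)
    if not rep.dropped_zero_variance_genes:
        return data, sets, rep
    keep_genes = np.array([g not in set(rep.dropped_zero_variance_genes) for g in data.gene_ids])
    keep_sets = [n not in set(rep.dropped_small_sets) for n in sets.set_names]
    new_data = data.subset_genes(np.flatnonzero(keep_genes))
    new_sets = GeneSetCollection(
        [n for n, k in zip(sets.set_names, keep_sets) if k],
        sets.membership[np.ix_(keep_genes, np.asarray(keep_sets))],
    )
    return new_data, new_sets, rep
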