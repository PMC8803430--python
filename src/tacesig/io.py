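"""Reading, collapsing and normalising expression matrices and related inputs.

The on-disk dialect is plain tab-delimited text throughout: expression
matrices are genes (or probes) x samples with row ids in the first column
and sample ids in the header; gene sets use the standard GMT layout; probe
maps, stemness weight vectors and cell-type signature matrices are small
TSV tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: marker for probes mapping to more than one gene
AMBIGUOUS = "__ambiguous__"
#: marker for probes with no gene annotation
UNMAPPED = "__unmapped__"


@dataclass
class ExpressionMatrix:
    """Genes (or probes) x samples matrix of log-scale intensities or z-scores.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene/probe id, columns by sample id. All cells must
        be finite.
    scale_tag : {"raw_log", "zscore", "linear"}
        Whether rows carry log2 intensities, per-gene z-scores, or linear
        (un-logged) intensities as produced by mixing.
    """

    values: pd.DataFrame
    scale_tag: str = "raw_log"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("raw_log", "zscore", "linear"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved); missing genes are an error."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.scale_tag)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: name -> unique gene symbols)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix.

    First column holds row ids, first row holds sample ids; every remaining
    cell must parse as a number. Non-numeric cells are reported with their
    row and column label.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for s in header:
        if s in seen:
            raise ValueError(f"duplicate sample id {s!r} in {path}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    try:
        num = df.astype(float)
    except ValueError:
        for row, col in ((r, c) for r in df.index for c in df.columns):
            try:
                float(df.at[row, col])
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {df.at[row, col]!r} at row {row!r}, "
                    f"column {col!r} in {path}"
                ) from None
        raise  # pragma: no cover - unreachable
    return ExpressionMatrix(num, scale_tag="raw_log")


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write the tab-delimited dialect read back by :func:`read_matrix`.

    Floats are written with ``repr`` precision so a read/write cycle is
    lossless.
    """
    m.values.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probe -> gene TSV.

    A blank/missing gene field marks the probe unmapped; a probe listed with
    several distinct genes (or a ``///``-joined field) is marked ambiguous.
    """
    out: dict[str, str] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["probe", "gene"], dtype=str,
        keep_default_na=False,
    )
    if df["probe"].duplicated().any():
        for probe, grp in df.groupby("probe", sort=False):
            genes = set(grp["gene"])
            if len(genes) > 1:
                out[probe] = AMBIGUOUS
            else:
                out[probe] = _classify_gene(genes.pop())
        return out
    for probe, gene in zip(df["probe"], df["gene"]):
        out[probe] = _classify_gene(gene)
    return out


def _classify_gene(gene: str) -> str:
    gene = gene.strip()
    if not gene:
        return UNMAPPED
    if "///" in gene:
        return AMBIGUOUS
    return gene


def collapse_probes(m: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Ambiguous and unmapped probes are dropped. When several probes map to
    one gene, the probe with the maximal mean expression across all samples
    is kept; ties are broken toward the lexicographically smallest probe id.
    """
    means = m.values.mean(axis=1)
    best: dict[str, str] = {}  # gene -> probe
    n_dropped = 0
    for probe in m.values.index:
        gene = probe_map.get(probe, UNMAPPED)
        if gene in (AMBIGUOUS, UNMAPPED):
            n_dropped += 1
            continue
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    if not best:
        raise ValueError("no probe maps to a gene; nothing to collapse")
    if n_dropped:
        logger.info("collapse_probes: dropped %d ambiguous/unmapped probes", n_dropped)
    genes = sorted(best)
    collapsed = m.values.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name=m.values.index.name)
    return ExpressionMatrix(collapsed, scale_tag=m.scale_tag)


def zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (sample SD, denominator n-1).

    Constant genes have no defined z-score and are dropped with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    vals = m.values
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any():
        dropped = vals.index[constant].tolist()
        warnings.warn(
            f"zscore: dropping {len(dropped)} constant gene(s): {dropped[:5]}",
            stacklevel=2,
        )
        vals = vals.loc[~constant]
        sd = sd.loc[~constant]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, scale_tag="zscore")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, genes; tab-delimited).

    The description field is discarded; duplicate genes within one set are
    de-duplicated preserving first occurrence; a duplicated set name is an
    error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_weights(path) -> pd.Series:
    """Read a two-column gene -> weight TSV into a float Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in weight file {path}")
    return pd.Series(df["weight"].to_numpy(float), index=df["gene"], name="weight")


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a marker-genes x cell-types signature matrix (nonnegative TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"duplicate genes or cell types in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative entries in signature matrix {path}")
    if (df.to_numpy() == 0).all(axis=0).any():
        raise ValueError(f"all-zero cell-type column in {path}")
    return df


def read_labels(path) -> pd.Series:
    """Read a two-column sample -> label TSV (labels 0=response, 1=nonresponse)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    labels = df["label"].astype(int)
    if not set(labels.unique()) <= {0, 1}:
        raise ValueError(f"labels must be 0/1 in {path}")
    return pd.Series(labels.to_numpy(), index=df["sample"], name="label")


def write_labels(labels: pd.Series, path) -> None:
    labels.to_csv(path, sep="\t", header=False)
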