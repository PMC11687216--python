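"""Reading, writing and manipulating OTU tables, sample metadata and trees.

The three standard inputs of the pipeline are

* an OTU count table (TSV, OTUs x samples, first header cell ``#OTU_ID``),
* a rooted phylogenetic tree (newick, branch lengths mandatory) whose tip
  labels are OTU ids,
* a sample metadata table (TSV) with season / layer / nucleic-acid fraction,
  coordinates, salinity and any number of additional numeric environmental
  variables.

Rarefaction (subsampling without replacement to a common depth) and its
bootstrap variant live here because every downstream analysis consumes
rarefied tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "RarefiedEnsemble",
    "ValidationError",
    "HABITAT_LABELS",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "read_metadata",
    "rarefy",
    "bootstrap_rarefy",
    "top_n_subcommunity",
    "classify_habitat",
    "observed_richness",
]


class ValidationError(ValueError):
    """An input violates a structural contract (ids, signs, shapes)."""


# Venice System salinity classes. Interior breakpoints are left-closed
# ([0.5, 5), [5, 18)); 30 belongs to polyhaline so that "marine" is
# strictly > 30.
HABITAT_LABELS = ("freshwater", "oligohaline", "mesohaline", "polyhaline", "marine")
_DEFAULT_BREAKPOINTS = (0.5, 5.0, 18.0, 30.0)


class OtuTable:
    """A validated OTU-by-sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : array-like of shape (n_otus, n_samples)
        Non-negative integers.
    otu_ids, sample_ids : sequences of unique str
    """

    def __init__(self, counts, otu_ids, sample_ids, validate: bool = True):
        counts = np.asarray(counts)
        otu_ids = [str(o) for o in otu_ids]
        sample_ids = [str(s) for s in sample_ids]
        if validate:
            self._validate(counts, otu_ids, sample_ids)
        self.counts = counts.astype(np.int64)
        self.otu_ids = otu_ids
        self.sample_ids = sample_ids
        self._otu_index = {o: i for i, o in enumerate(otu_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    @staticmethod
    def _validate(counts, otu_ids, sample_ids) -> None:
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(otu_ids), len(sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(otu_ids)} OTUs x {len(sample_ids)} samples"
            )
        if len(set(otu_ids)) != len(otu_ids):
            dup = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
            raise ValidationError(f"duplicate OTU ids: {dup}")
        if len(set(sample_ids)) != len(sample_ids):
            dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        if not np.issubdtype(counts.dtype, np.integer):
            frac = np.asarray(counts, dtype=float)
            bad = np.argwhere(frac != np.floor(frac))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}"
                )
        neg = np.argwhere(np.asarray(counts, dtype=float) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        colsums = np.asarray(counts, dtype=float).sum(axis=0)
        if np.any(colsums == 0):
            empty = [sample_ids[j] for j in np.flatnonzero(colsums == 0)]
            warnings.warn(f"samples with zero total reads: {empty}", stacklevel=3)

    # -- basic properties -------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised counts (each sample sums to 1)."""
        sums = self.sample_sums.astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def occupancy(self) -> np.ndarray:
        """Number of samples occupied, per OTU."""
        return (self.counts > 0).sum(axis=1)

    # -- conversions ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "OtuTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns), validate=validate)

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self._otu_index[o] for o in otu_ids]
        return OtuTable(self.counts[idx], list(otu_ids), self.sample_ids, validate=False)

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(self.counts[:, idx], self.otu_ids, list(sample_ids), validate=False)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(
            self.counts[keep],
            [o for o, k in zip(self.otu_ids, keep) if k],
            self.sample_ids,
            validate=False,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples)"


@dataclass
class SampleMetadata:
    """Per-sample metadata: design factors, coordinates and environment.

    ``frame`` is indexed by sample id and carries the mandatory columns
    season, layer, fraction, latitude, longitude, salinity; every additional
    numeric column is treated as an environmental variable. Salinity is
    itself an environmental variable.
    """

    frame: pd.DataFrame
    env_variables: list = field(default_factory=list)

    MANDATORY = ("season", "layer", "fraction", "latitude", "longitude", "salinity")

    def __post_init__(self):
        missing = [c for c in self.MANDATORY if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing mandatory columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        if not self.env_variables:
            extras = [
                c
                for c in self.frame.columns
                if c not in ("season", "layer", "fraction", "latitude", "longitude")
                and pd.api.types.is_numeric_dtype(self.frame[c])
            ]
            self.env_variables = extras  # salinity included
        envs = self.frame[self.env_variables]
        if not np.all(np.isfinite(envs.to_numpy(dtype=float))):
            bad = envs.columns[envs.isna().any() | ~np.isfinite(envs).all()].tolist()
            raise ValidationError(f"non-finite environmental values in {bad}")
        if (self.frame["salinity"] < 0).any():
            raise ValidationError("negative salinity in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def require_samples(self, sample_ids) -> None:
        """Hard error if any table sample lacks a metadata row."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    def aligned(self, sample_ids) -> "SampleMetadata":
        self.require_samples(sample_ids)
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy(), list(self.env_variables))

    def env_matrix(self, variables=None) -> pd.DataFrame:
        return self.frame[list(variables or self.env_variables)].astype(float)


@dataclass
class RarefiedEnsemble:
    """Bootstrap collection of rarefied tables sharing one depth and seed."""

    depth: int
    n_boot: int
    tables: list
    seed: int

    def __post_init__(self):
        if self.n_boot < 1 or len(self.tables) != self.n_boot:
            raise ValidationError("n_boot must be >= 1 and match len(tables)")
        for t in self.tables:
            if not np.all(t.sample_sums == self.depth):
                raise ValidationError("ensemble table column sums != depth")

    def __iter__(self):
        return iter(self.tables)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a tab-separated OTU table and normalise to OTUs x samples."""
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_as_rows":
        df = df.T
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric cells in OTU table {path}")
    return OtuTable.from_dataframe(df)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every edge must carry a branch length."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            label = node.name or "internal node"
            raise ValidationError(f"edge above {label!r} lacks a branch length")
        if node.length < 0:
            raise ValidationError(f"negative branch length above {node.name!r}")
    return tree


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, boot: int, sample_idx: int) -> np.random.Generator:
    # counter-based splitting: (boot, sample) sub-streams are independent of
    # iteration order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(boot, sample_idx)))


def rarefy(table: OtuTable, depth: int, seed: int, _boot: int = 0) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Multivariate-hypergeometric draw per sample; the same (seed, sample)
    pair always yields the same subsample regardless of evaluation order.
    """
    depth = int(depth)
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    sums = table.sample_sums
    shallow = [s for s, n in zip(table.sample_ids, sums) if n < depth]
    if shallow:
        raise ValidationError(f"samples shallower than depth {depth}: {shallow}")
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        rng = _sample_rng(seed, _boot, j)
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return OtuTable(out, table.otu_ids, table.sample_ids, validate=False)


def bootstrap_rarefy(table: OtuTable, depth: int, n_boot: int, seed: int) -> RarefiedEnsemble:
    """``n_boot`` independent rarefactions with deterministically derived sub-seeds."""
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    tables = [rarefy(table, depth, seed, _boot=b) for b in range(n_boot)]
    return RarefiedEnsemble(depth=int(depth), n_boot=int(n_boot), tables=tables, seed=int(seed))


# ---------------------------------------------------------------------------
# table manipulations
# ---------------------------------------------------------------------------

def top_n_subcommunity(table: OtuTable, n: int) -> OtuTable:
    """Keep the ``n`` OTUs with the largest summed relative abundance.

    Ranking uses relative (not raw) abundance so unequal library sizes do
    not bias it; ties break lexicographically on OTU id.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if table.n_otus <= n:
        return table
    score = table.relative_abundance().sum(axis=1)
    order = sorted(range(table.n_otus), key=lambda i: (-score[i], table.otu_ids[i]))
    keep = sorted(order[:n])  # preserve original row order
    return OtuTable(
        table.counts[keep],
        [table.otu_ids[i] for i in keep],
        table.sample_ids,
        validate=False,
    )


def classify_habitat(salinity: float, breakpoints=_DEFAULT_BREAKPOINTS) -> str:
    """Venice System habitat class for a salinity value.

    freshwater [0, 0.5), oligohaline [0.5, 5), mesohaline [5, 18),
    polyhaline [18, 30], marine (30, inf).
    """
    s = float(salinity)
    if not np.isfinite(s) or s < 0:
        raise ValidationError(f"salinity must be finite and >= 0, got {salinity}")
    b1, b2, b3, b4 = breakpoints
    if s < b1:
        return "freshwater"
    if s < b2:
        return "oligohaline"
    if s < b3:
        return "mesohaline"
    if s <= b4:
        return "polyhaline"
    return "marine"


def observed_richness(table: OtuTable) -> dict:
    """Number of OTUs with count > 0, per sample."""
    rich = (table.counts > 0).sum(axis=0)
    return {s: int(r) for s, r in zip(table.sample_ids, rich)}
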