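"""Count-table data model and table-level preprocessing.

The central object is :class:`OtuTable`, a thin wrapper around a pandas
DataFrame holding integer read counts with samples as rows and OTUs
(operational taxonomic units, 16S clusters at a fixed identity threshold)
as columns.  A *relative* variant holds per-sample proportions instead of
counts; operations that only make sense on integer counts (rarefaction,
low-count filtering) reject relative tables.

On disk an OTU table is a TSV with OTUs as rows: the first column header is
``otu_id``, the remaining headers are sample ids, and cells are integer
read counts.  Sample metadata is a TSV with columns ``sample_id``,
``source`` (rumen / plate / cohort), ``medium`` (defined / undefined /
none), ``dilution_exponent`` (d means the sample was diluted 10^-d; 0 is
the undiluted sample) and ``replicate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SOURCES = ("rumen", "plate", "cohort")
MEDIA = ("defined", "undefined", "none")

#: Canonical lineage ranks for the taxonomy TSV (species optional).
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_FAMILY_RANK_INDEX = 4

_UNASSIGNED = {"", "unassigned", "unclassified", "na", "none"}


class OtuTable:
    """Samples-by-OTUs count matrix with unique sample and OTU identifiers.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with OTU ids as columns.  Counts
        must be nonnegative; integral unless ``relative`` is True.
    relative:
        If True, rows are proportions: each row sums to 1 (within 1e-9)
        or is all zero.
    """

    def __init__(self, data: pd.DataFrame, relative: bool = False, validate: bool = True):
        self.data = data
        self.relative = relative
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            s, o = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[s]!r}, OTU {df.columns[o]!r}"
            )
        if not self.relative:
            if values.size and not np.issubdtype(values.dtype, np.integer):
                frac = values != np.floor(values)
                if frac.any():
                    s, o = np.argwhere(frac)[0]
                    raise ValueError(
                        f"non-integer count at sample {df.index[s]!r}, "
                        f"OTU {df.columns[o]!r}"
                    )
                self.data = df.astype(np.int64)
        else:
            sums = values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
            if bad.any():
                raise ValueError(
                    f"relative table rows must sum to 1 or 0; offending sample "
                    f"{df.index[np.argmax(bad)]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def copy(self) -> "OtuTable":
        return OtuTable(self.data.copy(), relative=self.relative, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.relative == other.relative and self.data.equals(other.data)

    def __repr__(self) -> str:
        kind = "relative" if self.relative else "counts"
        return f"OtuTable({self.shape[0]} samples x {self.shape[1]} OTUs, {kind})"


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU table TSV (OTUs as rows, samples as columns).

    Raises ``ValueError`` naming the offending cell on negative or
    non-integer counts, and on duplicate sample or OTU ids.
    """
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(s for s in header if header.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate OTU id {dup!r}")
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.columns.copy(), columns=df.index.copy(), dtype=np.int64)
    for otu in df.index:
        col = pd.to_numeric(df.loc[otu], errors="coerce")
        if col.isna().any():
            sample = col.index[col.isna().argmax()]
            raise ValueError(
                f"{path}: cell at OTU {otu!r}, sample {sample!r} is not an integer"
            )
        if (col != np.floor(col)).any():
            sample = col.index[(col != np.floor(col)).argmax()]
            raise ValueError(
                f"{path}: cell at OTU {otu!r}, sample {sample!r} is not an integer"
            )
        if (col < 0).any():
            sample = col.index[(col < 0).argmax()]
            raise ValueError(
                f"{path}: negative count at OTU {otu!r}, sample {sample!r}"
            )
        out[otu] = col.astype(np.int64).to_numpy()
    return OtuTable(out)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a count table as TSV (first column header ``otu_id``)."""
    df = table.data.T
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def filter_low_count_otus(table: OtuTable, max_total: int = 2) -> OtuTable:
    """Drop every OTU whose total count over *all* samples is <= ``max_total``.

    The default of 2 removes dataset-wide singletons and doubletons, which
    in amplicon data are enriched for chimeras and sequencing artifacts.
    The removal is defined on the pooled dataset, not per sample.
    """
    if table.relative:
        raise ValueError("low-count filtering requires an integer count table")
    if max_total < 0:
        raise ValueError("max_total must be >= 0")
    totals = table.data.sum(axis=0)
    keep = totals.index[totals > max_total]
    return OtuTable(table.data[keep].copy(), validate=False)


def samples_below_depth(table: OtuTable, depth: int) -> list[str]:
    """Sample ids whose total read count is below ``depth`` (rarefaction helper)."""
    totals = table.sample_totals()
    return list(totals.index[totals < depth])


def rarefy(table: OtuTable, depth: int, seed: int | np.random.Generator) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each row is drawn from the multivariate hypergeometric distribution, so
    subsampled counts never exceed the input counts and row sums equal
    ``depth`` exactly.  Deterministic given ``seed``.  Samples with fewer
    than ``depth`` reads raise; use :func:`samples_below_depth` to list and
    drop them explicitly first.
    """
    if table.relative:
        raise ValueError("rarefaction requires an integer count table")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    shallow = samples_below_depth(table, depth)
    if shallow:
        raise ValueError(
            f"samples with fewer than {depth} reads cannot be rarefied: {shallow}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.data.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return OtuTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        validate=False,
    )


def relative_abundance(table: OtuTable) -> OtuTable:
    """Divide each sample row by its total; all-zero rows stay all-zero."""
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, counts / totals, 0.0)
    return OtuTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        relative=True,
        validate=False,
    )


def observed_richness(table: OtuTable) -> pd.Series:
    """Number of OTUs with count >= 1, per sample."""
    return (table.data > 0).sum(axis=1)


# ---------------------------------------------------------------------------
# sample metadata


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame and return it indexed by ``sample_id``.

    Enforces the experimental-design invariants: rumen and cohort samples
    carry no medium; plate samples carry a medium and were plated from a
    diluted aliquot (dilution_exponent >= 1).
    """
    df = metadata.copy()
    if df.index.name != "sample_id":
        if "sample_id" not in df.columns:
            raise ValueError("metadata requires a sample_id column")
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    required = {"source", "medium", "dilution_exponent", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if not df["source"].isin(SOURCES).all():
        bad = df.loc[~df["source"].isin(SOURCES)].index[0]
        raise ValueError(f"unknown source for sample {bad!r}")
    if not df["medium"].isin(MEDIA).all():
        bad = df.loc[~df["medium"].isin(MEDIA)].index[0]
        raise ValueError(f"unknown medium for sample {bad!r}")
    df["dilution_exponent"] = df["dilution_exponent"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    if ((df["dilution_exponent"] < 0) | (df["dilution_exponent"] > 6)).any():
        raise ValueError("dilution_exponent must lie in [0, 6]")
    if (df["replicate"] < 1).any():
        raise ValueError("replicate must be a positive integer")
    nonplate = df["source"].isin(("rumen", "cohort"))
    if (df.loc[nonplate, "medium"] != "none").any():
        bad = df.loc[nonplate & (df["medium"] != "none")].index[0]
        raise ValueError(f"rumen/cohort sample {bad!r} must have medium 'none'")
    plate = df["source"] == "plate"
    if (df.loc[plate, "medium"] == "none").any():
        bad = df.loc[plate & (df["medium"] == "none")].index[0]
        raise ValueError(f"plate sample {bad!r} must name a medium")
    if (df.loc[plate, "dilution_exponent"] < 1).any():
        bad = df.loc[plate & (df["dilution_exponent"] < 1)].index[0]
        raise ValueError(f"plate sample {bad!r} must have dilution_exponent >= 1")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def rumen_sample_ids(metadata: pd.DataFrame) -> list[str]:
    """Original rumen sample plus its dilutions (the 'rumen' detection group)."""
    return list(metadata.index[metadata["source"] == "rumen"])


def plate_sample_ids(
    metadata: pd.DataFrame,
    medium: str | None = None,
    dilution: int | None = None,
) -> list[str]:
    mask = metadata["source"] == "plate"
    if medium is not None:
        mask &= metadata["medium"] == medium
    if dilution is not None:
        mask &= metadata["dilution_exponent"] == dilution
    return list(metadata.index[mask])


def cohort_sample_ids(metadata: pd.DataFrame) -> list[str]:
    return list(metadata.index[metadata["source"] == "cohort"])


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class Taxonomy:
    """Per-OTU ranked lineage (domain..genus, species optional).

    Lineages are stored as tuples of rank names; unassigned ranks are kept
    as the literal strings found in the input so that lineage strings
    round-trip, but rank accessors map them to ``None``.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def rank(self, otu_id: str, rank: str) -> str | None:
        try:
            i = TAXONOMY_RANKS.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}") from None
        lineage = self.lineages.get(otu_id)
        if lineage is None or i >= len(lineage):
            return None
        name = lineage[i].strip()
        return None if name.lower() in _UNASSIGNED else name

    def family(self, otu_id: str) -> str | None:
        return self.rank(otu_id, "family")

    def families(self, otu_ids: Iterable[str]) -> dict[str, set[str]]:
        """Group the given OTUs by assigned family, dropping unassigned ones."""
        out: dict[str, set[str]] = {}
        for otu in otu_ids:
            fam = self.family(otu)
            if fam is not None:
                out.setdefault(fam, set()).add(otu)
        return out


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy TSV with columns ``otu_id`` and ``lineage``.

    ``lineage`` is a semicolon-delimited ranked lineage, e.g.
    ``Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;GenusX``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "otu_id" not in df.columns or "lineage" not in df.columns:
        raise ValueError(f"{path}: taxonomy requires otu_id and lineage columns")
    if df["otu_id"].duplicated().any():
        dup = df.loc[df["otu_id"].duplicated(), "otu_id"].iloc[0]
        raise ValueError(f"{path}: duplicate taxonomy entry for OTU {dup!r}")
    lineages = {
        row.otu_id: tuple(part.strip() for part in row.lineage.split(";"))
        for row in df.itertuples()
    }
    return Taxonomy(lineages)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lineage in taxonomy.lineages.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")
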