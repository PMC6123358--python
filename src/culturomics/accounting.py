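"""Set-theoretic cultivability accounting.

Given the non-subsampled, low-count-filtered OTU table, these stages ask
which OTUs were detected where: the seven-way Venn partition of OTUs across
the three detection groups (rumen sample + dilutions, defined-medium
plates, undefined-medium plates), the cultivable fraction of the rumen
community, the richness gained by adding a second medium, the proportion
of each rumen dilution recovered on its matching plates, and the
plate-only "rare biosphere" with its detection survey across a cohort of
additional rumen microbiomes.

Presence means count >= 1 (configurable) in at least one sample of a
group.  All set operations work on the *non-rarefied* table: rarefied
tables are only used for ordination and richness statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    OtuTable,
    cohort_sample_ids,
    plate_sample_ids,
    rumen_sample_ids,
)


@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint OTU sets induced by the three detection groups."""

    rumen_only: frozenset[str]
    rumen_defined_only: frozenset[str]      # rumen & defined plates, not undefined
    rumen_undefined_only: frozenset[str]    # rumen & undefined plates, not defined
    rumen_both_media: frozenset[str]
    both_media_only: frozenset[str]         # both media, never in rumen
    defined_only: frozenset[str]
    undefined_only: frozenset[str]

    @property
    def rumen_all(self) -> frozenset[str]:
        return (
            self.rumen_only
            | self.rumen_defined_only
            | self.rumen_undefined_only
            | self.rumen_both_media
        )

    @property
    def defined_all(self) -> frozenset[str]:
        return (
            self.defined_only
            | self.both_media_only
            | self.rumen_defined_only
            | self.rumen_both_media
        )

    @property
    def undefined_all(self) -> frozenset[str]:
        return (
            self.undefined_only
            | self.both_media_only
            | self.rumen_undefined_only
            | self.rumen_both_media
        )

    @property
    def plates_all(self) -> frozenset[str]:
        return self.defined_all | self.undefined_all

    @property
    def shared(self) -> frozenset[str]:
        return self.rumen_all & self.plates_all

    @property
    def plate_only(self) -> frozenset[str]:
        return self.plates_all - self.rumen_all

    @property
    def universe(self) -> frozenset[str]:
        return self.rumen_all | self.plates_all

    def cardinalities(self) -> dict[str, int]:
        return {
            "rumen_only": len(self.rumen_only),
            "rumen_defined_only": len(self.rumen_defined_only),
            "rumen_undefined_only": len(self.rumen_undefined_only),
            "rumen_both_media": len(self.rumen_both_media),
            "both_media_only": len(self.both_media_only),
            "defined_only": len(self.defined_only),
            "undefined_only": len(self.undefined_only),
            "rumen_all": len(self.rumen_all),
            "defined_all": len(self.defined_all),
            "undefined_all": len(self.undefined_all),
            "plates_all": len(self.plates_all),
            "shared": len(self.shared),
            "plate_only": len(self.plate_only),
        }


def detected_otus(
    table: OtuTable, sample_ids: Iterable[str], min_count: int = 1
) -> set[str]:
    """OTUs with count >= ``min_count`` in at least one of the named samples."""
    sample_ids = list(sample_ids)
    unknown = [s for s in sample_ids if s not in table.data.index]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    sub = table.data.loc[sample_ids]
    mask = (sub >= min_count).any(axis=0)
    return set(sub.columns[mask])


def partition_from_sets(
    rumen: set[str], defined: set[str], undefined: set[str]
) -> VennPartition:
    """Seven-way partition from the three group detection sets."""
    return VennPartition(
        rumen_only=frozenset(rumen - defined - undefined),
        rumen_defined_only=frozenset((rumen & defined) - undefined),
        rumen_undefined_only=frozenset((rumen & undefined) - defined),
        rumen_both_media=frozenset(rumen & defined & undefined),
        both_media_only=frozenset((defined & undefined) - rumen),
        defined_only=frozenset(defined - rumen - undefined),
        undefined_only=frozenset(undefined - rumen - defined),
    )


def partition_otus(
    table: OtuTable, metadata: pd.DataFrame, min_count: int = 1
) -> VennPartition:
    """Partition detected OTUs by membership in the three detection groups.

    The rumen group is the original sample plus its dilutions; the two
    plate groups pool all dilutions and replicates of a medium.  Cohort
    samples do not take part in the partition.
    """
    groups = {
        "rumen": rumen_sample_ids(metadata),
        "defined": plate_sample_ids(metadata, medium="defined"),
        "undefined": plate_sample_ids(metadata, medium="undefined"),
    }
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"no samples in group {name!r}")
    sets = {
        name: detected_otus(table, ids, min_count) for name, ids in groups.items()
    }
    return partition_from_sets(sets["rumen"], sets["defined"], sets["undefined"])


def cultivable_fraction(partition: VennPartition) -> float:
    """Fraction of rumen-detected OTUs that also grew on any plate."""
    n_rumen = len(partition.rumen_all)
    if n_rumen == 0:
        raise ValueError("empty rumen detection set")
    return len(partition.shared) / n_rumen


def medium_gain(partition: VennPartition, added: str) -> float:
    """Proportional richness increase from adding a second medium.

    ``added`` names the medium being added; the gain is the number of OTUs
    detected only on that medium divided by the richness of the
    single-medium baseline (the other medium's full OTU set).
    """
    if added == "defined":
        exclusive = partition.defined_all - partition.undefined_all
        base = partition.undefined_all
    elif added == "undefined":
        exclusive = partition.undefined_all - partition.defined_all
        base = partition.defined_all
    else:
        raise ValueError(f"unknown medium {added!r}")
    if not base:
        raise ValueError("baseline medium detected no OTUs")
    return len(exclusive) / len(base)


def shared_per_dilution(
    table: OtuTable, metadata: pd.DataFrame, min_count: int = 1
) -> dict[tuple[int, str], float]:
    """Per (dilution, medium): fraction of the rumen dilution's OTUs on its plates.

    For each dilution exponent d with plates, the rumen sample sequenced at
    dilution d is compared against the plates inoculated from it.  Returns
    NaN (with a warning) for a dilution whose rumen sample detected nothing.
    """
    plate_meta = metadata[metadata["source"] == "plate"]
    out: dict[tuple[int, str], float] = {}
    for d in sorted(plate_meta["dilution_exponent"].unique()):
        rumen_ids = list(
            metadata.index[
                (metadata["source"] == "rumen")
                & (metadata["dilution_exponent"] == d)
            ]
        )
        if not rumen_ids:
            raise ValueError(f"no rumen sample sequenced at dilution {d}")
        rumen_set = detected_otus(table, rumen_ids, min_count)
        for medium in sorted(plate_meta["medium"].unique()):
            plate_ids = plate_sample_ids(metadata, medium=medium, dilution=int(d))
            if not plate_ids:
                continue
            plate_set = detected_otus(table, plate_ids, min_count)
            if not rumen_set:
                warnings.warn(
                    f"rumen sample at dilution {d} detected no OTUs", stacklevel=2
                )
                out[(int(d), medium)] = float("nan")
            else:
                out[(int(d), medium)] = len(rumen_set & plate_set) / len(rumen_set)
    return out


def rare_biosphere(partition: VennPartition) -> frozenset[str]:
    """Plate-detected OTUs never seen in the rumen sample or its dilutions."""
    return partition.plate_only


def cohort_survey(
    otus: Iterable[str], cohort_table: OtuTable, min_count: int = 1
) -> pd.DataFrame:
    """Detection count and frequency of each OTU across a cohort table.

    OTUs absent from the cohort table's column set get frequency 0.
    Returns a DataFrame indexed by otu_id with columns ``n_detected`` and
    ``detection_frequency``.
    """
    n_samples = cohort_table.shape[0]
    if n_samples == 0:
        raise ValueError("cohort table has no samples")
    otus = sorted(set(otus))
    present = [o for o in otus if o in cohort_table.data.columns]
    counts = pd.Series(0, index=otus, dtype=int)
    if present:
        counts.loc[present] = (
            (cohort_table.data[present] >= min_count).sum(axis=0).astype(int)
        )
    return pd.DataFrame(
        {
            "n_detected": counts,
            "detection_frequency": counts / n_samples,
        }
    )
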