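"""Core containers shared by every stage of the transect pipeline.

The pipeline views a study as a set of *transects*: ordered site sequences
crossing a putative contact zone (geological or ecological).  At each site a
sample of individuals is genotyped at a handful of multiallelic nuclear loci
(microsatellites), assigned to a maternal (mtDNA) lineage, and a smaller
sample is measured for quantitative traits.  Per-site climate summaries
characterize habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing allele copy (per copy, so half-missing calls exist)
MISSING = -1

#: the 19 bioclimatic variables used to profile habitat, in canonical order
CLIMATE_VARS = [f"bio{i}" for i in range(1, 20)]

#: precipitation-derived variables; constrained non-negative
PRECIP_VARS = [f"bio{i}" for i in range(12, 20)]


class FormatError(ValueError):
    """Malformed input text (Genepop / FASTA / CSV)."""


@dataclass
class Genotypes:
    """Diploid multiallelic genotypes for a set of individuals.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` and holds non-negative
    integer allele codes (microsatellite fragment sizes or arbitrary codes),
    with :data:`MISSING` marking an absent allele copy.  The two slots of a
    call are an unordered pair.
    """

    individual_ids: list[str]
    site_of: dict[str, str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if ((self.calls < 0) & (self.calls != MISSING)).any():
            raise ValueError("allele codes must be non-negative or MISSING")
        missing_sites = [i for i in self.individual_ids if i not in self.site_of]
        if missing_sites:
            raise ValueError(f"site_of does not cover individuals: {missing_sites[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sites(self) -> list[str]:
        """Distinct site ids in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.site_of[ind], None)
        return list(seen)

    def individuals_at(self, site_id: str) -> list[int]:
        """Row indices of individuals sampled at ``site_id``."""
        return [
            i for i, ind in enumerate(self.individual_ids)
            if self.site_of[ind] == site_id
        ]

    def subset(self, row_indices: Sequence[int]) -> "Genotypes":
        ids = [self.individual_ids[i] for i in row_indices]
        return Genotypes(
            individual_ids=ids,
            site_of={i: self.site_of[i] for i in ids},
            loci=list(self.loci),
            calls=self.calls[list(row_indices)].copy(),
        )

    def allele_counts(self, locus_index: int, rows: Sequence[int] | None = None
                      ) -> dict[int, int]:
        """Counts of called allele copies at one locus (missing excluded)."""
        a = self.calls[:, locus_index, :] if rows is None \
            else self.calls[list(rows), locus_index, :]
        a = a[a != MISSING]
        vals, counts = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class Site:
    """One sampling locality along a transect."""

    site_id: str
    position: float
    climate: dict[str, float] = field(default_factory=dict)
    habitat: str | None = None


@dataclass
class TransectDataset:
    """Everything the pipeline knows about one transect.

    ``traits`` maps site id to a DataFrame of trait-measured individuals
    (rows) by named quantitative traits (columns); trait individuals are
    sampled separately from the genotyped ones.  ``mtdna_lineage`` maps
    genotyped individuals to a lineage label; absent keys mean unassigned.
    """

    transect_id: str
    sites: list[Site]
    genotypes: Genotypes
    mtdna_lineage: dict[str, str] = field(default_factory=dict)
    traits: dict[str, pd.DataFrame] = field(default_factory=dict)
    trait_lineage: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("sites must be strictly ordered by position")
        known = {s.site_id for s in self.sites}
        orphans = {
            self.genotypes.site_of[i] for i in self.genotypes.individual_ids
        } - known
        if orphans:
            raise ValueError(f"genotyped individuals at unknown sites: {orphans}")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)

    def climate_frame(self) -> pd.DataFrame:
        """Sites × climate variables, in transect order."""
        return pd.DataFrame(
            [s.climate for s in self.sites], index=self.site_ids
        )


@dataclass
class SiteTable:
    """Per-site transect metadata and climate, possibly for many transects.

    Thin wrapper over a DataFrame indexed by ``(transect, site)`` with a
    ``position`` column and the 19 climate variables.
    """

    frame: pd.DataFrame

    def transects(self) -> list[str]:
        return list(dict.fromkeys(self.frame.index.get_level_values(0)))

    def for_transect(self, transect_id: str) -> pd.DataFrame:
        """Rows for one transect, sorted by position."""
        sub = self.frame.loc[transect_id]
        return sub.sort_values("position")

    def to_sites(self, transect_id: str) -> list[Site]:
        sub = self.for_transect(transect_id)
        return [
            Site(
                site_id=str(site_id),
                position=float(row["position"]),
                climate={v: float(row[v]) for v in CLIMATE_VARS},
            )
            for site_id, row in sub.iterrows()
        ]
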