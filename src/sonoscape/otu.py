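"""Metabarcoding OTU-table post-processing and BIN assignment.

The bespoke post-clustering rules applied to nocturnal-insect COI
metabarcoding data:

* **Low-abundance cleaning** — read counts below 0.01 % of their sample's
  total (computed on the incoming table, before any zeroing) are set to
  zero; OTUs left without reads are dropped.
* **Negative-control exclusion** — for each OTU, the maximum read count
  among negative-control samples is a contamination threshold: real-sample
  cells strictly below it are zeroed (optionally the whole OTU is removed
  instead); control columns are then dropped.
* **Geographic reference-library filtering** — BOLD-style reference
  records are kept if their country is on the South American country list,
  their coordinates fall in the continental bounding box
  (lat -58.4..17, lon -85.8..-30.3), or they come from Costa Rica; records
  must then carry a usable COI-5P sequence (present, not all hyphens,
  IUPAC characters only) and a BIN — except records of species that are
  wholly BIN-less in the dataset.
* **BIN assignment** — each OTU sequence is assigned to the nearest
  reference by uncorrected p-distance (mismatches over compared sites;
  gap and ambiguity positions excluded). Distance < 3 % identifies the
  reference's BIN as the OTU's species; >= 3 % makes the OTU a "genetic
  morpho-species" annotated with the nearest reference's genus/family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "OtuTable",
    "BinAssignment",
    "SOUTH_AMERICAN_COUNTRIES",
    "clean_low_abundance",
    "negative_control_filter",
    "filter_reference_library",
    "p_distance",
    "assign_bins",
]

logger = logging.getLogger(__name__)

#: Country names accepted directly by the reference-library filter.
SOUTH_AMERICAN_COUNTRIES = frozenset({
    "Argentina", "Bolivia", "Brazil", "Chile", "Colombia", "Ecuador",
    "Falkland Islands", "French Guiana", "Guiana", "Paraguay", "Peru",
    "Suriname", "Uruguay", "Venezuela",
})

BBOX_LAT = (-58.4, 17.0)
BBOX_LON = (-85.8, -30.3)
EXTRA_COUNTRIES = frozenset({"Costa Rica"})

IUPAC_NT = frozenset("ACGTURYSWKMBDHVN-")
_UNAMBIGUOUS = frozenset("ACGT")

SPECIES_DISTANCE = 0.03  # p-distance below which an OTU inherits the BIN
MIN_COMPARED_SITES = 100


@dataclass
class OtuTable:
    """OTU read counts (rows = OTUs, columns = samples) with control flags."""

    counts: pd.DataFrame
    control_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("read counts must be non-negative")
        if not np.issubdtype(self.counts.dtypes.iloc[0], np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("read counts must be integers")
            self.counts = self.counts.astype(int)
        unknown = set(self.control_samples) - set(self.counts.columns)
        if unknown:
            raise ValueError(f"unknown control samples: {sorted(unknown)}")
        if len(self.real_samples) < 1:
            raise ValueError("need at least one real (non-control) sample")

    @property
    def real_samples(self) -> list[str]:
        return [c for c in self.counts.columns if c not in self.control_samples]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def clean_low_abundance(table: OtuTable, frac: float = 0.0001) -> OtuTable:
    """Zero cells holding < ``frac`` of their sample's total reads.

    Thresholds use the per-sample totals of the incoming table (before any
    zeroing); the comparison is strict, so a cell exactly at the threshold
    is kept. OTUs with all-zero rows are dropped.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    counts = table.counts.copy()
    thresholds = counts.sum(axis=0) * frac
    zeroed = counts.lt(thresholds, axis=1)
    counts = counts.mask(zeroed, 0)
    counts = counts.loc[counts.sum(axis=1) > 0]
    return replace(table, counts=counts)


def negative_control_filter(table: OtuTable,
                            drop_whole_otu: bool = False) -> OtuTable:
    """Apply the negative-control contamination rule and drop controls.

    Per OTU, the threshold is the maximum read count across negative
    controls; real-sample cells strictly below it are zeroed. With
    ``drop_whole_otu`` the entire OTU is removed whenever any real cell
    falls below its threshold (the stricter reading). Without controls the
    table is returned unchanged with a warning. OTUs left empty are
    dropped.
    """
    if not table.control_samples:
        warnings.warn("no negative-control samples; table returned unchanged",
                      UserWarning, stacklevel=2)
        return table
    controls = list(table.control_samples)
    thresholds = table.counts[controls].max(axis=1)
    real = table.counts[table.real_samples].copy()
    below = real.lt(thresholds, axis=0)
    if drop_whole_otu:
        contaminated = below.any(axis=1) & (thresholds > 0)
        real = real.loc[~contaminated]
    else:
        real = real.mask(below, 0)
    real = real.loc[real.sum(axis=1) > 0]
    return OtuTable(counts=real, control_samples=())


def _valid_sequence(seq) -> bool:
    if not isinstance(seq, str) or not seq:
        return False
    s = seq.strip().upper()
    if not s or set(s) == {"-"}:
        return False
    return set(s) <= IUPAC_NT


def filter_reference_library(
    records: pd.DataFrame,
    country_list: frozenset[str] | set[str] = SOUTH_AMERICAN_COUNTRIES,
    bbox_lat: tuple[float, float] = BBOX_LAT,
    bbox_lon: tuple[float, float] = BBOX_LON,
    extra_countries: frozenset[str] | set[str] = EXTRA_COUNTRIES,
) -> pd.DataFrame:
    """Geographic and validity filtering of a BOLD-style reference table.

    Expects columns ``processid, bin_uri, species_name, nucleotides,
    markercode, country, lat, lon`` (extra columns pass through). A record
    is kept geographically if its country is listed, its coordinates fall
    inside the closed bounding box, or its country is in
    ``extra_countries``. It must then have a usable sequence (present, not
    all hyphens, IUPAC only), marker COI-5P, and a BIN — unless its species
    is wholly BIN-less in the dataset. Records with unparseable coordinates
    and no listed country are excluded with a logged reason.
    """
    df = records.copy()
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad_coords = (df["lat"].notna() & lat.isna()) | (df["lon"].notna() & lon.isna())
    for rid in df.loc[bad_coords, "processid"]:
        logger.info("record %s: unparseable coordinates", rid)

    in_box = (lat.between(*bbox_lat) & lon.between(*bbox_lon)).fillna(False)
    by_country = df["country"].isin(country_list)
    extra = df["country"].isin(extra_countries)
    geo_keep = by_country | in_box | extra
    df = df.loc[geo_keep & ~(bad_coords & ~by_country & ~extra)]

    seq_ok = df["nucleotides"].map(_valid_sequence)
    marker_ok = df["markercode"].astype(str).str.contains("COI-5P", na=False)
    df = df.loc[seq_ok & marker_ok]

    has_bin = df["bin_uri"].notna() & (df["bin_uri"].astype(str).str.len() > 0)
    # species wholly BIN-less anywhere in the (filtered) dataset keep their
    # BIN-less records
    species_with_bin = set(df.loc[has_bin, "species_name"].dropna())
    keep = has_bin | ~df["species_name"].isin(species_with_bin)
    return df.loc[keep].reset_index(drop=True)


_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=-1.0,
    open_gap_score=-2.0, extend_gap_score=-0.5)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected p-distance after global pairwise alignment.

    Returns (mismatches / compared sites, compared sites); only columns
    where both sequences have an unambiguous A/C/G/T count as compared
    sites — gaps and ambiguity codes are excluded from the denominator.
    """
    a = a.strip().upper().replace("-", "")
    b = b.strip().upper().replace("-", "")
    if a == b:
        return 0.0, len(a)
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    compared = 0
    mismatches = 0
    for ca, cb in zip(sa, sb):
        if ca in _UNAMBIGUOUS and cb in _UNAMBIGUOUS:
            compared += 1
            if ca != cb:
                mismatches += 1
    return (mismatches / compared if compared else np.nan), compared


@dataclass(frozen=True)
class BinAssignment:
    """Taxonomic unit assigned to one OTU."""

    otu_id: str
    unit_id: str | None
    distance: float
    status: str  # "species" | "morphospecies" | "unassigned"
    nearest_record: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    reason: str | None = None


def assign_bins(otu_sequences: dict[str, str],
                refs: pd.DataFrame,
                species_threshold: float = SPECIES_DISTANCE,
                min_compared: int = MIN_COMPARED_SITES) -> list[BinAssignment]:
    """Assign each OTU to its nearest reference BIN by p-distance.

    Distance below ``species_threshold`` (strict) adopts the nearest
    reference's BIN as an identified species; at or above it, the OTU
    becomes a genetic morpho-species ``MSP_<otu>`` carrying the nearest
    reference's genus/family annotation. Ties at equal distance are broken
    by lexicographic BIN id and logged. An OTU with no reference sharing at
    least ``min_compared`` comparable sites is returned unassigned.
    """
    if refs.empty:
        raise ValueError("reference set is empty")
    out: list[BinAssignment] = []
    for otu_id, seq in otu_sequences.items():
        candidates = []
        for _, ref in refs.iterrows():
            dist, compared = p_distance(seq, ref["nucleotides"])
            if compared >= min_compared:
                candidates.append((dist, str(ref.get("bin_uri") or ""), ref))
        if not candidates:
            out.append(BinAssignment(
                otu_id=otu_id, unit_id=None, distance=np.nan,
                status="unassigned",
                reason=f"no reference shares >= {min_compared} comparable sites"))
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_dist = candidates[0][0]
        tied = [c for c in candidates if np.isclose(c[0], best_dist)]
        if len({c[1] for c in tied}) > 1:
            logger.info("OTU %s: %d references tied at distance %.4f; "
                        "lexicographic BIN tie-break", otu_id, len(tied),
                        best_dist)
        dist, bin_uri, ref = tied[0]
        common = dict(
            distance=float(dist),
            nearest_record=str(ref.get("processid", "")),
            family=ref.get("family_name"),
            genus=ref.get("genus_name"),
            species=ref.get("species_name"),
        )
        if dist < species_threshold:
            out.append(BinAssignment(otu_id=otu_id, unit_id=bin_uri or None,
                                     status="species", **common))
        else:
            out.append(BinAssignment(otu_id=otu_id, unit_id=f"MSP_{otu_id}",
                                     status="morphospecies", **common))
    return out


def assignments_frame(assignments: list[BinAssignment]) -> pd.DataFrame:
    """Tabular view of BIN assignments."""
    return pd.DataFrame([{
        "otu_id": a.otu_id, "unit_id": a.unit_id, "distance": a.distance,
        "status": a.status, "nearest_record": a.nearest_record,
        "family": a.family, "genus": a.genus, "species": a.species,
        "reason": a.reason,
    } for a in assignments])
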