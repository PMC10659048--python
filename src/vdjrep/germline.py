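"""Germline IGH segment references with locus-zone annotation.

A heavy-chain rearrangement joins one variable (IGHV), one diversity (IGHD)
and one joining (IGHJ) gene segment.  The murine IGHV region is additionally
subdivided, 5' to 3', into *distal*, *median* and *proximal* zones whose
usage is regulated independently (chromatin accessibility along the locus),
so every functional V segment carries a zone label.

Coordinates are 0-based half-open.  ``locus_rank`` is the sole order
authority: rank 1 is the most 5' (distal) segment of its class, increasing
toward 3' (proximal).  ``anchor_offset`` is the offset of the conserved
2nd-CYS codon (V) or conserved TRP codon (J) from the segment start and must
sit on the segment's reading frame (a multiple of 3 here, since segments are
stored in frame).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SegmentClass",
    "Zone",
    "Functionality",
    "GermlineSegment",
    "ZoneMap",
    "GermlineReference",
    "GermlineError",
    "load_germline",
    "write_germline",
    "assign_zone",
    "strip_allele",
    "build_toy_reference",
]

_ALPHABET = frozenset("ACGT")

METADATA_COLUMNS = [
    "name",
    "class",
    "family",
    "locus_rank",
    "functionality",
    "anchor_offset",
    "zone",
]


class GermlineError(ValueError):
    """Raised for invalid germline references or failed lookups."""


class SegmentClass(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"


class Zone(str, enum.Enum):
    DISTAL = "distal"
    MEDIAN = "median"
    PROXIMAL = "proximal"


ZONES = (Zone.DISTAL, Zone.MEDIAN, Zone.PROXIMAL)


class Functionality(str, enum.Enum):
    FUNCTIONAL = "functional"
    ORF = "ORF"
    PSEUDOGENE = "pseudogene"


def strip_allele(name: str) -> str:
    """Strip an IMGT allele suffix (``IGHV1-2*01`` -> ``IGHV1-2``).

    Usage categories in this package are genes, not alleles.
    """
    return name.split("*", 1)[0]


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J gene segment."""

    name: str
    segment_class: SegmentClass
    sequence: str
    family: str
    locus_rank: int
    functionality: Functionality = Functionality.FUNCTIONAL
    anchor_offset: int | None = None
    zone: Zone | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GermlineError(f"segment {self.name!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise GermlineError(
                f"segment {self.name!r}: invalid characters {sorted(bad)} in sequence"
            )
        if self.segment_class is SegmentClass.D:
            if self.anchor_offset is not None:
                raise GermlineError(f"D segment {self.name!r} must not carry an anchor")
            if self.zone is not None:
                raise GermlineError(f"D segment {self.name!r} must not carry a zone")
        else:
            if self.anchor_offset is None:
                raise GermlineError(
                    f"{self.segment_class.value} segment {self.name!r} needs an anchor_offset"
                )
            if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
                raise GermlineError(
                    f"segment {self.name!r}: anchor_offset {self.anchor_offset} outside "
                    f"[0, {len(self.sequence) - 3}]"
                )
            if self.anchor_offset % 3 != 0:
                raise GermlineError(
                    f"segment {self.name!r}: anchor_offset {self.anchor_offset} off frame"
                )
        if self.segment_class is SegmentClass.J and self.zone is not None:
            raise GermlineError(f"J segment {self.name!r} must not carry a zone")

    @property
    def is_functional(self) -> bool:
        return self.functionality is Functionality.FUNCTIONAL

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


@dataclass
class ZoneMap:
    """Gene -> zone mapping with family-level fallback.

    Gene-level entries override family-level entries; an unresolvable name is
    an error, never a silent default.
    """

    by_gene: dict[str, Zone] = field(default_factory=dict)
    by_family: dict[str, Zone] = field(default_factory=dict)

    def assign(self, name: str, family: str | None = None) -> Zone:
        gene = strip_allele(name)
        if gene in self.by_gene:
            return self.by_gene[gene]
        if family is not None and family in self.by_family:
            return self.by_family[family]
        raise GermlineError(f"zone lookup failed for gene {name!r} (family {family!r})")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ZoneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"key", "level", "zone"}
        if not required.issubset(df.columns):
            raise GermlineError(f"zone map {path}: needs columns {sorted(required)}")
        zm = cls()
        for row in df.itertuples(index=False):
            zone = Zone(row.zone)
            if row.level == "gene":
                zm.by_gene[row.key] = zone
            elif row.level == "family":
                zm.by_family[row.key] = zone
            else:
                raise GermlineError(f"zone map {path}: bad level {row.level!r}")
        return zm

    def to_tsv(self, path: str | Path) -> None:
        rows = [("gene", k, z.value) for k, z in self.by_gene.items()]
        rows += [("family", k, z.value) for k, z in self.by_family.items()]
        pd.DataFrame(rows, columns=["level", "key", "zone"])[
            ["key", "level", "zone"]
        ].to_csv(path, sep="\t", index=False)


def assign_zone(segment_name: str, zone_map: ZoneMap, family: str | None = None) -> Zone:
    """Resolve the locus zone of an IGHV gene (gene entry, else family fallback)."""
    return zone_map.assign(segment_name, family)


@dataclass
class GermlineReference:
    """A validated set of germline segments grouped by class.

    The functional segments of each class define the category space K for
    segment-usage statistics downstream.
    """

    segments: list[GermlineSegment]

    def __post_init__(self) -> None:
        for cls in SegmentClass:
            names = [s.name for s in self.by_class(cls)]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise GermlineError(f"duplicate {cls.value} names: {sorted(dupes)}")
            if not any(s.is_functional for s in self.by_class(cls)):
                raise GermlineError(f"no functional {cls.value} segment in reference")
        for seg in self.by_class(SegmentClass.V):
            if seg.is_functional and seg.zone is None:
                raise GermlineError(f"functional V {seg.name!r} lacks a zone")
        zone_total = sum(self.zone_counts().values())
        if zone_total != len(self.functional(SegmentClass.V)):
            raise GermlineError("zone counts do not partition the functional V set")

    def by_class(self, cls: SegmentClass) -> list[GermlineSegment]:
        return sorted(
            (s for s in self.segments if s.segment_class is cls),
            key=lambda s: s.locus_rank,
        )

    def functional(self, cls: SegmentClass) -> list[GermlineSegment]:
        return [s for s in self.by_class(cls) if s.is_functional]

    def counts(self) -> dict[str, int]:
        return {cls.value: len(self.by_class(cls)) for cls in SegmentClass}

    def functional_counts(self) -> dict[str, int]:
        return {cls.value: len(self.functional(cls)) for cls in SegmentClass}

    def zone_counts(self) -> dict[Zone, int]:
        out = {z: 0 for z in ZONES}
        for seg in self.functional(SegmentClass.V):
            out[seg.zone] += 1
        return out

    def get(self, cls: SegmentClass, name: str) -> GermlineSegment:
        gene = strip_allele(name)
        for seg in self.by_class(cls):
            if seg.name == gene:
                return seg
        raise GermlineError(f"unknown {cls.value} segment {name!r}")

    def zone_map(self) -> ZoneMap:
        zm = ZoneMap()
        for seg in self.functional(SegmentClass.V):
            zm.by_gene[seg.name] = seg.zone
            # family fallback only when unambiguous within the family
            fam_zones = {
                s.zone for s in self.functional(SegmentClass.V) if s.family == seg.family
            }
            if len(fam_zones) == 1:
                zm.by_family[seg.family] = seg.zone
        return zm


def load_germline(fasta_path: str | Path, metadata_path: str | Path) -> GermlineReference:
    """Load a germline reference from a FASTA + metadata TSV pair.

    FASTA record ids must match metadata ``name`` rows 1:1; violations raise
    :class:`GermlineError` naming the offending record.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise GermlineError(f"metadata {metadata_path}: missing columns {sorted(missing_cols)}")
    meta_by_name: dict[str, dict] = {}
    for row in meta.to_dict("records"):
        if row["name"] in meta_by_name:
            raise GermlineError(f"duplicate metadata row for {row['name']!r}")
        meta_by_name[row["name"]] = row

    segments = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta_by_name:
            raise GermlineError(f"FASTA record {rec.id!r} has no metadata row")
        if rec.id in seen:
            raise GermlineError(f"duplicate FASTA record {rec.id!r}")
        seen.add(rec.id)
        row = meta_by_name[rec.id]
        anchor = row["anchor_offset"]
        zone = row["zone"]
        segments.append(
            GermlineSegment(
                name=rec.id,
                segment_class=SegmentClass(row["class"]),
                sequence=str(rec.seq).upper(),
                family=row["family"],
                locus_rank=int(row["locus_rank"]),
                functionality=Functionality(row["functionality"]),
                anchor_offset=int(anchor) if anchor not in ("", "NA") else None,
                zone=Zone(zone) if zone not in ("", "NA") else None,
            )
        )
    unmatched = set(meta_by_name) - seen
    if unmatched:
        raise GermlineError(f"metadata rows without FASTA record: {sorted(unmatched)}")
    return GermlineReference(segments)


def write_germline(
    reference: GermlineReference, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a reference back to FASTA + metadata TSV (round-trips with load_germline)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description="") for s in reference.segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for s in reference.segments:
        rows.append(
            {
                "name": s.name,
                "class": s.segment_class.value,
                "family": s.family,
                "locus_rank": s.locus_rank,
                "functionality": s.functionality.value,
                "anchor_offset": "" if s.anchor_offset is None else s.anchor_offset,
                "zone": "" if s.zone is None else s.zone.value,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_toy_reference(
    n_v_per_zone: Sequence[int] = (81, 34, 15),
    n_d: int = 15,
    n_j: int = 4,
    seed: int = 0,
    v_length: int = 48,
    v_anchor: int = 36,
    d_length_range: tuple[int, int] = (10, 16),
    j_length: int = 21,
    j_anchor: int = 12,
    family_size: int = 10,
) -> GermlineReference:
    """Build a seed-reproducible synthetic germline reference.

    The default zone composition (81/34/15 functional V segments) mirrors the
    distal/median/proximal split of the functional murine IGHV set, with 15 D
    and 4 J segments.  V anchors always hold a 2nd-CYS codon (TGT/TGC) and J
    anchors a TRP codon (TGG); the V tail 3' of the CYS codon
    (``v_length - v_anchor - 3`` nt) and the J head 5' of the TRP codon
    (``j_anchor`` nt) are the junction-facing ends exposed to trimming.
    """
    if len(n_v_per_zone) != 3:
        raise GermlineError("n_v_per_zone must have 3 entries (distal, median, proximal)")
    if sum(n_v_per_zone) < 1:
        raise GermlineError("at least one V segment required")
    if n_d < 1 or n_j < 1:
        raise GermlineError("n_d and n_j must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []

    rank = 0
    zone_tag = {Zone.DISTAL: "D", Zone.MEDIAN: "M", Zone.PROXIMAL: "P"}
    for zone, n_zone in zip(ZONES, n_v_per_zone):
        for i in range(n_zone):
            rank += 1
            seq = list(_random_seq(rng, v_length))
            seq[v_anchor : v_anchor + 3] = rng.choice(["TGT", "TGC"])
            family = f"IGHV{zone_tag[zone]}F{i // family_size + 1}"
            segments.append(
                GermlineSegment(
                    name=f"IGHV{zone_tag[zone]}{i + 1}",
                    segment_class=SegmentClass.V,
                    sequence="".join(seq),
                    family=family,
                    locus_rank=rank,
                    anchor_offset=v_anchor,
                    zone=zone,
                )
            )
    for i in range(n_d):
        d_len = int(rng.integers(d_length_range[0], d_length_range[1] + 1))
        segments.append(
            GermlineSegment(
                name=f"IGHD{i + 1}",
                segment_class=SegmentClass.D,
                sequence=_random_seq(rng, d_len),
                family=f"IGHDF{i // 4 + 1}",
                locus_rank=i + 1,
            )
        )
    for i in range(n_j):
        seq = list(_random_seq(rng, j_length))
        seq[j_anchor : j_anchor + 3] = "TGG"
        segments.append(
            GermlineSegment(
                name=f"IGHJ{i + 1}",
                segment_class=SegmentClass.J,
                sequence="".join(seq),
                family="IGHJF1",
                locus_rank=i + 1,
                anchor_offset=j_anchor,
            )
        )
    return GermlineReference(segments)
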