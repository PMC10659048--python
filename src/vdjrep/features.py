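"""Per-library categorical feature distributions of a clean repertoire.

Each feature is a frequency vector over a category space of size K, the
shape the dispersion-index statistics consume.  Two K conventions coexist:

* *reference-defined* spaces (segment usage per class, zone shares): K is
  fixed by the functional segments of the germline reference, so unused
  categories appear with frequency 0 and K is comparable across libraries;
* *observed* spaces (VDJ associations, CDR3 lengths, trim and D-length
  distributions): categories are whatever occurs, and the comparison layer
  takes K as the observed union across the libraries being compared.

CDR3 length follows the IMGT convention: junction minus the two anchor
residues (2nd-CYS and J-TRP).  Amino-acid composition is pooled across all
positions of all CDR3s of a given length, giving one 20-category vector per
length class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germline import GermlineError, GermlineReference, SegmentClass, Zone, ZoneMap, ZONES
from .ingest import CleanRepertoire

__all__ = [
    "FeatureOptions",
    "FrequencyVector",
    "FeatureTable",
    "segment_usage",
    "vdj_association_table",
    "zone_features",
    "cdr3_length_distribution",
    "cdr3_aa_composition",
    "junction_metrics",
    "compute_features",
    "FEATURE_FAMILIES",
]

log = logging.getLogger(__name__)

AA_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")
NO_D = "noD"

FEATURE_FAMILIES = [
    "v_usage",
    "d_usage",
    "j_usage",
    "vdj_assoc",
    "zone_share",
    "v_usage_by_zone",
    "cdr3_len",
    "cdr3_aa_comp",
    "d_len",
    "v3_trim",
    "j5_trim",
    "palindrome_vd",
    "palindrome_dj",
    "n_added_bins",
]


@dataclass(frozen=True)
class FrequencyVector:
    """A frequency vector over named categories.

    ``fixed_k``: K is part of the category-space definition (reference genes,
    the 3 zones, the 20 amino acids, binary bins).  Otherwise K is resolved
    as the observed union at comparison time.
    """

    name: str
    freqs: pd.Series
    K: int
    n: int
    fixed_k: bool = True

    def __post_init__(self) -> None:
        f = self.freqs
        if self.n > 0:
            if (f < -1e-12).any():
                raise ValueError(f"{self.name}: negative frequency")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: frequencies sum to {f.sum()}, not 1")

    @property
    def empty(self) -> bool:
        return self.n == 0

    @classmethod
    def from_counts(
        cls, name: str, counts: pd.Series, space: list | None = None, fixed_k: bool = True
    ) -> "FrequencyVector":
        if space is not None:
            counts = counts.reindex(space, fill_value=0)
        n = int(counts.sum())
        freqs = counts / n if n > 0 else counts.astype(float)
        K = len(space) if space is not None else int((counts > 0).sum())
        return cls(name=name, freqs=freqs.astype(float), K=max(K, 1), n=n, fixed_k=fixed_k)


def _tally(values: pd.Series, name: str, space: list | None = None, fixed_k: bool = True) -> FrequencyVector:
    counts = values.value_counts()
    return FrequencyVector.from_counts(name, counts, space=space, fixed_k=fixed_k)


def segment_usage(
    rep: CleanRepertoire, reference: GermlineReference, segment_class: SegmentClass
) -> FrequencyVector:
    """Usage frequencies over ALL functional genes of a class (zeros kept).

    Unresolvable calls (after allele stripping) raise, listing the offenders:
    the category space must match the reference.
    """
    col = {SegmentClass.V: "v_call", SegmentClass.D: "d_call", SegmentClass.J: "j_call"}[
        segment_class
    ]
    genes = [s.name for s in reference.functional(segment_class)]
    calls = rep.records[col]
    if segment_class is SegmentClass.D:
        calls = calls[calls.astype(str).str.len() > 0]  # noD records excluded
    unknown = sorted(set(calls) - set(genes))
    if unknown:
        raise GermlineError(
            f"{rep.library_id}: unresolvable {segment_class.value} calls {unknown[:10]}"
        )
    return _tally(calls, f"{segment_class.value.lower()}_usage", space=genes)


def vdj_association_table(rep: CleanRepertoire) -> FrequencyVector:
    """Frequencies over observed V x J x (D or noD) triples."""
    d = rep.records["d_call"].astype(str).replace("", NO_D)
    triples = rep.records["v_call"] + "|" + d + "|" + rep.records["j_call"]
    return _tally(triples, "vdj_assoc", fixed_k=False)


def zone_features(
    rep: CleanRepertoire, reference: GermlineReference, zone_map: ZoneMap | None = None
) -> tuple[FrequencyVector, dict[Zone, FrequencyVector]]:
    """Zone shares and per-zone (renormalized) V-usage vectors.

    ``zone_share`` is the fraction of records whose V lies in each zone;
    ``v_usage_by_zone[z]`` is the usage vector over the reference's zone-z
    genes renormalized within the zone.
    """
    zm = zone_map or reference.zone_map()
    fam = {s.name: s.family for s in reference.functional(SegmentClass.V)}
    zones = rep.records["v_call"].map(lambda g: zm.assign(g, fam.get(g)).value)
    share = _tally(zones, "zone_share", space=[z.value for z in ZONES])
    by_zone: dict[Zone, FrequencyVector] = {}
    for z in ZONES:
        genes = [s.name for s in reference.functional(SegmentClass.V) if zm.assign(s.name, s.family) is z]
        calls = rep.records["v_call"][zones == z.value]
        by_zone[z] = _tally(calls, f"v_usage_{z.value}", space=genes)
    return share, by_zone


def cdr3_length_distribution(rep: CleanRepertoire, cap: int = 30) -> FrequencyVector:
    """CDR3 amino-acid length frequencies (junction aa length minus 2 anchors).

    Support 1..cap with a ``>cap`` overflow bin; records without a
    translatable junction are excluded.
    """
    aa = rep.records["junction_aa"].astype(str)
    anchors = 2 if rep.records.attrs.get("anchors_included", True) else 0
    lengths = aa.str.len() - anchors
    lengths = lengths[(aa.str.len() > 0) & (lengths >= 1)]
    binned = lengths.where(lengths <= cap, cap + 1)
    space = list(range(1, cap + 2))  # cap+1 encodes the overflow bin
    return _tally(binned, "cdr3_len", space=space, fixed_k=False)


def cdr3_aa_composition(
    rep: CleanRepertoire, length_set: tuple[int, ...] = (11, 12, 13, 14)
) -> dict[int, FrequencyVector]:
    """Pooled amino-acid composition of CDR3s, per CDR3 length class (K=20)."""
    if not length_set:
        raise ValueError("length_set must be non-empty")
    aa = rep.records["junction_aa"].astype(str)
    anchors = 2 if rep.records.attrs.get("anchors_included", True) else 0
    # CDR3 = junction minus anchors
    cdr3 = aa.str.slice(1, -1) if anchors == 2 else aa
    out: dict[int, FrequencyVector] = {}
    for L in length_set:
        pool = "".join(cdr3[cdr3.str.len() == L])
        counts = pd.Series(list(pool)).value_counts() if pool else pd.Series(dtype=int)
        out[L] = FrequencyVector.from_counts(f"cdr3_aa_comp_{L}", counts, space=AA_ALPHABET)
    return out


def junction_metrics(
    rep: CleanRepertoire, trim_cap: int = 10
) -> dict[str, FrequencyVector]:
    """D length, V/J trim, palindrome and N-addition distributions.

    Requires junction decomposition; the caller should skip this family when
    it is unavailable (never fabricate zeros).  Palindrome features are
    binary: "with" iff any P nucleotide at the junction's two ends; N bins
    follow the <=6 / >=7 split of total added nucleotides.
    """
    if not rep.has_decomposition:
        raise ValueError(f"{rep.library_id}: junction decomposition unavailable")
    rec = rep.records
    has_d = rec["d_call"].astype(str).str.len() > 0
    out: dict[str, FrequencyVector] = {}
    out["d_len"] = _tally(rec.loc[has_d, "d_retained_len"], "d_len", fixed_k=False)
    trim_space = list(range(0, trim_cap + 2))  # trim_cap+1 = overflow bin
    for col in ("v3_trim", "j5_trim"):
        vals = rec[col].where(rec[col] <= trim_cap, trim_cap + 1)
        out[col] = _tally(vals, col, space=trim_space, fixed_k=False)
    pal_vd = np.where(rec["p3v_len"] + rec["p5d_len"] > 0, "with", "without")
    pal_dj = np.where(rec["p3d_len"] + rec["p5j_len"] > 0, "with", "without")
    out["palindrome_vd"] = _tally(pd.Series(pal_vd), "palindrome_vd", space=["without", "with"])
    out["palindrome_dj"] = _tally(pd.Series(pal_dj), "palindrome_dj", space=["without", "with"])
    n_bin = np.where(rec["n1_len"] + rec["n2_len"] <= 6, "le6", "ge7")
    out["n_added_bins"] = _tally(pd.Series(n_bin), "n_added_bins", space=["le6", "ge7"])
    return out


@dataclass
class FeatureOptions:
    length_set: tuple[int, ...] = (11, 12, 13, 14)
    cdr3_cap: int = 30
    trim_cap: int = 10


@dataclass
class FeatureTable:
    """All per-library feature vectors, keyed by feature name.

    ``vectors`` maps flat feature names (``v_usage``, ``v_usage_distal``,
    ``cdr3_aa_comp_12``, ...) to frequency vectors; ``families`` groups them
    into the 14 feature families.
    """

    library_id: str
    group: str
    n_unique: int
    vectors: dict[str, FrequencyVector] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fv in self.vectors.items():
            for cat, freq in fv.freqs.items():
                rows.append(
                    {
                        "library_id": self.library_id,
                        "group": self.group,
                        "feature": name,
                        "category": cat,
                        "frequency": freq,
                        "K": fv.K,
                        "n": fv.n,
                    }
                )
        return pd.DataFrame(rows)


def compute_features(
    rep: CleanRepertoire,
    reference: GermlineReference,
    zone_map: ZoneMap | None = None,
    options: FeatureOptions | None = None,
) -> FeatureTable:
    """Compute every feature family the analysis compares across groups.

    Junction-decomposition families are skipped with a warning when the
    source table lacks the decomposition columns.
    """
    opts = options or FeatureOptions()
    ft = FeatureTable(library_id=rep.library_id, group=rep.group, n_unique=rep.n_unique)

    def put(family: str, fv: FrequencyVector) -> None:
        ft.vectors[fv.name] = fv
        ft.families.setdefault(family, []).append(fv.name)

    put("v_usage", segment_usage(rep, reference, SegmentClass.V))
    put("d_usage", segment_usage(rep, reference, SegmentClass.D))
    put("j_usage", segment_usage(rep, reference, SegmentClass.J))
    put("vdj_assoc", vdj_association_table(rep))
    share, by_zone = zone_features(rep, reference, zone_map)
    put("zone_share", share)
    for z in ZONES:
        put("v_usage_by_zone", by_zone[z])
    put("cdr3_len", cdr3_length_distribution(rep, cap=opts.cdr3_cap))
    for L, fv in cdr3_aa_composition(rep, opts.length_set).items():
        put("cdr3_aa_comp", fv)
    if rep.has_decomposition:
        for fv in junction_metrics(rep, trim_cap=opts.trim_cap).values():
            family = fv.name if fv.name in FEATURE_FAMILIES else fv.name
            put(family, fv)
    else:
        log.warning(
            "%s: junction decomposition unavailable; skipping d_len/trim/palindrome/N families",
            rep.library_id,
        )
    return ft
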