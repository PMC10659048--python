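"""Read annotated rearrangement tables and build clean repertoires.

The retention rule mirrors the study design for expressed IgM libraries:
keep records that are productive AND carry a CDR3 (non-empty junction), then
deduplicate to one representative per unique CDR3 to remove PCR bias and
clonal expansion.  The dedup key defaults to the junction *nucleotide*
sequence (the stricter reading, preserving synonymous diversity) and can be
switched to the amino-acid junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import strip_allele
from .simulate import _X_MAP, DECOMPOSITION_FIELDS

__all__ = [
    "ColumnMap",
    "CleanRepertoire",
    "IngestError",
    "read_rearrangements",
    "filter_functional",
    "dedup_unique_cdr3",
    "clean_repertoire",
    "raw_repertoire",
]

log = logging.getLogger(__name__)

_TRUE = {"t", "true", "productive", "yes", "1"}
_FALSE = {"f", "false", "unproductive", "non-productive", "no", "0"}


class IngestError(ValueError):
    pass


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to source-file column headers.

    ``anchors_included`` records the junction convention of the source: True
    when the junction spans the 2nd-CYS through TRP codons inclusive (AIRR /
    IMGT junction), False when the column holds the bare CDR3.
    """

    sequence_id: str | None = "sequence_id"
    v_call: str = "v_call"
    d_call: str | None = "d_call"
    j_call: str = "j_call"
    junction: str = "junction"
    junction_aa: str | None = "junction_aa"
    productive: str = "productive"
    anchors_included: bool = True
    extension_prefix: str = "x_"

    @classmethod
    def airr(cls) -> "ColumnMap":
        return cls()

    @classmethod
    def imgt_highv_quest(cls) -> "ColumnMap":
        """Vocabulary adapter for IMGT/HighV-QUEST-style summary exports."""
        return cls(
            sequence_id="Sequence ID",
            v_call="V-GENE and allele",
            d_call="D-GENE and allele",
            j_call="J-GENE and allele",
            junction="JUNCTION",
            junction_aa="JUNCTION (AA)",
            productive="Functionality",
            anchors_included=True,
        )


def _parse_productive(values: pd.Series) -> pd.Series:
    norm = values.astype(str).str.strip().str.lower()
    out = pd.Series(np.nan, index=values.index, dtype=object)
    out[norm.isin(_TRUE)] = True
    # IMGT writes e.g. "unproductive (see comment)"
    out[norm.isin(_FALSE) | norm.str.startswith("unproductive")] = False
    return out


def read_rearrangements(path: str | Path, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read a rearrangement TSV into the canonical record table.

    Raises :class:`IngestError` naming any unmapped required column.
    Malformed rows (unparseable productivity, missing junction *and* missing
    productivity) are rejected at row level with a logged count.  Junction
    decomposition fields absent from the source leave the table flagged
    ``attrs["has_decomposition"] = False`` so downstream features skip the
    families that need them instead of fabricating zeros.
    """
    cm = column_map or ColumnMap.airr()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"v_call": cm.v_call, "j_call": cm.j_call, "junction": cm.junction,
                "productive": cm.productive}
    for canonical, source in required.items():
        if source not in df.columns:
            raise IngestError(f"{path}: column {canonical!r} unmapped (looked for {source!r})")

    out = pd.DataFrame(index=df.index)
    if cm.sequence_id and cm.sequence_id in df.columns:
        out["sequence_id"] = df[cm.sequence_id]
    else:
        out["sequence_id"] = [f"row-{i}" for i in range(len(df))]
    out["v_call"] = df[cm.v_call].map(strip_allele)
    if cm.d_call and cm.d_call in df.columns:
        out["d_call"] = df[cm.d_call].map(strip_allele)
    else:
        out["d_call"] = ""
    out["j_call"] = df[cm.j_call].map(strip_allele)
    out["junction"] = df[cm.junction].str.upper()
    if cm.junction_aa and cm.junction_aa in df.columns:
        out["junction_aa"] = df[cm.junction_aa]
    else:
        out["junction_aa"] = ""
    out["productive"] = _parse_productive(df[cm.productive])

    bad = out["productive"].isna()
    if bad.any():
        log.warning("%s: rejected %d malformed rows (unparseable productivity)", path, bad.sum())
        out = out[~bad]
    out["productive"] = out["productive"].astype(bool)

    inv = {v: k for k, v in _X_MAP.items()}
    x_cols = [c for c in df.columns if c in inv]
    has_decomp = {inv[c] for c in x_cols} >= set(DECOMPOSITION_FIELDS)
    if has_decomp:
        for c in x_cols:
            out[inv[c]] = pd.to_numeric(df.loc[out.index, c]).astype(int)
    else:
        log.warning("%s: no junction decomposition columns; trim/P/N features will be skipped", path)
    out.attrs["has_decomposition"] = bool(has_decomp)
    out.attrs["anchors_included"] = cm.anchors_included
    return out.reset_index(drop=True)


def filter_functional(records: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the productive records with a non-empty junction (order kept)."""
    keep = records["productive"].astype(bool) & (records["junction"].astype(str).str.len() > 0)
    out = records[keep].reset_index(drop=True)
    out.attrs = dict(records.attrs)
    return out


@dataclass
class CleanRepertoire:
    """One library's filtered, unique-CDR3 record set."""

    library_id: str
    group: str
    records: pd.DataFrame
    n_input: int
    n_filtered: int
    n_unique: int
    dedup_key: str = "junction"
    has_decomposition: bool = True

    def __post_init__(self) -> None:
        if not (self.n_unique <= self.n_filtered <= self.n_input):
            raise IngestError(
                f"{self.library_id}: counts violate n_unique <= n_filtered <= n_input "
                f"({self.n_unique}/{self.n_filtered}/{self.n_input})"
            )
        keys = self.records[self.dedup_key]
        if keys.duplicated().any():
            raise IngestError(f"{self.library_id}: dedup keys not pairwise distinct")

    def counts(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_filtered": self.n_filtered,
            "n_unique": self.n_unique,
        }


def dedup_unique_cdr3(
    records: pd.DataFrame,
    library_id: str = "",
    group: str = "",
    key: str = "junction",
    n_input: int | None = None,
) -> CleanRepertoire:
    """Keep one representative (first occurrence) per unique CDR3.

    ``key`` is ``"junction"`` (nucleotide, default) or ``"junction_aa"``.
    Idempotent: dedup(dedup(x)) == dedup(x).
    """
    if key not in ("junction", "junction_aa"):
        raise IngestError(f"dedup key must be junction or junction_aa, got {key!r}")
    n_filtered = len(records)
    uniq = records.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    uniq.attrs = dict(records.attrs)
    return CleanRepertoire(
        library_id=library_id,
        group=group,
        records=uniq,
        n_input=n_input if n_input is not None else n_filtered,
        n_filtered=n_filtered,
        n_unique=len(uniq),
        dedup_key=key,
        has_decomposition=bool(records.attrs.get("has_decomposition", True)),
    )


def raw_repertoire(records: pd.DataFrame, library_id: str = "", group: str = "") -> CleanRepertoire:
    """Wrap an *unfiltered* record table for feature extraction.

    Intended for simulator validation: productivity selection and unique-CDR3
    dedup both tilt junction statistics away from the generative law (stop
    codons penalize long junctions and stop-prone V tails), so parameter
    recovery must measure the raw emitted records.  Dedup bookkeeping uses
    ``sequence_id``, which is unique by construction.
    """
    return CleanRepertoire(
        library_id=library_id,
        group=group,
        records=records.reset_index(drop=True),
        n_input=len(records),
        n_filtered=len(records),
        n_unique=len(records),
        dedup_key="sequence_id",
        has_decomposition=bool(records.attrs.get("has_decomposition", True)),
    )


def clean_repertoire(
    raw: pd.DataFrame, library_id: str, group: str, key: str = "junction"
) -> CleanRepertoire:
    """Full retention pipeline: productive+CDR3 filter, then unique-CDR3 dedup."""
    filtered = filter_functional(raw)
    return dedup_unique_cdr3(filtered, library_id, group, key=key, n_input=len(raw))
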