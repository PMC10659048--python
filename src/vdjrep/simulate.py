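"""Mechanistic generative model of expressed IGH VDJ rearrangements.

The simulator reproduces the junction-forming steps of V(D)J recombination:

* categorical choice of one IGHV, IGHD and IGHJ segment (weights default to
  uniform over the functional segments of the reference);
* exonucleolytic trimming at the four coding ends cut by RAG1/2 (3'V, 5'D,
  3'D, 5'J), modelled as a truncated geometric deletion length;
* palindromic (P) nucleotides — short inverted repeats of the segment
  terminus left by Artemis hairpin opening — emitted only at ends with zero
  trimming;
* nontemplated (N) nucleotides added by TdT at the V-D and D-J joins, with
  Poisson-distributed lengths;
* productivity (in-frame, stop-free, CYS...TRP anchored junction), with
  optional rejection sampling to an expressed (productive-only) repertoire.

Condition knobs emulate the two experimental contrasts studied with this
model: hindlimb unloading (HU) shifts distal-zone IGHV usage, while aging
additionally shifts median-zone usage, reduces trimming at both IGHD ends,
lengthens N additions and raises the D-J palindrome rate.  Zone usage
factors act as a 5'->3' accessibility gradient within the targeted zone
(gene multiplier ``factor**w`` with ``w`` falling linearly from 1 at the
zone's 5' edge to 0 at its 3' edge): a flat per-zone scalar would leave the
renormalized within-zone usage vector — and hence the within-zone dispersion
index — unchanged, which is not what locus-contraction biology does.

Every emitted record satisfies the junction decomposition identity

    len(junction) = (V tail - v3_trim) + p3v + n1 + p5d
                  + (len(D) - d5_trim - d3_trim) + p3d + n2 + p5j
                  + (J head - j5_trim)

where "V tail" runs from the conserved 2nd-CYS codon to the V 3' end and
"J head" from the J 5' end through the conserved TRP codon.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import poisson as _poisson

from .germline import (
    GermlineError,
    GermlineReference,
    SegmentClass,
    Zone,
)

__all__ = [
    "SimulationConfig",
    "ProductivityReason",
    "sample_rearrangement",
    "determine_productivity",
    "apply_condition_effect",
    "simulate_repertoire",
    "write_airr",
    "translate",
    "revcomp",
    "truncated_geometric_pmf",
    "expected_junction_stats",
]

TRIM_ENDS = ("v3", "d5", "d3", "j5")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

DECOMPOSITION_FIELDS = [
    "v3_trim",
    "d5_trim",
    "d3_trim",
    "j5_trim",
    "d_retained_len",
    "p3v_len",
    "p5d_len",
    "p3d_len",
    "p5j_len",
    "n1_len",
    "n2_len",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string (stops as '*')."""
    return "".join(_CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


class ProductivityReason(str, enum.Enum):
    IN_FRAME_NO_STOP = "in_frame_no_stop"
    OUT_OF_FRAME = "out_of_frame"
    STOP_CODON = "stop_codon"
    ANCHOR_MISMATCH = "anchor_mismatch"


def determine_productivity(junction_nt: str) -> tuple[bool, ProductivityReason]:
    """Classify a junction: productive iff in-frame, stop-free and C...W anchored.

    Junctions shorter than 6 nt (no room for both anchors) are out_of_frame
    by convention.
    """
    if len(junction_nt) < 6 or len(junction_nt) % 3 != 0:
        return False, ProductivityReason.OUT_OF_FRAME
    aa = translate(junction_nt)
    if "*" in aa:
        return False, ProductivityReason.STOP_CODON
    if not (aa[0] == "C" and aa[-1] == "W"):
        return False, ProductivityReason.ANCHOR_MISMATCH
    return True, ProductivityReason.IN_FRAME_NO_STOP


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults are the packaged study conditions).

    Trim lengths are truncated geometric: ``P(T=t) proportional to p_trim**t``
    for ``t in 0..max_trim`` (further capped by the segment end's available
    nucleotides), so larger ``p_trim`` means more deletion.  ``p_palindrome``
    is the probability of a P insertion at an untrimmed end; an inserted P is
    the reverse complement of the terminal ``max_p`` nucleotides (2 by
    default, the short inverted repeats Artemis leaves).  N lengths are
    Poisson with mean ``n_mean`` per
    junction, bases i.i.d. with ``n_base_probs`` (uniform by default; set a
    GC bias here if wanted).
    """

    n_sequences: int = 10_000
    seed: int = 0
    v_weights: dict[str, float] | None = None
    d_weights: dict[str, float] | None = None
    j_weights: dict[str, float] | None = None
    p_trim: dict[str, float] = field(
        default_factory=lambda: {"v3": 0.70, "d5": 0.60, "d3": 0.60, "j5": 0.65}
    )
    max_trim: dict[str, int] = field(
        default_factory=lambda: {"v3": 8, "d5": 7, "d3": 7, "j5": 8}
    )
    p_palindrome: dict[str, float] = field(
        default_factory=lambda: {"v3": 0.25, "d5": 0.25, "d3": 0.25, "j5": 0.25}
    )
    max_p: int = 2
    n_mean: dict[str, float] = field(default_factory=lambda: {"vd": 4.0, "dj": 4.0})
    n_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    productive_only: bool = True
    nonfunctional_fraction: float = 0.0
    # condition-effect knobs (see apply_condition_effect)
    distal_v_factor: float = 2.5
    median_v_factor: float = 2.5
    d_trim_scale: float = 0.5
    n_mean_scale: float = 1.5
    p_dj_palindrome_scale: float = 1.5
    condition: str = "control"

    def validate(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        for end in TRIM_ENDS:
            if not 0.0 <= self.p_trim[end] < 1.0:
                raise ValueError(f"p_trim[{end}] must be in [0, 1)")
            if self.max_trim[end] < 0:
                raise ValueError(f"max_trim[{end}] must be >= 0")
            if not 0.0 <= self.p_palindrome[end] <= 1.0:
                raise ValueError(f"p_palindrome[{end}] must be in [0, 1]")
        if self.max_p < 0:
            raise ValueError("max_p must be >= 0")
        for j in ("vd", "dj"):
            if self.n_mean[j] < 0:
                raise ValueError(f"n_mean[{j}] must be >= 0")
        if abs(sum(self.n_base_probs) - 1.0) > 1e-9 or min(self.n_base_probs) < 0:
            raise ValueError("n_base_probs must be a probability vector")
        for scale in (
            self.distal_v_factor,
            self.median_v_factor,
            self.d_trim_scale,
            self.n_mean_scale,
            self.p_dj_palindrome_scale,
        ):
            if scale <= 0:
                raise ValueError("effect-knob scales must be > 0")
        if not 0.0 <= self.nonfunctional_fraction < 1.0:
            raise ValueError("nonfunctional_fraction must be in [0, 1)")
        for weights in (self.v_weights, self.d_weights, self.j_weights):
            if weights is not None:
                vals = list(weights.values())
                if min(vals) < 0 or max(vals) <= 0:
                    raise ValueError("segment weights must be >= 0 with >= 1 positive")


CONDITIONS = ("control", "HU", "aged")


def _zone_gradient(weights: dict[str, float], reference: GermlineReference, zone: Zone, factor: float) -> None:
    """Scale a zone's V weights by factor**w, w linear 1 -> 0 along the zone (5'->3')."""
    genes = [s for s in reference.functional(SegmentClass.V) if s.zone is zone]
    m = len(genes)
    for i, seg in enumerate(genes):
        w = 1.0 if m == 1 else 1.0 - i / (m - 1)
        weights[seg.name] = weights.get(seg.name, 0.0) * factor**w


def _uniform_weights(reference: GermlineReference, cls: SegmentClass) -> dict[str, float]:
    segs = reference.functional(cls)
    return {s.name: 1.0 for s in segs}


def apply_condition_effect(
    base: SimulationConfig, condition: str, reference: GermlineReference
) -> SimulationConfig:
    """Return a config with a condition's effect knobs applied.

    control -> identity; HU -> ``distal_v_factor`` gradient over distal-zone V
    weights only; aged -> distal and median gradients plus reduced D-end
    trimming (``d_trim_scale``), longer N additions (``n_mean_scale`` at both
    junctions; TdT acts systemically) and more D-J palindromes
    (``p_dj_palindrome_scale`` at the 3'D and 5'J ends).  Weights are
    renormalized at sampling time, so relative weights outside the targeted
    zone are untouched.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cfg = copy.deepcopy(base)
    cfg.condition = condition
    if condition == "control":
        return cfg
    weights = dict(base.v_weights) if base.v_weights is not None else _uniform_weights(
        reference, SegmentClass.V
    )
    _zone_gradient(weights, reference, Zone.DISTAL, cfg.distal_v_factor)
    if condition == "aged":
        _zone_gradient(weights, reference, Zone.MEDIAN, cfg.median_v_factor)
        for end in ("d5", "d3"):
            cfg.p_trim[end] = min(cfg.p_trim[end] * cfg.d_trim_scale, 0.999)
        for j in ("vd", "dj"):
            cfg.n_mean[j] = cfg.n_mean[j] * cfg.n_mean_scale
        for end in ("d3", "j5"):
            cfg.p_palindrome[end] = min(cfg.p_palindrome[end] * cfg.p_dj_palindrome_scale, 1.0)
    cfg.v_weights = weights
    return cfg


# ---------------------------------------------------------------------------
# sampling machinery


def _resolve_weights(
    reference: GermlineReference, cls: SegmentClass, weights: dict[str, float] | None
) -> tuple[list[str], np.ndarray]:
    segs = reference.functional(cls)
    names = [s.name for s in segs]
    if weights is None:
        w = np.ones(len(names))
    else:
        unknown = set(weights) - set(names)
        if unknown:
            raise GermlineError(
                f"{cls.value} weights name unknown/non-functional segments: {sorted(unknown)}"
            )
        w = np.array([weights.get(n, 0.0) for n in names], dtype=float)
    if w.sum() <= 0 or w.min() < 0:
        raise ValueError(f"{cls.value} weights must be >= 0 with >= 1 positive")
    return names, w / w.sum()


def _sample_trunc_geom(
    rng: np.random.Generator, q: float, tmax: np.ndarray
) -> np.ndarray:
    """Vectorized truncated geometric: P(T=t) ~ q**t, t in 0..tmax (per-element)."""
    tmax = np.asarray(tmax)
    if q <= 0.0:
        return np.zeros(tmax.shape, dtype=np.int64)
    u = rng.random(tmax.shape)
    denom = 1.0 - q ** (tmax + 1.0)
    t = np.floor(np.log1p(-u * denom) / math.log(q)).astype(np.int64)
    return np.clip(t, 0, tmax.astype(np.int64))


def truncated_geometric_pmf(q: float, tmax: int) -> np.ndarray:
    """pmf of the deletion-length law on 0..tmax."""
    if q <= 0.0:
        pmf = np.zeros(tmax + 1)
        pmf[0] = 1.0
        return pmf
    pmf = q ** np.arange(tmax + 1, dtype=float)
    return pmf / pmf.sum()


class _Machinery:
    """Precomputed per-reference arrays used by the batch sampler."""

    def __init__(self, config: SimulationConfig, reference: GermlineReference):
        config.validate()
        self.config = config
        self.reference = reference
        self.v_names, self.v_probs = _resolve_weights(reference, SegmentClass.V, config.v_weights)
        self.d_names, self.d_probs = _resolve_weights(reference, SegmentClass.D, config.d_weights)
        self.j_names, self.j_probs = _resolve_weights(reference, SegmentClass.J, config.j_weights)
        v_segs = reference.functional(SegmentClass.V)
        d_segs = reference.functional(SegmentClass.D)
        j_segs = reference.functional(SegmentClass.J)
        # V tail: 2nd-CYS codon through the 3' end; trimming may not enter the codon
        self.v_tails = [s.sequence[s.anchor_offset :] for s in v_segs]
        self.v_tail_len = np.array([len(t) for t in self.v_tails])
        self.v_tmax = np.minimum(config.max_trim["v3"], self.v_tail_len - 3)
        self.v_pal = [
            [revcomp(s.sequence[-k:]) for k in range(1, config.max_p + 1)] for s in v_segs
        ]
        self.d_seqs = [s.sequence for s in d_segs]
        self.d_len = np.array([len(s) for s in self.d_seqs])
        self.d5_tmax = np.minimum(config.max_trim["d5"], self.d_len)
        self.d3_tmax = np.minimum(config.max_trim["d3"], self.d_len)
        self.d_pal5 = [[revcomp(s[:k]) for k in range(1, config.max_p + 1)] for s in self.d_seqs]
        self.d_pal3 = [[revcomp(s[-k:]) for k in range(1, config.max_p + 1)] for s in self.d_seqs]
        # J head: 5' end through the TRP codon; trimming may not enter the codon
        self.j_heads = [s.sequence[: s.anchor_offset + 3] for s in j_segs]
        self.j_head_len = np.array([len(h) for h in self.j_heads])
        self.j_tmax = np.minimum(config.max_trim["j5"], self.j_head_len - 3)
        self.j_pal = [[revcomp(s.sequence[:k]) for k in range(1, config.max_p + 1)] for s in j_segs]

    def snapshot(self) -> dict:
        c = self.config
        return {
            "condition": c.condition,
            "seed": c.seed,
            "n_sequences": c.n_sequences,
            "productive_only": c.productive_only,
            "nonfunctional_fraction": c.nonfunctional_fraction,
            "v_genes": self.v_names,
            "v_probs": self.v_probs.tolist(),
            "d_genes": self.d_names,
            "d_probs": self.d_probs.tolist(),
            "j_genes": self.j_names,
            "j_probs": self.j_probs.tolist(),
            "p_trim": dict(c.p_trim),
            "max_trim": dict(c.max_trim),
            "v_tmax": self.v_tmax.tolist(),
            "d5_tmax": self.d5_tmax.tolist(),
            "d3_tmax": self.d3_tmax.tolist(),
            "j_tmax": self.j_tmax.tolist(),
            "d_lengths": self.d_len.tolist(),
            "p_palindrome": dict(c.p_palindrome),
            "max_p": c.max_p,
            "n_mean": dict(c.n_mean),
            "n_base_probs": list(c.n_base_probs),
        }

    def sample_batch(self, rng: np.random.Generator, m: int, assemble_mask=None):
        """Draw m rearrangements; returns a dict of numpy arrays + python lists.

        String assembly is restricted to ``assemble_mask`` (default: all) so
        rejection sampling can skip out-of-frame candidates cheaply.
        """
        c = self.config
        v_idx = rng.choice(len(self.v_names), size=m, p=self.v_probs)
        d_idx = rng.choice(len(self.d_names), size=m, p=self.d_probs)
        j_idx = rng.choice(len(self.j_names), size=m, p=self.j_probs)
        v3 = _sample_trunc_geom(rng, c.p_trim["v3"], self.v_tmax[v_idx])
        j5 = _sample_trunc_geom(rng, c.p_trim["j5"], self.j_tmax[j_idx])
        d5 = _sample_trunc_geom(rng, c.p_trim["d5"], self.d5_tmax[d_idx])
        d3 = _sample_trunc_geom(rng, c.p_trim["d3"], self.d3_tmax[d_idx])
        # D may not be over-deleted: resample the offending pairs (bounded retries)
        dlen = self.d_len[d_idx]
        for _ in range(100):
            bad = d5 + d3 > dlen
            if not bad.any():
                break
            d5[bad] = _sample_trunc_geom(rng, c.p_trim["d5"], self.d5_tmax[d_idx][bad])
            d3[bad] = _sample_trunc_geom(rng, c.p_trim["d3"], self.d3_tmax[d_idx][bad])
        else:  # pragma: no cover - requires pathological trim settings
            raise RuntimeError("could not draw valid D trims (D fully deleted repeatedly)")
        d_ret = dlen - d5 - d3

        def pal_lengths(p_end: float, trims: np.ndarray) -> np.ndarray:
            # P insertion = reverse complement of the terminal max_p nt,
            # possible only at an untrimmed (hairpin-derived) end
            if c.max_p == 0 or p_end == 0.0:
                return np.zeros(m, dtype=np.int64)
            active = (trims == 0) & (rng.random(m) < p_end)
            return np.where(active, c.max_p, 0)

        p3v = pal_lengths(c.p_palindrome["v3"], v3)
        p5d = pal_lengths(c.p_palindrome["d5"], d5)
        p3d = pal_lengths(c.p_palindrome["d3"], d3)
        p5j = pal_lengths(c.p_palindrome["j5"], j5)
        n1 = rng.poisson(c.n_mean["vd"], size=m)
        n2 = rng.poisson(c.n_mean["dj"], size=m)
        jlen = (
            self.v_tail_len[v_idx]
            - v3
            + p3v
            + n1
            + p5d
            + d_ret
            + p3d
            + n2
            + p5j
            + self.j_head_len[j_idx]
            - j5
        )

        if isinstance(assemble_mask, str):
            if assemble_mask != "in_frame":
                raise ValueError(f"unknown assemble mode {assemble_mask!r}")
            assemble_mask = (jlen % 3 == 0) & (jlen >= 6)
        elif assemble_mask is None:
            assemble_mask = np.ones(m, dtype=bool)
        n_total = int(n1[assemble_mask].sum() + n2[assemble_mask].sum())
        n_bases = rng.choice(list(_BASES), size=n_total, p=np.asarray(c.n_base_probs))
        junctions: list[str | None] = [None] * m
        pos = 0
        for i in np.flatnonzero(assemble_mask):
            vi, di, ji = v_idx[i], d_idx[i], j_idx[i]
            t = int(v3[i])
            vpart = self.v_tails[vi][: len(self.v_tails[vi]) - t] if t else self.v_tails[vi]
            k = int(n1[i])
            n1s = "".join(n_bases[pos : pos + k])
            pos += k
            dpart = self.d_seqs[di][int(d5[i]) : int(self.d_len[di] - d3[i])]
            k = int(n2[i])
            n2s = "".join(n_bases[pos : pos + k])
            pos += k
            junctions[i] = (
                vpart
                + (self.v_pal[vi][p3v[i] - 1] if p3v[i] else "")
                + n1s
                + (self.d_pal5[di][p5d[i] - 1] if p5d[i] else "")
                + dpart
                + (self.d_pal3[di][p3d[i] - 1] if p3d[i] else "")
                + n2s
                + (self.j_pal[ji][p5j[i] - 1] if p5j[i] else "")
                + self.j_heads[ji][int(j5[i]) :]
            )
        return {
            "v_idx": v_idx,
            "d_idx": d_idx,
            "j_idx": j_idx,
            "v3_trim": v3,
            "d5_trim": d5,
            "d3_trim": d3,
            "j5_trim": j5,
            "d_retained_len": d_ret,
            "p3v_len": p3v,
            "p5d_len": p5d,
            "p3d_len": p3d,
            "p5j_len": p5j,
            "n1_len": n1,
            "n2_len": n2,
            "junction_len": jlen,
            "junction": junctions,
        }


def _batch_to_frame(mach: _Machinery, batch: dict, keep: np.ndarray, id_prefix: str, start: int) -> pd.DataFrame:
    idx = np.flatnonzero(keep)
    junctions = [batch["junction"][i] for i in idx]
    aa = []
    productive = []
    for j in junctions:
        ok, _reason = determine_productivity(j)
        productive.append(ok)
        aa.append(translate(j) if len(j) % 3 == 0 and len(j) >= 3 else "")
    df = pd.DataFrame(
        {
            "sequence_id": [f"{id_prefix}{start + k}" for k in range(len(idx))],
            "v_call": [mach.v_names[i] for i in batch["v_idx"][idx]],
            "d_call": [mach.d_names[i] for i in batch["d_idx"][idx]],
            "j_call": [mach.j_names[i] for i in batch["j_idx"][idx]],
            "junction": junctions,
            "junction_aa": aa,
            "productive": productive,
        }
    )
    for f in DECOMPOSITION_FIELDS:
        df[f] = batch[f][idx]
    return df


def simulate_repertoire(
    config: SimulationConfig,
    reference: GermlineReference,
    id_prefix: str = "sim-",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a repertoire; returns (records table, ground-truth snapshot).

    With ``productive_only`` the sampler rejects until ``n_sequences``
    productive records are emitted (a ``nonfunctional_fraction`` share of
    nonproductive records can be retained to mimic raw expressed libraries).
    Fully reproducible from ``config.seed``.  Aborts with a diagnostic if the
    productive acceptance rate falls below 1%.
    """
    mach = _Machinery(config, reference)
    snapshot = mach.snapshot()
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    if n == 0:
        cols = [
            "sequence_id",
            "v_call",
            "d_call",
            "j_call",
            "junction",
            "junction_aa",
            "productive",
        ] + DECOMPOSITION_FIELDS
        return pd.DataFrame(columns=cols), snapshot

    frames: list[pd.DataFrame] = []
    if not config.productive_only:
        batch = mach.sample_batch(rng, n)
        frames.append(_batch_to_frame(mach, batch, np.ones(n, dtype=bool), id_prefix, 0))
    else:
        n_nonfunc = int(round(config.nonfunctional_fraction * n))
        n_prod_target = n - n_nonfunc
        got_prod = 0
        got_nonf = 0
        attempts = 0
        accepted = 0
        while got_prod < n_prod_target or got_nonf < n_nonfunc:
            missing = (n_prod_target - got_prod) + (n_nonfunc - got_nonf)
            m = max(1024, int(missing * 3.5))
            # skip string assembly for out-of-frame draws unless we still need
            # nonfunctional records
            mask_mode = "in_frame" if n_nonfunc == 0 else None
            batch = mach.sample_batch(rng, m, assemble_mask=mask_mode)
            in_frame = (batch["junction_len"] % 3 == 0) & (batch["junction_len"] >= 6)
            prod = np.zeros(m, dtype=bool)
            for i in np.flatnonzero(in_frame):
                prod[i] = "*" not in translate(batch["junction"][i])
            keep = np.zeros(m, dtype=bool)
            if got_prod < n_prod_target:
                pi = np.flatnonzero(prod)[: n_prod_target - got_prod]
                keep[pi] = True
                got_prod += len(pi)
            if got_nonf < n_nonfunc:
                ni = np.flatnonzero(~prod)[: n_nonfunc - got_nonf]
                keep[ni] = True
                got_nonf += len(ni)
            frames.append(_batch_to_frame(mach, batch, keep, id_prefix, 0))
            attempts += m
            accepted += int(prod.sum())
            if attempts >= 4096 and accepted / attempts < 0.01:
                raise RuntimeError(
                    f"productive acceptance rate {accepted / attempts:.4f} < 1% "
                    f"after {attempts} draws; check trim/N settings against the reference"
                )
    out = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
    out = out.iloc[:n].reset_index(drop=True)
    out["sequence_id"] = [f"{id_prefix}{k:06d}" for k in range(len(out))]
    return out, snapshot


def sample_rearrangement(
    config: SimulationConfig, reference: GermlineReference, rng: np.random.Generator
) -> pd.Series:
    """Draw a single rearrangement record (no productivity rejection)."""
    mach = _Machinery(config, reference)
    batch = mach.sample_batch(rng, 1)
    df = _batch_to_frame(mach, batch, np.ones(1, dtype=bool), "one-", 0)
    return df.iloc[0]


# ---------------------------------------------------------------------------
# AIRR serialization

AIRR_CORE = ["sequence_id", "v_call", "d_call", "j_call", "junction", "junction_aa", "productive"]
_X_MAP = {
    "v3_trim": "x_v3_trim",
    "d5_trim": "x_d5_trim",
    "d3_trim": "x_d3_trim",
    "j5_trim": "x_j5_trim",
    "d_retained_len": "x_d_retained",
    "p3v_len": "x_p3v",
    "p5d_len": "x_p5d",
    "p3d_len": "x_p3d",
    "p5j_len": "x_p5j",
    "n1_len": "x_n1",
    "n2_len": "x_n2",
}


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as an AIRR Rearrangement TSV (productive serialized T/F).

    Junction decomposition fields go to ``x_``-prefixed extension columns.
    """
    df = records.copy()
    df["productive"] = np.where(df["productive"].astype(bool), "T", "F")
    df = df.rename(columns=_X_MAP)
    cols = AIRR_CORE + [v for k, v in _X_MAP.items() if v in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# exact moments of the generative law (oracles for parameter recovery)


def _trunc_geom_moments(q: float, tmax: int) -> tuple[float, float]:
    pmf = truncated_geometric_pmf(q, tmax)
    t = np.arange(tmax + 1)
    mean = float((pmf * t).sum())
    var = float((pmf * t**2).sum() - mean**2)
    return mean, var


def expected_junction_stats(snapshot: dict) -> dict:
    """Exact marginal means/variances of trims and N lengths under a snapshot.

    V3/J5 trims marginalize the truncated-geometric law over segment usage
    (the cap depends on the segment drawn).  D-end trims additionally
    condition on the joint validity constraint ``d5 + d3 <= len(D)`` — the
    sampler resamples offending pairs, which tilts the marginals, and this
    oracle reproduces that law exactly by enumeration.
    """
    out: dict[str, dict[str, float]] = {}

    def mix(probs, tmaxes, q) -> tuple[float, float]:
        m1 = m2 = 0.0
        for p, tm in zip(probs, tmaxes):
            mean, var = _trunc_geom_moments(q, int(tm))
            m1 += p * mean
            m2 += p * (var + mean**2)
        return m1, m2 - m1**2

    mean, var = mix(snapshot["v_probs"], snapshot["v_tmax"], snapshot["p_trim"]["v3"])
    out["v3_trim"] = {"mean": mean, "var": var}
    mean, var = mix(snapshot["j_probs"], snapshot["j_tmax"], snapshot["p_trim"]["j5"])
    out["j5_trim"] = {"mean": mean, "var": var}

    q5, q3 = snapshot["p_trim"]["d5"], snapshot["p_trim"]["d3"]
    m5 = m5sq = m3 = m3sq = mret = mretsq = 0.0
    for p, t5, t3, dlen in zip(
        snapshot["d_probs"], snapshot["d5_tmax"], snapshot["d3_tmax"], snapshot["d_lengths"]
    ):
        pmf5 = truncated_geometric_pmf(q5, int(t5))
        pmf3 = truncated_geometric_pmf(q3, int(t3))
        joint = np.outer(pmf5, pmf3)
        a, b = np.meshgrid(np.arange(int(t5) + 1), np.arange(int(t3) + 1), indexing="ij")
        valid = (a + b) <= dlen
        joint = np.where(valid, joint, 0.0)
        joint /= joint.sum()
        e5 = float((joint * a).sum())
        e3 = float((joint * b).sum())
        ret = dlen - a - b
        m5 += p * e5
        m5sq += p * float((joint * a**2).sum())
        m3 += p * e3
        m3sq += p * float((joint * b**2).sum())
        mret += p * float((joint * ret).sum())
        mretsq += p * float((joint * ret**2).sum())
    out["d5_trim"] = {"mean": m5, "var": m5sq - m5**2}
    out["d3_trim"] = {"mean": m3, "var": m3sq - m3**2}
    out["d_retained_len"] = {"mean": mret, "var": mretsq - mret**2}
    for j, col in (("vd", "n1_len"), ("dj", "n2_len")):
        lam = snapshot["n_mean"][j]
        out[col] = {"mean": lam, "var": lam}

    # marginal P(trim = 0) per end, for palindrome-rate oracles
    p_zero: dict[str, float] = {}
    for end, probs, tmaxes in (
        ("v3", snapshot["v_probs"], snapshot["v_tmax"]),
        ("j5", snapshot["j_probs"], snapshot["j_tmax"]),
    ):
        q = snapshot["p_trim"][end]
        p_zero[end] = float(
            sum(p * truncated_geometric_pmf(q, int(tm))[0] for p, tm in zip(probs, tmaxes))
        )
    pz5 = pz3 = 0.0
    for p, t5, t3, dlen in zip(
        snapshot["d_probs"], snapshot["d5_tmax"], snapshot["d3_tmax"], snapshot["d_lengths"]
    ):
        pmf5 = truncated_geometric_pmf(q5, int(t5))
        pmf3 = truncated_geometric_pmf(q3, int(t3))
        joint = np.outer(pmf5, pmf3)
        a, b = np.meshgrid(np.arange(int(t5) + 1), np.arange(int(t3) + 1), indexing="ij")
        joint = np.where((a + b) <= dlen, joint, 0.0)
        joint /= joint.sum()
        pz5 += p * float(joint[0, :].sum())
        pz3 += p * float(joint[:, 0].sum())
    p_zero["d5"], p_zero["d3"] = pz5, pz3
    out["p_zero_trim"] = p_zero

    # derived binary-feature rates: palindromes fire independently at
    # untrimmed ends; total N additions are Poisson(lambda_vd + lambda_dj)
    pal = snapshot["p_palindrome"]
    out["palindrome_vd_rate"] = 1.0 - (1.0 - pal["v3"] * p_zero["v3"]) * (
        1.0 - pal["d5"] * p_zero["d5"]
    )
    out["palindrome_dj_rate"] = 1.0 - (1.0 - pal["d3"] * p_zero["d3"]) * (
        1.0 - pal["j5"] * p_zero["j5"]
    )
    lam_total = snapshot["n_mean"]["vd"] + snapshot["n_mean"]["dj"]
    out["n_ge7_rate"] = float(_poisson.sf(6, lam_total))
    return out
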