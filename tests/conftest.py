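import numpy as np
import pytest

from vdjrep import germline
from vdjrep.germline import (
    Functionality,
    GermlineReference,
    GermlineSegment,
    SegmentClass,
    Zone,
)


@pytest.fixture(scope="session")
def murine_ref():
    """Default synthetic murine-like reference: 130 functional V (81/34/15), 15 D, 4 J."""
    return germline.build_toy_reference(seed=7)


@pytest.fixture(scope="session")
def small_ref():
    """A small reference for fast simulation-heavy tests."""
    return germline.build_toy_reference(n_v_per_zone=(4, 2, 2), n_d=3, n_j=3, seed=11)


def _v(name, seq_tail, zone, rank, functionality=Functionality.FUNCTIONAL):
    # 12 nt of 5' padding + CYS codon + tail; anchor at offset 12
    seq = "ATGGCCGCCGCA" + "TGT" + seq_tail
    return GermlineSegment(
        name=name,
        segment_class=SegmentClass.V,
        sequence=seq,
        family=f"{name}F",
        locus_rank=rank,
        functionality=functionality,
        anchor_offset=12,
        zone=zone,
    )


def _j(name, seq_head, rank):
    # head + TRP codon + 6 nt of 3' padding; anchor right after the head
    seq = seq_head + "TGG" + "GGTACC"
    return GermlineSegment(
        name=name,
        segment_class=SegmentClass.J,
        sequence=seq,
        family="JF",
        locus_rank=rank,
        anchor_offset=len(seq_head),
    )


def _d(name, seq, rank):
    return GermlineSegment(
        name=name, segment_class=SegmentClass.D, sequence=seq, family="DF", locus_rank=rank
    )


@pytest.fixture(scope="session")
def tiny_ref():
    """Hand-built 3V/2D/1J reference with known sequences (V1 tail ends ...AG)."""
    segments = [
        _v("V1", "GCTTCCAG", Zone.DISTAL, 1),  # tail ends AG -> P = revcomp(AG) = CT
        _v("V2", "GATCGTCA", Zone.MEDIAN, 2),
        _v("V3", "CCTAGGTT", Zone.PROXIMAL, 3),
        _d("D1", "GGTATTACGAC", 1),
        _d("D2", "TCTACTATGGTTACGAC", 2),
        _j("J1", "CCTAACTAC", 1),  # 9-nt head, anchor_offset 9
    ]
    return GermlineReference(segments)
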