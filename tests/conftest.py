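"""Shared fixtures: tiny guide libraries, hand-built BAMs, simulated screens."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from grnavar import (
    GuideDesign,
    SimulationConfig,
    build_custom_reference,
    simulate_screen,
)
from grnavar.simulate import DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def small_designs() -> list[GuideDesign]:
    return [
        GuideDesign("gA", "G" + "ACGT" * 4 + "AAA", "GENE1", True),
        GuideDesign("gB", "G" + "TGCA" * 4 + "CCC", "GENE1", True),
        GuideDesign("gC", "G" + "CCGG" * 4 + "TTT", "", False),
    ]


@pytest.fixture(scope="session")
def small_reference(small_designs):
    return build_custom_reference(small_designs, DEFAULT_TEMPLATE)


@pytest.fixture(scope="session")
def sim_screen(tmp_path_factory):
    """A modest noiseless-ish screen used by several integration tests."""
    config = SimulationConfig(
        n_cells=80,
        n_guides=16,
        n_nontargeting=4,
        mean_umis_per_cell=25.0,
        mean_reads_per_umi=6.0,
        error_rate=1e-3,
        seed=11,
    )
    return simulate_screen(config, tmp_path_factory.mktemp("sim"))


def make_bam(
    path: Path,
    contigs: dict[str, int],
    reads: list[dict],
) -> Path:
    """Write a BAM from read dicts (keys: name, contig, pos, cigar, seq,
    tags, flag); reads are written in the given order."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )
    order = {name: i for i, name in enumerate(contigs)}
    reads = sorted(
        reads,
        key=lambda s: (
            s.get("contig") is None,
            order.get(s.get("contig"), 0),
            s.get("pos", 0),
        ),
    )
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for spec in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = spec.get("name", "r")
            seg.flag = spec.get("flag", 0)
            contig = spec.get("contig")
            if contig is None:
                seg.reference_id = -1
            else:
                seg.reference_id = order[contig]
                seg.reference_start = spec.get("pos", 0)
                seg.cigartuples = spec.get("cigar")
                seg.mapping_quality = 255
            seg.query_sequence = spec.get("seq")
            for tag, value in spec.get("tags", {}).items():
                seg.set_tag(tag, value)
            bam.write(seg)
    try:
        pysam.index(str(path))
    except pysam.SamtoolsError:  # unsorted unit fixtures: streamed, not fetched
        pass
    return path
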