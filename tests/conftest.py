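import warnings

import pytest

from seedribo import annotation, mapping, psite
from seedribo import simulate as sim


def make_mrna(
    tid: str = "T1",
    utr5: str = "A" * 10,
    cds: str = "ATG" + "GCT" * 8 + "TAA",
    utr3: str = "C" * 8,
    gene_id: str | None = None,
) -> annotation.TranscriptModel:
    seq = utr5 + cds + utr3
    return annotation.TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or tid.split(".")[0],
        biotype="mRNA",
        sequence=seq,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
    )


@pytest.fixture(scope="session")
def sim_reference():
    return sim.simulate_reference(seed=1)


@pytest.fixture(scope="session")
def ref(sim_reference):
    return sim_reference[0]


@pytest.fixture(scope="session")
def dry_library(ref):
    """A 20 000-read dry-stage library pushed through trim -> map ->
    calibrate -> P-site assignment, with its truth table."""
    reads, truth = sim.simulate_footprints(ref, sim.PRESETS["dry"], 20_000, seed=2)
    trimmed = []
    for rid, seq, _q in reads:
        t = mapping.trim_read(seq)
        if t is not None:
            trimmed.append((rid, t))
    footprints, tally, unmapped = mapping.hierarchical_map(trimmed, ref)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        offsets = psite.estimate_offsets(footprints, ref)
    records, stats = psite.assign_psites(footprints, offsets, ref)
    return {
        "reads": reads,
        "truth": truth,
        "trimmed": trimmed,
        "footprints": footprints,
        "tally": tally,
        "unmapped": unmapped,
        "offsets": offsets,
        "records": records,
        "stats": stats,
    }
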