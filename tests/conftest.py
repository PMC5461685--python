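import numpy as np
import pytest

from sekit.algebra import SignalTrack
from sekit.pipeline import call_pipeline
from sekit.simulate import LandscapeSpec, make_genes, make_landscape, make_reads

GENOME_BP = 10_000  # dense-oracle genome size


def random_track(rng: np.random.Generator, genome_bp: int = GENOME_BP) -> SignalTrack:
    """Random piecewise-constant track on one small chromosome."""
    n_blocks = int(rng.integers(0, 12))
    rows = []
    pos = 0
    for _ in range(n_blocks):
        pos += int(rng.integers(0, 800))
        width = int(rng.integers(1, 900))
        if pos + width >= genome_bp:
            break
        rows.append(("chr1", pos, pos + width, float(rng.integers(1, 30))))
        pos += width
    return SignalTrack(rows)


def dense(track: SignalTrack, genome_bp: int = GENOME_BP) -> np.ndarray:
    arr = np.zeros(genome_bp)
    for s, e, v in track.segments("chr1"):
        arr[s:e] = v
    return arr


@pytest.fixture(scope="session")
def landscape():
    """Default planted landscape (seed 0) shared across tests."""
    spec = LandscapeSpec(seed=0)
    peaks, truth = make_landscape(spec)
    reads = make_reads(peaks, seed=0)
    genes, markers = make_genes(truth, spec.chrom_sizes, seed=0)
    return {
        "spec": spec,
        "peaks": peaks,
        "truth": truth,
        "reads": reads,
        "genes": genes,
        "markers": markers,
    }


@pytest.fixture(scope="session")
def called(landscape):
    """Full pipeline result on the default landscape."""
    table, regions, curve = call_pipeline(
        landscape["peaks"], reads=landscape["reads"], genes=landscape["genes"]
    )
    return {"table": table, "regions": regions, "curve": curve}
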