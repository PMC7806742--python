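import numpy as np
import pytest

from tscepi.simulate import SimulationConfig, Study, simulate_study
from tscepi.types import ChromSizes, Interval, PeakSet


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down study that keeps the full design (all scenarios, marks,
    enhancers, decoys) but runs in a couple of seconds."""
    kwargs = dict(
        seed=seed,
        n_genes=300,
        chrom_length=8_000_000,
        n_enhancers=80,
        n_cobound_intergenic=30,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study() -> Study:
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_study):
    from tscepi.simulate import write_study

    d = tmp_path_factory.mktemp("study")
    write_study(small_study, d)
    return d


def random_peakset(
    rng: np.random.Generator,
    n: int,
    chroms: dict[str, int],
    max_len: int = 400,
    factor: str = "X",
) -> PeakSet:
    names = list(chroms)
    ivs = []
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chroms[chrom] - length + 1))
        ivs.append(Interval(chrom, start, start + length))
    return PeakSet(factor, None, ivs)


def bitmap(peaks: PeakSet, chroms: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base boolean cover of a peak set (oracle for the interval algebra)."""
    cover = {c: np.zeros(length, dtype=bool) for c, length in chroms.items()}
    for iv in peaks:
        cover[iv.chrom][iv.start : iv.end] = True
    return cover


def bitmap_to_spans(cover: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    spans = []
    for chrom in sorted(cover):
        arr = cover[chrom]
        padded = np.concatenate([[False], arr, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        spans.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return spans


def peakset_to_spans(peaks: PeakSet) -> list[tuple[str, int, int]]:
    return sorted((iv.chrom, iv.start, iv.end) for iv in peaks)


@pytest.fixture
def toy_sizes() -> ChromSizes:
    return ChromSizes([("chr1", 100_000), ("chr2", 50_000)])
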