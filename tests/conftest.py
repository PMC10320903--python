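import numpy as np
import pytest

from regionstack import GenomeAssembly, RegionSet
from regionstack.regions import POINT


@pytest.fixture
def assembly():
    return GenomeAssembly(name="toy", chrom_sizes={"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def small_assembly():
    return GenomeAssembly(name="tiny", chrom_sizes={"chr1": 10_000})


def make_regions(assembly, rows, kind=POINT, name="test"):
    import pandas as pd

    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(kind=kind, records=df, assembly=assembly, name=name)


@pytest.fixture
def write_text_track(tmp_path):
    def _write(intervals, fname="track.txt"):
        p = tmp_path / fname
        with open(p, "w") as fh:
            for chrom, s, e, v in intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
        return p

    return _write


@pytest.fixture
def write_text_contacts(tmp_path):
    def _write(binsize, chrom_sizes, triplets, fname="contacts.txt"):
        p = tmp_path / fname
        with open(p, "w") as fh:
            fh.write(f"#binsize\t{binsize}\n")
            for chrom, length in chrom_sizes.items():
                fh.write(f"#chrom\t{chrom}\t{length}\n")
            for i, j, v in triplets:
                fh.write(f"{i}\t{j}\t{v}\n")
        return p

    return _write


def random_step_track(rng, chrom_len, max_intervals=12):
    """Random non-overlapping step intervals on one chromosome."""
    n = rng.integers(1, max_intervals + 1)
    cuts = np.sort(rng.choice(np.arange(1, chrom_len), size=2 * n, replace=False))
    out = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        out.append((int(a), int(b), float(rng.normal(0, 3))))
    return out


def per_bp_mean_oracle(intervals, chrom_len, edges):
    """Brute-force per-basepair bin means; uncovered bp are 0, outside NaN."""
    bp = np.zeros(chrom_len)
    for s, e, v in intervals:
        bp[s:e] = v
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        a_i, b_i = int(round(a)), int(round(b))
        if b_i <= 0 or a_i >= chrom_len:
            out.append(np.nan)
            continue
        lo, hi = max(a_i, 0), min(b_i, chrom_len)
        out.append(bp[lo:hi].mean() if hi > lo else np.nan)
    return np.array(out)
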