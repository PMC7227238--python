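import numpy as np
import pytest

from csn import (
    RegionConfig,
    SynthConfig,
    build_csn,
    build_ppcsn,
    generate_dataset,
)

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def random_tokens(rng, length, alphabet):
    return tuple(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


@pytest.fixture(scope="session")
def preset_dataset():
    """The default synthetic genome: 5 families x 20 genes, seed 42."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def preset_run(preset_dataset):
    """CSN and edge-count-matched ppCSN built once on the default genome."""
    ds = preset_dataset
    csn = build_csn(ds.cds, ds.promoters)
    pp = build_ppcsn(csn, seed=1)
    return ds, csn, pp


@pytest.fixture()
def tiny_config():
    """A fast, small study configuration for structural tests."""
    return SynthConfig(n_families=3, genes_per_family=5, cds_len=120,
                       prom_len=40, motifs_per_family=2, motif_len_tokens=5,
                       prom_motif_len=6, seed=11)


@pytest.fixture()
def tiny_run(tiny_config):
    ds = generate_dataset(tiny_config)
    cfg = RegionConfig(promoter_window=40, cds_window=120)
    csn = build_csn(ds.cds, ds.promoters, cfg=cfg)
    return ds, csn, cfg


def brute_directional_ars(target, ref):
    """All-substrings scan: the independent oracle for suffix-array scoring.

    A position's match extends while tokens are equal and plain ACGT
    (ambiguous tokens match nothing, not even themselves).
    """
    def valid(tok):
        return not (set(tok) - set("ACGT"))

    n, m = len(target), len(ref)
    total = 0
    for i in range(n):
        best = 0
        for j in range(m):
            k = 0
            while (i + k < n and j + k < m
                   and target[i + k] == ref[j + k] and valid(target[i + k])):
                k += 1
            best = max(best, k)
        total += best
    return total / n
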