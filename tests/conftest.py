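import numpy as np
import pytest

from rcdomains.tracks_io import BinnedTrack


def make_track(values, bin_size=50_000, chrom="chr1", role="signal", mask=None):
    return BinnedTrack(chrom, bin_size, np.asarray(values, dtype=float),
                       role=role, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def spike_tracks(seed, n_bg=1000, n_sp=100, r=0.5, bg_noise_sd=0.05,
                 spike_floor=100.0, spike_mu=300.0, spike_sd=0.4):
    """Pull-down/control RPM pair built as P = r·C (+ noise) with spiked
    signal bins appended; returns (P, C, r, n_bg)."""
    g = np.random.default_rng(seed)
    C = g.lognormal(np.log(100), 0.3, n_bg + n_sp)
    P = r * C
    if bg_noise_sd > 0:
        P = P * np.exp(g.normal(0.0, bg_noise_sd, n_bg + n_sp))
    P[n_bg:] += spike_floor + g.lognormal(np.log(spike_mu), spike_sd, n_sp)
    return (make_track(P, role="rpm"), make_track(C, role="rpm"), r, n_bg)
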