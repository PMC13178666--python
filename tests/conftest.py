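import numpy as np
import pytest

from ciliaquant.simulate import CellMotif, CiliaVideoSpec, rect_motif


def make_cbf_video(freqs, amps=None, *, n_frames=200, fps=100.0, cell_px=32,
                   noise_sd=0.0, seed=0, phase_gradient=(0.05, 0.05)):
    """Horizontal strip of square cells, one per requested frequency."""
    if amps is None:
        amps = [300.0] * len(freqs)
    gap, side = 4, cell_px
    cells = [
        rect_motif(i + 1, gap, gap + side, gap + i * (side + gap), gap + side + i * (side + gap),
                   beat_frequency=f, amplitude=a, phase_gradient=phase_gradient)
        for i, (f, a) in enumerate(zip(freqs, amps))
    ]
    width = gap + len(freqs) * (side + gap)
    return CiliaVideoSpec(
        n_frames=n_frames, fps=fps, height=side + 2 * gap, width=width,
        cells=cells, noise_sd=noise_sd, seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
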