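"""Synthetic calcium-imaging movies with known ground truth.

Each cell is a disk-shaped footprint whose pixels share one temporal
signal: a Poisson spike train convolved with an exponential calcium
decay kernel ``exp(-t / tau)``, scaled by an amplitude.  Pixel values
are the sum of a static smooth background field, the cell signals, and
i.i.d. Gaussian noise.  Because the detection algorithm consumes only
temporal correlations, this captures exactly the structure it needs:
within-cell pixel pairs correlate at ``sv / (sv + noise_sd^2)`` (sv the
stationary signal variance), background pairs at 0.

The defaults describe the package's reference study condition: a
128 x 128 movie of 2000 raw frames (200 after the pipeline's 10-frame
averaging) with 15 disjoint disk cells of radius 4-6 at SNR 1, spike
rate 0.02 events/frame and decay constant 20 frames — GCaMP-like
transients (~2.5 s decay at ~8 Hz) at a realistic firing sparsity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk

from .movie_io import Footprint, Movie

__all__ = [
    "SynthConfig",
    "generate",
    "expected_pairwise_corr",
    "signal_variance",
    "calcium_kernel",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-movie generator.

    ``noise_sd=None`` resolves to the analytic signal SD, i.e. SNR
    (signal variance over noise variance) of exactly 1.
    """

    frame_shape: tuple[int, int] = (128, 128)
    T: int = 2000
    n_cells: int = 15
    radius_range: tuple[float, float] = (4.0, 6.0)
    min_center_spacing: float = 16.0
    spike_rate: float = 0.02  # expected events per frame
    decay_tau: float = 20.0  # frames
    amplitude: float = 1.0  # intensity units per spike
    noise_sd: float | None = None  # None -> SNR 1
    background: float = 5.0  # amplitude of the smooth static field
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2 or self.n_cells < 0:
            raise ValueError("need T >= 2 and n_cells >= 0")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (low, high)")
        if self.noise_sd is None:
            object.__setattr__(self, "noise_sd", math.sqrt(signal_variance(self)))

    def resolved_noise_sd(self) -> float:
        assert self.noise_sd is not None
        return self.noise_sd

    def with_snr(self, snr: float) -> "SynthConfig":
        """Copy with noise scaled so signal_variance / noise_var = snr."""
        from dataclasses import replace

        return replace(self, noise_sd=math.sqrt(signal_variance(self) / snr))


def calcium_kernel(tau: float, length: int | None = None) -> np.ndarray:
    """Exponential decay kernel ``exp(-t / tau)``, truncated at ~10 tau."""
    if length is None:
        length = max(int(math.ceil(10 * tau)), 1)
    return np.exp(-np.arange(length) / tau)


def signal_variance(config: SynthConfig) -> float:
    """Stationary variance of a cell trace (filtered Poisson shot noise).

    Spike counts per frame are i.i.d. Poisson(rate); filtering by the
    kernel g gives variance ``amplitude^2 * rate * sum_h g_h^2`` with
    ``sum_h g_h^2 = 1 / (1 - exp(-2 / tau))`` for the exponential kernel.
    """
    ssq = 1.0 / (1.0 - math.exp(-2.0 / config.decay_tau))
    return config.amplitude**2 * config.spike_rate * ssq


def expected_pairwise_corr(config: SynthConfig, same_cell: bool) -> float:
    """Analytic correlation between two pixels (shared signal + own noise)."""
    if not same_cell:
        return 0.0
    sv = signal_variance(config)
    return sv / (sv + config.resolved_noise_sd() ** 2)


def _background_field(shape: tuple[int, int], scale: float) -> np.ndarray:
    """Fixed smooth low-order polynomial field; static over time."""
    H, W = shape
    y = np.linspace(0.0, 1.0, H)[:, None]
    x = np.linspace(0.0, 1.0, W)[None, :]
    field = 0.6 + 0.2 * x + 0.15 * y - 0.25 * x * y + 0.15 * x**2 + 0.1 * y**2
    return scale * field


def _place_centers(config: SynthConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample (row, col, radius) triples with the required spacing."""
    H, W = config.frame_shape
    r_lo, r_hi = config.radius_range
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(config.n_cells, 1)
    while len(placed) < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} cells with spacing "
                f"{config.min_center_spacing} in a {H}x{W} frame"
            )
        attempts += 1
        radius = rng.uniform(r_lo, r_hi)
        margin = radius + 1
        row = rng.uniform(margin, H - 1 - margin)
        col = rng.uniform(margin, W - 1 - margin)
        if all(
            math.hypot(row - r0, col - c0) >= config.min_center_spacing
            for r0, c0, _ in placed
        ):
            placed.append((row, col, radius))
    return placed


def generate(
    config: SynthConfig, spike_trains: np.ndarray | None = None
) -> tuple[Movie, list[Footprint], np.ndarray]:
    """Generate a movie, its ground-truth footprints, and the cell traces.

    ``spike_trains`` (shape ``(n_cells, T)``, counts per frame) overrides
    the Poisson draws — handy for constructing exactly-known signals.
    Returns traces of shape ``(n_cells, T)`` (signal only, no noise).
    """
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.frame_shape
    T = config.T
    centers = _place_centers(config, rng)
    footprints = []
    for row, col, radius in centers:
        rr, cc = draw_disk((row, col), radius + 0.5, shape=(H, W))
        footprints.append(Footprint(pixels=frozenset(zip(rr.tolist(), cc.tolist()))))
    if spike_trains is None:
        spike_trains = rng.poisson(config.spike_rate, size=(config.n_cells, T))
    else:
        spike_trains = np.asarray(spike_trains)
        if spike_trains.shape != (config.n_cells, T):
            raise ValueError("spike_trains must have shape (n_cells, T)")
    kernel = calcium_kernel(config.decay_tau)
    traces = np.empty((config.n_cells, T))
    for i in range(config.n_cells):
        traces[i] = config.amplitude * np.convolve(spike_trains[i], kernel)[:T]
    data = np.empty((T, H, W), dtype=np.float32)
    data[:] = _background_field((H, W), config.background)[None]
    for fp, trace in zip(footprints, traces):
        rows, cols = zip(*sorted(fp.pixels))
        data[:, rows, cols] += trace[:, None].astype(np.float32)
    noise_sd = config.resolved_noise_sd()
    if noise_sd > 0:
        # chunked to keep peak memory modest on long movies
        for t0 in range(0, T, 256):
            t1 = min(t0 + 256, T)
            data[t0:t1] += rng.normal(0.0, noise_sd, size=(t1 - t0, H, W)).astype(
                np.float32
            )
    return Movie(data=data), footprints, traces
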