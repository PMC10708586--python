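"""Class-conditioned synthetic EEG, digit stimuli and proxy saliency targets.

The generator emulates the experimental setting — 14-channel, 250-sample
trials recorded at 128 Hz while a white digit on a black screen is shown —
with an analytically controllable model: class ``k`` drives every channel
with a sinusoid at a class-specific frequency (plus channel-specific phase
and Gaussian noise), so class identity is a spectral peak and separability
is set by the amplitude/noise ratio.  Stimulus images come from a built-in
5x7 bitmap glyph set (white on black, like the experiment's screen), and
saliency ground truth is a Gaussian-blurred glyph mask normalised to unit
mass — a stated proxy, not an emulation, of an attention-model output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .eeg_io import (
    N_CHANNELS,
    SAMPLING_RATE,
    TARGET_SAMPLES,
    EEGRecord,
    build_manifest,
)

NYQUIST = SAMPLING_RATE / 2.0


@dataclass
class StimulusImage:
    """Square grayscale digit image with values in [0, 1]."""

    pixels: np.ndarray
    digit: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("stimulus image must be square 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class SaliencyMap:
    """Non-negative 2-D map; when ``normalized`` the values sum to one."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("saliency values must be non-negative")

    def normalize(self) -> "SaliencyMap":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero saliency map")
        return SaliencyMap(self.values / total, normalized=True)


@dataclass
class SynthConfig:
    """World description for the synthetic generator.

    ``class_freqs`` defaults to an even spread of 2..29 Hz over the classes
    (well under the 64 Hz Nyquist limit); ``amp_matrix`` defaults to unit
    amplitude on every channel; ``noise_sd`` of 0.5 gives a clearly
    learnable but non-trivial 2:1 amplitude-to-noise ratio.
    """

    n_per_class: int = 10
    n_classes: int = 10
    seed: int = 0
    class_freqs: np.ndarray | None = None
    amp_matrix: np.ndarray | None = None
    noise_sd: float = 0.5
    image_size: int = 299
    blur_sigma: float | None = None

    def __post_init__(self):
        if not 1 <= self.n_classes <= 10:
            raise ValueError("n_classes must be in 1..10")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.image_size < 28:
            raise ValueError("image_size must be at least 28")
        if self.class_freqs is None:
            self.class_freqs = (
                np.linspace(2.0, 29.0, self.n_classes)
                if self.n_classes > 1
                else np.array([10.0])
            )
        self.class_freqs = np.asarray(self.class_freqs, dtype=float)
        if self.class_freqs.size != self.n_classes:
            raise ValueError("class_freqs must have one entry per class")
        if (self.class_freqs <= 0).any() or (self.class_freqs >= NYQUIST).any():
            raise ValueError(f"class frequencies must lie in (0, {NYQUIST}) Hz")
        if self.amp_matrix is None:
            self.amp_matrix = np.ones((self.n_classes, N_CHANNELS))
        self.amp_matrix = np.asarray(self.amp_matrix, dtype=float)
        if self.amp_matrix.shape != (self.n_classes, N_CHANNELS):
            raise ValueError(
                f"amp_matrix must be ({self.n_classes}, {N_CHANNELS})"
            )
        if self.blur_sigma is None:
            self.blur_sigma = self.image_size / 30.0
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")


def generate_eeg_dataset(config: SynthConfig) -> list[EEGRecord]:
    """Draw ``n_per_class`` records per class from the sinusoid-plus-noise model.

    Channel ``c`` of a class-``k`` record carries
    ``amp[k, c] * sin(2*pi*f_k*t + phi_c + psi_r) + noise`` where the
    channel phases ``phi_c`` are fixed by the seed (making channels
    distinguishable) and ``psi_r`` is a per-record global phase.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(TARGET_SAMPLES) / SAMPLING_RATE
    phi = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    records = []
    for k in range(config.n_classes):
        f_k = config.class_freqs[k]
        for r in range(config.n_per_class):
            psi = rng.uniform(0, 2 * np.pi)
            phase = 2 * np.pi * f_k * t[None, :] + phi[:, None] + psi
            signal = config.amp_matrix[k][:, None] * np.sin(phase)
            if config.noise_sd > 0:
                signal = signal + rng.normal(
                    0.0, config.noise_sd, size=signal.shape
                )
            # these stand in for real recordings, so the GAN-provenance
            # flag stays False
            records.append(
                EEGRecord(
                    signal,
                    label=k,
                    record_id=f"syn-{config.seed}-{k}-{r}",
                ).validate(TARGET_SAMPLES)
            )
    return records


# ---------------------------------------------------------------------------
# Stimulus images
# ---------------------------------------------------------------------------

_GLYPHS = {
    0: ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    9: ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
}

GLYPH_GRID = 7  # glyphs are padded to a 7x7 cell grid before upscaling


def digit_glyph(digit: int) -> np.ndarray:
    """The 7x7 binary cell grid for a digit (5x7 glyph, one blank column pad)."""
    if digit not in _GLYPHS:
        raise ValueError(f"digit must be 0..9, got {digit!r}")
    rows = np.array([[int(ch) for ch in row] for row in _GLYPHS[digit]], dtype=float)
    return np.pad(rows, ((0, 0), (1, 1)))


def render_digit_image(digit: int, image_size: int = 299) -> StimulusImage:
    """White digit glyph on black, nearest-neighbour upscaled to a square."""
    if image_size < GLYPH_GRID:
        raise ValueError(f"image_size must be >= {GLYPH_GRID}")
    cells = digit_glyph(digit)
    idx = (np.arange(image_size) * GLYPH_GRID) // image_size
    return StimulusImage(cells[np.ix_(idx, idx)], digit=digit)


def make_saliency_ground_truth(
    image: StimulusImage, blur_sigma: float
) -> SaliencyMap:
    """Gaussian-blurred glyph mask, normalised to unit mass."""
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    mask = (image.pixels > 0.5).astype(float)
    blurred = ndimage.gaussian_filter(mask, sigma=blur_sigma)
    return SaliencyMap(np.clip(blurred, 0.0, None)).normalize()


def generate_paired_dataset(config: SynthConfig):
    """Index-aligned (EEG record, stimulus image, saliency target) triples.

    Returns ``(records, images, maps, manifest)``; element ``i`` of each
    list describes the same trial.
    """
    records = generate_eeg_dataset(config)
    per_digit_image = {
        k: render_digit_image(k, config.image_size) for k in range(config.n_classes)
    }
    per_digit_map = {
        k: make_saliency_ground_truth(per_digit_image[k], config.blur_sigma)
        for k in range(config.n_classes)
    }
    images = [per_digit_image[rec.label] for rec in records]
    maps = [per_digit_map[rec.label] for rec in records]
    return records, images, maps, build_manifest(records)
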