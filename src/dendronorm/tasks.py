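"""Synthetic data generators for every experiment, plus an optional IDX reader.

Three task families are generated internally, so nothing needs downloading:

* **Binary addition** — pairs of integers presented as bit sequences
  (least-significant bit first) to a two-input recurrent network that must
  emit the bits of the sum; the carry makes the task causal in LSB-first
  order.
* **Synthetic images** — a desk-scale stand-in for 28×28 greyscale digit
  classification: ten fixed smooth random class templates whose informative
  structure is concentrated in the image centre, plus pixelwise Gaussian
  noise.
* **Word streams** — the letter-sequence stimulus of the self-organising
  network: two equiprobable three-letter "words" (``a b…b c`` and
  ``x y…y z``) over a six-letter alphabet, each letter driving its own
  group of 5 of 30 input neurons.

All generators are pure functions of their parameters and the supplied RNG.
The IDX reader is a convenience for externally obtained MNIST-format files
and is never required by the tests or the acceptance surface.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "BinaryAdditionSample",
    "SyntheticImageSet",
    "WordStream",
    "LETTER_GROUPS",
    "gen_binary_addition",
    "gen_synthetic_images",
    "gen_word_stream",
    "read_idx",
]


@dataclass(frozen=True)
class BinaryAdditionSample:
    """One addition problem as LSB-first bit sequences of equal length."""

    a_bits: np.ndarray
    b_bits: np.ndarray
    sum_bits: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.a_bits)
        if not (len(self.b_bits) == len(self.sum_bits) == m):
            raise ValueError("bit sequences must have equal length")

    @staticmethod
    def _to_int(bits: np.ndarray) -> int:
        return int(sum(int(b) << i for i, b in enumerate(bits)))

    @property
    def a(self) -> int:
        return self._to_int(self.a_bits)

    @property
    def b(self) -> int:
        return self._to_int(self.b_bits)

    @property
    def total(self) -> int:
        return self._to_int(self.sum_bits)


def gen_binary_addition(n: int, m: int, rng: np.random.Generator):
    """Draw ``n`` addition problems over ``m``-bit sequences.

    Addends are uniform on [0, 2^(m-1)) so the sum always fits in ``m``
    bits without an overflow step.  Returns ``(inputs, targets)`` with
    inputs (n, m, 2) — the two addend bits per timestep, LSB first — and
    targets (n, m), plus the per-sample dataclasses via ``as_samples``.
    """
    if m < 2:
        raise ValueError("need m >= 2 bits")
    # draw m-1 random bits per addend: uniform integers below 2^(m-1)
    a_bits = np.zeros((n, m), dtype=np.int64)
    b_bits = np.zeros((n, m), dtype=np.int64)
    a_bits[:, : m - 1] = rng.integers(0, 2, size=(n, m - 1))
    b_bits[:, : m - 1] = rng.integers(0, 2, size=(n, m - 1))
    s_bits = np.zeros((n, m), dtype=np.int64)
    carry = np.zeros(n, dtype=np.int64)
    for t in range(m):
        tot = a_bits[:, t] + b_bits[:, t] + carry
        s_bits[:, t] = tot % 2
        carry = tot // 2
    inputs = np.stack([a_bits, b_bits], axis=2).astype(float)
    return inputs, s_bits.astype(float)


def as_samples(inputs: np.ndarray, targets: np.ndarray) -> list[BinaryAdditionSample]:
    return [
        BinaryAdditionSample(inputs[i, :, 0], inputs[i, :, 1], targets[i])
        for i in range(inputs.shape[0])
    ]


@dataclass
class SyntheticImageSet:
    """Generated grey-value images in [0,1] with balanced integer labels."""

    images: np.ndarray  # (N, 28, 28)
    labels: np.ndarray  # (N,)
    templates: np.ndarray  # (10, 28, 28)
    noise_sd: float
    seed: int

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, 784) pixel matrix and one-hot labels, ready for a network."""
        x = self.images.reshape(len(self.labels), -1)
        y = np.eye(10)[self.labels]
        return x, y


def _make_templates(rng: np.random.Generator, side: int = 28, n_classes: int = 10):
    """Smooth random class templates with centre-weighted contrast.

    Each template is a Gaussian-filtered white-noise field, rescaled to full
    [0, 1] contrast and multiplied by a centred Gaussian envelope so that the
    class-discriminative pixels concentrate in the image centre — the
    miniature analogue of handwritten digits living in the middle of the
    frame.
    """
    yy, xx = np.mgrid[0:side, 0:side]
    centre = (side - 1) / 2.0
    envelope = np.exp(-(((yy - centre) ** 2 + (xx - centre) ** 2) / (2 * (side / 4.5) ** 2)))
    templates = np.empty((n_classes, side, side))
    for k in range(n_classes):
        field_ = gaussian_filter(rng.standard_normal((side, side)), sigma=2.5)
        field_ = (field_ - field_.min()) / (field_.max() - field_.min())
        templates[k] = field_ * envelope
    return templates


def gen_synthetic_images(
    n_per_class: int,
    rng: np.random.Generator,
    noise_sd: float = 0.25,
    side: int = 28,
    template_seed: int | None = None,
) -> SyntheticImageSet:
    """Balanced 10-class image set: class template + pixel noise, clipped.

    The class templates are a pure function of ``template_seed`` (derived
    from ``rng`` when not given), so train and test sets drawn with the
    same ``template_seed`` share classes while having independent noise.
    At the default noise level a nearest-template classifier stays above
    90% accuracy (the calibration property), so the task is learnable but
    not trivial for a small sparse network.
    """
    if n_per_class < 1:
        raise ValueError("need at least one image per class")
    if template_seed is None:
        template_seed = int(rng.integers(2**31))
    templates = _make_templates(np.random.default_rng(template_seed), side=side)
    labels = np.repeat(np.arange(10), n_per_class)
    rng.shuffle(labels)
    noise = rng.standard_normal((labels.size, side, side)) * noise_sd
    images = np.clip(templates[labels] + noise, 0.0, 1.0)
    return SyntheticImageSet(images, labels, templates, noise_sd, template_seed)


#: letter → the indices of its 5 dedicated input neurons (30 in total)
LETTER_GROUPS = {
    letter: np.arange(5 * i, 5 * i + 5) for i, letter in enumerate("abcxyz")
}


@dataclass
class WordStream:
    """A concatenation of randomly chosen words over {a,b,c} / {x,y,z}.

    ``letters`` is the presented letter sequence; ``drive`` is the (T, 30)
    binary matrix activating each letter's 5 input neurons; ``word_starts``
    marks the index of each word's first letter.
    """

    letters: str
    drive: np.ndarray
    n_rep: int
    word_starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.word_starts is None:
            self.word_starts = np.arange(0, len(self.letters), self.word_length)

    @property
    def word_length(self) -> int:
        return self.n_rep + 2


def gen_word_stream(length: int, n_rep: int, rng: np.random.Generator) -> WordStream:
    """Concatenate ``length`` independent equiprobable words.

    Each word is ``a b^n_rep c`` or ``x y^n_rep z``; predicting the next
    letter is deterministic inside a word (given a counter for the repeats)
    and chance-level at word boundaries, which is what the normalised
    accuracy score of the self-organising network accounts for.
    """
    if length < 1 or n_rep < 1:
        raise ValueError("length and n_rep must be >= 1")
    words = ["a" + "b" * n_rep + "c", "x" + "y" * n_rep + "z"]
    choices = rng.integers(0, 2, size=length)
    letters = "".join(words[c] for c in choices)
    drive = np.zeros((len(letters), 30))
    for t, letter in enumerate(letters):
        drive[t, LETTER_GROUPS[letter]] = 1.0
    return WordStream(letters=letters, drive=drive, n_rep=n_rep)


def read_idx(images_path, labels_path=None):
    """Read IDX-format (MNIST-style) image and optional label files.

    Images are scaled to [0, 1]; labels returned as an integer array.
    Raises ``ValueError`` on a bad magic number, truncated data, or an
    image/label count mismatch.  Entirely optional: nothing in the package
    requires external data.
    """
    images = _read_idx_array(images_path, expect_dims=3).astype(float) / 255.0
    if labels_path is None:
        return images
    labels = _read_idx_array(labels_path, expect_dims=1).astype(int)
    if labels.shape[0] != images.shape[0]:
        raise ValueError("image and label files disagree on the item count")
    return images, labels


def _read_idx_array(path, expect_dims: int) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(4)
        if len(header) < 4 or header[0] != 0 or header[1] != 0:
            raise ValueError(f"{path}: not an IDX file (bad magic number)")
        dtype_code, ndim = header[2], header[3]
        dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
                  0x0D: ">f4", 0x0E: ">f8"}
        if dtype_code not in dtypes:
            raise ValueError(f"{path}: unknown IDX dtype 0x{dtype_code:02x}")
        if ndim != expect_dims:
            raise ValueError(f"{path}: expected {expect_dims} dimensions, found {ndim}")
        dims = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=dtypes[dtype_code])
        if data.size != int(np.prod(dims)):
            raise ValueError(f"{path}: truncated IDX payload")
    return data.reshape(dims)
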