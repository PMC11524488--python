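"""Synthetic stimulus generators and the optional IDX reader.

Every generator is a pure function of its parameters and a seed.  The image
generators emulate the stimulus classes of developmental-plasticity
experiments: structured binary "natural" stimuli (procedurally drawn toy
glyphs with class-dependent correlated strokes, standing in for handwritten
digits), binarised sinusoidal gratings at evenly spaced orientations, and
i.i.d. Bernoulli noise images.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusBatch",
    "gaussian_data",
    "toy_glyphs",
    "glyph_templates",
    "gratings",
    "binary_noise",
    "read_idx",
    "write_idx",
]


@dataclass
class StimulusBatch:
    """Labelled set of binary images.

    ``images`` has shape ``(n, H, W)`` with values in {0, 1}; ``labels`` are
    integer class indices.
    """

    images: np.ndarray
    labels: np.ndarray
    generator: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.images, (0.0, 1.0)).all():
            raise ValueError("stimulus images must be binary")
        if self.labels.shape[0] != self.images.shape[0]:
            raise ValueError("labels and images disagree in length")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def flat(self) -> np.ndarray:
        """Images flattened to (n, H*W) for use as model input."""
        return self.images.reshape(self.n, -1)

    def save(self, path) -> None:
        import json

        with open(path, "wb") as fh:
            np.savez(
                fh,
                images=self.images,
                labels=self.labels,
                meta=np.frombuffer(
                    json.dumps(
                        {"generator": self.generator, "seed": self.seed, "params": self.params}
                    ).encode(),
                    dtype=np.uint8,
                ),
            )

    @staticmethod
    def load(path) -> "StimulusBatch":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            return StimulusBatch(
                images=data["images"], labels=data["labels"],
                generator=meta["generator"], seed=meta["seed"], params=meta["params"],
            )


def gaussian_data(mean: float, variance: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. scalar Gaussian data, shape (n, 1)."""
    if variance <= 0:
        raise ValueError("variance must be > 0")
    return mean + np.sqrt(variance) * rng.standard_normal((n, 1))


# ---------------------------------------------------------------------------
# toy glyphs


def _draw_line(img, r0, c0, r1, c1):
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rr = np.round(np.linspace(r0, r1, n)).astype(int)
    cc = np.round(np.linspace(c0, c1, n)).astype(int)
    img[rr, cc] = 1.0


def _draw_ring(img, cr, cc, radius, width=0.6):
    size = img.shape[0]
    r, c = np.mgrid[0:size, 0:size]
    d = np.sqrt((r - cr) ** 2 + (c - cc) ** 2)
    img[np.abs(d - radius) <= width] = 1.0


def glyph_templates(size: int, n_classes: int) -> np.ndarray:
    """Procedural binary templates (lines, arcs, crosses) for each class.

    Templates are drawn on an arbitrary grid size so image resolution is a
    free parameter; classes are guaranteed to differ in at least 10% of
    pixels (checked at generation time).
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if not 1 <= n_classes <= 10:
        raise ValueError("n_classes must be in 1..10")
    hi = size - 2
    mid = size // 2
    q = size // 4
    tpl = np.zeros((10, size, size))
    # 0: ring
    _draw_ring(tpl[0], mid, mid, mid - 2)
    # 1: vertical bar
    _draw_line(tpl[1], 1, mid, hi, mid)
    _draw_line(tpl[1], 1, mid - 1, hi, mid - 1)
    # 2: top bar + diagonal + bottom bar
    _draw_line(tpl[2], 1, 1, 1, hi)
    _draw_line(tpl[2], 1, hi, hi, 1)
    _draw_line(tpl[2], hi, 1, hi, hi)
    # 3: two stacked arcs (right-open)
    _draw_ring(tpl[3], q, mid, q)
    _draw_ring(tpl[3], size - q - 1, mid, q)
    tpl[3][:, : mid - 1] = 0.0
    _draw_line(tpl[3], q, 1, q, mid)
    _draw_line(tpl[3], size - q - 1, 1, size - q - 1, mid)
    # 4: open top + cross bar
    _draw_line(tpl[4], 1, q, mid, q)
    _draw_line(tpl[4], mid, 1, mid, hi)
    _draw_line(tpl[4], 1, size - q - 1, hi, size - q - 1)
    # 5: S-path
    _draw_line(tpl[5], 1, hi, 1, 1)
    _draw_line(tpl[5], 1, 1, mid, 1)
    _draw_line(tpl[5], mid, 1, mid, hi)
    _draw_line(tpl[5], mid, hi, hi, hi)
    _draw_line(tpl[5], hi, hi, hi, 1)
    # 6: vertical + lower ring
    _draw_line(tpl[6], 1, q, hi, q)
    _draw_ring(tpl[6], size - q - 1, mid, q - 1)
    # 7: top bar + steep diagonal
    _draw_line(tpl[7], 1, 1, 1, hi)
    _draw_line(tpl[7], 1, hi, hi, mid)
    # 8: two rings
    _draw_ring(tpl[8], q + 1, mid, q - 1)
    _draw_ring(tpl[8], size - q - 2, mid, q)
    # 9: upper ring + right vertical
    _draw_ring(tpl[9], q + 1, mid, q)
    _draw_line(tpl[9], q, size - q, hi, size - q)
    tpl = tpl[:n_classes]
    npix = size * size
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            if np.sum(tpl[i] != tpl[j]) < 0.1 * npix:
                raise AssertionError(f"glyph templates {i} and {j} differ in < 10% of pixels")
    return tpl


def toy_glyphs(
    n: int,
    size: int = 12,
    n_classes: int = 3,
    stroke_noise: float = 0.05,
    rng: np.random.Generator | None = None,
) -> StimulusBatch:
    """Class-structured binary images: fixed templates plus i.i.d. pixel flips.

    Each image is its class template with every pixel flipped independently
    with probability ``stroke_noise``, so within-class pixel correlations are
    nonzero by construction while classes stay well separated.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    tpl = glyph_templates(size, n_classes)
    labels = rng.integers(0, n_classes, size=n)
    images = tpl[labels].copy()
    if stroke_noise > 0:
        flips = rng.random(images.shape) < stroke_noise
        images = np.abs(images - flips.astype(float))
    return StimulusBatch(
        images=images, labels=labels, generator="toy_glyphs",
        params={"size": size, "n_classes": n_classes, "stroke_noise": stroke_noise},
    )


def gratings(
    n: int,
    size: int = 12,
    n_orientations: int = 16,
    rng: np.random.Generator | None = None,
    cycles: float = 2.0,
) -> StimulusBatch:
    """Binarised sinusoidal gratings at evenly spaced orientations.

    Phase is uniform per image; the sinusoid is thresholded at its mean
    (zero).  The orientation index is stored as the label.
    """
    if n_orientations < 2:
        raise ValueError("n_orientations must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    labels = rng.integers(0, n_orientations, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    thetas = labels * np.pi / n_orientations
    r, c = np.mgrid[0:size, 0:size] / size
    k = 2 * np.pi * cycles
    args = k * (c[None] * np.cos(thetas)[:, None, None] + r[None] * np.sin(thetas)[:, None, None])
    images = (np.sin(args + phases[:, None, None]) > 0).astype(float)
    return StimulusBatch(
        images=images, labels=labels, generator="gratings",
        params={"size": size, "n_orientations": n_orientations, "cycles": cycles},
    )


def binary_noise(
    n: int, size: int = 12, p: float = 0.5, rng: np.random.Generator | None = None
) -> StimulusBatch:
    """i.i.d. Bernoulli(p) pixel images (all share label 0)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    images = (rng.random((n, size, size)) < p).astype(float)
    return StimulusBatch(
        images=images, labels=np.zeros(n, dtype=int), generator="binary_noise",
        params={"size": size, "p": p},
    )


# ---------------------------------------------------------------------------
# IDX container (big-endian; the standard digit-image container format)

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
               0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}


def read_idx(path) -> np.ndarray:
    """Read an IDX array file (magic number, big-endian dimensions).

    Binarisation, if wanted, is applied downstream, not here.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise ValueError("IDX file truncated: missing magic number")
    zero, dtype_code, ndim = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zero != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"bad IDX magic number {raw[:4].hex()}")
    if len(raw) < 4 + 4 * ndim:
        raise ValueError("IDX file truncated: missing dimension sizes")
    dims = struct.unpack(f">{ndim}I", raw[4 : 4 + 4 * ndim])
    dtype = np.dtype(_IDX_DTYPES[dtype_code]).newbyteorder(">")
    payload = raw[4 + 4 * ndim :]
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(payload) != expected:
        raise ValueError(
            f"IDX payload has {len(payload)} bytes, dimensions {dims} require {expected}"
        )
    return np.frombuffer(payload, dtype=dtype).reshape(dims).astype(_IDX_DTYPES[dtype_code])


def write_idx(path, array: np.ndarray) -> None:
    """Write an array as IDX (used for round-trip tests and interchange)."""
    array = np.asarray(array)
    codes = {v: k for k, v in _IDX_DTYPES.items()}
    code = codes.get(np.dtype(array.dtype).type)
    if code is None:
        raise ValueError(f"dtype {array.dtype} not representable in IDX")
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, code, array.ndim]))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(np.ascontiguousarray(array, dtype=np.dtype(array.dtype).newbyteorder(">")).tobytes())
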