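"""Look-up-table inverse-CDF (LUT-iCDF) sampling of the standard normal.

Evidence-accumulation simulators spend most of their time drawing
within-trial Gaussian noise.  The LUT-iCDF method replaces each call to a
normal generator by a uniform *integer* draw used directly as an index into
a precomputed table of inverse-CDF values::

    probs  = x, 2x, ..., 1 - x          (granularity x, symmetric about 0.5)
    table  = ndtri(probs)               (N = (1 - x)/x entries)
    sample = table[U{0, ..., N-1}]

The resulting sampler is a discrete approximation of N(0, 1) whose CDF is
within ~x of the exact normal CDF everywhere; a granularity of 1e-4 (9999
table entries) is the recommended default and is indistinguishable from an
exact generator by a two-sample KS test at n = 10^6.

A halved table stores only the non-negative branch and reconstructs signs by
reflecting the uniform index about the table centre, giving a sampler with
exactly the same distribution at half the memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

DEFAULT_GRANULARITY = 1e-4

__all__ = [
    "NormalLUT",
    "HalvedLUT",
    "DEFAULT_GRANULARITY",
    "build_lut",
    "build_halved",
    "draw_standard_normal",
    "draw_halved",
    "lut_to_csv",
    "lut_from_csv",
]


@dataclass(frozen=True)
class NormalLUT:
    """Inverse-CDF table for the standard normal.

    Attributes
    ----------
    granularity : float
        Probability spacing ``x`` of the underlying uniform grid.
    values : numpy.ndarray
        ``ndtri(x), ndtri(2x), ..., ndtri(1 - x)`` — strictly increasing,
        antisymmetric about the centre.
    """

    granularity: float
    values: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def index_low(self) -> int:
        return 0

    @property
    def index_high(self) -> int:
        return self.size - 1

    def variance(self) -> float:
        """Variance of the table's atom distribution (uniform over entries)."""
        return float(np.mean(self.values**2))


@dataclass(frozen=True)
class HalvedLUT:
    """Non-negative half of a :class:`NormalLUT` (memory-halved variant).

    ``full_size`` is the size N of the parent table; for odd N the half
    table's first entry is the central zero.
    """

    granularity: float
    values: np.ndarray = field(repr=False)
    full_size: int

    @property
    def size(self) -> int:
        return self.values.shape[0]


def build_lut(granularity: float = DEFAULT_GRANULARITY) -> NormalLUT:
    """Construct the LUT for a given probability spacing.

    The probability grid starts at ``0 + x`` and finishes at ``1 - x`` (the
    open endpoints map to ∓∞ and are excluded), so the table holds
    ``(1 - x)/x`` entries.

    Raises
    ------
    ValueError
        If ``granularity`` is not in (0, 0.5), or the equally spaced
        sequence does not close exactly on ``1 - granularity``.
    """
    x = float(granularity)
    if not (0.0 < x < 0.5):
        raise ValueError(f"granularity must lie in (0, 0.5); got {granularity!r}")
    n_float = (1.0 - x) / x
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"granularity {granularity!r} does not tile (0, 1): "
            f"(1 - x)/x = {n_float!r} is not an integer"
        )
    probs = np.linspace(x, 1.0 - x, n)
    values = ndtri(probs)
    # enforce exact antisymmetry (ndtri is symmetric to ~1e-16 already)
    values = 0.5 * (values - values[::-1])
    return NormalLUT(granularity=x, values=values)


def build_halved(lut: NormalLUT) -> HalvedLUT:
    """Keep only the non-negative half of a table (centre included if N odd)."""
    n = lut.size
    half = lut.values[(n - 1) // 2 if n % 2 else n // 2 :].copy()
    return HalvedLUT(granularity=lut.granularity, values=half, full_size=n)


def _check_n(n: int) -> int:
    n = int(n)
    if n < 0:
        raise ValueError(f"number of draws must be non-negative; got {n}")
    return n


def draw_standard_normal(lut: NormalLUT, n, rng: np.random.Generator) -> np.ndarray:
    """Draw approximate N(0, 1) variates by uniform integer indexing.

    ``n`` may be an int or a shape tuple.  Each draw is ``values[k]`` with
    ``k`` uniform on ``[index_low, index_high]``; identical seeds give
    identical vectors.
    """
    if np.isscalar(n):
        n = _check_n(n)
    idx = rng.integers(0, lut.size, size=n)
    return lut.values[idx]


def draw_halved(hlut: HalvedLUT, n, rng: np.random.Generator) -> np.ndarray:
    """Draw from the halved table; distribution identical to the full table.

    A single uniform integer over the *full* index range [0, N) is reflected
    about the table centre, so no per-draw sign branch is needed and the
    atom probabilities match the full-table sampler exactly.
    """
    if np.isscalar(n):
        n = _check_n(n)
    nfull = hlut.full_size
    j = rng.integers(0, nfull, size=n)
    if nfull % 2:  # odd parent: half[0] is the central zero
        d = j - (nfull - 1) // 2
        return np.sign(d) * hlut.values[np.abs(d)]
    d = j - nfull // 2
    out = np.where(d >= 0, 1.0, -1.0)
    out *= hlut.values[np.where(d >= 0, d, -d - 1)]
    return out


def mirror_halved(hlut: HalvedLUT) -> np.ndarray:
    """Reconstruct the full, ordered table from its non-negative half."""
    if hlut.full_size % 2:
        neg = -hlut.values[:0:-1]
    else:
        neg = -hlut.values[::-1]
    return np.concatenate([neg, hlut.values])


def lut_to_csv(lut: NormalLUT, path) -> None:
    """Export table values as a single-column CSV (header ``icdf_value``)."""
    with open(path, "w") as fh:
        fh.write("icdf_value\n")
        for v in lut.values:
            fh.write(f"{float(v)!r}\n")


def lut_from_csv(path) -> NormalLUT:
    """Re-import a table written by :func:`lut_to_csv`.

    The granularity is recovered from the element count (x = 1/(N + 1)).
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "icdf_value":
            raise ValueError(f"expected header 'icdf_value', got {header!r}")
        values = np.array([float(line) for line in fh if line.strip()])
    if values.size == 0:
        raise ValueError("empty LUT file")
    return NormalLUT(granularity=1.0 / (values.size + 1), values=values)
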