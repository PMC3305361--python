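"""Intensity-space transforms.

Two-allele array genotyping works in a rotated coordinate system: a
*contrast* axis that separates the genotype clusters and an *average
intensity* axis that carries hybridization strength.  For A- and
B-allele intensities ``a, b > 0``:

MA transform
    contrast = (a - b) / (a + b),  average = log2((a + b) / 2)

CCS transform
    contrast = asinh(k * (a - b) / (a + b)) / asinh(k), same average.

The CCS (contrast-centers-stretch) variant compresses the homozygous
contrast range and stretches the heterozygous one, which makes the
three genotype clusters more evenly spaced before mixture fitting.
It fixes the points -1, 0 and +1 and is strictly increasing in the MA
contrast for any ``k > 0``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ma_transform",
    "ccs_transform",
    "ma_to_ccs",
    "ccs_to_ma",
    "summarize_probe_set",
]

DEFAULT_CCS_K = 4.0


def _check_positive(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be strictly positive")
    return a, b


def ma_transform(a_intensity, b_intensity):
    """Return ``(contrast, average)`` of the MA transform.

    contrast = (a - b)/(a + b) lies in (-1, 1) for positive inputs;
    average = log2((a + b)/2).  Accepts scalars or arrays.
    """
    a, b = _check_positive(a_intensity, b_intensity)
    s = a + b
    return (a - b) / s, np.log2(s / 2.0)


def ma_to_ccs(contrast, k: float = DEFAULT_CCS_K):
    """Map an MA contrast to the CCS scale: asinh(k*c)/asinh(k)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return np.arcsinh(k * np.asarray(contrast, dtype=float)) / np.arcsinh(k)


def ccs_to_ma(contrast, k: float = DEFAULT_CCS_K):
    """Inverse of :func:`ma_to_ccs`: sinh(c*asinh(k))/k."""
    if k <= 0:
        raise ValueError("k must be positive")
    return np.sinh(np.asarray(contrast, dtype=float) * np.arcsinh(k)) / k


def ccs_transform(a_intensity, b_intensity, k: float = DEFAULT_CCS_K):
    """Return ``(contrast, average)`` of the CCS transform with constant ``k``."""
    c, m = ma_transform(a_intensity, b_intensity)
    return ma_to_ccs(c, k), m


def summarize_probe_set(a_by_strand, b_by_strand, retained=None):
    """Average per-strand allele intensities into one (A, B) pair per sample.

    Parameters
    ----------
    a_by_strand, b_by_strand : mapping strand -> 1D array of per-sample
        linear intensities.  Strand keys must agree between the two.
    retained : optional iterable of strand keys to keep (strand QC
        decisions); defaults to all strands present.

    Returns
    -------
    (a, b) : arithmetic means over retained strands, linear scale.

    Raises
    ------
    ValueError if no strand is retained.
    """
    if set(a_by_strand) != set(b_by_strand):
        raise ValueError("A and B strand sets differ")
    strands = list(a_by_strand) if retained is None else [s for s in a_by_strand if s in set(retained)]
    if not strands:
        raise ValueError("probe set retains zero strands")
    a = np.mean([np.asarray(a_by_strand[s], dtype=float) for s in strands], axis=0)
    b = np.mean([np.asarray(b_by_strand[s], dtype=float) for s in strands], axis=0)
    return a, b
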