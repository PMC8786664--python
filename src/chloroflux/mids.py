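"""Mass-isotopomer distribution (MID) arithmetic.

A MID is the vector of fractional abundances of the m+0 ... m+n mass channels of
a metabolite fragment with n carbon atoms.  This module provides normalization
of raw channel intensities, correction for naturally occurring heavy isotopes
(binomial convolution model, solved by non-negative least squares), and the two
summary statistics used throughout the pipeline: fractional enrichment
(average fraction of labelled carbon per atom) and single mass-isotopomer
fractions.

Enrichment is kept as a fraction in [0, 1] internally; report writers convert
to percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "MIDVector",
    "IsotopeModel",
    "EmptyMeasurementError",
    "normalize_mid",
    "correction_matrix",
    "correct_natural_abundance",
    "enrichment",
    "isotopomer_fraction",
]

#: Natural abundance of 13C (fraction of all carbon).
NATURAL_13C = 0.0107

_SUM_TOL = 1e-9


class EmptyMeasurementError(ValueError):
    """Raised when a measurement contains no signal (all channels zero)."""


@dataclass(frozen=True)
class MIDVector:
    """Fractional abundances m+0 ... m+n of one fragment at one time point.

    Parameters
    ----------
    metabolite_id : str
        Metabolite (or fragment) name.
    n_carbons : int
        Number of carbon atoms in the measured fragment; the vector has
        ``n_carbons + 1`` entries.
    fractions : np.ndarray
        Non-negative fractions summing to 1.
    """

    metabolite_id: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if self.n_carbons < 1:
            raise ValueError(f"{self.metabolite_id}: fragment must have >= 1 carbon")
        if frac.ndim != 1 or frac.size != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} mass channels, "
                f"got {frac.size}"
            )
        if np.any(frac < -_SUM_TOL):
            raise ValueError(f"{self.metabolite_id}: negative mass fractions")
        if abs(frac.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite_id}: fractions sum to {frac.sum():.6g}, not 1"
            )

    def with_fractions(self, fractions: np.ndarray) -> "MIDVector":
        return MIDVector(self.metabolite_id, self.n_carbons, fractions)


@dataclass(frozen=True)
class IsotopeModel:
    """Isotope natural-abundance model for MID correction.

    ``p13`` is the natural 13C abundance applied to the fragment's unlabelled
    carbon positions.  ``extra_atoms`` optionally lists non-carbon atoms that
    also shift mass channels (relevant for derivatized GC-MS fragments, e.g.
    silicon from TMS groups), as ``(element, count, heavy_abundance)`` with the
    heavy isotope one mass unit up.  Extra-atom correction is off by default.
    """

    p13: float = NATURAL_13C
    extra_atoms: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p13 < 1.0:
            raise ValueError(f"p13 must be in [0, 1), got {self.p13}")
        for elem, count, p in self.extra_atoms:
            if count < 0 or not 0.0 <= p < 1.0:
                raise ValueError(f"bad extra-atom spec for {elem!r}")


def normalize_mid(
    raw_intensities, metabolite_id: str = "", n_carbons: int | None = None
) -> tuple[MIDVector, float]:
    """Normalize raw mass-channel intensities to a MID.

    Returns the normalized :class:`MIDVector` together with the total intensity
    (the sum over isotopologues, used downstream for pool quantification).

    Raises
    ------
    EmptyMeasurementError
        If every channel is zero.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("need a 1-D vector of at least two mass channels")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = float(raw.sum())
    if total <= 0.0:
        raise EmptyMeasurementError(f"{metabolite_id or 'fragment'}: all channels zero")
    n = raw.size - 1 if n_carbons is None else n_carbons
    return MIDVector(metabolite_id, n, raw / total), total


def _binomial_column(n_unlabelled: int, p: float, length: int) -> np.ndarray:
    col = np.zeros(length)
    k = np.arange(min(n_unlabelled, length - 1) + 1)
    col[k] = binom.pmf(k, n_unlabelled, p)
    return col


def correction_matrix(n_carbons: int, model: IsotopeModel) -> np.ndarray:
    """Natural-abundance convolution matrix for an ``n_carbons`` fragment.

    Column ``j`` holds the measured mass distribution of a species that is
    purely m+j: a binomial over its remaining ``n-j`` unlabelled carbons with
    success probability ``p13``, convolved with any configured extra-atom
    binomials.  Mass channels above m+n are truncated, so columns sum to <= 1.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    n = n_carbons
    size = n + 1
    extra = np.array([1.0])
    for _elem, count, p in model.extra_atoms:
        extra = np.convolve(extra, binom.pmf(np.arange(count + 1), count, p))
    mat = np.zeros((size, size))
    for j in range(size):
        col = _binomial_column(n - j, model.p13, size)
        col = np.convolve(col, extra)[:size]
        mat[j:, j] = col[: size - j]
    return mat


def correct_natural_abundance(mid: MIDVector, model: IsotopeModel) -> MIDVector:
    """Remove the natural heavy-isotope contribution from a measured MID.

    Solves ``measured = C @ true`` by non-negative least squares (never
    produces negative fractions on noisy input) and renormalizes.  With
    ``p13 = 0`` and no extra atoms this is the identity.
    """
    mat = correction_matrix(mid.n_carbons, model)
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"correction matrix for {mid.metabolite_id} is ill-conditioned"
        )
    sol, _ = nnls(mat, mid.fractions)
    total = sol.sum()
    if total <= 0:
        raise np.linalg.LinAlgError(
            f"natural-abundance correction annihilated {mid.metabolite_id}"
        )
    return mid.with_fractions(sol / total)


def enrichment(mid: MIDVector) -> float:
    """Average fractional 13C per carbon atom: sum_i i*m_i / n, in [0, 1]."""
    i = np.arange(mid.n_carbons + 1)
    return float(np.dot(i, mid.fractions) / mid.n_carbons)


def isotopomer_fraction(mid: MIDVector, i: int) -> float:
    """Relative abundance of the m+i mass isotopomer."""
    if not 0 <= i <= mid.n_carbons:
        raise IndexError(
            f"mass index {i} out of range for {mid.n_carbons}-carbon fragment"
        )
    return float(mid.fractions[i])
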