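"""Clebsch-Gordan coupling machinery for SO(3)-equivariant products.

``clebsch_gordan`` evaluates the standard coupling coefficient
<l1 m1 l2 m2 | l3 m3> in the complex spherical-harmonic basis via the Racah
formula, carried out in exact rational arithmetic before a final square root.

``real_coupling`` assembles the corresponding equivariant bilinear map for
*real* spherical tensors: the complex CG tensor conjugated with the
complex-to-real change of basis U.  The result is purely real when
l1 + l2 + l3 is even and purely imaginary when odd; in the odd case the tensor
is multiplied by -i, which leaves it an intertwiner because the real Wigner-D
matrices are real.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import factorial, sqrt

import numpy as np

__all__ = ["clebsch_gordan", "complex_to_real_matrix", "real_coupling"]


def _triangle_ok(l1: int, l2: int, l3: int) -> bool:
    return abs(l1 - l2) <= l3 <= l1 + l2


@lru_cache(maxsize=None)
def _cg_cached(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int) -> float:
    if m1 + m2 != m3 or not _triangle_ok(l1, l2, l3):
        return 0.0
    # Racah's closed form; each term is an exact rational.
    pref = Fraction(2 * l3 + 1) * Fraction(
        factorial(l1 + l2 - l3) * factorial(l1 - l2 + l3) * factorial(-l1 + l2 + l3),
        factorial(l1 + l2 + l3 + 1),
    )
    pref *= Fraction(
        factorial(l1 + m1) * factorial(l1 - m1)
        * factorial(l2 + m2) * factorial(l2 - m2)
        * factorial(l3 + m3) * factorial(l3 - m3)
    )
    k_min = max(0, l2 - l3 - m1, l1 - l3 + m2)
    k_max = min(l1 + l2 - l3, l1 - m1, l2 + m2)
    total = Fraction(0)
    for k in range(k_min, k_max + 1):
        denom = (
            factorial(k)
            * factorial(l1 + l2 - l3 - k)
            * factorial(l1 - m1 - k)
            * factorial(l2 + m2 - k)
            * factorial(l3 - l2 + m1 + k)
            * factorial(l3 - l1 - m2 + k)
        )
        total += Fraction((-1) ** k, denom)
    if total == 0:
        return 0.0
    sign = 1.0 if total > 0 else -1.0
    return sign * sqrt(float(pref * total * total))


def clebsch_gordan(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int) -> float:
    """Coupling coefficient <l1 m1 l2 m2 | l3 m3> (complex harmonic basis).

    Zero unless ``m1 + m2 == m3`` and ``|l1 - l2| <= l3 <= l1 + l2``.
    """
    for l, m in ((l1, m1), (l2, m2), (l3, m3)):
        if l < 0:
            raise ValueError("degrees must be nonnegative")
        if abs(m) > l:
            raise ValueError(f"|m| = {abs(m)} exceeds degree {l}")
    return _cg_cached(l1, l2, l3, m1, m2, m3)


@lru_cache(maxsize=64)
def complex_to_real_matrix(l: int) -> np.ndarray:
    """Unitary U with S = U Y: rows are real harmonics in terms of complex ones.

    Index convention: row/column index i corresponds to m = i - l.
    """
    dim = 2 * l + 1
    u = np.zeros((dim, dim), dtype=complex)
    u[l, l] = 1.0
    s = 1.0 / sqrt(2.0)
    for m in range(1, l + 1):
        u[l + m, l + m] = (-1.0) ** m * s         # cosine-type
        u[l + m, l - m] = s
        u[l - m, l + m] = -1j * (-1.0) ** m * s   # sine-type
        u[l - m, l - m] = 1j * s
    return u


@lru_cache(maxsize=256)
def real_coupling(l1: int, l2: int, l3: int) -> np.ndarray:
    """Equivariant bilinear coupling tensor T for real spherical tensors.

    Shape ``(2*l3+1, 2*l1+1, 2*l2+1)``; satisfies for every rotation R

        T contracted with (D^l1 a, D^l2 b) = D^l3 (T contracted with (a, b)).
    """
    if not _triangle_ok(l1, l2, l3):
        return np.zeros((2 * l3 + 1, 2 * l1 + 1, 2 * l2 + 1))
    c = np.zeros((2 * l3 + 1, 2 * l1 + 1, 2 * l2 + 1))
    for i3, m3 in enumerate(range(-l3, l3 + 1)):
        for i1, m1 in enumerate(range(-l1, l1 + 1)):
            m2 = m3 - m1
            if abs(m2) <= l2:
                c[i3, i1, l2 + m2] = _cg_cached(l1, l2, l3, m1, m2, m3)
    u1 = complex_to_real_matrix(l1)
    u2 = complex_to_real_matrix(l2)
    u3 = complex_to_real_matrix(l3)
    t = np.einsum("ax,xyz,by,cz->abc", u3, c.astype(complex), u1.conj(), u2.conj())
    if (l1 + l2 + l3) % 2 == 0:
        if np.abs(t.imag).max() > 1e-12:
            raise AssertionError("even-parity real coupling should be real")
        return np.ascontiguousarray(t.real)
    if np.abs(t.real).max() > 1e-12:
        raise AssertionError("odd-parity real coupling should be imaginary")
    return np.ascontiguousarray((-1j * t).real)
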