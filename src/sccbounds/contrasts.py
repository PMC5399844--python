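"""Contrast-coefficient vectors for the global interaction bounds.

The global lower bound minimises (risk scale) or maximises (odds-ratio
scale) a signed combination of per-profile quantities over all *contrast
vectors* for each exposure axis.  A contrast vector of length ``L`` has
coefficients in ``{-1, 0, +1}``:

* ``L`` even — exactly ``L/2`` coefficients ``+1`` and ``L/2`` ``-1``,
  no zeros;
* ``L`` odd — exactly one ``0``, with ``(L-1)/2`` each of ``+1`` and ``-1``.

Every distinct arrangement of that multiset is used, so the zero position
(odd ``L``) and the sign placements vary independently on the two axes.
The counts are ``C(L, L/2)`` for even ``L`` and ``L * C(L-1, (L-1)/2)``
for odd ``L``.  Enumeration order is lexicographic, which makes the argmin
contrast pair reported with the global bound deterministic.
"""

from __future__ import annotations

from itertools import permutations, product
from math import comb

__all__ = ["enumerate_contrasts", "contrast_pairs", "n_contrasts"]


def n_contrasts(L: int) -> int:
    """Number of contrast vectors of length ``L`` (closed form)."""
    if L < 2:
        raise ValueError(f"contrast vectors need L >= 2 levels, got {L}")
    if L % 2 == 0:
        return comb(L, L // 2)
    return L * comb(L - 1, (L - 1) // 2)


def enumerate_contrasts(L: int) -> list[tuple[int, ...]]:
    """All contrast vectors of length ``L``, sorted lexicographically.

    >>> enumerate_contrasts(2)
    [(-1, 1), (1, -1)]
    """
    if L < 2:
        raise ValueError(f"contrast vectors need L >= 2 levels, got {L}")
    half = L // 2
    if L % 2 == 0:
        multiset = (1,) * half + (-1,) * half
    else:
        multiset = (0,) + (1,) * half + (-1,) * half
    return sorted(set(permutations(multiset)))


def contrast_pairs(L1: int, L2: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Cartesian product of contrast vectors for the two axes.

    Ordered lexicographically by ``(u, v)``; the sign-flipped partners
    ``(-u, v)`` and ``(u, -v)`` of every pair are also present, so a signed
    product and its reciprocal are both visited by the global minimisation.
    """
    return list(product(enumerate_contrasts(L1), enumerate_contrasts(L2)))
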