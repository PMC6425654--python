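"""Tetrasomic inheritance math.

Gametes of an autotetraploid receive 2 of the 4 homologues, drawn at
random under bivalent pairing with no double reduction, so the B-allele
dosage of a gamete is hypergeometric.  F1 offspring dosage distributions
are the convolution of the two parental gamete distributions; panels in
Hardy-Weinberg equilibrium follow a Binomial(4, p) dosage distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, gcd

import numpy as np

from .datamodel import MAX_DOSAGE, N_DOSAGES, ValidationError

PLOIDY = 4
GAMETE_SIZE = 2


def _check_dosage(d) -> int:
    if d != int(d) or not 0 <= int(d) <= MAX_DOSAGE:
        raise ValidationError(f"dosage {d!r} outside 0..{MAX_DOSAGE}")
    return int(d)


def gamete_distribution(parent_dosage: int) -> np.ndarray:
    """Probabilities of gamete B-dosage 0, 1, 2 for a parent of given dosage.

    Hypergeometric draw of 2 of the 4 chromosomes:
    ``P(g) = C(d, g) C(4-d, 2-g) / C(4, 2)``.
    """
    d = _check_dosage(parent_dosage)
    probs = np.array(
        [comb(d, g) * comb(PLOIDY - d, GAMETE_SIZE - g) for g in range(3)],
        dtype=float,
    )
    return probs / comb(PLOIDY, GAMETE_SIZE)


@dataclass(frozen=True)
class SegregationPrior:
    """Expected F1 offspring dosage distribution for one parental pair."""

    parent1_dosage: int
    parent2_dosage: int
    proportions: tuple[float, ...]
    integer_ratio: tuple[int, ...]


def f1_segregation(parent1_dosage: int, parent2_dosage: int) -> SegregationPrior:
    """Expected offspring dosage proportions for an F1 cross.

    The 5-class distribution is the convolution of the two parental
    gamete distributions; ``integer_ratio`` is the same distribution
    reduced to smallest nonnegative integers.
    """
    d1 = _check_dosage(parent1_dosage)
    d2 = _check_dosage(parent2_dosage)
    g1 = gamete_distribution(d1)
    g2 = gamete_distribution(d2)
    props = np.convolve(g1, g2)
    assert props.shape == (N_DOSAGES,)
    return SegregationPrior(
        parent1_dosage=d1,
        parent2_dosage=d2,
        proportions=tuple(props),
        integer_ratio=tuple(smallest_integer_ratio(props)),
    )


def hw_proportions(allele_freq_b: float) -> np.ndarray:
    """Binomial(4, p) dosage-class proportions under Hardy-Weinberg."""
    p = float(allele_freq_b)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"allele frequency {p} outside [0, 1]")
    j = np.arange(N_DOSAGES)
    return np.array([comb(PLOIDY, int(i)) for i in j]) * p**j * (1 - p)**(PLOIDY - j)


def smallest_integer_ratio(proportions, max_denominator: int = 36) -> np.ndarray:
    """Reduce a rational probability vector to smallest integers (gcd 1).

    Denominators up to 36 cover every tetrasomic F1 segregation case.
    """
    fracs = [Fraction(float(p)).limit_denominator(max_denominator)
             for p in np.asarray(proportions, dtype=float)]
    approx = np.array([float(f) for f in fracs])
    if not np.allclose(approx, np.asarray(proportions, dtype=float), atol=1e-9):
        raise ValidationError("proportions are not rational within tolerance")
    denom = 1
    for f in fracs:
        denom = denom * f.denominator // gcd(denom, f.denominator)
    ints = [int(f * denom) for f in fracs]
    g = 0
    for v in ints:
        g = gcd(g, v)
    g = g or 1
    return np.array([v // g for v in ints], dtype=int)
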