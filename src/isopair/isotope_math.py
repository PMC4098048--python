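"""Isotopologue arithmetic for ¹²C/U-¹³C pair detection.

All of the pipeline's mass arithmetic lives here: deducing the number of
carbon atoms of a metabolite ion from the spacing between its monoisotopic
(M) and fully ¹³C-labelled (M′) signals, the first-order binomial
isotopologue abundance ratios used to validate candidate pairs, estimation
of the ¹³C enrichment degree of the labelled metabolome, and neutral-mass
reconstruction from adduct ions.

The isotope model is carbon-only: every carbon position is independently
¹³C with probability *p*, so isotopologue abundances follow a binomial
distribution.  For pattern *validation* only the first-order ratios are
needed — M+1/M on the native side and M′−1/M′ on the labelled side; the
full binomial ladder is used only by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DELTA_C",
    "PROTON_MASS",
    "DEFAULT_ADDUCTS",
    "IsotopeConstants",
    "EnrichmentModel",
    "carbon_count",
    "expected_m1_ratio",
    "expected_mprime_minus1_ratio",
    "estimate_enrichment",
    "max_direct_carbon",
    "neutral_mass",
    "binomial_pattern",
]

#: Mass difference between ¹³C and ¹²C, in u.
DELTA_C: float = 1.00335

#: Proton mass in u (5-decimal precision, consistent with DELTA_C).
PROTON_MASS: float = 1.00728

_NA_MASS = 22.98922       # Na⁺ adduct shift (sodium minus electron), u
_H2O_MASS = 18.01056      # neutral water loss, u

#: adduct name -> (total m/z shift applied to the neutral mass before
#: dividing by z, charge z).  ``m/z = (neutral + shift) / z``.
DEFAULT_ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (_NA_MASS, 1),
    "[M+H-H2O]+": (PROTON_MASS - _H2O_MASS, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
}


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the carbon-only isotope model."""

    delta_c: float = DELTA_C
    proton_mass: float = PROTON_MASS
    #: natural ¹³C incorporation probability (1.1 % of carbon).
    p_natural: float = 0.0111
    adduct_table: dict[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCTS)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.p_natural < 0.05):
            raise ValueError(f"p_natural out of range: {self.p_natural}")


@dataclass(frozen=True)
class EnrichmentModel:
    """Per-atom ¹³C incorporation probabilities of the two metabolomes.

    ``p_enriched`` is the enrichment degree of the U-¹³C labelled
    metabolome (e.g. 0.995 for the fungal co-cultivation, ~0.975 for
    commercially labelled plant material); ``p_natural`` the natural
    abundance of ¹³C.
    """

    p_enriched: float = 0.995
    p_natural: float = 0.0111

    def __post_init__(self) -> None:
        if not (self.p_enriched > 0.5 > self.p_natural > 0.0):
            raise ValueError(
                "require p_enriched > 0.5 > p_natural > 0, got "
                f"{self.p_enriched}, {self.p_natural}"
            )


def carbon_count(
    mz_m: float, mz_mprime: float, z: int, ppm: float = 2.5
) -> int | None:
    """Carbon atoms of an ion from the M/M′ m/z spacing.

    The spacing between the monoisotopic and the fully labelled signal is
    ``n_C · 1.00335 / z``, so ``n_C = round((mz_mprime − mz_m) · z /
    1.00335)``.  The rounded count is accepted only when the residual of
    the charge-scaled mass difference is within the ppm tolerance
    evaluated at ``mz_mprime`` (scaled by z, the error of a difference of
    two z-charged measurements); otherwise ``None`` is returned.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mz_mprime <= mz_m:
        return None
    diff = (mz_mprime - mz_m) * z
    n = round(diff / DELTA_C)
    if n < 1:
        return None
    tol_u = ppm * 1e-6 * mz_mprime * z
    if abs(diff - n * DELTA_C) > tol_u:
        return None
    return n


def expected_m1_ratio(n_c: int, p_nat: float) -> float:
    """Expected M+1/M intensity ratio of a native ion with ``n_c`` carbons.

    First-order binomial: ``n_c · p / (1 − p)``.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    return n_c * p_nat / (1.0 - p_nat)


def expected_mprime_minus1_ratio(n_c: int, p_enr: float) -> float:
    """Expected M′−1/M′ intensity ratio of a U-¹³C labelled ion.

    Ratio of the ¹³C(n−1)¹²C(1) isotopologue to the fully labelled
    ¹³C(n) one: ``n_c · (1 − p) / p``.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    if not (0.0 < p_enr <= 1.0):
        raise ValueError("p_enr must be in (0, 1]")
    return n_c * (1.0 - p_enr) / p_enr


def estimate_enrichment(ratio: float, n_c: int) -> float:
    """Enrichment degree from an observed M′−1/M′ ratio.

    Exact algebraic inverse of :func:`expected_mprime_minus1_ratio`:
    ``p = n_c / (n_c + ratio)``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    return n_c / (n_c + ratio)


def max_direct_carbon(p_enr: float) -> int:
    """Largest carbon count with unambiguous direct n_C assignment.

    At enrichment ``p`` the residual M′−1 signal grows with n_C; once it
    reaches the fully labelled M′ signal (ratio 1) the monoisotopic
    labelled ion is no longer identifiable among its isotopologue
    pattern.  The bound is ``floor(p / (1 − p))`` (ratio exactly 1
    included: at 98 % enrichment 49 carbons, at 85 % five).
    """
    if not (0.5 < p_enr < 1.0):
        raise ValueError("p_enr must be in (0.5, 1)")
    # guard against 0.98/0.02 = 48.999... float artefacts
    return math.floor(p_enr / (1.0 - p_enr) + 1e-9)


def neutral_mass(
    mz: float,
    z: int,
    adduct: str,
    adduct_table: dict[str, tuple[float, int]] | None = None,
) -> float:
    """Neutral monoisotopic mass from an adduct ion m/z.

    ``mass = mz · z − shift`` with the shift from the adduct table (for
    [M+H]⁺ one proton mass per charge).
    """
    table = DEFAULT_ADDUCTS if adduct_table is None else adduct_table
    try:
        shift, table_z = table[adduct]
    except KeyError:
        raise KeyError(
            f"unknown adduct {adduct!r}; known: {sorted(table)}"
        ) from None
    if z != table_z:
        raise ValueError(f"adduct {adduct} implies z={table_z}, got z={z}")
    return mz * z - shift


def binomial_pattern(
    n_c: int, p: float, truncate: float = 1e-4
) -> list[tuple[int, float]]:
    """Full binomial isotopologue pattern of an ``n_c``-carbon ion.

    Returns ``(k, abundance)`` for every number of ¹³C atoms ``k`` whose
    abundance exceeds ``truncate`` relative to the most abundant
    isotopologue; abundances are normalised so the base isotopologue of
    the ladder (k=0 for natural material, k=n for enriched) is the
    binomial term itself.  Used by the simulator only.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    pattern = [
        (k, math.comb(n_c, k) * p**k * (1.0 - p) ** (n_c - k))
        for k in range(n_c + 1)
    ]
    top = max(a for _, a in pattern)
    return [(k, a) for k, a in pattern if a >= truncate * top]
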