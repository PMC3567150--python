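"""Post-REML quantitative-genetic algebra.

A biallelic major locus with additive value a, dominance value d and
allele frequencies p, q contributes additive variance 2 p q alpha^2, where
alpha = a + (p - q) d is the gene-substitution effect (for the
two-genotype Grey locus, observed only as GG or Gg in a grey population,
alpha is simply the Gg-vs-GG regression coefficient).  Phenotypic variance
is partitioned as

    V_P = V_POLY + V_STX17 + V_ASIP + V_pe + V_e

and the derived proportions are repeatability
R = (V_POLY + V_STX17 + V_ASIP + V_pe)/V_P,
permanent-environment share c2 = V_pe/V_P, narrow-sense heritability
h2 = (V_POLY + V_STX17 + V_ASIP)/V_P, and its polygenic/locus parts
h2_POLY, h2_STX17, h2_ASIP.  Bivariate analyses compose the phenotypic
correlation from the polygenic and residual correlations:

    r_P = r_POLY sqrt(h2_1 h2_2) + r_e sqrt((1 - h2_1)(1 - h2_2)).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "LocusEffect",
    "DecompositionResult",
    "CorrelationResult",
    "locus_variance",
    "substitution_effect",
    "decompose",
    "compose_phenotypic_correlation",
    "round_half_up",
]


def round_half_up(x, decimals=2):
    """Decimal rounding with ties away from zero (table convention)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass
class LocusEffect:
    """Substitution effect of one biallelic locus.

    ``alpha`` is derived from (a, d, p) unless given directly; for a
    two-genotype locus (kind="two_genotype", like Grey) alpha = a.
    """

    locus: str
    a: float
    d: float = 0.0
    p: float = 0.5
    kind: str = "three_genotype"

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency p={self.p} outside [0, 1]")

    @property
    def q(self):
        return 1.0 - self.p

    @property
    def alpha(self):
        return substitution_effect(self.a, self.d, self.p, self.q, self.kind)

    @property
    def variance(self):
        return locus_variance(self.alpha, self.p, self.q)


def substitution_effect(a, d=0.0, p=0.5, q=None, locus_kind="three_genotype"):
    """Gene-substitution effect alpha.

    alpha = a for a two-genotype locus (Grey: only GG/Gg segregate in the
    grey population) and alpha = a + (p - q) d in general.  With d = 0 the
    expected phenotype change from one homozygote to the other is 2 alpha.
    """
    q = 1.0 - p if q is None else q
    if not (0.0 <= p <= 1.0) or abs(p + q - 1.0) > 1e-9:
        raise ValueError("require p in [0, 1] and p + q = 1")
    if locus_kind == "two_genotype":
        return float(a)
    return float(a + (p - q) * d)


def locus_variance(alpha, p, q=None):
    """Additive variance of a biallelic locus: 2 p q alpha^2."""
    q = 1.0 - p if q is None else q
    if not (0.0 <= p <= 1.0) or abs(p + q - 1.0) > 1e-9:
        raise ValueError("require p in [0, 1] and p + q = 1")
    return 2.0 * p * q * float(alpha) ** 2


@dataclass
class DecompositionResult:
    """Variance partition and derived proportions for one trait."""

    v_poly: float
    v_stx17: float
    v_asip: float
    v_pe: float
    v_e: float
    v_p: float
    repeatability: float
    c2: float
    h2: float
    h2_poly: float
    h2_stx17: float
    h2_asip: float

    def rounded(self, decimals=2):
        return {
            f.name: round_half_up(getattr(self, f.name), decimals)
            for f in fields(self)
        }


def decompose(
    varcomp: dict,
    effects=(),
    v_p_override: float | None = None,
) -> DecompositionResult:
    """Partition phenotypic variance into polygenic, major-locus,
    permanent-environment and residual parts.

    Parameters
    ----------
    varcomp : dict with keys v_poly, v_pe, v_e (squared trait units).
    effects : iterable of LocusEffect
        Loci named "stx17" and/or "asip"; an absent locus contributes 0.
    v_p_override : float, optional
        Use this phenotypic variance for the proportions instead of the
        component sum (to reproduce an externally reported V_P).
    """
    v_poly = float(varcomp["v_poly"])
    v_pe = float(varcomp.get("v_pe", 0.0))
    v_e = float(varcomp["v_e"])
    if min(v_poly, v_pe, v_e) < 0:
        raise ValueError("variance components must be non-negative")
    by_locus = {e.locus: e for e in effects}
    v_stx17 = by_locus["stx17"].variance if "stx17" in by_locus else 0.0
    v_asip = by_locus["asip"].variance if "asip" in by_locus else 0.0
    v_sum = v_poly + v_stx17 + v_asip + v_pe + v_e
    v_p = float(v_p_override) if v_p_override is not None else v_sum
    if v_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return DecompositionResult(
        v_poly=v_poly,
        v_stx17=v_stx17,
        v_asip=v_asip,
        v_pe=v_pe,
        v_e=v_e,
        v_p=v_p,
        repeatability=(v_poly + v_stx17 + v_asip + v_pe) / v_p,
        c2=v_pe / v_p,
        h2=(v_poly + v_stx17 + v_asip) / v_p,
        h2_poly=v_poly / v_p,
        h2_stx17=v_stx17 / v_p,
        h2_asip=v_asip / v_p,
    )


@dataclass
class CorrelationResult:
    """Bivariate correlation estimates for one trait pair and scenario."""

    trait_pair: tuple
    scenario: int
    r_poly: float
    r_poly_se: float
    r_e: float = 0.0
    r_e_se: float = 0.0
    r_p: float | None = None

    def __post_init__(self):
        for r in (self.r_poly, self.r_e):
            if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
                raise ValueError(f"correlation {r} outside [-1, 1]")


def compose_phenotypic_correlation(r_poly, r_e, h2_1, h2_2):
    """Phenotypic correlation composed from polygenic and residual parts."""
    for h2 in (h2_1, h2_2):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"heritability {h2} outside [0, 1]")
    for r in (r_poly, r_e):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    return r_poly * np.sqrt(h2_1 * h2_2) + r_e * np.sqrt(
        (1.0 - h2_1) * (1.0 - h2_2)
    )
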