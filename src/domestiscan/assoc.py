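"""Exact association testing and linkage disequilibrium.

The association test is Fisher's exact test on the 2x2 table of allele
(reference vs pooled alternate) by phenotype (spread vs compact), computed
by direct hypergeometric enumeration in log space: with margins fixed, the
two-sided p-value is the sum of point probabilities of all tables at most
as probable as the observed one.  Accessions are treated as haploid units
(inbred, effectively homozygous lines), so allele counts are accession
counts.

LD between two biallelic sites is the classical haplotype-frequency
r-squared and D-prime, computed over accessions with complete calls at
both sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DomestiscanError
from .panel_io import Panel
from .variants import Variant, VariantTable

logger = logging.getLogger(__name__)

#: Relative tolerance when comparing point probabilities to the observed
#: one — the standard guard against ties lost to floating-point rounding.
_REL_TIE_TOL = 1e-7


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates the full hypergeometric support with fixed margins and sums
    the point probabilities <= P(observed) * (1 + 1e-7), in log space.
    Returns a value clipped to (0, 1].
    """
    for name, x in zip("abcd", (a, b, c, d)):
        if x < 0:
            raise DomestiscanError(f"negative count {name}={x}")
    n = a + b + c + d
    if n < 1:
        raise DomestiscanError("empty table")
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    log_pmf = (
        _log_binom(r1, xs) + _log_binom(r2, c1 - xs) - _log_binom(n, c1)
    )
    log_obs = log_pmf[a - lo]
    keep = log_pmf <= log_obs + math.log1p(_REL_TIE_TOL)
    p = float(np.exp(logsumexp(log_pmf[keep])))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


@dataclass
class AssociationResult:
    """Per-variant exact-test results plus the top association signal.

    ``table`` columns: position_upstream_bp, a, b, c, d (rows = phenotype
    spread/compact, columns = ref/alt allele), p_two_sided, neg_log10_p,
    p_bonferroni (reference only; the scan itself reports raw p).
    """

    table: pd.DataFrame
    top_hit: int  # position_upstream_bp of the minimal p (tie -> most distal)


def _biallelic_counts(variant: Variant, panel: Panel) -> tuple[int, int, int, int]:
    """2x2 counts (spread-ref, spread-alt, compact-ref, compact-alt)."""
    a = b = c = d = 0
    for acc, allele in variant.calls.items():
        if allele is None:
            continue
        is_ref = allele == variant.ref_allele
        if panel.phenotype_of(acc) == "spread":
            a += is_ref
            b += not is_ref
        else:
            c += is_ref
            d += not is_ref
    return a, b, c, d


def association_scan(vt: VariantTable, panel: Panel) -> AssociationResult:
    """Fisher-exact association of every variant with the binary phenotype.

    Multiallelic sites are biallelized as reference vs pooled alternates.
    A variant monomorphic after missing-data exclusion gets p = 1.0 with a
    warning.  Rows are ordered distal -> proximal.
    """
    if not vt.variants:
        raise DomestiscanError("variant table is empty")
    rows = []
    for v in vt.variants:
        a, b, c, d = _biallelic_counts(v, panel)
        if (a + c == 0) or (b + d == 0):
            logger.warning(
                "variant at %d bp upstream is monomorphic after missing-data "
                "exclusion; p set to 1.0",
                v.position_upstream_bp,
            )
            p = 1.0
        else:
            p = fisher_exact_two_sided(a, b, c, d)
        rows.append(
            {
                "position_upstream_bp": v.position_upstream_bp,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p_two_sided": p,
                "neg_log10_p": -math.log10(p),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "position_upstream_bp", ascending=False, ignore_index=True
    )
    table["p_bonferroni"] = (table["p_two_sided"] * len(table)).clip(upper=1.0)
    best_p = table["p_two_sided"].min()
    top_hit = int(
        table.loc[table["p_two_sided"] == best_p, "position_upstream_bp"].max()
    )
    return AssociationResult(table=table, top_hit=top_hit)


# -- linkage disequilibrium ---------------------------------------------


def ld_pair(
    calls_i: dict[str, str | None], calls_j: dict[str, str | None]
) -> tuple[float, float]:
    """Haplotype-frequency r-squared and D-prime for two biallelic sites.

    Computed over accessions with non-missing calls at both sites.  Returns
    (nan, nan) when either site is monomorphic after filtering.
    """
    common = [
        acc
        for acc in calls_i
        if calls_i[acc] is not None and calls_j.get(acc) is not None
    ]
    if len(common) < 2:
        raise DomestiscanError("fewer than 2 accessions complete at both sites")
    ai = [calls_i[acc] for acc in common]
    aj = [calls_j[acc] for acc in common]
    alleles_i = sorted(set(ai))
    alleles_j = sorted(set(aj))
    if len(alleles_i) > 2 or len(alleles_j) > 2:
        raise DomestiscanError("ld_pair requires biallelic input; biallelize first")
    if len(alleles_i) < 2 or len(alleles_j) < 2:
        return (math.nan, math.nan)
    A, B = alleles_i[0], alleles_j[0]
    n = len(common)
    p_a = sum(x == A for x in ai) / n
    p_b = sum(x == B for x in aj) / n
    p_ab = sum(x == A and y == B for x, y in zip(ai, aj)) / n
    D = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = D * D / denom
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d_max == 0 else abs(D) / d_max
    return (min(r2, 1.0), min(dprime, 1.0))


@dataclass
class LDMatrix:
    """Symmetric pairwise LD over the biallelic variants of a region."""

    positions: list[int]  # upstream bp, distal -> proximal
    r2: np.ndarray
    dprime: np.ndarray

    def to_long(self) -> pd.DataFrame:
        rows = []
        k = len(self.positions)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "pos_i": self.positions[i],
                        "pos_j": self.positions[j],
                        "r2": self.r2[i, j],
                        "dprime": self.dprime[i, j],
                    }
                )
        return pd.DataFrame(rows)


def ld_matrix(vt: VariantTable, panel: Panel) -> LDMatrix:
    """All-pairs LD over biallelic variants (multiallelic sites pooled to
    ref vs alt first, matching the association scan's biallelization)."""
    usable: list[Variant] = []
    pooled_calls: list[dict[str, str | None]] = []
    for v in vt.variants:
        calls = {
            acc: (None if a is None else ("R" if a == v.ref_allele else "X"))
            for acc, a in v.calls.items()
        }
        usable.append(v)
        pooled_calls.append(calls)
    if len(usable) < 2:
        raise DomestiscanError("need >= 2 variants for an LD matrix")
    k = len(usable)
    r2 = np.full((k, k), np.nan)
    dp = np.full((k, k), np.nan)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(dp, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            rij, dij = ld_pair(pooled_calls[i], pooled_calls[j])
            r2[i, j] = r2[j, i] = rij
            dp[i, j] = dp[j, i] = dij
    return LDMatrix(
        positions=[v.position_upstream_bp for v in usable], r2=r2, dprime=dp
    )
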