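"""Overlap statistics: hypergeometric tail probability and hinge enrichment.

Given N residues of which b bind drugs, and h hinge residues of which s fall
among the b, the probability of observing an overlap at least that large by
chance is the hypergeometric upper tail

    P(X >= s),  X ~ Hypergeometric(N, b, h),
             = 1 - sum_{i<s} C(b, i) C(N-b, h-i) / C(N, h).

The enrichment e = s(N-b) / [b(h-s)] compares the density of hinge residues
inside the binding site, s/b, with their density elsewhere, (h-s)/(N-b);
e > 1 exactly when s exceeds the random expectation h*b/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .binding import BindingSiteSet
from .errors import NumberingMismatchError, UndefinedEnrichmentError
from .hinges import HingeSet


@dataclass
class OverlapResult:
    """The (N, h, b, s) tuple with its significance and enrichment."""

    N: int
    h: int
    b: int
    s: int
    P: float
    e: float

    @property
    def fraction_binding(self) -> float:
        """s/b — fraction of binding residues that act as hinges."""
        return self.s / self.b if self.b else float("nan")

    def formatted_p(self) -> str:
        """P to three significant figures in scientific notation."""
        return f"{self.P:.3g}" if self.P >= 1e-3 else f"{self.P:.2e}"


def overlap(hinges: HingeSet, binding: BindingSiteSet) -> int:
    """s = |hinge union ∩ binding residues| (both on reference numbering)."""
    hinge_union = hinges.union
    if hinge_union and binding.residues:
        h_chains = {rid[0] for rid in hinge_union}
        b_chains = {rid[0] for rid in binding.residues}
        if not (h_chains & b_chains):
            raise NumberingMismatchError(
                f"hinge chains {sorted(h_chains)} and binding chains "
                f"{sorted(b_chains)} are disjoint — numbering mismatch?")
    return len(hinge_union & binding.residues)


def hypergeom_pvalue(s: int, N: int, h: int, b: int) -> float:
    """Upper-tail P(X >= s) for X ~ Hypergeometric(N, b, h).

    Evaluated through the library survival function (log-space internally),
    accurate to 3 significant figures down to ~1e-12.  s = 0 returns
    exactly 1.
    """
    if not (0 <= h <= N and 0 <= b <= N):
        raise ValueError(f"need 0 <= h, b <= N; got N={N}, h={h}, b={b}")
    if not (0 <= s <= min(h, b)):
        raise ValueError(f"need 0 <= s <= min(h, b); got s={s}, h={h}, b={b}")
    if s == 0:
        return 1.0
    return float(hypergeom.sf(s - 1, N, b, h))


def enrichment(s: int, N: int, h: int, b: int) -> float:
    """e = s(N-b) / [b(h-s)]; 0 when s = 0, +inf when s = h."""
    if b == 0 or h == 0:
        raise UndefinedEnrichmentError(f"h={h}, b={b}: enrichment undefined")
    if not (0 <= s <= min(h, b)) or h > N or b > N:
        raise ValueError(f"invalid counts N={N}, h={h}, b={b}, s={s}")
    if s == 0:
        return 0.0
    if s == h:
        return float("inf")
    return s * (N - b) / (b * (h - s))


def overlap_result(hinges: HingeSet, binding: BindingSiteSet, N: int) -> OverlapResult:
    """Bundle counts, P and e for one protein/family."""
    s = overlap(hinges, binding)
    h, b = hinges.h, binding.b
    return OverlapResult(N=N, h=h, b=b, s=s,
                         P=hypergeom_pvalue(s, N, h, b),
                         e=enrichment(s, N, h, b))


@dataclass
class AggregateSummary:
    n_results: int
    mean_P: float
    sd_P: float
    mean_e: float
    sd_e: float
    mean_fraction: float
    sd_fraction: float
    single_result: bool = False
    excluded: list = field(default_factory=list)


def aggregate(results: list[OverlapResult],
              exclude: list[str] | None = None,
              labels: list[str] | None = None) -> AggregateSummary:
    """Arithmetic mean and sample SD of P, e and s/b across families.

    ``exclude`` drops labelled results (leave-one-out style sensitivity).
    A single result reports SD 0 with ``single_result`` set.
    """
    if not results:
        raise ValueError("no results to aggregate")
    exclude = exclude or []
    if labels is not None:
        kept = [r for lbl, r in zip(labels, results) if lbl not in exclude]
    else:
        kept = list(results)
    if not kept:
        raise ValueError("all results excluded")
    ps = np.array([r.P for r in kept])
    es = np.array([r.e for r in kept])
    fr = np.array([r.fraction_binding for r in kept])
    single = len(kept) == 1

    def sd(x):
        return 0.0 if single else float(np.std(x, ddof=1))

    return AggregateSummary(
        n_results=len(kept),
        mean_P=float(ps.mean()), sd_P=sd(ps),
        mean_e=float(es.mean()), sd_e=sd(es),
        mean_fraction=float(fr.mean()), sd_fraction=sd(fr),
        single_result=single, excluded=list(exclude))
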