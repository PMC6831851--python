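"""Hypergeometric over-representation statistics with BH-FDR control.

Used for co-complex enrichment of ΣLLS percentiles, disease-annotation
enrichment of network proteins, and marker-based class assignment.  Only the
upper tail (over-representation) is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSets

__all__ = [
    "EnrichmentResult",
    "hypergeom_p",
    "bh_fdr",
    "annotate_enrichment",
    "marker_assignment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap
    K: int  # term size within background
    n: int  # query size
    N: int  # background size
    p: float
    q: float = float("nan")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on the input."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_enrichment(query: set[str], sets: AnnotationSets, background: set[str]) -> list[EnrichmentResult]:
    """Per-term hypergeometric enrichment of ``query`` within ``background``.

    Terms with zero overlap are skipped; q-values are BH-adjusted across the
    tested (overlapping) terms.  Results are sorted by (q, p, term).
    """
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term in sorted(sets.sets):
        members = sets.sets[term] & background
        k = len(members & query)
        if k == 0:
            continue
        rows.append((term, k, len(members), hypergeom_p(k, len(members), n, N)))
    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (t, k, K, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.q, r.p, r.term))


def marker_assignment(
    entity_features: dict[str, set[str]],
    marker_sets: AnnotationSets,
    background: set[str] | None = None,
    confidence: float = 0.95,
) -> dict[str, str | None]:
    """Assign each entity the marker class its detected genes over-represent.

    Per entity the hypergeometric p against each marker set is computed over
    the background; the minimum-p label is assigned if p <= 1 - confidence,
    else the entity is left unassigned (None).
    """
    if not marker_sets.sets:
        raise ValueError("empty marker sets")
    bg = set(background) if background is not None else set(marker_sets.universe)
    for feats in entity_features.values():
        bg |= feats
    N = len(bg)
    alpha = 1.0 - confidence
    out: dict[str, str | None] = {}
    for entity in sorted(entity_features):
        feats = entity_features[entity] & bg
        best: tuple[float, str] | None = None
        for term in sorted(marker_sets.sets):
            members = marker_sets.sets[term] & bg
            if not members:
                continue
            k = len(members & feats)
            p = hypergeom_p(k, len(members), len(feats), N)
            if best is None or p < best[0]:
                best = (p, term)
        out[entity] = best[1] if best is not None and best[0] <= alpha else None
    return out
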