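"""Headline arithmetic over published interactome counts.

The NTera2 ECSC/DNLC mitochondrial interactome study reports its network
sizes and validation rates as raw counts; the derived percentages and union
sizes used throughout reporting are simple arithmetic over those counts and
are recomputed here rather than hard-coded.  Analytic threshold identities
(the normal critical value behind the |Z| cutoff, the Ascore behind the 95%
localization rule) live here too.
"""

from __future__ import annotations

from scipy.stats import norm

from .phospho import ascore_threshold

__all__ = [
    "REPORTED_COUNTS",
    "z_critical",
    "ascore_threshold",
    "percentage",
    "union_edges",
    "proteome_coverage_pct",
    "novel_edge_pct",
    "neuronal_cell_pct",
    "phosphosite_total",
    "support_pct",
]

#: published counts for the NTera2 ECSC/DNLC mitochondrial interactome;
#: inputs to the derived arithmetic below.
REPORTED_COUNTS = {
    "ecsc_edges": 3320,  # static ECSC network edges
    "dnlc_edges": 3567,  # static DNLC network edges
    "ecsc_specific_edges": 2875,  # ECSC edges absent from the DNLC network
    "dnlc_specific_edges": 3122,  # DNLC edges absent from the ECSC network
    "network_proteins": 600,  # unique mitochondrial proteins in either network
    "mt_proteome": 1672,  # estimated human mitochondrial proteome size
    "ecsc_novel_edges": 3086,  # ECSC edges with no prior report
    "ecsc_supported_edges": 2219,  # ECSC edges confirmed by external evidence
    "neuronal_cells": 2180,  # DNLC single cells assigned the neuronal type
    "dnlc_cells": 2952,  # DNLC single cells profiled
    "phosphosites_s": 121,  # retained serine phosphosites
    "phosphosites_t": 40,  # retained threonine phosphosites
    "phosphosites_y": 24,  # retained tyrosine phosphosites
}


def z_critical(p: float = 0.05) -> float:
    """Two-sided normal critical value; p=0.05 -> 1.96."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(norm.ppf(1.0 - p / 2.0))


def percentage(part: int, whole: int) -> int:
    """part/whole as a percentage rounded to the nearest integer."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return int(round(100.0 * part / whole))


def union_edges(
    total_a: int = REPORTED_COUNTS["ecsc_edges"],
    total_b: int = REPORTED_COUNTS["dnlc_edges"],
    specific_a: int = REPORTED_COUNTS["ecsc_specific_edges"],
) -> int:
    """Union of two edge sets from their totals and one specific count."""
    shared = total_a - specific_a
    if shared < 0 or shared > total_b:
        raise ValueError("inconsistent edge counts")
    return total_a + total_b - shared


def proteome_coverage_pct(
    covered: int = REPORTED_COUNTS["network_proteins"],
    proteome: int = REPORTED_COUNTS["mt_proteome"],
) -> int:
    return percentage(covered, proteome)


def novel_edge_pct(
    novel: int = REPORTED_COUNTS["ecsc_novel_edges"],
    total: int = REPORTED_COUNTS["ecsc_edges"],
) -> int:
    return percentage(novel, total)


def neuronal_cell_pct(
    neuronal: int = REPORTED_COUNTS["neuronal_cells"],
    total: int = REPORTED_COUNTS["dnlc_cells"],
) -> int:
    return percentage(neuronal, total)


def phosphosite_total(
    n_s: int = REPORTED_COUNTS["phosphosites_s"],
    n_t: int = REPORTED_COUNTS["phosphosites_t"],
    n_y: int = REPORTED_COUNTS["phosphosites_y"],
) -> int:
    return n_s + n_t + n_y


def support_pct(
    supported: int = REPORTED_COUNTS["ecsc_supported_edges"],
    total: int = REPORTED_COUNTS["ecsc_edges"],
) -> int:
    return percentage(supported, total)
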