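"""Differential (DF) network between two cell states.

Each pair's fold change is FC = ΣLLS_DNLC / ΣLLS_ECSC; a pair scored in only
one state (or with nonpositive evidence there) takes a small positive floor
for the missing state, so state-specific pairs still enter the DF network.
Significance is a Z-score on log2 FC over all DF edges (empirical mean/sd;
|Z| >= 1.96 corresponds to two-sided p <= 0.05), and a significant edge with
FC >= 2 (resp. <= 1/2) is labeled specific to the differentiated
(resp. stem-cell) state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DifferentialEdge",
    "Z_THRESHOLD",
    "FC_CUTOFF",
    "compute_fold_changes",
    "zscore_edges",
    "classify_rewired",
]

Z_THRESHOLD = 1.96
FC_CUTOFF = 2.0

LABEL_NONE = "none"
LABEL_DNLC = "dnlc_specific"
LABEL_ECSC = "ecsc_specific"


@dataclass(frozen=True)
class DifferentialEdge:
    pair: tuple[str, str]
    sigma_lls_ecsc: float
    sigma_lls_dnlc: float
    fc: float
    log2fc: float
    z: float = float("nan")
    significant: bool = False
    rewired_label: str = LABEL_NONE


def compute_fold_changes(
    ecsc_scores: dict[tuple[str, str], float],
    dnlc_scores: dict[tuple[str, str], float],
    floor: float | None = None,
    pairs=None,
) -> pd.DataFrame:
    """Fold change of ΣLLS (DNLC over ECSC) for every DF pair.

    ``pairs`` restricts the DF domain (typically the union of the two static
    networks' edges); by default every pair scored in either state enters.
    ``floor`` replaces a missing or nonpositive state score; the default is
    the minimum positive ΣLLS observed in either state.
    """
    if pairs is None:
        pairs = set(ecsc_scores) | set(dnlc_scores)
    pairs = sorted(pairs)
    if not pairs:
        raise ValueError("no pairs to compare")
    if floor is None:
        observed = [
            v
            for scores in (ecsc_scores, dnlc_scores)
            for p in pairs
            if (v := scores.get(p)) is not None and v > 0
        ]
        if not observed:
            raise ValueError("no positive scores from which to derive a floor")
        floor = min(observed)
    if floor <= 0:
        raise ValueError("floor must be positive")

    rows = []
    for pair in pairs:
        e = ecsc_scores.get(pair, float("nan"))
        d = dnlc_scores.get(pair, float("nan"))
        e_eff = e if np.isfinite(e) and e > 0 else floor
        d_eff = d if np.isfinite(d) and d > 0 else floor
        fc = d_eff / e_eff
        rows.append(
            {
                "protein_a": pair[0],
                "protein_b": pair[1],
                "sigma_lls_ecsc": e_eff,
                "sigma_lls_dnlc": d_eff,
                "fc": fc,
                "log2fc": np.log2(fc),
            }
        )
    return pd.DataFrame(rows)


def zscore_edges(edges: pd.DataFrame, z_threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Standardize log2 FC over all DF edges and flag |Z| >= z_threshold."""
    lfc = edges["log2fc"].to_numpy(dtype=float)
    finite = np.isfinite(lfc)
    if finite.sum() < 2:
        raise ValueError("need at least 2 edges with finite log2fc")
    mean = lfc[finite].mean()
    sd = lfc[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("zero standard deviation of log2fc: Z undefined")
    out = edges.copy()
    out["z"] = (lfc - mean) / sd
    out["significant"] = np.abs(out["z"]) >= z_threshold
    return out


def classify_rewired(edges: pd.DataFrame, fc_cutoff: float = FC_CUTOFF) -> pd.DataFrame:
    """Label significant edges with FC >= cutoff (or <= 1/cutoff) as rewired.

    Significance gates rewiring: a non-significant edge keeps label 'none'
    regardless of its fold change.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    if "significant" not in edges.columns:
        raise ValueError("run zscore_edges first")
    out = edges.copy()
    fc = out["fc"].to_numpy(dtype=float)
    sig = out["significant"].to_numpy(dtype=bool)
    label = np.full(len(out), LABEL_NONE, dtype=object)
    label[sig & (fc >= fc_cutoff)] = LABEL_DNLC
    label[sig & (fc <= 1.0 / fc_cutoff)] = LABEL_ECSC
    out["rewired_label"] = label
    return out
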