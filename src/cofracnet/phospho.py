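"""Phosphosite localization filtering and cell-state classification.

Sites carry an Ascore (−10·log10 of the localization p-value, so 13 ≈ 95%
confidence), per-state triplicate detection flags and a known-site flag
(membership in a public phosphosite repository).  A site is retained in a
state iff its Ascore clears the confidence cutoff AND it was detected in at
least two of the three replicates of that state or is a known site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PhosphoSiteRecord",
    "ascore_confidence",
    "ascore_threshold",
    "retain_sites",
    "classify_sites",
    "read_phosphosites",
    "write_phosphosites",
]

RESIDUES = ("S", "T", "Y")


@dataclass
class PhosphoSiteRecord:
    protein: str
    position: int
    residue: str
    ascore: float
    detections: dict[str, tuple[bool, bool, bool]]
    known_site: bool = False
    #: optional planted ground truth (simulation only): state -> should pass
    truth_pass: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue not in RESIDUES:
            raise ValueError(f"residue must be one of {RESIDUES}, got {self.residue!r}")
        if self.ascore < 0:
            raise ValueError("ascore must be >= 0")
        for state, flags in self.detections.items():
            if len(flags) != 3:
                raise ValueError(f"state {state!r}: expected 3 replicate flags")

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.protein, self.position, self.residue)


def ascore_confidence(ascore: float) -> float:
    """Localization confidence 1 − 10^(−Ascore/10); Ascore 13 ≈ 0.95."""
    if ascore < 0:
        raise ValueError("ascore must be >= 0")
    return 1.0 - 10.0 ** (-ascore / 10.0)


def ascore_threshold(confidence: float = 0.95) -> int:
    """Integer Ascore cutoff equivalent to a confidence level.

    Reported to the nearest integer, the convention under which 95%
    confidence corresponds to the canonical cutoff of 13
    (−10·log10(0.05) = 13.01).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return int(round(-10.0 * math.log10(1.0 - confidence)))


def retain_sites(
    records: list[PhosphoSiteRecord],
    ascore_min: float = 13.0,
    min_replicates: int = 2,
) -> dict[str, list[PhosphoSiteRecord]]:
    """Apply the retention rule per state.

    Retained in a state iff ascore >= ascore_min AND (detected in >=
    min_replicates of the 3 replicates of that state OR known_site).
    """
    retained: dict[str, list[PhosphoSiteRecord]] = {}
    for rec in records:
        for state, flags in rec.detections.items():
            detected = sum(bool(f) for f in flags)
            evidence = detected >= min_replicates or (rec.known_site and detected >= 1)
            if rec.ascore >= ascore_min and evidence:
                retained.setdefault(state, []).append(rec)
    return retained


def classify_sites(retained: dict[str, list[PhosphoSiteRecord]]) -> dict:
    """Partition retained sites into state-specific / shared and tally residues.

    Returns a dict with 'residue_counts' ({S,T,Y} over the union of retained
    sites), 'specific' (state -> site-key set), 'shared' (site-key set) and
    'total' (= sum of the residue counts).
    """
    keys_per_state = {state: {r.site_key for r in recs} for state, recs in retained.items()}
    states = sorted(keys_per_state)
    all_keys: set[tuple[str, int, str]] = set()
    for ks in keys_per_state.values():
        all_keys |= ks
    shared = set.intersection(*keys_per_state.values()) if len(states) > 1 else set()
    specific = {
        state: keys_per_state[state]
        - set().union(*(keys_per_state[s] for s in states if s != state))
        for state in states
    } if len(states) > 1 else {s: set(keys_per_state[s]) for s in states}

    residue_counts = {r: 0 for r in RESIDUES}
    for (_, _, residue) in all_keys:
        residue_counts[residue] += 1
    return {
        "residue_counts": residue_counts,
        "specific": specific,
        "shared": shared,
        "total": sum(residue_counts.values()),
    }


# ---------------------------------------------------------------------------
# TSV round trip

_COLUMNS = ["protein", "position", "residue", "ascore", "known_site"]


def write_phosphosites(records: list[PhosphoSiteRecord], path: str | Path,
                       states: tuple[str, str] = ("ECSC", "DNLC")) -> Path:
    rows = []
    for r in records:
        row = {
            "protein": r.protein,
            "position": r.position,
            "residue": r.residue,
            "ascore": r.ascore,
            "known_site": int(r.known_site),
        }
        for state in states:
            flags = r.detections.get(state, (False, False, False))
            for i, f in enumerate(flags, start=1):
                row[f"{state}_rep{i}"] = int(f)
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_phosphosites(path: str | Path, states: tuple[str, str] = ("ECSC", "DNLC")) -> list[PhosphoSiteRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        detections = {
            state: tuple(bool(row[f"{state}_rep{i}"]) for i in (1, 2, 3)) for state in states
        }
        records.append(
            PhosphoSiteRecord(
                protein=str(row["protein"]),
                position=int(row["position"]),
                residue=str(row["residue"]),
                ascore=float(row["ascore"]),
                detections=detections,
                known_site=bool(row["known_site"]),
            )
        )
    return records
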