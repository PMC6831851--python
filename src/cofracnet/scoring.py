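"""Co-elution similarity scoring of protein pairs.

Three complementary measures per separation technique:

* **pcc** -- Pearson correlation of the two elution profiles;
* **wcc** -- weighted cross-correlation: the maximum over integer fraction
  shifts s (|s| <= max_shift) of w(s) * cos(s), where cos(s) is the cosine
  similarity of the shifted overlap and w(s) = 1 - |s|/(max_shift + 1);
  negative values are floored at 0, so wcc lies in [0, 1];
* **coapex** -- the fraction of experiments in which both proteins attain
  their maximum count in the same fraction (ties break to the earliest
  fraction).

A pair is scored for a technique only if both proteins survive the
peptide-count filter in BOTH replicates of that technique; pcc/wcc are then
computed on replicate-concatenated profiles (shifts never cross the
replicate boundary) and coapex across the technique's replicate experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FractionationExperiment, canonical_pair

__all__ = [
    "PairScoreRecord",
    "METRICS",
    "filter_proteins",
    "pcc",
    "wcc",
    "coapex",
    "score_all_pairs",
]

METRICS = ("pcc", "wcc", "coapex")


@dataclass(frozen=True)
class PairScoreRecord:
    """Raw similarity scores of one canonical pair in one state."""

    pair: tuple[str, str]
    state: str
    raw_scores: dict  # (technique, metric) -> float


def filter_proteins(
    exp: FractionationExperiment,
    min_distinct_peptides: int = 2,
    min_fractions_detected: int = 2,
) -> FractionationExperiment:
    """Zero sub-threshold cells, then drop sparsely detected proteins.

    Cells with fewer than ``min_distinct_peptides`` distinct peptides are
    set to 0 (a single peptide does not reliably place a protein in a
    fraction); proteins left with fewer than ``min_fractions_detected``
    nonzero fractions are removed (a 1-fraction profile carries no
    co-elution information).
    """
    counts = exp.data.to_numpy().copy()
    counts[counts < min_distinct_peptides] = 0
    detected = (counts > 0).sum(axis=1) >= min_fractions_detected
    data = pd.DataFrame(
        counts[detected], index=exp.data.index[detected], columns=exp.data.columns
    )
    return FractionationExperiment(exp.state, exp.technique, exp.replicate, data)


def pcc(profile_a, profile_b) -> float:
    """Pearson product-moment correlation over all fractions."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _shift_cosine(a: np.ndarray, b: np.ndarray, s: int) -> float:
    """Cosine similarity of a[i] against b[i - s] over the overlap."""
    n = len(a)
    if s >= 0:
        a_seg, b_seg = a[s:], b[: n - s]
    else:
        a_seg, b_seg = a[: n + s], b[-s:]
    na, nb = np.linalg.norm(a_seg), np.linalg.norm(b_seg)
    if na == 0 or nb == 0:
        return 0.0
    return float(a_seg @ b_seg / (na * nb))


def wcc(profile_a, profile_b, max_shift: int = 2) -> float:
    """Weighted cross-correlation, in [0, 1]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("all-zero profile: wcc undefined")
    best = 0.0
    for s in range(-max_shift, max_shift + 1):
        w = 1.0 - abs(s) / (max_shift + 1)
        best = max(best, w * _shift_cosine(a, b, s))
    return best


def _apex(profile: np.ndarray) -> int:
    """Index of the maximum count; earliest fraction on ties."""
    return int(np.argmax(profile))


def coapex(pair: tuple[str, str], experiments: list[FractionationExperiment]) -> float:
    """Fraction of experiments in which both apexes coincide.

    Only experiments in which both proteins are detected (nonzero rows)
    enter the denominator; a pair never co-detected has no defined score.
    """
    a, b = pair
    co_detected = 0
    matches = 0
    for exp in experiments:
        if a not in exp.data.index or b not in exp.data.index:
            continue
        pa = exp.data.loc[a].to_numpy(dtype=float)
        pb = exp.data.loc[b].to_numpy(dtype=float)
        if pa.max() == 0 or pb.max() == 0:
            continue
        co_detected += 1
        if _apex(pa) == _apex(pb):
            matches += 1
    if co_detected == 0:
        raise ValueError(f"pair {pair} never co-detected")
    return matches / co_detected


# ---------------------------------------------------------------------------
# vectorized all-pairs scoring


def _pairwise_pcc(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(m)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def _pairwise_wcc(segments: list[np.ndarray], max_shift: int = 2) -> np.ndarray:
    """All-pairs wcc on replicate-concatenated profiles.

    ``segments`` holds one (n_proteins x n_fractions) block per replicate;
    shifts are applied within each block so that cross-correlation never
    crosses the replicate boundary.
    """
    n = segments[0].shape[0]
    best = np.zeros((n, n))
    for s in range(-max_shift, max_shift + 1):
        w = 1.0 - abs(s) / (max_shift + 1)
        num = np.zeros((n, n))
        sq_a = np.zeros(n)
        sq_b = np.zeros(n)
        for seg in segments:
            f = seg.shape[1]
            if s >= 0:
                a_seg, b_seg = seg[:, s:], seg[:, : f - s]
            else:
                a_seg, b_seg = seg[:, : f + s], seg[:, -s:]
            num += a_seg @ b_seg.T
            sq_a += (a_seg**2).sum(axis=1)
            sq_b += (b_seg**2).sum(axis=1)
        denom = np.sqrt(np.outer(sq_a, sq_b))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, num / denom, 0.0)
        best = np.maximum(best, w * cos)
    return np.clip(best, 0.0, None)


def score_all_pairs(
    experiments: list[FractionationExperiment],
    max_shift: int = 2,
    min_distinct_peptides: int = 2,
    min_fractions_detected: int = 2,
) -> dict[str, pd.DataFrame]:
    """Score every eligible pair in every state.

    Returns one long-format DataFrame per state with columns
    ``protein_a, protein_b, technique, pcc, wcc, coapex`` (pair canonical,
    NaN where a metric is undefined for the pair).
    """
    by_state: dict[str, dict[str, list[FractionationExperiment]]] = {}
    for exp in experiments:
        by_state.setdefault(exp.state, {}).setdefault(exp.technique, []).append(exp)
    if not by_state:
        raise ValueError("no experiments supplied")

    out: dict[str, pd.DataFrame] = {}
    for state, by_tech in sorted(by_state.items()):
        frames = []
        for technique, reps in sorted(by_tech.items()):
            if len(reps) < 2:
                raise ValueError(
                    f"state {state!r} technique {technique!r}: need >= 2 replicates"
                )
            reps = sorted(reps, key=lambda e: e.replicate)
            filtered = [
                filter_proteins(e, min_distinct_peptides, min_fractions_detected)
                for e in reps
            ]
            eligible = sorted(set.intersection(*(set(f.data.index) for f in filtered)))
            if len(eligible) < 2:
                continue
            blocks = [f.data.loc[eligible].to_numpy(dtype=float) for f in filtered]
            concat = np.hstack(blocks)

            pcc_m = _pairwise_pcc(concat)
            wcc_m = _pairwise_wcc(blocks, max_shift=max_shift)
            apexes = np.stack([blk.argmax(axis=1) for blk in blocks])  # reps x prot
            same = (apexes[:, :, None] == apexes[:, None, :]).sum(axis=0)
            coapex_m = same / len(blocks)

            iu, ju = np.triu_indices(len(eligible), k=1)
            names = np.asarray(eligible, dtype=object)
            frames.append(
                pd.DataFrame(
                    {
                        "protein_a": names[iu],
                        "protein_b": names[ju],
                        "technique": technique,
                        "pcc": pcc_m[iu, ju],
                        "wcc": wcc_m[iu, ju],
                        "coapex": coapex_m[iu, ju],
                    }
                )
            )
        if not frames:
            raise ValueError(f"state {state!r}: no technique yielded scorable pairs")
        out[state] = pd.concat(frames, ignore_index=True)
    return out
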