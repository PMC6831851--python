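"""Log-likelihood integration of raw co-elution scores into ΣLLS networks.

Each (technique, metric) evidence source is binned (equal-frequency bins over
the labeled reference pairs) and every bin receives a log-likelihood score

    LLS(bin) = ln[ ((pos_bin + c) / (neg_bin + c)) / (pos_tot / neg_tot) ]

with pseudocount c keeping the score finite; the prior odds use raw totals.
A pair's ΣLLS is the sum of bin LLS values over every evidence source for
which it has a score -- missing evidence contributes 0 -- and the per-state
static network keeps pairs with ΣLLS above the cutoff (default 1.45, the
stringent threshold at which most reference co-complex pairs are recovered).
Benchmarking uses ROC/AUC against reference positives (co-complex pairs) and
negatives (catalog proteins that never share a complex), with 5-fold
cross-validation split at the complex level to prevent leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .enrichment import hypergeom_p
from .io import ReferenceComplexCatalog
from .scoring import METRICS

__all__ = [
    "LlsModel",
    "StaticNetwork",
    "derive_reference_pairs",
    "fit_lls",
    "sum_lls",
    "choose_threshold",
    "crossvalidate",
    "percentile_cocomplex_enrichment",
]

DEFAULT_THRESHOLD = 1.45


@dataclass
class LlsModel:
    """Per-(technique, metric) bin tables: inner edges + LLS per bin."""

    tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    prior_odds: float
    pseudocount: float = 1.0
    n_bins: int = 10

    def lls_for(self, technique: str, metric: str, values: np.ndarray) -> np.ndarray:
        edges, lls = self.tables[(technique, metric)]
        idx = np.digitize(np.asarray(values, dtype=float), edges)
        return lls[idx]


@dataclass
class StaticNetwork:
    """Thresholded per-state ΣLLS network."""

    state: str
    edges: pd.DataFrame  # protein_a, protein_b, sigma_lls
    threshold: float
    auc: float

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["protein_a"], self.edges["protein_b"]))

    def node_set(self) -> set[str]:
        return set(self.edges["protein_a"]) | set(self.edges["protein_b"])


def derive_reference_pairs(
    catalog: ReferenceComplexCatalog, scored_universe: set[str]
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Reference positives and negatives restricted to the scored universe.

    Positives: canonical pairs sharing at least one complex.  Negatives:
    pairs of catalog proteins that never share a complex.
    """
    present = sorted(catalog.universe & set(scored_universe))
    if len(present) < 2:
        raise ValueError("fewer than 2 catalog proteins in the scored universe")
    present_set = set(present)
    positives = {
        p for p in catalog.co_complex_pairs() if p[0] in present_set and p[1] in present_set
    }
    negatives: set[tuple[str, str]] = set()
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            if (a, b) not in positives:
                negatives.add((a, b))
    return positives, negatives


def _melt_scores(scores: pd.DataFrame) -> pd.DataFrame:
    long = scores.melt(
        id_vars=["protein_a", "protein_b", "technique"],
        value_vars=[m for m in METRICS if m in scores.columns],
        var_name="metric",
        value_name="score",
    )
    return long.dropna(subset=["score"])


def fit_lls(
    scores: pd.DataFrame,
    positives: set[tuple[str, str]],
    negatives: set[tuple[str, str]],
    n_bins: int = 10,
    pseudocount: float = 1.0,
) -> LlsModel:
    """Fit per-evidence LLS bin tables from labeled reference pairs only."""
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative reference pair")
    long = _melt_scores(scores)
    keys = list(zip(long["protein_a"], long["protein_b"]))
    label = np.array([1 if k in positives else (0 if k in negatives else -1) for k in keys])
    long = long.assign(label=label)
    ref = long[long["label"] >= 0]
    if ref.empty:
        raise ValueError("no reference pair carries a score")
    pos_tot = max(int((ref.drop_duplicates(["protein_a", "protein_b"])["label"] == 1).sum()), 1)
    neg_tot = max(int((ref.drop_duplicates(["protein_a", "protein_b"])["label"] == 0).sum()), 1)
    prior = pos_tot / neg_tot

    tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (technique, metric), grp in ref.groupby(["technique", "metric"], sort=True):
        vals = grp["score"].to_numpy(dtype=float)
        labs = grp["label"].to_numpy()
        # equal-frequency edges over the POSITIVE reference scores: negatives
        # dominate the labeled pairs by orders of magnitude, so pooled
        # quantiles would spend every bin on the noise region and collapse
        # all informative scores into one bin; positives define the signal
        # range the bins must resolve
        anchor = vals[labs == 1] if (labs == 1).any() else vals
        qs = np.quantile(anchor, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)  # collapses if scores tie
        edges = edges[edges > vals.min()]  # drop edges that leave a bin empty
        idx = np.digitize(vals, edges)
        nb = len(edges) + 1
        pos_b = np.bincount(idx[labs == 1], minlength=nb).astype(float)
        neg_b = np.bincount(idx[labs == 0], minlength=nb).astype(float)
        lls = np.log((pos_b + pseudocount) / (neg_b + pseudocount) / prior)
        tables[(str(technique), str(metric))] = (edges, lls)
    return LlsModel(tables=tables, prior_odds=prior, pseudocount=pseudocount, n_bins=n_bins)


def sum_lls(model: LlsModel, scores: pd.DataFrame) -> pd.DataFrame:
    """ΣLLS per pair: sum of bin LLS over all available evidence sources."""
    long = _melt_scores(scores)
    parts = []
    for (technique, metric), grp in long.groupby(["technique", "metric"], sort=True):
        key = (str(technique), str(metric))
        if key not in model.tables:
            continue
        contrib = model.lls_for(*key, grp["score"].to_numpy(dtype=float))
        parts.append(
            pd.DataFrame(
                {
                    "protein_a": grp["protein_a"].to_numpy(),
                    "protein_b": grp["protein_b"].to_numpy(),
                    "lls": contrib,
                }
            )
        )
    if not parts:
        raise ValueError("no evidence source overlaps the fitted model")
    allp = pd.concat(parts, ignore_index=True)
    out = (
        allp.groupby(["protein_a", "protein_b"], sort=True)["lls"]
        .sum()
        .reset_index()
        .rename(columns={"lls": "sigma_lls"})
    )
    return out


def _labeled_scores(
    sigma: pd.DataFrame,
    positives: set[tuple[str, str]],
    negatives: set[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray]:
    keys = list(zip(sigma["protein_a"], sigma["protein_b"]))
    y, s = [], []
    vals = sigma["sigma_lls"].to_numpy(dtype=float)
    for k, v in zip(keys, vals):
        if k in positives:
            y.append(1)
            s.append(v)
        elif k in negatives:
            y.append(0)
            s.append(v)
    return np.asarray(y), np.asarray(s)


def choose_threshold(
    sigma: pd.DataFrame,
    positives: set[tuple[str, str]],
    negatives: set[tuple[str, str]],
    state: str = "",
    fixed: float | None = DEFAULT_THRESHOLD,
) -> StaticNetwork:
    """ROC over ΣLLS against the reference labels; retain ΣLLS > threshold.

    With ``fixed`` set (default 1.45) the cutoff is imposed; with
    ``fixed=None`` the cutoff maximizing Youden's J on the labeled pairs is
    used.
    """
    y, s = _labeled_scores(sigma, positives, negatives)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need both positive and negative scored pairs")
    auc = float(roc_auc_score(y, s))
    if fixed is not None:
        threshold = float(fixed)
    else:
        fpr, tpr, thr = roc_curve(y, s)
        j = tpr - fpr
        # roc_curve thresholds are inclusive (score >= thr is positive) but
        # the network retains strictly greater scores; nudge just below
        threshold = float(np.nextafter(thr[int(np.argmax(j))], -np.inf))
    edges = sigma[sigma["sigma_lls"] > threshold].reset_index(drop=True)
    return StaticNetwork(state=state, edges=edges, threshold=threshold, auc=auc)


def crossvalidate(
    catalog: ReferenceComplexCatalog,
    scores: pd.DataFrame,
    k: int = 5,
    n_bins: int = 10,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> list[float]:
    """Complex-level k-fold cross-validated AUC of ΣLLS.

    Folds are split at the complex level (all pairs of a complex share a
    fold) because co-complex pairs are exchangeable within a complex and a
    pair-level split would leak; negatives are assigned to folds uniformly.
    The LLS model is refit on the training folds only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cids = sorted(catalog.complexes)
    if k > len(cids):
        raise ValueError(f"k={k} exceeds the number of complexes ({len(cids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cids))
    fold_of_complex = {cids[j]: i % k for i, j in enumerate(order)}

    scored_universe = set(scores["protein_a"]) | set(scores["protein_b"])
    positives, negatives = derive_reference_pairs(catalog, scored_universe)
    # a positive belongs to the fold of the first (sorted) complex containing it
    pair_fold: dict[tuple[str, str], int] = {}
    for cid in cids:
        members = sorted(catalog.complexes[cid])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pair_fold.setdefault((a, b), fold_of_complex[cid])
    neg_sorted = sorted(negatives)
    neg_fold = rng.integers(0, k, size=len(neg_sorted))

    aucs = []
    for fold in range(k):
        train_pos = {p for p in positives if pair_fold[p] != fold}
        test_pos = {p for p in positives if pair_fold[p] == fold}
        train_neg = {p for p, f in zip(neg_sorted, neg_fold) if f != fold}
        test_neg = {p for p, f in zip(neg_sorted, neg_fold) if f == fold}
        # membership edits between folds may overlap: keep test pairs unseen
        test_pos -= train_pos
        model = fit_lls(scores, train_pos, train_neg, n_bins=n_bins, pseudocount=pseudocount)
        sigma = sum_lls(model, scores)
        y, s = _labeled_scores(sigma, test_pos, test_neg)
        if len(np.unique(y)) < 2:
            raise ValueError(f"fold {fold}: held-out labels are degenerate")
        aucs.append(float(roc_auc_score(y, s)))
    return aucs


def percentile_cocomplex_enrichment(
    sigma: pd.DataFrame,
    catalog: ReferenceComplexCatalog,
    percentile: float = 0.20,
    tail: str = "top",
) -> dict:
    """Hypergeometric co-complex enrichment of the top (or bottom)
    percentile of ΣLLS-ranked, reference-covered pairs."""
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    universe = catalog.universe
    covered = sigma[
        sigma["protein_a"].isin(universe) & sigma["protein_b"].isin(universe)
    ].copy()
    if covered.empty:
        raise ValueError("no scored pair is covered by the reference catalog")
    co = catalog.co_complex_pairs()
    is_pos = np.array(
        [(a, b) in co for a, b in zip(covered["protein_a"], covered["protein_b"])]
    )
    n_sel = max(int(math.ceil(percentile * len(covered))), 1)
    order = covered["sigma_lls"].to_numpy().argsort()
    sel_idx = order[-n_sel:] if tail == "top" else order[:n_sel]
    k = int(is_pos[sel_idx].sum())
    result = {
        "k": k,
        "K": int(is_pos.sum()),
        "n": n_sel,
        "N": len(covered),
        "p": hypergeom_p(k, int(is_pos.sum()), n_sel, len(covered)),
    }
    return result
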