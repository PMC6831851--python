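"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are plain TSV.  Elution matrices are protein x fraction
tables of distinct-peptide counts; complex catalogs and annotation sets use a
GMT-like layout (id, description, then tab-separated members); networks are
edge lists with the pair serialized in lexicographic order.  Readers reject
structural errors instead of repairing them; writers sort their output so that
byte-identical files come from identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FractionationExperiment",
    "ReferenceComplexCatalog",
    "AnnotationSets",
    "canonical_pair",
    "read_experiment",
    "write_experiment",
    "read_complex_catalog",
    "write_complex_catalog",
    "read_annotation_sets",
    "write_network",
    "read_network",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in lexicographic order."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid protein pair")
    return (a, b) if a < b else (b, a)


@dataclass
class FractionationExperiment:
    """One (cell state, separation technique, replicate) elution matrix.

    ``data`` is a protein x fraction DataFrame of non-negative integer
    distinct-peptide counts; the index holds unique protein identifiers and
    the columns are ordered fraction labels.
    """

    state: str
    technique: str
    replicate: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if (self.data.values < 0).any():
            raise ValueError("peptide counts must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def fractions(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.state, self.technique, self.replicate)


@dataclass
class ReferenceComplexCatalog:
    """A CORUM-like catalog: complex id -> member set (size >= 2)."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 members")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return frozenset(out)

    def co_complex_pairs(self) -> set[tuple[str, str]]:
        """All canonical pairs co-occurring in at least one complex."""
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    pairs.add((a, b))
        return pairs


@dataclass
class AnnotationSets:
    """Flat term -> member-set annotations over a background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for s in self.sets.values():
                u |= s
            self.universe = frozenset(u)
        else:
            # harmonize: clip annotation sets to the declared background
            self.sets = {t: frozenset(s) & self.universe for t, s in self.sets.items()}


# ---------------------------------------------------------------------------
# elution matrices


def read_experiment(path: str | Path, state: str, technique: str, replicate: str) -> FractionationExperiment:
    """Parse a protein x fraction TSV (header row = fraction labels).

    Missing cells are read as 0.  Duplicate protein rows, negative counts and
    non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate protein ids {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: malformed numeric cell at protein {df.index[r]!r}, fraction {df.columns[c]!r}"
        )
    counts = numeric.fillna(0)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative peptide count")
    counts = counts.astype(int)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns = counts.columns.astype(str)
    return FractionationExperiment(state=state, technique=technique, replicate=replicate, data=counts)


def write_experiment(exp: FractionationExperiment, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    exp.data.to_csv(path, sep="\t", index_label="protein")
    return path


# ---------------------------------------------------------------------------
# complex catalogs / annotation sets (GMT-like)


def _read_gmt(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty file")
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least id and description")
        cid = fields[0]
        if cid in out:
            raise ValueError(f"{path}:{lineno}: duplicate id {cid!r}")
        members = [m for m in fields[2:] if m]
        out[cid] = members
    return out


def read_complex_catalog(path: str | Path) -> ReferenceComplexCatalog:
    """Read a GMT-like complex catalog; entries with <2 members are dropped
    with a warning (they carry no pairwise information)."""
    raw = _read_gmt(path)
    complexes: dict[str, frozenset[str]] = {}
    for cid, members in raw.items():
        ms = frozenset(members)
        if len(ms) < 2:
            warnings.warn(f"complex {cid!r} has <2 members; dropped", stacklevel=2)
            continue
        complexes[cid] = ms
    return ReferenceComplexCatalog(complexes=complexes)


def write_complex_catalog(catalog: ReferenceComplexCatalog | dict[str, frozenset[str]], path: str | Path,
                          description: str = "complex") -> Path:
    complexes = catalog.complexes if isinstance(catalog, ReferenceComplexCatalog) else catalog
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for cid in sorted(complexes):
            members = "\t".join(sorted(complexes[cid]))
            fh.write(f"{cid}\t{description}\t{members}\n")
    return path


def read_annotation_sets(path: str | Path, universe: set[str] | None = None) -> AnnotationSets:
    raw = _read_gmt(path)
    sets = {t: frozenset(m) for t, m in raw.items()}
    return AnnotationSets(sets=sets, universe=frozenset(universe) if universe else frozenset())


# ---------------------------------------------------------------------------
# networks / edge lists


def write_network(edges: pd.DataFrame, path: str | Path) -> Path:
    """Write an edge list with the pair sorted lexicographically.

    ``edges`` must carry ``protein_a``/``protein_b`` columns; remaining
    columns are written in their existing order.  Scores survive a round trip
    to at least 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = edges.copy()
    if len(df):
        a = df["protein_a"].to_numpy(dtype=object)
        b = df["protein_b"].to_numpy(dtype=object)
        swap = a > b
        a[swap], b[swap] = b[swap], a[swap].copy()
        df["protein_a"], df["protein_b"] = a, b
        df = df.sort_values(["protein_a", "protein_b"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")
    return path


def read_network(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "protein_a" not in df.columns or "protein_b" not in df.columns:
        raise ValueError(f"{path}: missing protein_a/protein_b columns")
    return df
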