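"""Synthetic co-fractionation data with planted ground truth.

Emulates the design of a two-state biochemical-fractionation / MS study:
two cell states (pluripotent ECSC-like and differentiated DNLC-like), two
separation techniques (SEC and IEC), duplicate replicates per experiment,
and a planted catalog of protein complexes of which a configurable fraction
is rewired between the states.

The generative model starts at the protein x fraction distinct-peptide-count
matrix (the post-search-engine representation): each complex is assigned an
apex fraction per technique -- SEC apexes are ordered by a decreasing summed
member-mass proxy, IEC apexes are uniform -- and every member elutes as a
discretized Gaussian peak around that apex.  Observed counts are Poisson
draws around the peak intensity with a per-replicate log-normal amplitude
jitter (the count-dispersion knob); background proteins and members removed
by rewiring elute as independent monomer peaks; dropout zeroes a protein's
whole row in a replicate.  Apexes, masses and baseline amplitudes are drawn
from replicate-independent streams so that replicates of the same experiment
share their signal and differ only in counting noise, dropout and jitter.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FractionationExperiment, ReferenceComplexCatalog, canonical_pair
from .phospho import PhosphoSiteRecord

__all__ = [
    "NoiseParams",
    "SimulationTruth",
    "STATES",
    "TECHNIQUES",
    "DEFAULT_FRACTIONS",
    "simulate_catalog",
    "apply_rewiring",
    "simulate_experiment",
    "simulate_phosphosites",
]

STATES = ("ECSC", "DNLC")
TECHNIQUES = ("SEC", "IEC")
#: fraction counts per replicate; the source study reports only the total
#: number of fractions collected, so the per-technique split is a default.
DEFAULT_FRACTIONS = {"SEC": 80, "IEC": 95}


@dataclass(frozen=True)
class NoiseParams:
    """Noise model of the elution simulator.

    peak_width: Gaussian peak s.d. in fractions.
    count_dispersion: s.d. of the per-(protein, replicate) log-normal
        amplitude jitter (0 = pure Poisson counting noise).
    dropout_prob: probability that a protein's entire row is zeroed in one
        replicate (missed detection of the protein in that run).
    monomer_prob: probability that a complex member also carries a secondary
        monomer peak (a partially unassembled pool).
    amplitude: median peak height in distinct-peptide counts.
    counting_noise: when False, counts are the rounded peak intensities
        instead of Poisson draws (a fully deterministic signal).
    """

    peak_width: float = 1.0
    count_dispersion: float = 0.25
    dropout_prob: float = 0.05
    monomer_prob: float = 0.1
    amplitude: float = 30.0
    counting_noise: bool = True


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated study.

    complexes_per_state maps each state label to an equal-length list of
    member sets; index i refers to the same planted complex in both states,
    so rewiring is a per-index membership edit.  rewired_pairs is exactly
    the set of canonical co-complex pairs present in one state only.
    """

    complexes_per_state: dict[str, list[frozenset[str]]]
    rewired_pairs: frozenset[tuple[str, str]]
    protein_universe: list[str]
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        universe = set(self.protein_universe)
        for state, complexes in self.complexes_per_state.items():
            for members in complexes:
                if len(members) < 2:
                    raise ValueError(f"complex of size {len(members)} in state {state!r}")
                if not members <= universe:
                    raise ValueError("complex member outside protein universe")

    def co_complex_pairs(self, state: str) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes_per_state[state]:
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    pairs.add((a, b))
        return pairs

    def complex_members(self, state: str) -> set[str]:
        out: set[str] = set()
        for members in self.complexes_per_state[state]:
            out |= members
        return out

    def catalog(self, state: str) -> ReferenceComplexCatalog:
        """The planted complexes of one state as a reference catalog."""
        return ReferenceComplexCatalog(
            complexes={
                f"cplx{i:03d}": members
                for i, members in enumerate(self.complexes_per_state[state])
            }
        )


def _sizes_from_spec(size_distribution, n_complexes: int, rng: np.random.Generator) -> np.ndarray:
    """Accept either an inclusive (min, max) range or an explicit size list."""
    if isinstance(size_distribution, tuple) and len(size_distribution) == 2:
        lo, hi = size_distribution
        if lo < 2:
            raise ValueError(f"minimum complex size {lo} < 2")
        return rng.integers(int(lo), int(hi) + 1, size=n_complexes)
    sizes = np.asarray(list(size_distribution), dtype=int)
    if len(sizes) != n_complexes:
        raise ValueError("explicit size list length must equal n_complexes")
    if (sizes < 2).any():
        raise ValueError("complex sizes must be >= 2")
    return sizes


def simulate_catalog(
    n_complexes: int,
    size_distribution=(2, 10),
    n_background_proteins: int = 200,
    seed: int = 0,
    noise: NoiseParams | None = None,
) -> SimulationTruth:
    """Plant a disjoint complex catalog over a named protein universe.

    Proteins are named P0000, P0001, ... with complex members first and
    background singletons after.  Both states start identical; use
    :func:`apply_rewiring` to introduce state differences.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = _sizes_from_spec(size_distribution, n_complexes, rng)
    n_members = int(sizes.sum())
    universe = [f"P{i:04d}" for i in range(n_members + n_background_proteins)]
    complexes: list[frozenset[str]] = []
    cursor = 0
    for s in sizes:
        complexes.append(frozenset(universe[cursor : cursor + int(s)]))
        cursor += int(s)
    return SimulationTruth(
        complexes_per_state={state: list(complexes) for state in STATES},
        rewired_pairs=frozenset(),
        protein_universe=universe,
        noise=noise or NoiseParams(),
        seed=seed,
    )


def apply_rewiring(truth: SimulationTruth, fraction_rewired: float, seed: int | None = None) -> SimulationTruth:
    """Alter membership of a fraction of complexes in the second state.

    A selected complex either loses one member (size > 2) or has one member
    swapped for an unused background protein; rewired_pairs is recomputed as
    the symmetric difference of co-complex pairs between the two states.
    """
    if not 0.0 <= fraction_rewired <= 1.0:
        raise ValueError("fraction_rewired must be in [0, 1]")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    state_a, state_b = STATES
    base = truth.complexes_per_state[state_a]
    n_rewire = int(round(fraction_rewired * len(base)))
    chosen = sorted(rng.choice(len(base), size=n_rewire, replace=False).tolist())

    used = truth.complex_members(state_a)
    background_pool = [p for p in truth.protein_universe if p not in used]
    rng.shuffle(background_pool)

    altered = list(base)
    for idx in chosen:
        members = sorted(altered[idx])
        victim = members[int(rng.integers(len(members)))]
        remove = len(members) > 2 and rng.random() < 0.5
        if remove:
            altered[idx] = frozenset(m for m in members if m != victim)
        else:
            if not background_pool:
                if len(members) > 2:
                    altered[idx] = frozenset(m for m in members if m != victim)
                    continue
                raise ValueError("background pool exhausted; cannot swap members of a heterodimer")
            incoming = background_pool.pop()
            altered[idx] = frozenset([incoming] + [m for m in members if m != victim])

    new_truth = replace(
        truth,
        complexes_per_state={state_a: list(base), state_b: altered},
    )
    pairs_a = new_truth.co_complex_pairs(state_a)
    pairs_b = new_truth.co_complex_pairs(state_b)
    return replace(new_truth, rewired_pairs=frozenset(pairs_a ^ pairs_b))


# ---------------------------------------------------------------------------
# elution matrices


def _stream(*keys) -> np.random.Generator:
    """Deterministic named substream: integers and strings key the stream."""
    entropy = [k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_experiment(
    truth: SimulationTruth,
    state: str,
    technique: str,
    replicate: str,
    n_fractions: int | None = None,
    seed: int | None = None,
) -> FractionationExperiment:
    """Simulate one replicate elution matrix for (state, technique).

    Replicates of the same (state, technique) share apexes, masses and
    baseline amplitudes (drawn from replicate-independent streams keyed on
    the base seed) and differ only in Poisson noise, amplitude jitter and
    dropout, which are keyed on the replicate label as well.
    """
    noise = truth.noise
    if n_fractions is None:
        n_fractions = DEFAULT_FRACTIONS.get(technique, 80)
    if n_fractions < 10:
        raise ValueError("n_fractions must be >= 10")
    margin = int(math.ceil(2 * noise.peak_width))
    if n_fractions <= 2 * margin + 1:
        raise ValueError(
            f"n_fractions={n_fractions} too small for peak width {noise.peak_width}"
        )
    base = truth.seed if seed is None else seed
    universe = truth.protein_universe
    n_prot = len(universe)
    prot_index = {p: i for i, p in enumerate(universe)}

    # replicate-independent protein attributes (state/technique independent)
    attr = _stream(base, "protein-attrs")
    mass = attr.lognormal(mean=4.0, sigma=0.5, size=n_prot)  # kDa-scale proxy
    amplitude = noise.amplitude * attr.lognormal(mean=0.0, sigma=0.3, size=n_prot)
    monomer_flag = attr.random(n_prot) < noise.monomer_prob

    # monomer apexes: per (technique, protein), shared across states/replicates
    mono = _stream(base, "monomer-apex", technique)
    lo, hi = margin, n_fractions - 1 - margin
    monomer_apex = mono.integers(lo, hi + 1, size=n_prot)

    complexes = truth.complexes_per_state[state]
    # apex layout is computed from the base-state catalog so that it is
    # identical across states: a single-membership edit changes a complex's
    # elution volume negligibly, and a state-dependent layout would smear
    # spurious differential co-elution over every unrelated protein
    layout_complexes = truth.complexes_per_state[STATES[0]]
    if technique == "SEC":
        # big assemblies elute first: order complexes by decreasing summed mass
        total_mass = np.array(
            [sum(mass[prot_index[m]] for m in members) for members in layout_complexes]
        )
        order = np.argsort(-total_mass, kind="stable")
        span = max(hi - lo, 1)
        apex_of_rank = lo + np.round(
            np.linspace(0, span, num=max(len(complexes), 2))[: len(complexes)]
        ).astype(int)
        complex_apex = np.empty(len(complexes), dtype=int)
        complex_apex[order] = apex_of_rank
    else:
        # distinct apexes per complex: assemblies with different composition
        # carry different net charge, so IEC resolves them into different
        # fractions (falls back to sampling with replacement if overfull)
        cstream = _stream(base, "complex-apex", technique)
        positions = np.arange(lo, hi + 1)
        replace = len(complexes) > len(positions)
        complex_apex = cstream.choice(positions, size=max(len(complexes), 1), replace=replace)[
            : len(complexes)
        ]

    fracs = np.arange(n_fractions)

    def peak(apex: int, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((fracs - apex) / noise.peak_width) ** 2)

    rep = _stream(base, "replicate-noise", state, technique, replicate)
    jitter = np.exp(rep.normal(0.0, noise.count_dispersion, size=n_prot))

    intensity = np.zeros((n_prot, n_fractions))
    in_complex = np.zeros(n_prot, dtype=bool)
    for ci, members in enumerate(complexes):
        for m in members:
            i = prot_index[m]
            in_complex[i] = True
            intensity[i] += peak(int(complex_apex[ci]), amplitude[i] * jitter[i])
    for i in range(n_prot):
        if not in_complex[i]:
            intensity[i] += peak(int(monomer_apex[i]), amplitude[i] * jitter[i])
        elif monomer_flag[i]:
            intensity[i] += peak(int(monomer_apex[i]), 0.5 * amplitude[i] * jitter[i])

    if noise.counting_noise:
        counts = rep.poisson(intensity).astype(int)
    else:
        counts = np.rint(intensity).astype(int)
    dropped = rep.random(n_prot) < noise.dropout_prob
    counts[dropped] = 0

    data = pd.DataFrame(counts, index=list(universe), columns=[f"F{j+1}" for j in range(n_fractions)])
    return FractionationExperiment(state=state, technique=technique, replicate=replicate, data=data)


def simulate_all_experiments(
    truth: SimulationTruth,
    replicates: tuple[str, ...] = ("r1", "r2"),
    n_fractions: dict[str, int] | None = None,
) -> list[FractionationExperiment]:
    """The full 2-state x 2-technique x replicate design."""
    n_fractions = n_fractions or DEFAULT_FRACTIONS
    out = []
    for state in STATES:
        for technique in TECHNIQUES:
            for rep in replicates:
                out.append(
                    simulate_experiment(
                        truth, state, technique, rep, n_fractions=n_fractions.get(technique)
                    )
                )
    return out


# ---------------------------------------------------------------------------
# phosphosites


def simulate_phosphosites(
    truth: SimulationTruth,
    n_sites: int,
    residue_mix: tuple[float, float, float] = (121, 40, 24),
    ascore_distribution=("uniform", 0.0, 40.0),
    detect_prob: float = 0.75,
    known_prob: float = 0.3,
    seed: int | None = None,
) -> list[PhosphoSiteRecord]:
    """Simulate a phosphosite table with ground-truth filter labels.

    residue_mix gives relative S:T:Y frequencies (default matches the
    observed mitochondrial site composition).  Each site is present in one
    or both states; per-replicate detection flags are Bernoulli(detect_prob)
    where present.  The stored truth labels apply the retention rule
    (Ascore >= 13 and >= 2/3 replicates, or a known site) per state.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mix = np.asarray(residue_mix, dtype=float)
    mix = mix / mix.sum()
    residues = rng.choice(list("STY"), size=n_sites, p=mix)
    kind, *params = ascore_distribution
    if kind == "uniform":
        ascores = rng.uniform(params[0], params[1], size=n_sites)
    elif kind == "exponential":
        ascores = rng.exponential(params[0], size=n_sites)
    else:
        raise ValueError(f"unknown ascore distribution {kind!r}")

    records: list[PhosphoSiteRecord] = []
    universe = truth.protein_universe
    for i in range(n_sites):
        protein = universe[int(rng.integers(len(universe)))]
        position = int(rng.integers(1, 800))
        presence = rng.choice(["both", STATES[0], STATES[1]], p=[0.4, 0.3, 0.3])
        detections = {}
        for state in STATES:
            if presence in ("both", state):
                flags = tuple(bool(x) for x in rng.random(3) < detect_prob)
            else:
                flags = (False, False, False)
            detections[state] = flags
        known = bool(rng.random() < known_prob)
        rec = PhosphoSiteRecord(
            protein=protein,
            position=position,
            residue=str(residues[i]),
            ascore=float(ascores[i]),
            detections=detections,
            known_site=known,
        )
        rec.truth_pass = {
            state: rec.ascore >= 13.0
            and (
                sum(rec.detections[state]) >= 2
                or (rec.known_site and sum(rec.detections[state]) >= 1)
            )
            for state in STATES
        }
        records.append(rec)
    return records
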