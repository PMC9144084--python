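"""Calibrated simulator of mosaic mitochondrial-genome alignments.

The generator emulates the statistical regime the detection pipeline
assumes: a few deeply diverged "species" lineages (default two donor
lineages at 8.5% and 4.5% p-distance from the recipient lineage), shallow
conspecific variation (0.3%), and planted donor fragments spliced into
recipient genomes with an exact number of post-transfer mutations.  All
substitution is independent-site and Jukes-Cantor-like (uniform choice
among the three alternative bases), with no indels, so alignments are
gapless and planted breakpoints are exact alignment columns.

Per-branch substitution probabilities are calibrated so that the
*expected* pairwise p-distance between species references matches the
configured targets exactly, accounting for coincident substitutions on
both branches (two sequences at branch probabilities ``q1``, ``q2`` from
a common ancestor differ per site with probability
``q1 + q2 - (4/3) q1 q2``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .alignio import MultipleAlignment, SequenceRecord

__all__ = [
    "PlantedEvent",
    "SimulationConfig",
    "TruthEvent",
    "SyntheticTruth",
    "simulate",
    "write_truth",
    "read_truth",
    "paper_mimic_config",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationConfigError(ValueError):
    """Unsatisfiable or malformed simulation configuration."""


class TruthParseError(ValueError):
    """Malformed truth JSON."""


@dataclass(frozen=True)
class PlantedEvent:
    """A donor fragment to splice into one recipient individual."""

    recipient: str  # individual id, e.g. "A3"
    donor_species: str  # species label, e.g. "B"
    start: int  # 1-based alignment column
    length: int  # columns
    n_mutations: int  # post-transfer substitutions inside the fragment

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the mitochondrial regime the pipeline targets: a
    ~16.5 kb genome, a recipient species with five sequenced individuals
    and two single-genome donor species at 8.5% and 4.5% divergence from
    it, and 0.3% conspecific divergence.
    """

    genome_length: int = 16_500
    species: tuple[str, ...] = ("A", "B", "C")
    n_individuals: tuple[int, ...] = (5, 1, 1)
    interspecific_divergence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("A", "B"): 0.085, ("A", "C"): 0.045, ("B", "C"): 0.080}
    )
    intraspecific_divergence: float = 0.003
    planted_events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def individual_ids(self) -> list[str]:
        out = []
        for sp, n in zip(self.species, self.n_individuals):
            out.extend(f"{sp}{k}" for k in range(1, n + 1))
        return out

    def groups(self) -> dict[str, str]:
        """Mapping individual id -> species label."""
        return {
            iid: iid.rstrip("0123456789") for iid in self.individual_ids()
        }

    def validate(self) -> None:
        if len(self.species) != len(self.n_individuals):
            raise SimulationConfigError("species / n_individuals length mismatch")
        if len(self.species) < 2:
            raise SimulationConfigError("need at least 2 species")
        for pair in _species_pairs(self.species):
            d = _lookup_divergence(self.interspecific_divergence, pair)
            if not (0 < d < 0.75):
                raise SimulationConfigError(
                    f"interspecific divergence for {pair} must be in (0, 0.75)"
                )
        if not (0 < self.intraspecific_divergence < 0.75):
            raise SimulationConfigError("intraspecific divergence must be in (0, 0.75)")
        ids = set(self.individual_ids())
        by_recipient: dict[str, list[PlantedEvent]] = {}
        for ev in self.planted_events:
            if ev.recipient not in ids:
                raise SimulationConfigError(f"unknown recipient {ev.recipient!r}")
            if ev.donor_species not in self.species:
                raise SimulationConfigError(f"unknown donor species {ev.donor_species!r}")
            if ev.start < 1 or ev.end > self.genome_length:
                raise SimulationConfigError(
                    f"event at {ev.start}..{ev.end} outside genome 1..{self.genome_length}"
                )
            if ev.n_mutations < 0 or ev.n_mutations > ev.length:
                raise SimulationConfigError("n_mutations must be in 0..length")
            by_recipient.setdefault(ev.recipient, []).append(ev)
        for rec, evs in by_recipient.items():
            evs = sorted(evs, key=lambda e: e.start)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.start <= prev.end:
                    raise SimulationConfigError(
                        f"overlapping planted events for recipient {rec!r}"
                    )


def _species_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    return [
        (species[i], species[j])
        for i in range(len(species))
        for j in range(i + 1, len(species))
    ]


def _lookup_divergence(
    table: Mapping[tuple[str, str], float], pair: tuple[str, str]
) -> float:
    if pair in table:
        return table[pair]
    rev = (pair[1], pair[0])
    if rev in table:
        return table[rev]
    raise SimulationConfigError(f"no divergence target for species pair {pair}")


def _pair_expected(q1: float, q2: float) -> float:
    # P(differ) for two branches at per-site substitution probs q1, q2
    return q1 + q2 - (4.0 / 3.0) * q1 * q2


def _solve_two_branch(d: float) -> float:
    """Per-branch probability q with _pair_expected(q, q) == d (exact)."""
    # (4/3) q^2 - 2 q + d = 0, smaller root
    disc = 4.0 - (16.0 / 3.0) * d
    if disc < 0:
        raise SimulationConfigError(f"divergence target {d} unreachable")
    return (2.0 - np.sqrt(disc)) / (8.0 / 3.0)


def _solve_branch_rates(config: SimulationConfig) -> dict[str, float]:
    """Star-phylogeny per-species branch substitution probabilities whose
    expected pairwise p-distances meet the configured targets."""
    sp = config.species
    pairs = _species_pairs(sp)
    targets = np.array(
        [_lookup_divergence(config.interspecific_divergence, p) for p in pairs]
    )
    if len(sp) == 2:
        q = _solve_two_branch(float(targets[0]))
        return {sp[0]: q, sp[1]: q}

    idx = {s: i for i, s in enumerate(sp)}

    def residual(q: np.ndarray) -> np.ndarray:
        return np.array(
            [_pair_expected(q[idx[a]], q[idx[b]]) for a, b in pairs]
        ) - targets

    x0 = np.full(len(sp), float(targets.mean()) / 2)
    sol = least_squares(
        residual, x0, bounds=(0.0, 0.745), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not sol.success or np.abs(sol.fun).max() > 1e-8:
        raise SimulationConfigError(
            "interspecific divergence targets are not jointly satisfiable "
            "on a star phylogeny"
        )
    return {s: float(sol.x[idx[s]]) for s in sp}


def _mutate(seq: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute masked sites to a uniformly chosen different base."""
    out = seq.copy()
    sites = np.flatnonzero(mask)
    if len(sites) == 0:
        return out
    # offset 1..3 within ACGT, cyclic, guarantees a different base
    cur = np.searchsorted(_ACGT, out[sites])
    shift = rng.integers(1, 4, size=len(sites))
    out[sites] = _ACGT[(cur + shift) % 4]
    return out


@dataclass(frozen=True)
class TruthEvent:
    recipient: str
    donor_id: str
    donor_species: str
    begin: int
    end: int
    mutation_positions: tuple[int, ...]  # 1-based alignment columns


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    events: tuple[TruthEvent, ...]
    realized_reference_divergence: Mapping[str, float]  # "A-B" -> p-distance
    seed: int
    genome_length: int


def simulate(config: SimulationConfig) -> tuple[MultipleAlignment, SyntheticTruth]:
    """Generate a gapless mosaic alignment plus its ground truth.

    Draw an ancestral sequence, derive one reference per species on a
    calibrated star phylogeny, derive individuals at the conspecific
    rate, then splice planted donor fragments into their recipients and
    apply exactly the configured number of post-transfer mutations at
    recorded positions.  All randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    ancestral = _ACGT[rng.integers(0, 4, size=L)]
    rates = _solve_branch_rates(config)
    refs = {
        sp: _mutate(ancestral, rng.random(L) < rates[sp], rng)
        for sp in config.species
    }
    q_intra = _solve_two_branch(config.intraspecific_divergence)
    rows: dict[str, np.ndarray] = {}
    for sp, n in zip(config.species, config.n_individuals):
        for k in range(1, n + 1):
            rows[f"{sp}{k}"] = _mutate(refs[sp], rng.random(L) < q_intra, rng)

    truth_events = []
    for ev in config.planted_events:
        donor_id = f"{ev.donor_species}1"
        s, e = ev.start - 1, ev.end
        frag = rows[donor_id][s:e].copy()
        pos = rng.choice(ev.length, size=ev.n_mutations, replace=False)
        cur = np.searchsorted(_ACGT, frag[pos])
        frag[pos] = _ACGT[(cur + rng.integers(1, 4, size=ev.n_mutations)) % 4]
        rows[ev.recipient][s:e] = frag
        truth_events.append(
            TruthEvent(
                recipient=ev.recipient,
                donor_id=donor_id,
                donor_species=ev.donor_species,
                begin=ev.start,
                end=ev.end,
                mutation_positions=tuple(sorted(int(p) + ev.start for p in pos)),
            )
        )

    realized = {}
    for a, b in _species_pairs(config.species):
        realized[f"{a}-{b}"] = float((refs[a] != refs[b]).mean())

    records = [
        SequenceRecord(iid, rows[iid].tobytes().decode("ascii"),
                       description=f"synthetic species {iid.rstrip('0123456789')}")
        for iid in config.individual_ids()
    ]
    truth = SyntheticTruth(
        events=tuple(truth_events),
        realized_reference_divergence=realized,
        seed=config.seed,
        genome_length=L,
    )
    return MultipleAlignment(records), truth


def paper_mimic_config(seed: int = 0) -> SimulationConfig:
    """The bundled mosaic regime used throughout the test-suite.

    Species A is the recipient (five individuals, two of them clean);
    species B donates three fragments to A3 (140, 1710, and 359 columns,
    with 0, 2, and 0 post-transfer mutations) and the 1710-column
    fragment again to A4 (2 mutations); species C donates a 425-column
    fragment to A5 (4 mutations).  Divergences: A-B 8.5%, A-C 4.5%,
    conspecific 0.3%.
    """
    return SimulationConfig(
        planted_events=(
            PlantedEvent("A3", "B", 5566, 140, 0),
            PlantedEvent("A3", "B", 10_167, 1710, 2),
            PlantedEvent("A3", "B", 15_606, 359, 0),
            PlantedEvent("A4", "B", 10_167, 1710, 2),
            PlantedEvent("A5", "C", 12_946, 425, 4),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth (de)serialisation

_TRUTH_FIELDS = ("events", "realized_reference_divergence", "seed", "genome_length")
_EVENT_FIELDS = (
    "recipient", "donor_id", "donor_species", "begin", "end", "mutation_positions"
)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """JSON with sorted keys; byte-stable for identical truths."""
    payload = {
        "events": [
            {f: getattr(ev, f) if f != "mutation_positions"
             else list(ev.mutation_positions) for f in _EVENT_FIELDS}
            for ev in truth.events
        ],
        "realized_reference_divergence": dict(truth.realized_reference_divergence),
        "seed": truth.seed,
        "genome_length": truth.genome_length,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TruthParseError(f"invalid truth JSON: {exc}") from exc
    for f in _TRUTH_FIELDS:
        if f not in payload:
            raise TruthParseError(f"truth file missing field {f!r}")
    events = []
    for k, ev in enumerate(payload["events"]):
        for f in _EVENT_FIELDS:
            if f not in ev:
                raise TruthParseError(f"event {k} missing field {f!r}")
        events.append(
            TruthEvent(
                recipient=ev["recipient"],
                donor_id=ev["donor_id"],
                donor_species=ev["donor_species"],
                begin=int(ev["begin"]),
                end=int(ev["end"]),
                mutation_positions=tuple(int(p) for p in ev["mutation_positions"]),
            )
        )
    return SyntheticTruth(
        events=tuple(events),
        realized_reference_divergence={
            k: float(v) for k, v in payload["realized_reference_divergence"].items()
        },
        seed=int(payload["seed"]),
        genome_length=int(payload["genome_length"]),
    )
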