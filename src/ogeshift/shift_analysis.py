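"""Shift classification of labelled vs unlabelled OFFGEL observations.

Observations of the same peptide sequence in its unlabelled and iTRAQ-labelled
forms are paired, screened for replicate reproducibility, and classified by
the direction of the fraction shift:

* ``basic_A``  - the labelled form focuses in more basic wells,
* ``none_B``   - both forms focus in the same well(s),
* ``acidic_C`` - the labelled form focuses in more acidic wells,
* ``irreproducible_D`` - labelled replicates do not agree on a fraction set.

The direction is decided on the midpoints of the consensus fraction sets with
a configurable half-well threshold.  The module also computes per-fraction
acidic/basic residue composition profiles, retention-time deltas, and a
pI-consistency filter flagging observations far from their predicted well.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_core import validate_sequence
from .oge_model import FractionSet

__all__ = [
    "LabelState",
    "ShiftClass",
    "FractionObservation",
    "PeptidePair",
    "ClassifiedPair",
    "pair_observations",
    "modal_fraction_set",
    "consensus_fraction_set",
    "reproducibility_filter",
    "classify_shift",
    "classify_pairs",
    "composition_profile",
    "retention_delta",
    "pi_consistency_filter",
]

ACIDIC_RESIDUES = frozenset("DE")
BASIC_RESIDUES = frozenset("KR")


class LabelState(str, enum.Enum):
    UNLABELLED = "unlabelled"
    LABELLED = "labelled"


class ShiftClass(str, enum.Enum):
    BASIC_A = "basic_A"
    NONE_B = "none_B"
    ACIDIC_C = "acidic_C"
    IRREPRODUCIBLE_D = "irreproducible_D"


@dataclass(frozen=True)
class FractionObservation:
    """One OFFGEL sighting of a peptide in one experiment."""

    sequence: str
    label_state: LabelState
    experiment_id: str
    fractions: FractionSet
    retention_time: float | None = None
    confidence: float | None = None
    flags: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        object.__setattr__(self, "label_state", LabelState(self.label_state))
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError("retention_time must be non-negative")


@dataclass(frozen=True)
class PeptidePair:
    """Matched unlabelled/labelled observations for one sequence."""

    sequence: str
    unlabelled_obs: tuple[FractionObservation, ...]
    labelled_obs: tuple[FractionObservation, ...]

    def __post_init__(self) -> None:
        if not self.unlabelled_obs or not self.labelled_obs:
            raise ValueError("a pair needs observations on both sides")
        for obs in (*self.unlabelled_obs, *self.labelled_obs):
            if obs.sequence != self.sequence:
                raise ValueError("observation sequence mismatch")


def pair_observations(
    observations: Iterable[FractionObservation],
) -> tuple[list[PeptidePair], list[FractionObservation]]:
    """Group observations by sequence into pairs; sequences seen in only one
    label state are returned separately as unmatched."""
    by_seq: dict[str, dict[LabelState, list[FractionObservation]]] = defaultdict(
        lambda: {LabelState.UNLABELLED: [], LabelState.LABELLED: []}
    )
    order: list[str] = []
    for obs in observations:
        if obs.sequence not in by_seq:
            order.append(obs.sequence)
        by_seq[obs.sequence][obs.label_state].append(obs)
    pairs: list[PeptidePair] = []
    unmatched: list[FractionObservation] = []
    for seq in order:
        sides = by_seq[seq]
        if sides[LabelState.UNLABELLED] and sides[LabelState.LABELLED]:
            pairs.append(PeptidePair(
                seq,
                tuple(sides[LabelState.UNLABELLED]),
                tuple(sides[LabelState.LABELLED]),
            ))
        else:
            unmatched.extend(sides[LabelState.UNLABELLED])
            unmatched.extend(sides[LabelState.LABELLED])
    return pairs, unmatched


def modal_fraction_set(fraction_sets: Iterable[FractionSet]) -> tuple[FractionSet, int]:
    """Modal fraction set and its multiplicity.

    Ties are broken toward the smaller (more specific) set, then toward the
    more acidic wells, so the choice is deterministic.
    """
    counts = Counter(fraction_sets)
    best = min(counts.items(), key=lambda kv: (-kv[1], len(kv[0].wells), kv[0].wells))
    return best[0], best[1]


def consensus_fraction_set(
    observations: Sequence[FractionObservation],
) -> tuple[FractionSet, int]:
    """Modal fraction set across replicate observations (see
    :func:`modal_fraction_set` for the tie-break rule)."""
    return modal_fraction_set(obs.fractions for obs in observations)


def reproducibility_filter(pair: PeptidePair, min_replicates: int = 3) -> bool:
    """True when at least ``min_replicates`` labelled observations agree on
    the same fraction set (set equality)."""
    _, multiplicity = consensus_fraction_set(pair.labelled_obs)
    return multiplicity >= min_replicates


def classify_shift(pair: PeptidePair, threshold: float = 0.5) -> ShiftClass:
    """Direction of the consensus fraction-set midpoint shift.

    ``delta = mid(labelled) - mid(unlabelled)``; basic_A when delta >=
    +threshold wells, acidic_C when delta <= -threshold, none_B otherwise.
    The pair is assumed to have passed :func:`reproducibility_filter`.
    """
    nl, _ = consensus_fraction_set(pair.unlabelled_obs)
    lab, _ = consensus_fraction_set(pair.labelled_obs)
    delta = lab.midpoint - nl.midpoint
    if delta >= threshold:
        return ShiftClass.BASIC_A
    if delta <= -threshold:
        return ShiftClass.ACIDIC_C
    return ShiftClass.NONE_B


@dataclass(frozen=True)
class ClassifiedPair:
    sequence: str
    shift_class: ShiftClass
    consensus_unlabelled: FractionSet
    consensus_labelled: FractionSet
    midpoint_delta: float
    n_labelled_agreeing: int


def classify_pairs(
    pairs: Iterable[PeptidePair],
    min_replicates: int = 3,
    threshold: float = 0.5,
) -> list[ClassifiedPair]:
    """Run the reproducibility rule then the shift rule on every pair."""
    results: list[ClassifiedPair] = []
    for pair in pairs:
        nl, _ = consensus_fraction_set(pair.unlabelled_obs)
        lab, agree = consensus_fraction_set(pair.labelled_obs)
        if agree < min_replicates:
            cls = ShiftClass.IRREPRODUCIBLE_D
        else:
            cls = classify_shift(pair, threshold)
        results.append(ClassifiedPair(
            sequence=pair.sequence,
            shift_class=cls,
            consensus_unlabelled=nl,
            consensus_labelled=lab,
            midpoint_delta=lab.midpoint - nl.midpoint,
            n_labelled_agreeing=agree,
        ))
    return results


def composition_profile(
    peptides_by_fraction: Iterable[tuple[str, FractionSet | Iterable[int]]],
) -> pd.DataFrame:
    """Mean acidic (D+E) and basic (K+R) residue counts per unlabelled fraction.

    Each (sequence, fractions) item contributes to every well it was observed
    in.  Fractions with no peptides are absent from the result.  Returns a
    DataFrame indexed by fraction with columns ``mean_acidic``, ``mean_basic``
    and ``n_peptides``.
    """
    acidic: dict[int, list[int]] = defaultdict(list)
    basic: dict[int, list[int]] = defaultdict(list)
    for sequence, fractions in peptides_by_fraction:
        validate_sequence(sequence)
        n_acid = sum(1 for r in sequence if r in ACIDIC_RESIDUES)
        n_base = sum(1 for r in sequence if r in BASIC_RESIDUES)
        for well in fractions:
            acidic[well].append(n_acid)
            basic[well].append(n_base)
    rows = {
        well: {
            "mean_acidic": sum(acidic[well]) / len(acidic[well]),
            "mean_basic": sum(basic[well]) / len(basic[well]),
            "n_peptides": len(acidic[well]),
        }
        for well in sorted(acidic)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "fraction"
    return frame


def retention_delta(pairs: Iterable[PeptidePair]) -> tuple[pd.DataFrame, int]:
    """Per-fraction mean labelled-minus-unlabelled retention time.

    Pairs lacking a retention time on either side are excluded; the count of
    excluded pairs is returned alongside the per-fraction table.  A pair is
    grouped under every well of its unlabelled consensus set.
    """
    deltas: dict[int, list[float]] = defaultdict(list)
    excluded = 0
    for pair in pairs:
        rt_nl = [o.retention_time for o in pair.unlabelled_obs
                 if o.retention_time is not None]
        rt_l = [o.retention_time for o in pair.labelled_obs
                if o.retention_time is not None]
        if not rt_nl or not rt_l:
            excluded += 1
            continue
        delta = sum(rt_l) / len(rt_l) - sum(rt_nl) / len(rt_nl)
        nl, _ = consensus_fraction_set(pair.unlabelled_obs)
        for well in nl:
            deltas[well].append(delta)
    rows = {
        well: {
            "mean_delta_min": sum(values) / len(values),
            "n_pairs": len(values),
        }
        for well, values in sorted(deltas.items())
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "fraction"
    return frame, excluded


def pi_consistency_filter(
    obs: FractionObservation, predicted_well: int, tol_wells: int = 1
) -> bool:
    """Keep an identification when an observed well lies within ``tol_wells``
    of the well predicted from the computed pI (for the observation's label
    state).  Flagged (False) observations are candidate false positives."""
    return min(abs(w - predicted_well) for w in obs.fractions) <= tol_wells
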