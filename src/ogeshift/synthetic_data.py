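"""Simulated OFFGEL observation datasets with known ground truth.

The generator emulates the statistical structure the shift analysis assumes:
tryptic peptides with a known pI distribution, pI-driven well assignment with
adjacent-well spillover noise, replicate structure, and injected
label-induced fraction offsets per shift group.

Per peptide the generator samples a shift group (A basic, B none, C acidic,
D irreproducible), draws the unlabelled well per replicate from the true pI
plus spillover, and sets the labelled wells to the unlabelled consensus
shifted by the group's offset (clamped to the strip).  Group-D peptides draw
random labelled wells per replicate, conditioned on *not* reaching replicate
agreement - a draw that happened to agree would not be an irreproducible
peptide.  Group feasibility respects strip geometry: a peptide whose true
well leaves no room for a basic offset is never assigned group A (mirroring
the observed data, where peptides at the basic end of the strip cannot shift
further), and symmetrically for group C at the acidic end.

Default group proportions follow the observed cohort (70:34:11:7 over the
four groups); the default spillover rate of 0.15 reflects that a clear
majority of peptides focus in a single well with the remainder in an
adjacent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from pyteomics import parser as _pyt_parser

from .charge_model import PKaTable, isoelectric_point
from .chem_core import STANDARD_RESIDUES, native_species, validate_sequence
from .oge_model import DEFAULT_LAYOUT, FractionSet, StripLayout, locate_pi
from .shift_analysis import (
    FractionObservation,
    LabelState,
    modal_fraction_set,
)

__all__ = [
    "TRYPSIN_RULE",
    "SimulationConfig",
    "SimulatedDataset",
    "tryptic_digest",
    "random_protein",
    "simulate_oge_observation",
    "simulate_paired_dataset",
]

#: cleave C-terminal to K or R unless the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"

_GROUPS = ("A", "B", "C", "D")
#: observed cohort proportions, 70:34:11:7
_DEFAULT_GROUP_PROBS = {"A": 70 / 122, "B": 34 / 122, "C": 11 / 122, "D": 7 / 122}


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico tryptic peptides of a protein, in N- to C-terminal order.

    Cleavage is C-terminal to K/R except before proline; concatenations up
    to ``missed_cleavages`` are included.
    """
    validate_sequence(protein)
    fragments = sorted(
        set(_pyt_parser.icleave(protein, TRYPSIN_RULE,
                                missed_cleavages=missed_cleavages)),
        key=lambda item: (item[0], len(item[1])),
    )
    return [peptide for _, peptide in fragments]


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Protein with residues drawn i.i.d. uniformly over the 20 standard
    amino acids (pI diversity matters more than compositional realism)."""
    alphabet = sorted(STANDARD_RESIDUES)
    return "".join(rng.choice(alphabet, size=length))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``spillover`` is the probability that a replicate observation lands in a
    well adjacent to the pI-mapped one; ``offsets`` give the labelled-form
    well shift for the basic (A) and acidic (C) groups in wells.
    ``rt_shift_fraction1`` is the labelled-minus-unlabelled retention-time
    increase (minutes) applied to peptides whose unlabelled consensus is
    well 1; other wells get no shift.
    """

    seed: int
    n_proteins: int = 20
    protein_length: int = 300
    fasta: str | None = None
    missed_cleavages: int = 0
    min_peptide_length: int = 6
    spillover: float = 0.15
    n_replicates: int = 3
    group_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_PROBS))
    offset_basic: int = 2
    offset_acidic: int = -2
    rt_shift_fraction1: float = 6.0
    layout: StripLayout = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        if not 0.0 <= self.spillover < 1.0:
            raise ValueError("spillover must lie in [0, 1)")
        probs = self.group_probs
        if set(probs) - set(_GROUPS) or any(p < 0 for p in probs.values()):
            raise ValueError("group_probs must be non-negative over A/B/C/D")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("group_probs must sum to 1")
        if self.offset_basic < 1 or self.offset_acidic > -1:
            raise ValueError("offsets must shift by at least one well")


@dataclass(frozen=True)
class SimulatedDataset:
    observations: tuple[FractionObservation, ...]
    truth: "pd.DataFrame"  # sequence, group, true_pi, true_well

    @property
    def sequences(self) -> list[str]:
        return list(self.truth["sequence"])


def simulate_oge_observation(
    true_pi: float,
    layout: StripLayout,
    spillover: float,
    rng: np.random.Generator,
) -> FractionSet:
    """One noisy well observation: the pI-mapped well with probability
    1 - spillover, otherwise an adjacent well (edge wells spill inward)."""
    well = locate_pi(layout, true_pi).well
    if spillover > 0.0 and rng.random() < spillover:
        if well == 1:
            well += 1
        elif well == layout.n_wells:
            well -= 1
        else:
            well += rng.choice((-1, 1))
    return FractionSet.of(int(well))


def _feasible_groups(well: int, cfg: SimulationConfig) -> list[str]:
    feasible = ["B", "D"]
    if well + cfg.offset_basic <= cfg.layout.n_wells:
        feasible.append("A")
    if well + cfg.offset_acidic >= 1:
        feasible.append("C")
    return feasible


def _sample_group(well: int, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    feasible = _feasible_groups(well, cfg)
    probs = np.array([cfg.group_probs.get(g, 0.0) for g in feasible])
    if probs.sum() == 0.0:
        return "B"
    return str(rng.choice(feasible, p=probs / probs.sum()))


def _digest_pool(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    if cfg.fasta is not None:
        from Bio import SeqIO

        proteins = [str(rec.seq) for rec in SeqIO.parse(cfg.fasta, "fasta")]
    else:
        proteins = [random_protein(rng, cfg.protein_length)
                    for _ in range(cfg.n_proteins)]
    seen: set[str] = set()
    peptides: list[str] = []
    for protein in proteins:
        for peptide in tryptic_digest(protein, cfg.missed_cleavages):
            if len(peptide) < cfg.min_peptide_length or peptide in seen:
                continue
            if set(peptide) - STANDARD_RESIDUES:
                continue
            seen.add(peptide)
            peptides.append(peptide)
    return peptides


def simulate_paired_dataset(
    cfg: SimulationConfig, table: PKaTable | None = None
) -> SimulatedDataset:
    """Generate a replicated paired dataset plus its ground-truth table."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    observations: list[FractionObservation] = []
    truth_rows: list[dict] = []

    for sequence in _digest_pool(cfg, rng):
        true_pi = isoelectric_point(native_species(sequence), table)
        true_well = locate_pi(layout, true_pi).well
        group = _sample_group(true_well, cfg, rng)
        base_rt = float(rng.uniform(20.0, 60.0))

        unlabelled_sets = [
            simulate_oge_observation(true_pi, layout, cfg.spillover, rng)
            for _ in range(cfg.n_replicates)
        ]
        consensus, _ = modal_fraction_set(unlabelled_sets)
        consensus_well = consensus.wells[0]

        if group == "D":
            labelled_sets = _draw_irreproducible_wells(cfg, rng)
        else:
            offset = {"A": cfg.offset_basic, "B": 0, "C": cfg.offset_acidic}[group]
            shifted = min(max(consensus_well + offset, 1), layout.n_wells)
            labelled_sets = [FractionSet.of(shifted)] * cfg.n_replicates

        rt_shift = cfg.rt_shift_fraction1 if consensus_well == 1 else 0.0
        for r in range(cfg.n_replicates):
            observations.append(FractionObservation(
                sequence, LabelState.UNLABELLED, f"exp{r + 1}",
                unlabelled_sets[r], retention_time=base_rt))
            observations.append(FractionObservation(
                sequence, LabelState.LABELLED, f"exp{r + 1}",
                labelled_sets[r], retention_time=base_rt + rt_shift))
        truth_rows.append({
            "sequence": sequence,
            "group": group,
            "true_pi": true_pi,
            "true_well": true_well,
        })

    truth = pd.DataFrame(truth_rows, columns=["sequence", "group",
                                              "true_pi", "true_well"])
    return SimulatedDataset(tuple(observations), truth)


def _draw_irreproducible_wells(
    cfg: SimulationConfig, rng: np.random.Generator, min_replicates: int = 3
) -> list[FractionSet]:
    """Random wells per replicate, conditioned on no fraction set reaching
    ``min_replicates`` agreement (the definition of an irreproducible
    peptide)."""
    n_wells = cfg.layout.n_wells
    while True:
        wells = rng.integers(1, n_wells + 1, size=cfg.n_replicates)
        counts = np.bincount(wells)
        if cfg.n_replicates < min_replicates or counts.max() < min_replicates:
            return [FractionSet.of(int(w)) for w in wells]
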