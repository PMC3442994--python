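"""Henderson-Hasselbalch net charge and isoelectric point for modified peptides.

The ionizable inventory of a peptide species is built deterministically:
acidic groups are D, E, free C, Y and the C-terminus; basic groups are H, K,
R and the N-terminal alpha-amine.  An iTRAQ tag replaces the native amine at
its site with an ``tag_amine`` group (the N-methylpiperazine of the tag,
default pKa 7.60); carbamidomethylated cysteine contributes no group.

Net charge at a given pH is

    Z(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH))

which is strictly decreasing in pH, so the pI (the root of Z) is unique and
found by bisection on [0, 14].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np
from scipy.optimize import bisect

from .chem_core import N_TERM, PeptideSpecies, labelled_species, native_species

__all__ = [
    "PKaTable",
    "IonizableGroup",
    "PiShift",
    "UndefinedPIError",
    "default_pka_table",
    "ionizable_inventory",
    "net_charge",
    "isoelectric_point",
    "pi_shift",
]

ACIDIC_SIDE_CHAINS = frozenset("DECY")
BASIC_SIDE_CHAINS = frozenset("HKR")


class UndefinedPIError(ValueError):
    """The species has no acidic or no basic group, so Z never crosses zero."""


class IonizableGroup(NamedTuple):
    identifier: str
    pka: float
    sign: int  # +1 basic, -1 acidic


@dataclass(frozen=True)
class PKaTable:
    """Dissociation constants for side chains, termini and modification groups.

    The packaged default is a Bjellqvist-style set used for IPG work.  Use
    :meth:`override` to derive a modified copy; the packaged file is never
    mutated.
    """

    side_chain: dict[str, float]
    n_terminus: float
    c_terminus: float
    modification_groups: dict[str, float]

    def __post_init__(self) -> None:
        values = [*self.side_chain.values(), self.n_terminus, self.c_terminus,
                  *self.modification_groups.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")
        if "tag_amine" not in self.modification_groups:
            raise ValueError("pKa table must define tag_amine")

    def override(self, *, n_terminus: float | None = None,
                 c_terminus: float | None = None,
                 side_chain: dict[str, float] | None = None,
                 modification_groups: dict[str, float] | None = None) -> "PKaTable":
        """Return a copy with selected entries replaced."""
        return PKaTable(
            side_chain={**self.side_chain, **(side_chain or {})},
            n_terminus=self.n_terminus if n_terminus is None else n_terminus,
            c_terminus=self.c_terminus if c_terminus is None else c_terminus,
            modification_groups={**self.modification_groups,
                                 **(modification_groups or {})},
        )


def load_pka_table(path) -> PKaTable:
    side_chain: dict[str, float] = {}
    mod_groups: dict[str, float] = {}
    n_term = c_term = None
    with open(path, "r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            group, pka = row["group"], float(row["pka"])
            if group == "n_terminus":
                n_term = pka
            elif group == "c_terminus":
                c_term = pka
            elif group in ACIDIC_SIDE_CHAINS | BASIC_SIDE_CHAINS:
                side_chain[group] = pka
            else:
                mod_groups[group] = pka
    if n_term is None or c_term is None:
        raise ValueError("pKa table must define n_terminus and c_terminus")
    return PKaTable(side_chain, n_term, c_term, mod_groups)


_DEFAULT_TABLE: PKaTable | None = None


def default_pka_table() -> PKaTable:
    """The packaged Bjellqvist-style default (cached, returned as-is)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("ogeshift.data") / "pka_bjellqvist.tsv"
        ) as path:
            _DEFAULT_TABLE = load_pka_table(path)
    return _DEFAULT_TABLE


def ionizable_inventory(species: PeptideSpecies,
                        table: PKaTable | None = None) -> list[IonizableGroup]:
    """List the ionizable groups of a species with pKa and charge sign.

    Tagged amines (N-terminus or lysine) contribute the tag's basic group
    instead of the native amine; carbamidomethylated cysteines contribute
    nothing.
    """
    table = table or default_pka_table()
    groups: list[IonizableGroup] = []

    def _site_groups(native: IonizableGroup, site) -> Iterable[IonizableGroup]:
        mod = species.modification_at(site)
        if mod is None:
            yield native
            return
        if not mod.suppresses_site_group:
            yield native
        for name, sign in mod.added_groups:
            yield IonizableGroup(name, table.modification_groups[name], sign)

    groups.extend(_site_groups(
        IonizableGroup("n_terminus", table.n_terminus, +1), N_TERM))
    for i, res in enumerate(species.sequence):
        if res in table.side_chain:
            sign = +1 if res in BASIC_SIDE_CHAINS else -1
            groups.extend(_site_groups(
                IonizableGroup(res, table.side_chain[res], sign), i + 1))
    groups.append(IonizableGroup("c_terminus", table.c_terminus, -1))
    return groups


def net_charge(inventory: Iterable[IonizableGroup], ph):
    """Net charge (elementary charges) at one pH or a vector of pH values."""
    ph = np.asarray(ph, dtype=float)
    if np.any(ph < 0.0) or np.any(ph > 14.0):
        raise ValueError("pH out of range [0, 14]")
    charge = np.zeros_like(ph)
    for _, pka, sign in inventory:
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return float(charge) if charge.ndim == 0 else charge


def isoelectric_point(species: PeptideSpecies,
                      table: PKaTable | None = None,
                      xtol: float = 1e-4) -> float:
    """pI of a species: the unique root of the net-charge curve on [0, 14]."""
    inventory = ionizable_inventory(species, table)
    n_basic = sum(1 for g in inventory if g.sign > 0)
    n_acidic = sum(1 for g in inventory if g.sign < 0)
    if n_basic == 0 or n_acidic == 0:
        raise UndefinedPIError(
            f"{species.sequence}: inventory has {n_basic} basic and "
            f"{n_acidic} acidic groups; net charge never crosses zero")
    return float(bisect(lambda ph: net_charge(inventory, ph),
                        0.0, 14.0, xtol=xtol))


class PiShift(NamedTuple):
    unlabelled: float
    labelled: float
    delta: float


def pi_shift(sequence: str, table: PKaTable | None = None) -> PiShift:
    """pI of the native (CAM-fixed) and fully iTRAQ-labelled forms.

    ``delta = labelled - unlabelled``; a negative delta is an acidic shift.
    """
    unlabelled = isoelectric_point(native_species(sequence), table)
    labelled = isoelectric_point(labelled_species(sequence), table)
    return PiShift(unlabelled, labelled, labelled - unlabelled)
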