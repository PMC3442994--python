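"""Residue-level peptide chemistry for iTRAQ-labelled tryptic peptides.

Monoisotopic masses are computed by summing residue masses from the packaged
constant table plus one water, plus the mass deltas of any attached
modifications.  Two printed-mass conventions from the source tables are
exposed: the *neutral* monoisotopic mass of the unlabelled species ("Mass NL")
and the *singly protonated* monoisotopic mass of the fully labelled species
("Mass L"), whose difference is ``n_tags x tag_mass + proton``.

The iTRAQ 4-plex tag reacts with the peptide N-terminus and every lysine
epsilon-amino group; tyrosine side chains are not counted as labelling sites
(reactivity is marginal, below a few percent).  Carbamidomethylation is
treated as a fixed modification on every cysteine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "N_TERM",
    "ModificationSpec",
    "PeptideSpecies",
    "MassReport",
    "MassCheck",
    "ITRAQ4PLEX",
    "CARBAMIDOMETHYL",
    "MODIFICATIONS",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "PROTON_MASS",
    "TAG_MASS",
    "validate_sequence",
    "count_itraq_sites",
    "native_species",
    "labelled_species",
    "neutral_monoisotopic_mass",
    "protonated_labelled_mass",
    "printed_pair_difference",
    "mass_consistency_check",
]

#: site marker for the peptide N-terminus (residue sites are 1-based ints)
N_TERM = "N-term"

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _load_constants() -> tuple[dict[str, float], dict[str, float], dict[str, dict]]:
    residues: dict[str, float] = {}
    constants: dict[str, float] = {}
    modifications: dict[str, dict] = {}
    path = resources.files("ogeshift.data") / "constants.tsv"
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            kind, name = row["kind"], row["name"]
            value = float(row["mono_mass"])
            if kind == "residue":
                residues[name] = value
            elif kind == "constant":
                constants[name] = value
            elif kind == "modification":
                targets = frozenset(row["targets"].split(","))
                modifications[name] = {"mono_delta": value, "targets": targets}
            else:  # pragma: no cover - guarded by the packaged file
                raise ValueError(f"unknown constant kind {kind!r}")
    return residues, constants, modifications


RESIDUE_MASSES, _CONSTANTS, _MOD_TABLE = _load_constants()
WATER_MASS = _CONSTANTS["water"]
PROTON_MASS = _CONSTANTS["proton"]
TAG_MASS = _MOD_TABLE["iTRAQ4plex"]["mono_delta"]


@dataclass(frozen=True)
class ModificationSpec:
    """A chemical modification and its effect on mass and ionizable groups.

    ``suppresses_site_group`` declares that the native ionizable group at the
    modified site (the alpha-amine for an N-terminal tag, the side-chain group
    for a residue-level modification) is abolished.  ``added_groups`` lists
    (group identifier, charge sign) pairs the modification introduces.
    """

    name: str
    targets: frozenset[str]
    mono_delta: float
    suppresses_site_group: bool = False
    added_groups: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not (self.mono_delta == self.mono_delta and abs(self.mono_delta) < 1e6):
            raise ValueError("mono_delta must be finite")


ITRAQ4PLEX = ModificationSpec(
    name="iTRAQ4plex",
    targets=_MOD_TABLE["iTRAQ4plex"]["targets"],
    mono_delta=TAG_MASS,
    suppresses_site_group=True,
    added_groups=(("tag_amine", +1),),
)

CARBAMIDOMETHYL = ModificationSpec(
    name="carbamidomethyl",
    targets=_MOD_TABLE["carbamidomethyl"]["targets"],
    mono_delta=_MOD_TABLE["carbamidomethyl"]["mono_delta"],
    suppresses_site_group=True,
)

MODIFICATIONS: Mapping[str, ModificationSpec] = {
    ITRAQ4PLEX.name: ITRAQ4PLEX,
    CARBAMIDOMETHYL.name: CARBAMIDOMETHYL,
}


class SequenceError(ValueError):
    """Raised for empty sequences or non-standard residue codes."""


def validate_sequence(text: str, *, normalise_case: bool = False) -> str:
    """Validate a raw string as a peptide sequence of standard residues.

    Lowercase input is rejected unless ``normalise_case`` is set, in which
    case it is upper-cased first.  Ambiguity codes (B, J, O, U, X, Z) are
    always rejected.
    """
    if normalise_case:
        text = text.upper()
    if not text:
        raise SequenceError("empty peptide sequence")
    bad = sorted(set(text) - STANDARD_RESIDUES)
    if bad:
        raise SequenceError(f"non-standard residue code(s) {bad!r} in {text!r}")
    return text


def count_itraq_sites(sequence: str) -> int:
    """Number of iTRAQ labelling sites: the N-terminus plus every lysine."""
    sequence = validate_sequence(sequence)
    return 1 + sequence.count("K")


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide sequence with attached modifications.

    ``modifications`` is a tuple of (modification name, site) pairs where the
    site is :data:`N_TERM` or a 1-based residue position.  At most one
    modification may occupy a site; modification targets are enforced
    (iTRAQ: N-terminus and K; carbamidomethyl: C).
    """

    sequence: str
    modifications: tuple[tuple[str, int | str], ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        seen: set[int | str] = set()
        for name, site in self.modifications:
            spec = MODIFICATIONS[name]
            if site in seen:
                raise ValueError(f"site {site!r} modified more than once")
            seen.add(site)
            if site == N_TERM:
                target = N_TERM
            else:
                if not (isinstance(site, int) and 1 <= site <= len(self.sequence)):
                    raise ValueError(f"site {site!r} outside sequence")
                target = self.sequence[site - 1]
            if target not in spec.targets:
                raise ValueError(f"{name} cannot modify site {site!r} ({target})")

    def modification_at(self, site: int | str) -> ModificationSpec | None:
        for name, s in self.modifications:
            if s == site:
                return MODIFICATIONS[name]
        return None

    @property
    def n_tags(self) -> int:
        return sum(1 for name, _ in self.modifications if name == ITRAQ4PLEX.name)


def native_species(sequence: str) -> PeptideSpecies:
    """Unlabelled species with carbamidomethyl fixed on every cysteine."""
    sequence = validate_sequence(sequence)
    mods = tuple(
        (CARBAMIDOMETHYL.name, i + 1)
        for i, res in enumerate(sequence)
        if res == "C"
    )
    return PeptideSpecies(sequence, mods)


def labelled_species(sequence: str) -> PeptideSpecies:
    """Fully iTRAQ-labelled species: tag on the N-terminus and every lysine,
    carbamidomethyl on every cysteine."""
    sequence = validate_sequence(sequence)
    mods: list[tuple[str, int | str]] = [(ITRAQ4PLEX.name, N_TERM)]
    for i, res in enumerate(sequence):
        if res == "K":
            mods.append((ITRAQ4PLEX.name, i + 1))
        elif res == "C":
            mods.append((CARBAMIDOMETHYL.name, i + 1))
    return PeptideSpecies(sequence, tuple(mods))


def neutral_monoisotopic_mass(species: PeptideSpecies) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    mass = WATER_MASS + sum(RESIDUE_MASSES[res] for res in species.sequence)
    mass += sum(MODIFICATIONS[name].mono_delta for name, _ in species.modifications)
    return mass


def protonated_labelled_mass(species: PeptideSpecies) -> float:
    """Singly protonated mass of a fully labelled species ("Mass L").

    Raises ``ValueError`` when any labelling site (N-terminus or lysine) is
    untagged, since the printed convention applies to complete labelling.
    """
    if species.modification_at(N_TERM) is not ITRAQ4PLEX:
        raise ValueError("species is not labelled at the N-terminus")
    for i, res in enumerate(species.sequence):
        if res == "K" and species.modification_at(i + 1) is not ITRAQ4PLEX:
            raise ValueError(f"lysine at position {i + 1} is not labelled")
    return neutral_monoisotopic_mass(species) + PROTON_MASS


def printed_pair_difference(sequence: str) -> float:
    """The "Difference" column convention: n_sites x tag mass + proton."""
    return count_itraq_sites(sequence) * TAG_MASS + PROTON_MASS


@dataclass(frozen=True)
class MassReport:
    """Theoretical masses for one sequence under the printed conventions."""

    neutral_mono: float
    protonated_labelled: float
    printed_difference: float


def mass_report(sequence: str) -> MassReport:
    return MassReport(
        neutral_mono=neutral_monoisotopic_mass(native_species(sequence)),
        protonated_labelled=protonated_labelled_mass(labelled_species(sequence)),
        printed_difference=printed_pair_difference(sequence),
    )


@dataclass(frozen=True)
class MassCheck:
    """Outcome of checking one fixture row against theoretical masses."""

    sequence: str
    passed: bool
    skipped: bool
    delta_nl: float | None = None
    delta_l: float | None = None


def mass_consistency_check(row: Mapping[str, object], tol: float = 0.03) -> MassCheck:
    """Compare a fixture row's printed masses with theory.

    Rows flagged ``$`` carry an unexplained extra modification and are
    skipped.  A row passes when both printed mass columns are within ``tol``
    Da of the theoretical values.
    """
    sequence = str(row["sequence"])
    flags = str(row.get("flags", "") or "")
    if "$" in flags:
        return MassCheck(sequence, passed=False, skipped=True)
    report = mass_report(sequence)
    delta_nl = float(row["mass_nl"]) - report.neutral_mono
    delta_l = float(row["mass_l"]) - report.protonated_labelled
    passed = abs(delta_nl) <= tol and abs(delta_l) <= tol
    return MassCheck(sequence, passed=passed, skipped=False,
                     delta_nl=delta_nl, delta_l=delta_l)
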