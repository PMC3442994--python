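"""Fixture tables, observation file IO, run configuration and the pipeline.

The three packaged fixture tables hold the observed peptide cohort: 70
basic-shift (A), 34 same-fraction (B) and 11 acidic-shift (C) peptide pairs,
each with printed unlabelled/labelled masses, fraction assignments and
verbatim ``$``/``*`` flags.  Observation files are plain TSV; fraction lists
are serialised as comma-joined integers without spaces ("3,4").  Output
masses are formatted to 2 decimals and pI values to 2 decimals so result
files diff reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .charge_model import PKaTable, default_pka_table, isoelectric_point, load_pka_table
from .chem_core import labelled_species, mass_consistency_check, native_species
from .oge_model import DEFAULT_LAYOUT, FractionSet, StripLayout, locate_pi, parse_fraction_set
from .shift_analysis import (
    ClassifiedPair,
    FractionObservation,
    LabelState,
    composition_profile,
    classify_pairs,
    pair_observations,
    pi_consistency_filter,
    retention_delta,
)

__all__ = [
    "FIXTURE_NAMES",
    "FIXTURE_ROW_COUNTS",
    "RunConfig",
    "load_fixture",
    "fixture_observations",
    "read_observations",
    "write_observations",
    "write_classification",
    "run_pipeline",
]

logger = logging.getLogger("ogeshift")

FIXTURE_FILES = {
    "basic_shift_A": "table_basic_shift_A.tsv",
    "same_fraction_B": "table_same_fraction_B.tsv",
    "acidic_shift_C": "table_acidic_shift_C.tsv",
}
FIXTURE_NAMES = tuple(FIXTURE_FILES)
FIXTURE_ROW_COUNTS = {"basic_shift_A": 70, "same_fraction_B": 34, "acidic_shift_C": 11}

OBSERVATION_COLUMNS = ["sequence", "label_state", "experiment_id", "fractions",
                       "retention_time_min", "confidence"]


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged fixture table and enforce its row-count invariant."""
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    path = resources.files("ogeshift.data") / FIXTURE_FILES[name]
    with path.open("r", encoding="utf-8") as handle:
        frame = pd.read_csv(handle, sep="\t", dtype={"frac_nl": str, "frac_l": str})
    if "flags" not in frame.columns:
        frame["flags"] = ""
    frame["flags"] = frame["flags"].fillna("")
    required = {"index", "sequence", "mass_nl", "mass_l", "difference",
                "frac_nl", "frac_l", "flags"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"fixture {name} missing columns {sorted(missing)}")
    if len(frame) != FIXTURE_ROW_COUNTS[name]:
        raise ValueError(
            f"fixture {name} has {len(frame)} rows, "
            f"expected {FIXTURE_ROW_COUNTS[name]}")
    return frame


def fixture_observations(
    name: str, layout: StripLayout = DEFAULT_LAYOUT
) -> list[FractionObservation]:
    """Replay a fixture table as one pseudo-experiment of paired observations."""
    rows = load_fixture(name)
    observations: list[FractionObservation] = []
    for _, row in rows.iterrows():
        for state, column in ((LabelState.UNLABELLED, "frac_nl"),
                              (LabelState.LABELLED, "frac_l")):
            observations.append(FractionObservation(
                sequence=row["sequence"],
                label_state=state,
                experiment_id=name,
                fractions=parse_fraction_set(row[column], layout),
                flags=row["flags"],
            ))
    return observations


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one pipeline run."""

    layout: StripLayout = DEFAULT_LAYOUT
    pka_table: PKaTable = field(default_factory=default_pka_table)
    min_replicates: int = 3
    shift_threshold: float = 0.5
    confidence_cutoff: float = 95.0
    pi_filter_tol_wells: int = 1
    seed: int = 0
    output_dir: Path | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Read a declarative TOML config; unset keys keep their defaults."""
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        layout_kwargs = raw.get("layout", {})
        layout = StripLayout(**layout_kwargs) if layout_kwargs else DEFAULT_LAYOUT
        table = default_pka_table()
        if "pka_table" in raw:
            table = load_pka_table(raw["pka_table"])
        if "pka_overrides" in raw:
            over = dict(raw["pka_overrides"])
            table = table.override(
                n_terminus=over.pop("n_terminus", None),
                c_terminus=over.pop("c_terminus", None),
                side_chain={k: v for k, v in over.items()
                            if k in table.side_chain},
                modification_groups={k: v for k, v in over.items()
                                     if k in table.modification_groups},
            )
        kwargs = {k: raw[k] for k in ("min_replicates", "shift_threshold",
                                      "confidence_cutoff", "pi_filter_tol_wells",
                                      "seed") if k in raw}
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        return cls(layout=layout, pka_table=table, **kwargs)

    def describe(self) -> dict:
        """JSON-serialisable echo of the full resolved configuration."""
        return {
            "layout": dataclasses.asdict(self.layout),
            "pka_table": {
                "side_chain": self.pka_table.side_chain,
                "n_terminus": self.pka_table.n_terminus,
                "c_terminus": self.pka_table.c_terminus,
                "modification_groups": self.pka_table.modification_groups,
            },
            "min_replicates": self.min_replicates,
            "shift_threshold": self.shift_threshold,
            "confidence_cutoff": self.confidence_cutoff,
            "pi_filter_tol_wells": self.pi_filter_tol_wells,
            "seed": self.seed,
        }


def read_observations(
    path: str | Path, layout: StripLayout = DEFAULT_LAYOUT
) -> list[FractionObservation]:
    """Read an observation TSV; malformed rows raise with their line number."""
    frame = pd.read_csv(path, sep="\t", dtype={"fractions": str})
    missing = {"sequence", "label_state", "experiment_id", "fractions"} - set(
        frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        logger.warning("%s: no observation rows", path)
        return []
    observations = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            rt = row.get("retention_time_min")
            conf = row.get("confidence")
            observations.append(FractionObservation(
                sequence=str(row["sequence"]),
                label_state=LabelState(str(row["label_state"])),
                experiment_id=str(row["experiment_id"]),
                fractions=parse_fraction_set(row["fractions"], layout),
                retention_time=None if pd.isna(rt) else float(rt),
                confidence=None if pd.isna(conf) else float(conf),
                flags=str(row.get("flags", "") or ""),
            ))
        except (ValueError, KeyError) as err:
            raise ValueError(f"{path}:{line}: {err}") from err
    return observations


def write_observations(path: str | Path,
                       observations: Iterable[FractionObservation]) -> None:
    rows = [{
        "sequence": o.sequence,
        "label_state": o.label_state.value,
        "experiment_id": o.experiment_id,
        "fractions": str(o.fractions),
        "retention_time_min": "" if o.retention_time is None
        else f"{o.retention_time:.2f}",
        "confidence": "" if o.confidence is None else f"{o.confidence:.1f}",
        "flags": o.flags,
    } for o in observations]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS + ["flags"]).to_csv(
        path, sep="\t", index=False)


def write_classification(path: str | Path,
                         classified: Sequence[ClassifiedPair]) -> None:
    rows = [{
        "sequence": c.sequence,
        "group": c.shift_class.value,
        "consensus_nl": str(c.consensus_unlabelled),
        "consensus_l": str(c.consensus_labelled),
        "midpoint_delta": f"{c.midpoint_delta:.2f}",
        "n_replicates": c.n_labelled_agreeing,
    } for c in classified]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _predicted_well(obs: FractionObservation, cfg: RunConfig) -> int:
    species = (labelled_species(obs.sequence)
               if obs.label_state is LabelState.LABELLED
               else native_species(obs.sequence))
    pi = isoelectric_point(species, cfg.pka_table)
    return locate_pi(cfg.layout, pi).well


def run_pipeline(cfg: RunConfig,
                 observations: Sequence[FractionObservation]) -> dict:
    """Pair -> reproducibility -> classify -> profile -> pI filter.

    Returns a result bundle (classified pairs, composition and retention
    tables, filter flags, summary) and, when ``cfg.output_dir`` is set,
    writes the output TSVs plus a machine-readable run summary.
    """
    usable = [o for o in observations
              if o.confidence is None or o.confidence >= cfg.confidence_cutoff]
    pairs, unmatched = pair_observations(usable)
    classified = classify_pairs(pairs, cfg.min_replicates, cfg.shift_threshold)

    by_class: dict[str, int] = {}
    for c in classified:
        by_class[c.shift_class.value] = by_class.get(c.shift_class.value, 0) + 1

    composition = composition_profile(
        (c.sequence, c.consensus_unlabelled) for c in classified)
    retention, rt_excluded = retention_delta(pairs)

    flagged = []
    for obs in usable:
        predicted = _predicted_well(obs, cfg)
        if not pi_consistency_filter(obs, predicted, cfg.pi_filter_tol_wells):
            flagged.append({"sequence": obs.sequence,
                            "label_state": obs.label_state.value,
                            "experiment_id": obs.experiment_id,
                            "observed": str(obs.fractions),
                            "predicted_well": predicted})

    summary = {
        "config": cfg.describe(),
        "n_observations": len(observations),
        "n_below_confidence": len(observations) - len(usable),
        "n_pairs": len(pairs),
        "n_unmatched": len(unmatched),
        "counts_per_group": by_class,
        "n_retention_excluded": rt_excluded,
        "n_pi_flagged": len(flagged),
    }
    bundle = {
        "pairs": pairs,
        "classified": classified,
        "composition": composition,
        "retention": retention,
        "pi_flagged": pd.DataFrame(flagged),
        "summary": summary,
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_classification(out / "classification.tsv", classified)
        composition.round(3).to_csv(out / "composition.tsv", sep="\t")
        retention.round(3).to_csv(out / "retention_delta.tsv", sep="\t")
        bundle["pi_flagged"].to_csv(out / "pi_flagged.tsv", sep="\t", index=False)
        with open(out / "run_summary.json", "w", encoding="utf-8") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
    return bundle
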