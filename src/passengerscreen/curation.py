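"""Classify literature evidence into disease-enriched/-depleted metabolite sets.

The input is a per-study evidence matrix with one record per
(metabolite, study, direction).  A metabolite is classified in a direction
when at least ``min_studies`` distinct studies report it in that direction;
counting is per direction, not a majority vote, so a metabolite with, say,
four enriched and one depleted record is classified enriched.  A metabolite
reaching the threshold in *both* directions is flagged conflicting and
excluded.

The package ships a transcription of the colorectal-cancer metabolomics
survey (29 classified metabolites: 26 enriched, 3 depleted) and the list of
13 CRC-enriched genera from the metagenomic meta-analysis; see
:func:`load_crc_evidence` and :func:`load_crc_genera`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import pandas as pd

from .gsmm import Environment

__all__ = [
    "MetaboliteEvidence",
    "MetaboliteDirectory",
    "classify_metabolites",
    "map_to_environment",
    "load_crc_evidence",
    "load_crc_genera",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaboliteEvidence:
    metabolite: str
    study: str
    direction: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if self.direction not in ("enriched", "depleted"):
            raise ValueError(f"direction must be enriched/depleted, got {self.direction!r}")


@dataclass
class MetaboliteDirectory:
    """Outcome of evidence classification.

    ``excluded`` holds metabolites with insufficient support; ``conflicting``
    (a subset of excluded cases, kept separately) holds metabolites whose
    evidence reached the threshold in both directions.  ``mapping``
    optionally translates curated names to model/environment identifiers.
    """

    enriched: Set[str]
    depleted: Set[str]
    excluded: Set[str]
    conflicting: Set[str] = field(default_factory=set)
    mapping: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.enriched & self.depleted:
            raise ValueError("a metabolite cannot be both enriched and depleted")

    @property
    def n_classified(self) -> int:
        return len(self.enriched) + len(self.depleted)


def _as_records(evidence) -> List[MetaboliteEvidence]:
    if isinstance(evidence, pd.DataFrame):
        return [
            MetaboliteEvidence(str(r.metabolite), str(r.study), str(r.direction))
            for r in evidence.itertuples(index=False)
        ]
    return list(evidence)


def classify_metabolites(
    evidence: Union[pd.DataFrame, Iterable[MetaboliteEvidence]],
    min_studies: int = 3,
) -> MetaboliteDirectory:
    """Assign each metabolite a direction supported by >= ``min_studies`` studies.

    Raises ``ValueError`` on dirty input: the same (metabolite, study) pair
    reported in both directions.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    records = _as_records(evidence)
    seen: Dict[tuple, str] = {}
    support: Dict[str, Dict[str, Set[str]]] = {}
    for rec in records:
        key = (rec.metabolite, rec.study)
        prev = seen.get(key)
        if prev is not None and prev != rec.direction:
            raise ValueError(
                f"study {rec.study!r} reports {rec.metabolite!r} in both directions"
            )
        seen[key] = rec.direction
        support.setdefault(rec.metabolite, {"enriched": set(), "depleted": set()})[
            rec.direction
        ].add(rec.study)

    enriched, depleted, excluded, conflicting = set(), set(), set(), set()
    for met, dirs in support.items():
        hit_e = len(dirs["enriched"]) >= min_studies
        hit_d = len(dirs["depleted"]) >= min_studies
        if hit_e and hit_d:
            conflicting.add(met)
            excluded.add(met)
            log.warning("metabolite %r reaches the threshold in both directions", met)
        elif hit_e:
            enriched.add(met)
        elif hit_d:
            depleted.add(met)
        else:
            excluded.add(met)
    return MetaboliteDirectory(enriched, depleted, excluded, conflicting)


def map_to_environment(
    directory: MetaboliteDirectory,
    env: Environment,
    which: str = "enriched",
) -> Set[str]:
    """Translate the classified (default: enriched) set into environment ids.

    Uses ``directory.mapping`` when provided, falling back to
    case-insensitive exact name matching.  Names without a counterpart in
    the environment are logged, never silently dropped.
    """
    wanted = getattr(directory, which)
    lower_env = {m.lower(): m for m in env.uptake_limits}
    out: Set[str] = set()
    for name in wanted:
        target = directory.mapping.get(name, name)
        if target in env.uptake_limits:
            out.add(target)
        elif target.lower() in lower_env:
            out.add(lower_env[target.lower()])
        else:
            log.warning("metabolite %r has no match in environment %r", name, env.name)
    return out


# ---------------------------------------------------------------------------
# bundled transcriptions
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("passengerscreen").joinpath("data", name)


def load_crc_evidence() -> pd.DataFrame:
    """The transcribed CRC metabolomics evidence matrix (147 records)."""
    with resources.as_file(_data_path("crc_metabolite_evidence.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_crc_genera() -> pd.DataFrame:
    """The transcribed table of CRC-enriched genera and their mOTUs."""
    with resources.as_file(_data_path("crc_enriched_genera.tsv")) as p:
        return pd.read_csv(p, sep="\t")
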