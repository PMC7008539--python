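"""Readers and writers for models, environments, evidence and abundances.

Two model sources are supported:

* SBML (level 3, fbc bounds), parsed with cobrapy and converted to the
  package's :class:`~passengerscreen.gsmm.MetabolicModel`;
* a tabular toy-model format, one reaction per line::

      # comment lines start with '#'
      @metabolites A A_e B          (optional; if present, referencing an
                                     undeclared metabolite is an error)
      EX_A<TAB>0<TAB>10<TAB>-1 A_e +1 A
      GROW<TAB>0<TAB>1000<TAB>-2 A<TAB>biomass

  Metabolite identifiers ending in ``_e`` are boundary (environment-facing)
  species and carry no mass-balance row.  A reaction touching exactly one
  boundary metabolite is an import reaction; it is normalised on load so
  that positive flux means uptake.  Exactly one reaction must carry the
  ``biomass`` token.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gsmm import Environment, MetabolicModel

__all__ = [
    "ModelParseError",
    "read_model",
    "read_tabular_model",
    "read_sbml_model",
    "write_tabular_model",
    "read_environment",
    "write_environment",
    "read_evidence",
    "write_evidence",
    "read_abundance_studies",
    "write_abundance_studies",
]

log = logging.getLogger(__name__)

BOUNDARY_SUFFIX = "_e"


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the location."""


# ---------------------------------------------------------------------------
# tabular toy-model format
# ---------------------------------------------------------------------------

_COEF_RE = re.compile(r"^[+-]?\d+(\.\d+)?([eE][+-]?\d+)?$")


def _parse_stoich(spec: str, lineno: int) -> Dict[str, float]:
    tokens = spec.split()
    if len(tokens) % 2 != 0:
        raise ModelParseError(
            f"line {lineno}: stoichiometry {spec!r} must alternate coefficient "
            "and metabolite"
        )
    out: Dict[str, float] = {}
    for k in range(0, len(tokens), 2):
        coef_tok, met = tokens[k], tokens[k + 1]
        if not _COEF_RE.match(coef_tok):
            raise ModelParseError(
                f"line {lineno}: expected a coefficient, got {coef_tok!r}"
            )
        out[met] = out.get(met, 0.0) + float(coef_tok)
    return out


def read_tabular_model(
    source: Union[str, Path],
    model_id: Optional[str] = None,
    genus: str = "",
    taxon_label: str = "",
) -> MetabolicModel:
    """Parse the one-reaction-per-line tabular format."""
    path = Path(source)
    lines = path.read_text(encoding="utf-8").splitlines()
    declared: Optional[set] = None
    reactions: List[Tuple[str, float, float, Dict[str, float], bool]] = []
    seen_ids: set = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@metabolites"):
            declared = set() if declared is None else declared
            declared.update(line.split()[1:])
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ModelParseError(
                f"line {lineno}: expected at least 4 tab-separated fields"
            )
        rxn_id = fields[0].strip()
        if rxn_id in seen_ids:
            raise ModelParseError(f"line {lineno}: duplicate reaction id {rxn_id!r}")
        seen_ids.add(rxn_id)
        try:
            lb, ub = float(fields[1]), float(fields[2])
        except ValueError as exc:
            raise ModelParseError(f"line {lineno}: bad bound: {exc}") from None
        stoich = _parse_stoich(fields[3].strip(), lineno)
        is_biomass = len(fields) > 4 and fields[4].strip().lower() == "biomass"
        if declared is not None:
            unknown = set(stoich) - declared
            if unknown:
                raise ModelParseError(
                    f"line {lineno}: undeclared metabolite(s) {sorted(unknown)}"
                )
        reactions.append((rxn_id, lb, ub, stoich, is_biomass))

    if not reactions:
        raise ModelParseError(f"{path}: no reactions found")
    biomass_ids = [r[0] for r in reactions if r[4]]
    if len(biomass_ids) != 1:
        raise ModelParseError(
            f"{path}: expected exactly one biomass reaction, found "
            f"{len(biomass_ids)} ({biomass_ids})"
        )

    all_mets: List[str] = []
    for _, _, _, stoich, _ in reactions:
        for met in stoich:
            if met not in all_mets:
                all_mets.append(met)
    internal = [m for m in all_mets if not m.endswith(BOUNDARY_SUFFIX)]
    boundary = [m for m in all_mets if m.endswith(BOUNDARY_SUFFIX)]
    row = {m: i for i, m in enumerate(internal)}

    n_r = len(reactions)
    S = sp.lil_matrix((len(internal), n_r))
    lbs = np.zeros(n_r)
    ubs = np.zeros(n_r)
    rxn_ids = []
    import_map: Dict[str, str] = {}
    for j, (rxn_id, lb, ub, stoich, _) in enumerate(reactions):
        ext = [m for m in stoich if m.endswith(BOUNDARY_SUFFIX)]
        flip = False
        if len(ext) == 1:
            # import reaction: normalise so positive flux consumes the
            # boundary species (uptake direction)
            if stoich[ext[0]] > 0:
                flip = True
            if ext[0] in import_map:
                raise ModelParseError(
                    f"{path}: boundary metabolite {ext[0]!r} has two import "
                    f"reactions ({import_map[ext[0]]!r}, {rxn_id!r})"
                )
            import_map[ext[0]] = rxn_id
        sign = -1.0 if flip else 1.0
        for met, coef in stoich.items():
            if met in row:
                S[row[met], j] = sign * coef
        lbs[j], ubs[j] = (-ub, -lb) if flip else (lb, ub)
        rxn_ids.append(rxn_id)

    return MetabolicModel(
        model_id=model_id or path.stem,
        metabolite_ids=internal,
        reaction_ids=rxn_ids,
        stoichiometry=S.tocsc(),
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_reaction=biomass_ids[0],
        import_map=import_map,
        boundary_metabolite_ids=boundary,
        genus=genus,
        taxon_label=taxon_label,
    )


def write_tabular_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialise a model to the tabular format (inverse of the reader)."""
    path = Path(path)
    rxn_to_boundary = {r: m for m, r in model.import_map.items()}
    S = model.stoichiometry.tocsc()
    lines = [f"# model {model.model_id}"]
    if model.genus:
        lines.append(f"# genus {model.genus}")
    for j, rxn in enumerate(model.reaction_ids):
        parts = []
        bnd = rxn_to_boundary.get(rxn)
        if bnd is not None and bnd.endswith(BOUNDARY_SUFFIX):
            parts.append(f"-1 {bnd}")
        col = S.getcol(j).tocoo()
        for i, coef in zip(col.row, col.data):
            parts.append(f"{'+' if coef > 0 else ''}{coef:g} {model.metabolite_ids[i]}")
        stoich = " ".join(parts)
        tag = "\tbiomass" if rxn == model.biomass_reaction else ""
        lines.append(
            f"{rxn}\t{model.lower_bounds[j]:g}\t{model.upper_bounds[j]:g}\t{stoich}{tag}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

DEFAULT_BIOMASS_PATTERN = r"biomass|bio1"


def read_sbml_model(
    source: Union[str, Path],
    biomass_pattern: str = DEFAULT_BIOMASS_PATTERN,
    genus: str = "",
    taxon_label: str = "",
) -> MetabolicModel:
    """Read an SBML model and convert it to a :class:`MetabolicModel`.

    The biomass reaction is taken from the model objective if it names
    exactly one reaction; otherwise reactions matching ``biomass_pattern``
    (case-insensitive) are considered, and anything other than exactly one
    candidate is an error.  Exchange reactions (single-metabolite columns)
    are normalised so positive flux means uptake.
    """
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(source))
    except Exception as exc:  # pragma: no cover - cobra error text varies
        raise ModelParseError(f"{source}: SBML parse failure: {exc}") from exc

    objective_rxns = [
        r.id for r in cm.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective_rxns) == 1:
        biomass = objective_rxns[0]
    else:
        pat = re.compile(biomass_pattern, re.IGNORECASE)
        candidates = [r.id for r in cm.reactions if pat.search(r.id)]
        if len(candidates) != 1:
            raise ModelParseError(
                f"{source}: cannot identify a unique biomass reaction "
                f"(objective names {len(objective_rxns)}, pattern matches "
                f"{len(candidates)})"
            )
        biomass = candidates[0]

    met_ids = [m.id for m in cm.metabolites]
    row = {m: i for i, m in enumerate(met_ids)}
    n_r = len(cm.reactions)
    S = sp.lil_matrix((len(met_ids), n_r))
    lbs = np.zeros(n_r)
    ubs = np.zeros(n_r)
    rxn_ids = []
    import_map: Dict[str, str] = {}
    for j, rxn in enumerate(cm.reactions):
        mets = rxn.metabolites
        flip = False
        if len(mets) == 1 and rxn.id != biomass:
            (met, coef), = mets.items()
            # cobra convention: exchange consumes the boundary species, so
            # positive flux is export; flip to our uptake-positive convention
            if coef < 0:
                flip = True
            import_map[met.id] = rxn.id
        sign = -1.0 if flip else 1.0
        for met, coef in mets.items():
            S[row[met.id], j] = sign * coef
        lbs[j], ubs[j] = (
            (-rxn.upper_bound, -rxn.lower_bound) if flip
            else (rxn.lower_bound, rxn.upper_bound)
        )
        rxn_ids.append(rxn.id)

    return MetabolicModel(
        model_id=cm.id or Path(str(source)).stem,
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        stoichiometry=S.tocsc(),
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_reaction=biomass,
        import_map=import_map,
        genus=genus,
        taxon_label=taxon_label,
    )


def read_model(source: Union[str, Path], **kwargs) -> MetabolicModel:
    """Dispatch on file extension: ``.xml``/``.sbml`` -> SBML, else tabular."""
    suffix = Path(source).suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return read_sbml_model(source, **kwargs)
    return read_tabular_model(source, **kwargs)


# ---------------------------------------------------------------------------
# environments, evidence, abundances
# ---------------------------------------------------------------------------

def read_environment(path: Union[str, Path], name: Optional[str] = None) -> Environment:
    """Environment TSV: columns ``metabolite``, ``uptake_limit``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"metabolite", "uptake_limit"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns metabolite, uptake_limit")
    limits = dict(zip(df["metabolite"].astype(str), df["uptake_limit"].astype(float)))
    return Environment(name=name or path.stem, uptake_limits=limits)


def write_environment(env: Environment, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {"metabolite": list(env.uptake_limits), "uptake_limit": list(env.uptake_limits.values())}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_evidence(path: Union[str, Path]) -> pd.DataFrame:
    """Evidence TSV: columns ``metabolite``, ``study``, ``direction``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"metabolite", "study", "direction"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df[["metabolite", "study", "direction"]]


def write_evidence(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_abundance_studies(
    study_paths: Dict[str, Union[str, Path]],
    metadata_path: Union[str, Path],
):
    """Load per-study abundance TSVs (rows species, columns samples) plus a
    sample-metadata TSV (sample, study, label, optional sub_block)."""
    from .enrichment import AbundanceStudySet

    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    if "sub_block" not in meta.columns:
        meta["sub_block"] = ""
    meta["sub_block"] = meta["sub_block"].fillna("")
    tables = {
        study: pd.read_csv(p, sep="\t", index_col=0) for study, p in study_paths.items()
    }
    return AbundanceStudySet(tables=tables, metadata=meta)


def write_abundance_studies(abund, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study, table in abund.tables.items():
        table.to_csv(out / f"abundance_{study}.tsv", sep="\t", float_format="%.8g")
    abund.metadata.to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
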