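"""Synthetic study inputs with known ground truth.

Everything the screening pipeline consumes can be generated here: a basal
environment with a flagged disease-metabolite subset, toy metabolic models
whose biomass depends on designated substrates, a genus-structured
community in which "disease" genera preferentially require disease
metabolites, a literature-style evidence matrix, and blocked case-control
abundance tables with planted effect sizes.

The toy models are deliberately simple import -> (convert) -> biomass
chains: the pipeline's contracts depend only on FBA behaviour under bound
changes, not on network realism.  All randomness flows from a single
master seed through named substreams, so each component can be regenerated
independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import AbundanceStudySet
from .gsmm import Environment, MetabolicModel

__all__ = [
    "CommunitySpec",
    "generate_environment",
    "generate_model",
    "generate_community",
    "generate_evidence_matrix",
    "generate_abundance_studies",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the scale of the real study where that scale matters
    to the statistics: 26 disease metabolites inside a basal environment of
    60, a community of 200 models in 20 genera of which a quarter are
    disease genera, and a dependence strength of 0.8 (the probability that
    a disease-genus model draws each required substrate from the disease
    set rather than from the whole environment).
    """

    n_models: int = 200
    n_genera: int = 20
    disease_genus_fraction: float = 0.25
    disease_metabolite_count: int = 26
    environment_size: int = 60
    dependence_strength: float = 0.8
    substitutability: float = 0.1
    min_required: int = 2
    max_required: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disease_genus_fraction", "dependence_strength", "substitutability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genera > self.n_models:
            raise ValueError("n_genera must not exceed n_models")
        if self.disease_metabolite_count > self.environment_size:
            raise ValueError("disease_metabolite_count exceeds environment_size")


def generate_environment(spec: CommunitySpec) -> Tuple[Environment, Set[str]]:
    """A basal environment with log-uniform uptake limits in [0.1, 100]
    mmol/gDW/h and a random disease-metabolite subset."""
    rng = _substream(spec.seed, "environment")
    mets = [f"met{i:03d}_e" for i in range(spec.environment_size)]
    limits = 10.0 ** rng.uniform(-1.0, 2.0, size=spec.environment_size)
    env = Environment(
        name=f"synthetic-{spec.seed}",
        uptake_limits=dict(zip(mets, limits.round(6))),
    )
    disease = set(rng.choice(mets, size=spec.disease_metabolite_count, replace=False))
    return env, disease


def generate_model(
    required: Dict[str, int],
    substitutable_pairs: Sequence[Tuple[str, str]] = (),
    genus: str = "",
    model_id: str = "toy",
    seed: int = 0,
) -> MetabolicModel:
    """Build an import -> convert -> biomass chain model.

    ``required`` maps environment metabolite ids (boundary species, by
    convention suffixed ``_e``) to their biomass stoichiometry (>= 1).
    Each pair in ``substitutable_pairs`` shares a pooled downstream
    metabolite, so either substrate alone satisfies that requirement; the
    pair's stoichiometry is taken from its first member (the second member
    need not appear in ``required``).
    """
    if not required:
        raise ValueError("required must be non-empty")

    def internal(met: str) -> str:
        # internal counterpart of a boundary species: met042_e -> met042
        return met[: -len("_e")] if met.endswith("_e") else f"{met}_c"
    paired: Dict[str, Tuple[str, str]] = {}
    for a, b in substitutable_pairs:
        paired[a] = (a, b)

    reactions: List[Tuple[str, float, float, str]] = []  # id, lb, ub, kind
    rows: List[str] = []
    entries: List[Tuple[int, int, float]] = []
    boundary: List[str] = []
    import_map: Dict[str, str] = {}

    def row_of(met: str) -> int:
        if met not in rows:
            rows.append(met)
        return rows.index(met)

    def add_import(met: str) -> str:
        ext = met if met.endswith("_e") else f"{met}_e"
        rxn = f"EX_{internal(met)}"
        if ext not in boundary:
            boundary.append(ext)
            j = len(reactions)
            reactions.append((rxn, 0.0, 1e4, "import"))
            entries.append((row_of(internal(met)), j, 1.0))
            import_map[met] = rxn
        return rxn

    biomass_terms: List[Tuple[str, float]] = []
    handled: Set[str] = set()
    for met, stoich in required.items():
        if met in handled:
            continue
        if met in paired:
            a, b = paired[met]
            pool = f"pool_{internal(a)}_{internal(b)}"
            for sub in (a, b):
                add_import(sub)
                j = len(reactions)
                reactions.append((f"CONV_{internal(sub)}", 0.0, 1e6, "conv"))
                entries.append((row_of(internal(sub)), j, -1.0))
                entries.append((row_of(pool), j, 1.0))
            biomass_terms.append((pool, float(stoich)))
            handled.update((a, b))
        else:
            add_import(met)
            biomass_terms.append((internal(met), float(stoich)))
            handled.add(met)

    j_bio = len(reactions)
    reactions.append(("BIOMASS", 0.0, 1e6, "biomass"))
    for met, stoich in biomass_terms:
        entries.append((row_of(met), j_bio, -stoich))

    S = sp.lil_matrix((len(rows), len(reactions)))
    for i, j, v in entries:
        S[i, j] = v
    return MetabolicModel(
        model_id=model_id,
        metabolite_ids=list(rows),
        reaction_ids=[r[0] for r in reactions],
        stoichiometry=S.tocsc(),
        lower_bounds=np.array([r[1] for r in reactions]),
        upper_bounds=np.array([r[2] for r in reactions]),
        biomass_reaction="BIOMASS",
        import_map=import_map,
        boundary_metabolite_ids=boundary,
        genus=genus,
        taxon_label=model_id,
    )


def generate_community(
    spec: CommunitySpec,
    env: Optional[Environment] = None,
    disease_set: Optional[Set[str]] = None,
) -> Tuple[List[MetabolicModel], pd.DataFrame]:
    """A genus-structured cohort of toy models with ground-truth labels.

    Genus sizes follow a Dirichlet-multinomial split; models in disease
    genera draw each required substrate from the disease set with
    probability ``dependence_strength`` and uniformly from the environment
    otherwise.  Returns the models and a ground-truth table with columns
    model_id, genus, disease_enriched.
    """
    if env is None or disease_set is None:
        env, disease_set = generate_environment(spec)
    rng = _substream(spec.seed, "community")
    env_mets = list(env.uptake_limits)
    disease_list = sorted(disease_set)

    weights = rng.dirichlet(np.full(spec.n_genera, 2.0))
    sizes = rng.multinomial(spec.n_models - spec.n_genera, weights) + 1
    n_disease_genera = max(1, round(spec.n_genera * spec.disease_genus_fraction))
    disease_genera = set(rng.choice(spec.n_genera, size=n_disease_genera, replace=False))

    models: List[MetabolicModel] = []
    truth_rows = []
    counter = 0
    for g in range(spec.n_genera):
        genus = f"genus{g:02d}"
        is_disease = g in disease_genera
        for _ in range(sizes[g]):
            model_id = f"m{counter:04d}"
            counter += 1
            n_req = int(rng.integers(spec.min_required, spec.max_required + 1))
            required: Dict[str, int] = {}
            while len(required) < n_req:
                if is_disease and rng.random() < spec.dependence_strength:
                    met = disease_list[rng.integers(len(disease_list))]
                else:
                    met = env_mets[rng.integers(len(env_mets))]
                if met not in required:
                    required[met] = int(rng.integers(1, 3))
            pairs: List[Tuple[str, str]] = []
            for met in list(required):
                if rng.random() < spec.substitutability:
                    alt = env_mets[rng.integers(len(env_mets))]
                    if alt not in required and all(alt not in p for p in pairs):
                        pairs.append((met, alt))
            models.append(
                generate_model(required, pairs, genus=genus, model_id=model_id)
            )
            truth_rows.append(
                {"model_id": model_id, "genus": genus, "disease_enriched": is_disease}
            )
    return models, pd.DataFrame(truth_rows)


def generate_evidence_matrix(
    n_metabolites: int = 30,
    n_studies: int = 10,
    p_report: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """A literature-style (metabolite, study, direction) matrix for testing
    the curation logic; each metabolite gets a latent direction and each
    study reports it with probability ``p_report``."""
    rng = _substream(seed, "evidence")
    rows = []
    for i in range(n_metabolites):
        direction = "enriched" if rng.random() < 0.7 else "depleted"
        for s in range(n_studies):
            if rng.random() < p_report:
                rows.append(
                    {"metabolite": f"met{i:03d}", "study": f"S{s:02d}", "direction": direction}
                )
    return pd.DataFrame(rows, columns=["metabolite", "study", "direction"])


def generate_abundance_studies(
    n_studies: int = 5,
    n_samples_per_study: int = 40,
    n_species: int = 50,
    planted_effects: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> AbundanceStudySet:
    """Blocked case-control relative-abundance tables with planted effects.

    Per study, species abundances are log-normal around species base
    means (log10 scale, sd 1) plus a study offset (sd 0.5, the block
    structure); a planted effect shifts the case-sample log10 mean of that
    species by the effect size.  Columns are renormalised to sum to 1.
    """
    if n_studies < 3:
        raise ValueError("need >= 3 studies to exercise the prevalence filter")
    planted_effects = planted_effects or {}
    rng = _substream(seed, "abundance")
    species = [f"sp{i:03d}" for i in range(n_species)]
    base = rng.normal(-3.0, 1.0, size=n_species)  # log10 relative abundance

    tables: Dict[str, pd.DataFrame] = {}
    meta_rows = []
    for s in range(n_studies):
        study = f"study{s}"
        offset = rng.normal(0.0, 0.5, size=n_species)
        cols = {}
        n_case = n_samples_per_study // 2
        for i in range(n_samples_per_study):
            sample = f"{study}_s{i:02d}"
            is_case = i < n_case
            mu = base + offset
            if is_case:
                mu = mu + np.array([planted_effects.get(sp, 0.0) for sp in species])
            vals = 10.0 ** rng.normal(mu, 1.0)
            vals = vals / vals.sum()
            cols[sample] = vals
            meta_rows.append(
                {
                    "sample": sample,
                    "study": study,
                    "label": "case" if is_case else "control",
                    "sub_block": "",
                }
            )
        tables[study] = pd.DataFrame(cols, index=species)
    return AbundanceStudySet(tables=tables, metadata=pd.DataFrame(meta_rows))
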