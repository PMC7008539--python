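"""End-to-end orchestration: score a model cohort, then test enrichment.

``run_scoring`` loads models, constrains them to the basal environment,
computes MI and SGA per model, calibrates the copula once on the cohort
and adds MR.  ``run_enrichment`` ranks the cohort by each score, computes
the running-sum statistic with both Monte-Carlo nulls and a Mann-Whitney
comparison of disease vs background models, BH-adjusted across the three
scores.  Every output carries the master seed and a config hash; two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from . import curation, enrichment, io, scores as scores_mod
from .gsmm import Environment, MetabolicModel, SUPPLEMENT_LIMIT

__all__ = ["RunConfig", "ConfigError", "run_scoring", "run_enrichment", "load_models"]

SCORE_COLUMNS = ("MI", "SGA", "MR")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    environment: str = ""
    model_source: str = ""
    evidence: str = ""
    labels: str = ""
    out_dir: str = "results"
    threshold: float = 0.3
    n_random: int = 1000
    supplement_limit: float = SUPPLEMENT_LIMIT
    n_perm: int = 10000
    n_genera: int = 0  # 0 = use the observed number of positive genera
    min_studies: int = 3
    seed: int = 0
    alternative: str = "two_sided"

    _FLOATS = ("threshold", "supplement_limit")
    _INTS = ("n_random", "n_perm", "n_genera", "min_studies", "seed")

    def validate(self, require_paths: bool = True) -> None:
        if self.threshold <= 0 or self.n_random <= 0 or self.n_perm <= 0:
            raise ConfigError("threshold, n_random and n_perm must be positive")
        if self.supplement_limit <= 0:
            raise ConfigError("supplement_limit must be positive")
        if self.alternative not in ("two_sided", "greater"):
            raise ConfigError(f"unknown alternative {self.alternative!r}")
        if require_paths:
            for name in ("environment", "model_source", "evidence", "labels"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise ConfigError(f"{name} path {p!r} does not exist")

    # -- flat key=value round-trip --------------------------------------
    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if not hasattr(cfg, key) or key.startswith("_"):
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            setattr(cfg, key, cls._coerce(key, value))
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def _coerce(cls, key: str, value: str):
        if key in cls._FLOATS:
            return float(value)
        if key in cls._INTS:
            return int(value)
        return value

    def to_file(self, path: Union[str, Path]) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_models(source: Union[str, Path]) -> List[MetabolicModel]:
    """Load every model under ``source`` (a directory of .tsv/.xml/.sbml
    files or a single file)."""
    src = Path(source)
    paths = (
        sorted(p for p in src.iterdir() if p.suffix.lower() in {".tsv", ".xml", ".sbml"})
        if src.is_dir()
        else [src]
    )
    models = [io.read_model(p) for p in paths]
    if not models:
        raise ConfigError(f"no loadable models under {source}")
    return models


def _attach_labels(models: List[MetabolicModel], labels_path: str) -> Dict[str, bool]:
    df = pd.read_csv(labels_path, sep="\t")
    need = {"model_id", "genus", "disease_enriched"}
    if not need <= set(df.columns):
        raise ConfigError(f"labels file must have columns {sorted(need)}")
    genus_of = dict(zip(df["model_id"].astype(str), df["genus"].astype(str)))
    for m in models:
        if m.model_id in genus_of and not m.genus:
            m.genus = genus_of[m.model_id]
    flags = df["disease_enriched"].astype(str).str.lower().isin(["true", "1", "yes"])
    return dict(zip(df["model_id"].astype(str), flags))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_scoring(
    config: RunConfig,
    models: Optional[List[MetabolicModel]] = None,
    env: Optional[Environment] = None,
    disease_set: Optional[Set[str]] = None,
    labels: Optional[Dict[str, bool]] = None,
    write: bool = True,
) -> pd.DataFrame:
    """Compute the full score table (MI, SGA, MR per model).

    Inputs may be passed in memory (as the analysis drivers do) or loaded
    from the paths in ``config``.  Models without basal growth are listed
    in a skip report, never silently dropped.
    """
    config.validate(require_paths=models is None)
    if models is None:
        models = load_models(config.model_source)
        env = io.read_environment(config.environment)
        evidence = io.read_evidence(config.evidence)
        directory = curation.classify_metabolites(evidence, min_studies=config.min_studies)
        disease_set = curation.map_to_environment(directory, env)
        labels = _attach_labels(models, config.labels)
    assert env is not None and disease_set is not None

    table, fit, skipped = scores_mod.score_cohort(
        models,
        env,
        disease_set,
        labels=labels,
        threshold=config.threshold,
        n_random=config.n_random,
        limit=config.supplement_limit,
        seed=config.seed,
    )

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(table, out / "scores.tsv")
        meta = {
            "seed": config.seed,
            "n_random": config.n_random,
            "threshold": config.threshold,
            "supplement_limit": config.supplement_limit,
            "environment": env.name,
            "n_disease_metabolites": len(disease_set),
            "theta": round(fit.theta, 10),
            "tau": round(fit.tau_observed, 10),
            "theta_clamped": fit.clamped,
            "n_models_scored": len(table),
            "n_models_skipped": len(skipped),
            "config_hash": config.config_hash(),
        }
        (out / "scores_meta.txt").write_text(
            "\n".join(f"{k} = {v}" for k, v in meta.items()) + "\n"
        )
        (out / "skipped_models.txt").write_text("\n".join(skipped) + ("\n" if skipped else ""))
    return table


def run_enrichment(
    score_table: pd.DataFrame,
    config: RunConfig,
    write: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, enrichment.EnrichmentResult]]:
    """Running-sum enrichment plus group tests for each score column.

    Returns the summary table (score, max_W, p_null1, p_null2, U, p,
    adj_p) and the per-score :class:`EnrichmentResult` objects.
    """
    config.validate(require_paths=False)
    labels = score_table["disease_enriched"].to_numpy(dtype=bool)
    if labels.all() or not labels.any():
        raise ConfigError("score table needs both positive and negative models")
    n_genera = config.n_genera or score_table.loc[
        score_table["disease_enriched"], "genus"
    ].nunique()

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(3 * len(SCORE_COLUMNS))
    rows = []
    results: Dict[str, enrichment.EnrichmentResult] = {}
    for i, score in enumerate(SCORE_COLUMNS):
        tie_ss, null1_ss, null2_ss = streams[3 * i : 3 * i + 3]
        ranked = enrichment.rank_models(score_table, score, seed=tie_ss)
        res = enrichment.cumulative_weight(ranked)
        res.p_null1, _ = enrichment.null_rank_shuffle(
            ranked, n_perm=config.n_perm, seed=null1_ss
        )
        res.p_null2, _ = enrichment.null_genus_resample(
            score_table, ranked, n_genera=n_genera, n_perm=config.n_perm, seed=null2_ss
        )
        res.n_perm = config.n_perm
        res.seed = config.seed
        results[score] = res

        pos = score_table.loc[score_table["disease_enriched"], score]
        neg = score_table.loc[~score_table["disease_enriched"], score]
        U, p = enrichment.mann_whitney_u(pos, neg, alternative=config.alternative)
        rows.append(
            {
                "score": score,
                "max_W": res.max_W,
                "p_null1": res.p_null1,
                "p_null2": res.p_null2,
                "U": U,
                "p": p,
            }
        )
        if write:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            ranked_df = pd.DataFrame(
                {
                    "position": np.arange(1, len(ranked.model_ids) + 1),
                    "model_id": ranked.model_ids,
                    "label": ranked.labels.astype(int),
                    "W": res.W,
                }
            )
            _write_tsv(ranked_df, out / f"enrichment_{score}.tsv")

    summary = pd.DataFrame(rows)
    summary["adj_p"] = enrichment.bh_adjust(summary["p"])
    if write:
        out = Path(config.out_dir)
        _write_tsv(summary, out / "enrichment_summary.tsv")
        (out / "enrichment_meta.txt").write_text(
            f"seed = {config.seed}\nn_perm = {config.n_perm}\n"
            f"n_genera_null2 = {n_genera}\nalternative = {config.alternative}\n"
            f"config_hash = {config.config_hash()}\n"
        )
    return summary, results
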