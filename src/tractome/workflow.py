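"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the stages in study order — ingest (or
simulate), lineage exclusion, rare-taxon filtering, rarefied alpha
diversity with group tests, clr/Aitchison ordination with PERMANOVA,
adjacent-site similarity, and the migration screen — writing every
stage's outputs as TSV plus a JSON manifest recording the version, the
thresholds actually applied, the per-stage seeds and the SHA-256 digest
of every file. Identical config + seed reproduces identical digests.

Alpha diversity is computed on the lineage-excluded but NOT rare-filtered
table; the rare-taxon filter applies to everything downstream of it.
All randomness flows from a single root seed, expanded deterministically
into one child seed per stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as _div
from . import migration as _mig
from . import ordination as _ord
from . import profiles_io as _io
from . import synthetic_data as _syn

logger = logging.getLogger("tractome")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input`` (reports_dir/metadata paths) and ``simulate``
    (a :class:`~tractome.synthetic_data.SyntheticCohortConfig` field
    mapping) must be present.
    """

    input: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    rank_level: str = "species"
    min_global_fraction: float = 1e-7
    min_sample_count: int = 5
    rarefaction_depth: int | str = _div.DEFAULT_RAREFACTION_DEPTH
    zero_strategy: str = "pseudocount"
    pseudocount: float = 1.0
    n_permutations: int = 999
    permanova_factors: list[str] = field(default_factory=lambda: ["condition", "site"])
    lfc_threshold: float = _mig.DEFAULT_LFC_THRESHOLD
    presence_threshold: float = _mig.DEFAULT_PRESENCE_THRESHOLD
    prevalence: float = _mig.DEFAULT_PREVALENCE
    min_evaluable: int = 4
    select_taxon: str | None = None
    select_threshold: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValueError(
                "config must contain exactly one of 'input' and 'simulate'"
            )
        if self.input is not None:
            for key in ("reports_dir", "metadata"):
                if key not in self.input:
                    raise ValueError(f"input block lacks {key!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _stage_seeds(root_seed: int, names: list[str]) -> dict[str, int]:
    """Expand the root seed into one deterministic child seed per stage."""
    state = np.random.SeedSequence(root_seed).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(config: PipelineConfig) -> _io.AbundanceTable:
    reports_dir = Path(config.input["reports_dir"])
    meta = _io.read_metadata(config.input["metadata"])
    lineages = None
    taxonomy = config.input.get("taxonomy")
    if taxonomy is None:
        candidate = reports_dir.parent / "taxonomy.tsv"
        if candidate.exists():
            taxonomy = str(candidate)
    if taxonomy:
        lineages = _io.read_lineage_table(taxonomy)
    profiles = []
    for m in meta:
        matches = sorted(reports_dir.glob(f"{m.sample_id}.*")) or sorted(
            reports_dir.glob(f"{m.sample_id}")
        )
        if not matches:
            raise FileNotFoundError(
                f"no report file for sample {m.sample_id} in {reports_dir}"
            )
        prof = _io.read_taxonomic_report(matches[0], config.rank_level)
        if lineages:
            prof = _io.attach_lineages(prof, lineages)
        profiles.append(prof)
    return _io.merge_profiles(profiles, meta, rank_level=config.rank_level)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed, ["simulate", "rarefaction", "permanova"]
    )
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {},
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "file": path.name,
            "sha256": _sha256(path),
        }

    def write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        record(name, path)

    # --- ingest ----------------------------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = _syn.SyntheticCohortConfig(
                **{**config.simulate, "seed": seeds["simulate"]}
            )
            table_raw, truth = _syn.generate_cohort(sim_cfg)
            sim_dir = out / "simulated"
            _syn.write_cohort(table_raw, sim_dir, truth)
            # Re-read through the parsers so the file path is exercised.
            config_in = PipelineConfig(
                input={
                    "reports_dir": str(sim_dir / "reports"),
                    "metadata": str(sim_dir / "metadata.csv"),
                    "taxonomy": str(sim_dir / "taxonomy.tsv"),
                },
                rank_level=config.rank_level,
            )
            table = _load_input(config_in)
            for name in ("metadata.csv", "taxonomy.tsv", "planted_truth.tsv"):
                record(f"simulated/{name}", sim_dir / name)
        else:
            table = _load_input(config)
    except Exception as exc:
        raise PipelineError(f"stage ingest: {exc}") from exc

    try:
        _io.write_table(table, out / "merged_counts.tsv", out / "metadata.tsv")
        record("merged_counts.tsv", out / "merged_counts.tsv")
        record("metadata.tsv", out / "metadata.tsv")
    except Exception as exc:
        raise PipelineError(f"stage write-merged: {exc}") from exc

    # --- filtering -------------------------------------------------------
    try:
        excluded = _io.exclude_lineages(table)
        filtered = _io.filter_rare_taxa(
            excluded, config.min_global_fraction, config.min_sample_count
        )
        manifest["parameters"]["filter"] = {
            "min_global_fraction": config.min_global_fraction,
            "min_sample_count": config.min_sample_count,
            "n_taxa_input": table.n_taxa,
            "n_taxa_after_exclusion": excluded.n_taxa,
            "n_taxa_after_rare_filter": filtered.n_taxa,
        }
        _io.write_table(
            filtered, out / "filtered_counts.tsv", out / "metadata.tsv"
        )
        record("filtered_counts.tsv", out / "filtered_counts.tsv")
    except Exception as exc:
        raise PipelineError(f"stage filter: {exc}") from exc

    # --- alpha diversity (on excluded, unfiltered counts) ---------------
    try:
        rarefied = _div.rarefy(
            excluded, depth=config.rarefaction_depth, seed=seeds["rarefaction"]
        )
        manifest["parameters"]["rarefaction"] = {
            "depth": config.rarefaction_depth,
            "seed": seeds["rarefaction"],
            "n_samples_retained": rarefied.n_samples,
        }
        alpha = _div.alpha_table(rarefied)
        write_df(alpha, "alpha_diversity.tsv")
        tests = []
        for factor in ("condition", "site"):
            levels = {getattr(s, factor) for s in rarefied.samples}
            if len(levels) >= 2:
                tests.append(_div.compare_alpha_by(alpha, rarefied, by=factor))
        if tests:
            write_df(pd.concat(tests, ignore_index=True), "alpha_tests.tsv")
    except Exception as exc:
        raise PipelineError(f"stage diversity: {exc}") from exc

    # --- ordination ------------------------------------------------------
    try:
        clr = _ord.clr_transform(
            filtered, zero_strategy=config.zero_strategy,
            pseudocount=config.pseudocount,
        )
        pca = _ord.aitchison_pca(clr)
        scores = pd.DataFrame(
            pca.scores[:, : min(10, pca.scores.shape[1])],
            columns=[f"PC{i + 1}" for i in range(min(10, pca.scores.shape[1]))],
        )
        scores.insert(0, "sample_id", clr.sample_ids)
        write_df(scores, "pca_scores.tsv")
        write_df(
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(len(pca.explained))],
                    "explained_fraction": pca.explained,
                }
            ),
            "explained_variance.tsv",
        )
        dist = _ord.aitchison_distance_matrix(clr)
        factors = {
            f: [getattr(s, f) for s in filtered.samples]
            for f in config.permanova_factors
            if len({getattr(s, f) for s in filtered.samples}) >= 2
        }
        if factors:
            results = _ord.permanova(
                dist, factors, n_perm=config.n_permutations,
                seed=seeds["permanova"],
            )
            write_df(
                pd.DataFrame(
                    [
                        {
                            "factor": r.factor,
                            "ss": r.ss,
                            "df": r.df,
                            "pseudo_F": r.pseudo_F,
                            "r_squared": r.r_squared,
                            "p_value": r.p_value,
                            "n_permutations": r.n_permutations,
                            "seed": r.seed,
                        }
                        for r in results
                    ]
                ),
                "permanova.tsv",
            )
        manifest["parameters"]["ordination"] = {
            "zero_strategy": config.zero_strategy,
            "pseudocount": config.pseudocount,
            "n_permutations": config.n_permutations,
            "factors": list(factors),
            "seed": seeds["permanova"],
        }
        sims = _ord.adjacent_similarity(filtered)
        write_df(
            pd.DataFrame(
                [
                    {
                        "subject_id": s.subject_id,
                        "pair": s.pair,
                        "bray_curtis": s.bray_curtis,
                        "spearman_rho": s.spearman_rho,
                    }
                    for s in sims
                ]
            ),
            "adjacent_similarity.tsv",
        )
    except Exception as exc:
        raise PipelineError(f"stage ordination: {exc}") from exc

    # --- migration -------------------------------------------------------
    try:
        findings = _mig.screen_all_pairs(
            filtered,
            lfc_threshold=config.lfc_threshold,
            presence_threshold=config.presence_threshold,
            prevalence=config.prevalence,
            min_evaluable=config.min_evaluable,
        )
        write_df(findings, "migration_findings.tsv")
        write_df(_mig.site_overlap_table(filtered), "venn_regions.tsv")
        manifest["parameters"]["migration"] = {
            "lfc_threshold": config.lfc_threshold,
            "presence_threshold": config.presence_threshold,
            "prevalence": config.prevalence,
            "min_evaluable": config.min_evaluable,
        }
        if config.select_taxon:
            subjects = _mig.select_subjects_by_taxon(
                filtered, config.select_taxon, config.select_threshold
            )
            path = out / "selected_subjects.txt"
            path.write_text("\n".join(subjects) + "\n")
            record("selected_subjects.txt", path)
    except Exception as exc:
        raise PipelineError(f"stage migration: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
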