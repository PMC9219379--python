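"""Synthetic paired multi-site cohort generator with planted ground truth.

The generator emulates a low-biomass paired-design metagenomic study of
the female reproductive tract: two condition groups (benign B, malignant
M), up to four swab sites per subject (CCT, EMT, FTT, OCT; occasional
sites missing), per-sample read depths drawn log-normally and clipped at
a floor, a shared contaminant background present in every sample (the
"kitome" of low-biomass sequencing), taxa planted with monotone abundance
gradients along the tract, and taxa planted with a condition-specific
enrichment. Counts are Dirichlet-multinomial so site profiles are
overdispersed relative to plain multinomial sampling.

Every planted effect is returned as :class:`PlantedTruth`, so recovery of
the migration screen and of the ordination tests can be measured against
a known answer. The cohort is fully determined by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles_io import (
    SITES,
    AbundanceTable,
    SampleMetadata,
    TaxonRecord,
    write_bracken_report,
    write_lineage_table,
    write_metadata,
)

#: Site order along the tract; "increased along the tract" means
#: increasing with this index (lower tract -> ovary).
SITE_INDEX = {site: i for i, site in enumerate(SITES)}

# Genera recurrently reported as reagent/laboratory contaminants in
# low-biomass studies; used to name the contaminant background.
_CONTAMINANT_GENERA = (
    "Ralstonia",
    "Brevundimonas",
    "Pseudomonas",
    "Cutibacterium",
    "Acinetobacter",
    "Burkholderia",
    "Methylobacterium",
    "Sphingomonas",
    "Bradyrhizobium",
    "Delftia",
)

_BACTERIAL_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Tenericutes",
)


@dataclass
class SyntheticCohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the cohort scale this pipeline targets: 35 malignant
    and 30 benign subjects, read depths around 20k clipped at the 6172
    rarefaction floor, a 30% contaminant background, ten gradient taxa at
    one log2 unit per adjacent-site step and ten condition-signature taxa
    at two log2 units, with 10% of sites missing.
    """

    n_subjects_benign: int = 30
    n_subjects_malignant: int = 35
    n_taxa: int = 300
    depth_log_mean: float = math.log(20000)
    depth_log_sd: float = 0.5
    min_depth: int = 6172
    n_gradient_taxa: int = 10
    gradient_log2_step: float = 1.0
    n_signature_taxa: int = 10
    signature_log2_effect: float = 2.0
    contaminant_fraction: float = 0.3
    n_contaminant_taxa: int = 30
    dropout_site_prob: float = 0.1
    dispersion: float = 2000.0
    subject_dispersion: float = 200.0
    n_excluded_taxa: int = 2
    rank_level: str = "species"
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_gradient_taxa + self.n_signature_taxa + self.n_contaminant_taxa
        )
        if planted > self.n_taxa:
            raise ValueError(
                f"planted taxa ({planted}) exceed n_taxa ({self.n_taxa})"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("contaminant_fraction", "dropout_site_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects_benign < 0 or self.n_subjects_malignant < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_subjects_benign + self.n_subjects_malignant == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.dispersion <= 0 or self.subject_dispersion <= 0:
            raise ValueError("dispersion parameters must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of planted effects: disjoint taxon lists."""

    gradient_taxa: list[tuple[str, str]]  # (taxon, increased|decreased)
    signature_taxa: list[tuple[str, str]]  # (taxon, enriched condition B|M)
    contaminant_taxa: list[str]
    excluded_taxa: list[str] = field(default_factory=list)

    def validate(self) -> None:
        g = {t for t, _ in self.gradient_taxa}
        s = {t for t, _ in self.signature_taxa}
        c = set(self.contaminant_taxa)
        if (g & s) or (g & c) or (s & c):
            raise ValueError("planted taxon roles must be disjoint")


def _make_taxa(config: SyntheticCohortConfig, rng: np.random.Generator):
    """Invent a taxon list: bacterial species with simple genus/phylum
    lineages, contaminants named after known kitome genera, plus a couple
    of taxa that the lineage-exclusion step should remove."""
    taxa: list[TaxonRecord] = []
    for i in range(config.n_taxa):
        genus = f"Genus{i // 5:03d}"
        phylum = _BACTERIAL_PHYLA[(i // 5) % len(_BACTERIAL_PHYLA)]
        taxa.append(
            TaxonRecord(
                taxon_id=10000 + i,
                name=f"{genus} species{i:03d}",
                rank="species",
                lineage=(
                    ("genus", genus),
                    ("phylum", phylum),
                    ("domain", "Bacteria"),
                ),
            )
        )
    excluded: list[TaxonRecord] = []
    if config.n_excluded_taxa >= 1:
        excluded.append(
            TaxonRecord(
                taxon_id=90001,
                name="Chloroplast organellar sp.",
                rank="species",
                lineage=(
                    ("genus", "Chloroplast"),
                    ("phylum", "Cyanobacteria"),
                    ("domain", "Bacteria"),
                ),
            )
        )
    if config.n_excluded_taxa >= 2:
        excluded.append(
            TaxonRecord(
                taxon_id=90002,
                name="Trypanosoma synthetica",
                rank="species",
                lineage=(
                    ("genus", "Trypanosoma"),
                    ("kingdom", "Protista"),
                    ("domain", "Eukaryota"),
                ),
            )
        )
    return taxa, excluded[: config.n_excluded_taxa]


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[AbundanceTable, PlantedTruth]:
    """Draw one cohort.

    Per subject, a base composition is drawn once (the subject effect);
    each site's composition multiplies the planted gradient taxa by
    2^(direction x step x site index) and, in the enriched condition, the
    signature taxa by 2^effect, then renormalises. Contaminant taxa keep a
    shared cross-sample expectation (no subject effect). Counts are drawn
    Dirichlet-multinomial at a log-normal depth clipped at ``min_depth``;
    whole sites drop out independently. Identical seeds give bitwise
    identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxa, excluded_taxa = _make_taxa(config, rng)
    n = config.n_taxa

    # Rank-abundance base profile (lognormal), then carve out roles.
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    order = np.argsort(base)[::-1]  # descending abundance

    contaminant_idx = order[: config.n_contaminant_taxa]
    # Plant gradients/signatures among moderately abundant community taxa
    # (ranks just below the contaminant block) so planted effects live in
    # the abundance regime the screen is meant to resolve.
    pool = order[
        config.n_contaminant_taxa : config.n_contaminant_taxa
        + max(4 * (config.n_gradient_taxa + config.n_signature_taxa), 40)
    ]
    pool = pool[: len(pool)]
    chosen = rng.choice(
        pool,
        size=min(len(pool), config.n_gradient_taxa + config.n_signature_taxa),
        replace=False,
    )
    gradient_idx = chosen[: config.n_gradient_taxa]
    signature_idx = chosen[config.n_gradient_taxa :]

    grad_dirs = rng.choice([1.0, -1.0], size=len(gradient_idx))
    sig_groups = rng.choice(["B", "M"], size=len(signature_idx))

    is_contaminant = np.zeros(n, dtype=bool)
    is_contaminant[contaminant_idx] = True

    community = base.copy()
    community[is_contaminant] = 0.0
    community /= community.sum()
    contaminant_profile = np.zeros(n)
    contaminant_profile[contaminant_idx] = base[contaminant_idx]
    contaminant_profile /= contaminant_profile.sum()

    # Rename contaminants after kitome genera for realism.
    for k, j in enumerate(sorted(contaminant_idx.tolist())):
        genus = _CONTAMINANT_GENERA[k % len(_CONTAMINANT_GENERA)]
        taxa[j] = TaxonRecord(
            taxon_id=taxa[j].taxon_id,
            name=f"{genus} contaminant sp. C{k:02d}",
            rank="species",
            lineage=(
                ("genus", genus),
                ("phylum", "Proteobacteria"),
                ("domain", "Bacteria"),
            ),
        )

    truth = PlantedTruth(
        gradient_taxa=[
            (taxa[j].name, "increased" if d > 0 else "decreased")
            for j, d in zip(gradient_idx, grad_dirs)
        ],
        signature_taxa=[
            (taxa[j].name, g) for j, g in zip(signature_idx, sig_groups)
        ],
        contaminant_taxa=[taxa[j].name for j in sorted(contaminant_idx.tolist())],
        excluded_taxa=[t.name for t in excluded_taxa],
    )
    truth.validate()

    all_taxa = taxa + excluded_taxa
    n_all = len(all_taxa)
    # Excluded taxa get a small fixed share of every sample.
    excluded_share = 0.005

    subjects = [
        (f"M{i + 1:03d}", "M") for i in range(config.n_subjects_malignant)
    ] + [(f"B{i + 1:03d}", "B") for i in range(config.n_subjects_benign)]

    samples: list[SampleMetadata] = []
    count_rows: list[np.ndarray] = []
    cf = config.contaminant_fraction

    for subject_id, condition in subjects:
        # Subject effect on the community (not on contaminants).
        alpha = config.subject_dispersion * community
        subj_comm = np.zeros(n)
        nz = community > 0
        subj_comm[nz] = rng.dirichlet(alpha[nz])

        if condition == "M":
            ligation = rng.choice(["yes", "no", "unknown"], p=[0.37, 0.31, 0.32])
            platinum = rng.choice(
                ["sensitive", "resistant", "unknown"], p=[0.54, 0.23, 0.23]
            )
        else:
            ligation = rng.choice(["yes", "no", "unknown"], p=[0.23, 0.57, 0.20])
            platinum = "unknown"

        dropped = rng.random(len(SITES)) < config.dropout_site_prob
        for site in SITES:
            s_idx = SITE_INDEX[site]
            take = not dropped[s_idx]
            # Draw depth and site composition regardless of dropout so the
            # retained samples' randomness does not depend on which other
            # sites dropped.
            depth = int(
                max(
                    config.min_depth,
                    round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)),
                )
            )
            comp = subj_comm.copy()
            for j, d in zip(gradient_idx, grad_dirs):
                comp[j] *= 2.0 ** (d * config.gradient_log2_step * s_idx)
            for j, g in zip(signature_idx, sig_groups):
                if condition == g:
                    comp[j] *= 2.0 ** config.signature_log2_effect
            comp /= comp.sum()
            mixture = (1.0 - cf) * comp + cf * contaminant_profile

            full = np.zeros(n_all)
            full[:n] = mixture * (1.0 - excluded_share * len(excluded_taxa))
            for e in range(len(excluded_taxa)):
                full[n + e] = excluded_share
            pos = full > 0
            p = np.zeros(n_all)
            p[pos] = rng.dirichlet(config.dispersion * full[pos])
            counts = rng.multinomial(depth, p)
            if not take:
                continue
            samples.append(
                SampleMetadata(
                    sample_id=f"{subject_id}_{site}",
                    subject_id=subject_id,
                    site=site,
                    condition=condition,
                    ligation=str(ligation),
                    platinum=str(platinum),
                )
            )
            count_rows.append(counts)

    table = AbundanceTable(
        counts=np.vstack(count_rows).astype(np.int64),
        taxa=all_taxa,
        samples=samples,
        rank_level=config.rank_level,
    )
    return table, truth


def truth_report(truth: PlantedTruth) -> pd.DataFrame:
    """Planted effects as a tidy table (one row per planted taxon)."""
    rows = []
    for taxon, direction in truth.gradient_taxa:
        rows.append({"taxon": taxon, "role": "gradient", "direction": direction})
    for taxon, group in truth.signature_taxa:
        rows.append({"taxon": taxon, "role": "signature", "direction": group})
    for taxon in truth.contaminant_taxa:
        rows.append({"taxon": taxon, "role": "contaminant", "direction": ""})
    for taxon in truth.excluded_taxa:
        rows.append({"taxon": taxon, "role": "excluded", "direction": ""})
    return pd.DataFrame(rows, columns=["taxon", "role", "direction"])


def write_cohort(
    table: AbundanceTable, out_dir: str | Path, truth: PlantedTruth | None = None
) -> Path:
    """Emit the cohort as per-sample Bracken-dialect reports plus a
    metadata CSV and a taxonomy sidecar, so the full pipeline can be
    exercised end to end from files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = out / "reports"
    reports.mkdir(exist_ok=True)
    for i, sample in enumerate(table.samples):
        profile = {
            rec: int(c)
            for rec, c in zip(table.taxa, table.counts[i])
            if c > 0
        }
        write_bracken_report(profile, reports / f"{sample.sample_id}.bracken.tsv")
    write_metadata(table.samples, out / "metadata.csv")
    write_lineage_table(table.taxa, out / "taxonomy.tsv")
    if truth is not None:
        truth_report(truth).to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    return out
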