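"""Parse per-sample reports and apply the two taxon filters.

Writes a simulated cohort to disk as Bracken-dialect reports, reads the
reports back through the parser, merges them into one cohort table, then
(1) excludes mitochondrial/chloroplast lineages and non-fungal
eukaryotes and (2) removes rare taxa (< 1e-7 of all reads, or detected
in fewer than 5 samples).
"""

import tempfile
from pathlib import Path

from tractome import (
    SyntheticCohortConfig,
    exclude_lineages,
    filter_rare_taxa,
    generate_cohort,
    merge_profiles,
    read_taxonomic_report,
    write_cohort,
)
from tractome.profiles_io import attach_lineages, read_lineage_table, read_metadata

config = SyntheticCohortConfig(
    n_subjects_benign=8, n_subjects_malignant=8, n_taxa=100,
    n_contaminant_taxa=12, n_gradient_taxa=4, n_signature_taxa=4, seed=7,
)
table, truth = generate_cohort(config)

with tempfile.TemporaryDirectory() as tmp:
    out = write_cohort(table, tmp, truth)
    meta = read_metadata(out / "metadata.csv")
    lineages = read_lineage_table(out / "taxonomy.tsv")
    profiles = [
        attach_lineages(
            read_taxonomic_report(out / "reports" / f"{m.sample_id}.bracken.tsv"),
            lineages,
        )
        for m in meta
    ]
    merged = merge_profiles(profiles, meta)

print(f"merged: {merged.n_samples} samples x {merged.n_taxa} taxa, "
      f"{merged.counts.sum()} reads")
excluded = exclude_lineages(merged)
print(f"after lineage exclusion: {excluded.n_taxa} taxa "
      f"(removed {merged.n_taxa - excluded.n_taxa}: organellar reads and "
      "non-fungal eukaryotes)")
filtered = filter_rare_taxa(excluded)
print(f"after rare-taxon filter: {filtered.n_taxa} taxa "
      f"(removed {excluded.n_taxa - filtered.n_taxa} rare/sparse taxa)")
# The filtered table is the input for ordination and the migration screen;
# alpha diversity intentionally uses the unfiltered (excluded-only) counts.
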