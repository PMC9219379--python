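import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tractome.profiles_io import (
    AbundanceTable,
    SampleMetadata,
    TaxonRecord,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_BACT = (("genus", "GenusX"), ("phylum", "Proteobacteria"), ("domain", "Bacteria"))


def bacterial_taxon(name: str, taxid: int = 1) -> TaxonRecord:
    genus = name.split()[0]
    return TaxonRecord(
        taxon_id=taxid,
        name=name,
        rank="species",
        lineage=(
            ("genus", genus),
            ("phylum", "Proteobacteria"),
            ("domain", "Bacteria"),
        ),
    )


def make_table(
    counts,
    taxon_names=None,
    sites=None,
    subjects=None,
    conditions=None,
    taxa=None,
) -> AbundanceTable:
    """Hand-built AbundanceTable with sensible metadata defaults."""
    counts = np.asarray(counts)
    n_samples, n_taxa = counts.shape
    if taxa is None:
        if taxon_names is None:
            taxon_names = [f"Taxon sp{j:02d}" for j in range(n_taxa)]
        taxa = [bacterial_taxon(name, 100 + j) for j, name in enumerate(taxon_names)]
    if sites is None:
        sites = ["CCT"] * n_samples
    if subjects is None:
        subjects = [f"S{i:02d}" for i in range(n_samples)]
    if conditions is None:
        conditions = ["B"] * n_samples
    samples = [
        SampleMetadata(
            sample_id=f"{subj}_{site}_{i}",
            subject_id=subj,
            site=site,
            condition=cond,
        )
        for i, (subj, site, cond) in enumerate(zip(subjects, sites, conditions))
    ]
    return AbundanceTable(counts=counts, taxa=taxa, samples=samples)


def paired_table(profiles_by_subject_site, taxon_names, conditions=None):
    """Build a table from {subject: {site: count-vector}}."""
    rows, samples = [], []
    conditions = conditions or {}
    for subject, site_map in profiles_by_subject_site.items():
        for site, vec in site_map.items():
            rows.append(vec)
            samples.append(
                SampleMetadata(
                    sample_id=f"{subject}_{site}",
                    subject_id=subject,
                    site=site,
                    condition=conditions.get(subject, "B"),
                )
            )
    taxa = [bacterial_taxon(n, 100 + j) for j, n in enumerate(taxon_names)]
    return AbundanceTable(counts=np.asarray(rows), taxa=taxa, samples=samples)


@pytest.fixture
def kraken_report(tmp_path):
    """A tiny Kraken2-dialect report: two species under one genus, plus an
    unclassified line and a second genus with no species rows."""
    text = (
        "  0.50\t50\t50\tU\t0\tunclassified\n"
        " 99.50\t9950\t0\tR\t1\troot\n"
        " 99.50\t9950\t10\tD\t2\t  Bacteria\n"
        " 80.00\t8000\t0\tP\t1224\t    Proteobacteria\n"
        " 80.00\t8000\t0\tG\t561\t      Escherichia\n"
        " 60.00\t6000\t6000\tS\t562\t        Escherichia coli\n"
        " 20.00\t2000\t2000\tS\t564\t        Escherichia fergusonii\n"
        " 19.50\t1940\t1940\tG\t570\t      Klebsiella\n"
    )
    path = tmp_path / "sample.kreport"
    path.write_text(text)
    return path


@pytest.fixture
def bracken_report(tmp_path):
    text = (
        "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\t"
        "added_reads\tnew_est_reads\tfraction_total_reads\n"
        "Escherichia coli\t562\tS\t6000\t100\t6100\t0.61\n"
        "Klebsiella pneumoniae\t573\tS\t3900\t0\t3900\t0.39\n"
    )
    path = tmp_path / "sample.bracken"
    path.write_text(text)
    return path
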