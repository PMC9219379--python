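"""Taxonomic-profile ingestion and cohort table assembly.

This module parses per-sample taxonomic profiling reports (Kraken2- and
Bracken-dialect tab-separated files), merges them into a single cohort
abundance table, and applies the two filters used before downstream
analysis: removal of mitochondrial/chloroplast reads and non-fungal
eukaryotes, and removal of rare taxa (below a global relative-abundance
floor or seen in too few samples).

The :class:`AbundanceTable` built here — a samples x taxa count matrix with
per-taxon lineage and per-sample metadata — is the single currency passed
between every downstream stage (diversity, ordination, migration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tractome")

#: Canonical taxonomic ranks, most inclusive first.
RANKS = (
    "root",
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

#: Swab sites along the reproductive tract, lower to upper.
SITES = ("CCT", "EMT", "FTT", "OCT")

CONDITIONS = ("B", "M")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# Kraken2 report rank codes -> canonical rank names.
_KRAKEN_RANK_CODES = {
    "R": "root",
    "D": "domain",
    "K": "kingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
    "S1": "strain",
}

_BRACKEN_HEADER_PREFIX = "name\ttaxonomy_id"


class ReportParseError(ValueError):
    """A taxonomic report line could not be parsed."""


@dataclass(frozen=True)
class TaxonRecord:
    """Identity of one taxon as emitted by the profiler.

    ``lineage`` lists ancestors from the nearest (e.g. genus for a species)
    up toward the root, as ``(rank, name)`` pairs. It may be empty when the
    source report does not encode hierarchy (Bracken-dialect files).
    """

    taxon_id: int
    name: str
    rank: str
    lineage: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("taxon name must be non-empty")
        if self.rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {self.rank!r}")
        idx = [_RANK_INDEX[r] for r, _ in self.lineage if r in _RANK_INDEX]
        if any(b >= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"lineage ranks must ascend toward the root for {self.name!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Identity used when merging profiles: (name, rank)."""
        return (self.name, self.rank)

    def lineage_names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.lineage)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study annotations: subject, swab site and condition."""

    sample_id: str
    subject_id: str
    site: str
    condition: str
    ligation: str = "unknown"
    platinum: str = "unknown"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class AbundanceTable:
    """Cohort count matrix: samples (rows) x taxa (columns).

    Invariants enforced on construction: non-negative integer counts, shape
    agreement with the taxa/sample lists, unique taxon names at the
    aggregation rank, unique sample ids and unique (subject, site) pairs.
    """

    counts: np.ndarray
    taxa: list[TaxonRecord]
    samples: list[SampleMetadata]
    rank_level: str = "species"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.samples), len(self.taxa)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique at the aggregation rank")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("sample ids must be unique")
        pairs = [(s.subject_id, s.site) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(subject_id, site) pairs must be unique")

    # -- convenience views ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxon_names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def subject_site_index(self) -> dict[tuple[str, str], int]:
        """Map (subject_id, site) -> row index."""
        return {(s.subject_id, s.site): i for i, s in enumerate(self.samples)}

    def select_taxa(self, mask: np.ndarray | Sequence[int]) -> "AbundanceTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AbundanceTable(
            counts=self.counts[:, idx].copy(),
            taxa=[self.taxa[i] for i in idx],
            samples=list(self.samples),
            rank_level=self.rank_level,
        )

    def select_samples(self, mask: np.ndarray | Sequence[int]) -> "AbundanceTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AbundanceTable(
            counts=self.counts[idx, :].copy(),
            taxa=list(self.taxa),
            samples=[self.samples[i] for i in idx],
            rank_level=self.rank_level,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.taxon_names
        )


# ---------------------------------------------------------------------------
# Report parsing
# ---------------------------------------------------------------------------


def _parse_kraken2(
    lines: list[str], rank_level: str, path: str
) -> dict[TaxonRecord, int]:
    """Parse a Kraken2-style report (no header; six tab-separated columns:
    percent, clade reads, direct reads, rank code, taxid, indented name).

    The count returned for a row is the clade count — reads assigned at or
    below that taxon — which is the report's at-or-below convention.
    Lineage is reconstructed from the indentation hierarchy.
    """
    out: dict[TaxonRecord, int] = {}
    # stack of (depth, rank, name) of current ancestors
    stack: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ReportParseError(
                f"{path}: line {lineno}: expected 6 tab-separated fields, "
                f"got {len(parts)}"
            )
        try:
            clade_reads = int(parts[1])
            taxid = int(parts[4])
        except ValueError as exc:
            raise ReportParseError(f"{path}: line {lineno}: {exc}") from None
        code = parts[3].strip()
        raw_name = parts[5]
        depth = (len(raw_name) - len(raw_name.lstrip(" "))) // 2
        name = raw_name.strip()
        if code == "U":
            continue
        rank = _KRAKEN_RANK_CODES.get(code)
        if rank is None:
            base = code.rstrip("0123456789")
            if base not in _KRAKEN_RANK_CODES:
                logger.warning(
                    "%s: line %d: unknown rank code %r; row skipped",
                    path,
                    lineno,
                    code,
                )
                continue
            rank = None  # intermediate clade without a canonical rank
        while stack and stack[-1][0] >= depth:
            stack.pop()
        if rank == rank_level:
            lineage = tuple(
                (r, n)
                for _, r, n in reversed(stack)
                if r is not None and r != "root"
            )
            rec = TaxonRecord(
                taxon_id=taxid, name=name, rank=rank, lineage=lineage
            )
            _accumulate(out, rec, clade_reads, path)
        stack.append((depth, rank, name))
    return out


def _parse_bracken(
    lines: list[str], rank_level: str, path: str
) -> dict[TaxonRecord, int]:
    """Parse a Bracken-style report (headered; name, taxonomy_id,
    taxonomy_lvl, kraken_assigned_reads, added_reads, new_est_reads,
    fraction_total_reads). The re-estimated read count is used. Bracken
    reports carry no hierarchy, so lineage is empty unless attached later
    (see :func:`attach_lineages`)."""
    out: dict[TaxonRecord, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 7:
            raise ReportParseError(
                f"{path}: line {lineno}: expected 7 tab-separated fields, "
                f"got {len(parts)}"
            )
        name = parts[0].strip()
        code = parts[2].strip()
        rank = _KRAKEN_RANK_CODES.get(code)
        if rank is None:
            logger.warning(
                "%s: line %d: unknown rank code %r; row skipped", path, lineno, code
            )
            continue
        try:
            taxid = int(parts[1])
            reads = int(parts[5])
        except ValueError as exc:
            raise ReportParseError(f"{path}: line {lineno}: {exc}") from None
        if rank != rank_level:
            continue
        rec = TaxonRecord(taxon_id=taxid, name=name, rank=rank)
        _accumulate(out, rec, reads, path)
    return out


def _accumulate(
    out: dict[TaxonRecord, int], rec: TaxonRecord, count: int, path: str
) -> None:
    for existing in out:
        if existing.key == rec.key and existing is not rec:
            logger.warning(
                "%s: duplicate taxon %r at rank %r; counts summed",
                path,
                rec.name,
                rec.rank,
            )
            out[existing] += count
            return
    out[rec] = out.get(rec, 0) + count


def read_taxonomic_report(
    path: str | Path, rank_level: str = "species"
) -> dict[TaxonRecord, int]:
    """Read one per-sample taxonomic report, keeping rows at ``rank_level``.

    The dialect (Kraken2-style vs Bracken-style) is auto-detected from the
    header line. Returns an insertion-ordered mapping of TaxonRecord to
    assigned read count; an empty file yields an empty mapping.
    """
    if rank_level not in _RANK_INDEX:
        raise ValueError(f"unknown rank level {rank_level!r}")
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        return {}
    if lines[0].startswith(_BRACKEN_HEADER_PREFIX):
        return _parse_bracken(lines, rank_level, str(path))
    return _parse_kraken2(lines, rank_level, str(path))


def attach_lineages(
    profile: Mapping[TaxonRecord, int],
    lineages: Mapping[int, tuple[tuple[str, str], ...]],
) -> dict[TaxonRecord, int]:
    """Attach lineages (taxid -> ancestor list) to a lineage-less profile."""
    out: dict[TaxonRecord, int] = {}
    for rec, count in profile.items():
        lin = lineages.get(rec.taxon_id)
        if lin is not None and not rec.lineage:
            rec = replace(rec, lineage=tuple(lin))
        out[rec] = count
    return out


# ---------------------------------------------------------------------------
# Cohort assembly and filtering
# ---------------------------------------------------------------------------


def merge_profiles(
    profiles: Sequence[Mapping[TaxonRecord, int]],
    metadata: Sequence[SampleMetadata],
    rank_level: str = "species",
) -> AbundanceTable:
    """Merge per-sample profiles into one cohort table.

    Taxa are unioned across samples (absent taxa zero-filled) and columns
    are sorted by taxon name so the output is deterministic regardless of
    input order. Each sample's total read count is conserved exactly.
    """
    if len(profiles) != len(metadata):
        raise ValueError(
            f"{len(profiles)} profiles but {len(metadata)} metadata entries"
        )
    sids = [m.sample_id for m in metadata]
    if len(set(sids)) != len(sids):
        dupes = sorted({s for s in sids if sids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")

    by_key: dict[tuple[str, str], TaxonRecord] = {}
    for prof in profiles:
        for rec in prof:
            prev = by_key.get(rec.key)
            if prev is None or (not prev.lineage and rec.lineage):
                by_key[rec.key] = rec
    taxa = sorted(by_key.values(), key=lambda t: t.name)
    col = {t.key: j for j, t in enumerate(taxa)}

    counts = np.zeros((len(profiles), len(taxa)), dtype=np.int64)
    for i, prof in enumerate(profiles):
        for rec, c in prof.items():
            counts[i, col[rec.key]] += c
    return AbundanceTable(
        counts=counts, taxa=taxa, samples=list(metadata), rank_level=rank_level
    )


_ORGANELLE_MARKERS = ("mitochondri", "chloroplast")


def _is_excluded(taxon: TaxonRecord) -> bool:
    names = (taxon.name,) + taxon.lineage_names()
    lowered = [n.lower() for n in names]
    if any(m in n for n in lowered for m in _ORGANELLE_MARKERS):
        return True
    ranks = {r: n for r, n in taxon.lineage}
    domain = ranks.get("domain", "")
    kingdom = ranks.get("kingdom", "")
    if domain == "Eukaryota" and kingdom != "Fungi":
        return True
    return False


def exclude_lineages(table: AbundanceTable) -> AbundanceTable:
    """Drop mitochondrial/chloroplast taxa and non-fungal eukaryotes.

    Bacteria, archaea, viruses and fungi are retained. A taxon with no
    lineage information is retained with a logged warning, since exclusion
    cannot be established for it.
    """
    keep = np.ones(table.n_taxa, dtype=bool)
    for j, taxon in enumerate(table.taxa):
        if not taxon.lineage:
            if any(m in taxon.name.lower() for m in _ORGANELLE_MARKERS):
                keep[j] = False
            else:
                logger.warning(
                    "taxon %r has no lineage; retained (exclusion unprovable)",
                    taxon.name,
                )
            continue
        if _is_excluded(taxon):
            keep[j] = False
    if keep.all():
        return table
    return table.select_taxa(keep)


def filter_rare_taxa(
    table: AbundanceTable,
    min_global_fraction: float = 1e-7,
    min_sample_count: int = 5,
) -> AbundanceTable:
    """Remove rare taxa, the artifact-suppression step.

    A taxon is removed iff its share of the grand total read count is below
    ``min_global_fraction`` (default 1e-7, i.e. 0.00001% of the whole
    dataset) OR it has nonzero counts in fewer than ``min_sample_count``
    samples (default 5). The two conditions combine disjunctively and both
    are evaluated once against the table as given (single pass).
    """
    if table.n_taxa == 0:
        return table
    grand = int(table.counts.sum())
    if grand == 0:
        raise ValueError("table has no reads; cannot apply abundance filter")
    totals = table.counts.sum(axis=0)
    prevalence = (table.counts > 0).sum(axis=0)
    keep = (totals / grand >= min_global_fraction) & (
        prevalence >= min_sample_count
    )
    if keep.all():
        return table
    return table.select_taxa(keep)


def to_relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Counts -> within-sample fractions; each row sums to 1 exactly
    (to floating precision); zeros stay zero."""
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = table.samples[zero[0]].sample_id
        raise ValueError(f"sample {bad!r} has zero total count")
    return table.counts / totals[:, None]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "subject_id",
    "site",
    "condition",
    "ligation",
    "platinum",
]


def _format_lineage(lineage: tuple[tuple[str, str], ...]) -> str:
    return ";".join(f"{r}:{n}" for r, n in lineage)


def _parse_lineage(text: str) -> tuple[tuple[str, str], ...]:
    if not text or text in ("-", "nan"):
        return ()
    out = []
    for part in text.split(";"):
        rank, _, name = part.partition(":")
        out.append((rank, name))
    return tuple(out)


def write_table(
    table: AbundanceTable, path: str | Path, metadata_path: str | Path
) -> None:
    """Write the merged table as TSV (taxa as rows, samples as columns)
    with a sidecar metadata TSV."""
    df = pd.DataFrame(
        {
            "taxon": table.taxon_names,
            "rank": [t.rank for t in table.taxa],
            "taxon_id": [t.taxon_id for t in table.taxa],
            "lineage": [_format_lineage(t.lineage) for t in table.taxa],
        }
    )
    for i, sid in enumerate(table.sample_ids):
        df[sid] = table.counts[i, :]
    df.to_csv(path, sep="\t", index=False)
    write_metadata(table.samples, metadata_path)


def read_table(path: str | Path, metadata_path: str | Path) -> AbundanceTable:
    """Inverse of :func:`write_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"lineage": str}, keep_default_na=False)
    meta = read_metadata(metadata_path)
    sample_cols = [c for c in df.columns if c not in ("taxon", "rank", "taxon_id", "lineage")]
    order = {m.sample_id: m for m in meta}
    if set(sample_cols) != set(order):
        raise ValueError("metadata sample ids do not match table columns")
    samples = [order[c] for c in sample_cols]
    taxa = [
        TaxonRecord(
            taxon_id=int(row.taxon_id),
            name=row.taxon,
            rank=row.rank,
            lineage=_parse_lineage(row.lineage),
        )
        for row in df.itertuples()
    ]
    counts = df[sample_cols].to_numpy(dtype=np.int64).T
    rank_level = taxa[0].rank if taxa else "species"
    return AbundanceTable(
        counts=counts, taxa=taxa, samples=samples, rank_level=rank_level
    )


def write_metadata(
    samples: Iterable[SampleMetadata], path: str | Path
) -> None:
    rows = [
        [s.sample_id, s.subject_id, s.site, s.condition, s.ligation, s.platinum]
        for s in samples
    ]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep=sep, index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample metadata table (TSV or CSV, auto-detected)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    out = []
    for row in df.itertuples():
        out.append(
            SampleMetadata(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                site=row.site,
                condition=row.condition,
                ligation=getattr(row, "ligation", "unknown") or "unknown",
                platinum=getattr(row, "platinum", "unknown") or "unknown",
            )
        )
    return out


def write_bracken_report(
    profile: Mapping[TaxonRecord, int], path: str | Path
) -> None:
    """Write one per-sample profile as a Bracken-dialect report."""
    total = sum(profile.values())
    lines = [
        "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\t"
        "added_reads\tnew_est_reads\tfraction_total_reads"
    ]
    code = {v: k for k, v in _KRAKEN_RANK_CODES.items()}
    for rec, count in profile.items():
        frac = count / total if total else 0.0
        lines.append(
            f"{rec.name}\t{rec.taxon_id}\t{code[rec.rank]}\t{count}\t0\t"
            f"{count}\t{frac:.8f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_lineage_table(
    taxa: Iterable[TaxonRecord], path: str | Path
) -> None:
    """Write a taxonomy sidecar (taxid -> lineage) for lineage-less dialects."""
    rows = [
        [t.taxon_id, t.name, t.rank, _format_lineage(t.lineage)] for t in taxa
    ]
    pd.DataFrame(rows, columns=["taxon_id", "taxon", "rank", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_lineage_table(
    path: str | Path,
) -> dict[int, tuple[tuple[str, str], ...]]:
    df = pd.read_csv(path, sep="\t", dtype={"lineage": str}, keep_default_na=False)
    return {
        int(row.taxon_id): _parse_lineage(row.lineage) for row in df.itertuples()
    }
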