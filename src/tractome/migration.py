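"""Adjacent-site migration screen and site-overlap summaries.

The screen asks which taxa change consistently between adjacent swab
sites along the reproductive tract, within one condition group. For each
subject sampled at both sites of a pair, a taxon detected at both sites
is a directional candidate when the log2 ratio of its downstream to
upstream relative abundance is at least 0.5 in magnitude; a taxon
detected at exactly one site counts toward that side's direction when its
relative abundance there is at least 0.05%. A taxon is called increased
(or decreased) along the tract only when the same-direction candidate
call recurs in at least 75% of the group's evaluable subjects, and each
call is then checked with an unpaired Wilcoxon rank-sum test between the
two sites' samples.

Also here: the four-site Venn decomposition of taxon occurrence and the
selection of subjects carrying a taxon above a relative-abundance
threshold at any site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from difflib import get_close_matches
from itertools import combinations

import numpy as np
import pandas as pd

from . import diversity
from .ordination import ADJACENT_PAIRS, clr_transform
from .profiles_io import SITES, AbundanceTable, to_relative_abundance

logger = logging.getLogger("tractome")

DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_PRESENCE_THRESHOLD = 0.0005  # 0.05% relative abundance
DEFAULT_PREVALENCE = 0.75

_UP_CALLS = ("up", "one_side_only_up")
_DOWN_CALLS = ("down", "one_side_only_down")


@dataclass(frozen=True)
class PairedEvidence:
    """One taxon's adjacent-site comparison within one subject.

    ``log2_diff`` is log2(ra_downstream) - log2(ra_upstream) and is None
    when the taxon is detected at only one site; one-side-only calls
    require the present side to reach the presence threshold.
    """

    subject_id: str
    taxon: str
    pair: str
    ra_a: float
    ra_b: float
    log2_diff: float | None
    call: str  # up | down | one_side_only_up | one_side_only_down | none


@dataclass(frozen=True)
class DirectionalTaxonFinding:
    """Outcome of the adjacent-site screen for one taxon and direction."""

    taxon: str
    pair: str
    group: str
    direction: str  # increased | decreased
    n_evaluable: int
    n_consistent: int
    prevalence_fraction: float
    wilcoxon_p: float
    passed: bool


def _normalise_pair(pair) -> tuple[str, str]:
    if isinstance(pair, str):
        a, _, b = pair.partition("-")
        pair = (a, b)
    a, b = pair
    if a not in SITES or b not in SITES:
        raise ValueError(f"unknown sites in pair {pair!r}")
    return a, b


def paired_evidence(
    table: AbundanceTable,
    subject: str,
    pair,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> list[PairedEvidence]:
    """Per-taxon directional evidence for one subject and one site pair.

    Taxa absent at both sites are omitted; taxa present at exactly one
    site are omitted unless the present side's relative abundance reaches
    ``presence_threshold``.
    """
    a, b = _normalise_pair(pair)
    index = table.subject_site_index()
    for site in (a, b):
        if (subject, site) not in index:
            raise KeyError(f"subject {subject!r} has no sample at site {site}")
    ra = to_relative_abundance(table)
    va = ra[index[(subject, a)]]
    vb = ra[index[(subject, b)]]
    out: list[PairedEvidence] = []
    pair_name = f"{a}-{b}"
    for j, name in enumerate(table.taxon_names):
        xa, xb = float(va[j]), float(vb[j])
        if xa == 0.0 and xb == 0.0:
            continue
        if xa > 0.0 and xb > 0.0:
            l2 = float(np.log2(xb) - np.log2(xa))
            if l2 >= lfc_threshold:
                call = "up"
            elif l2 <= -lfc_threshold:
                call = "down"
            else:
                call = "none"
            out.append(
                PairedEvidence(subject, name, pair_name, xa, xb, l2, call)
            )
        else:
            present = xb if xa == 0.0 else xa
            if present < presence_threshold:
                continue
            call = "one_side_only_up" if xa == 0.0 else "one_side_only_down"
            out.append(
                PairedEvidence(subject, name, pair_name, xa, xb, None, call)
            )
    return out


def evaluable_subjects(table: AbundanceTable, pair, group: str | None) -> list[str]:
    """Subjects (optionally restricted to one condition group) sampled at
    both sites of the pair."""
    a, b = _normalise_pair(pair)
    index = table.subject_site_index()
    subjects = sorted(
        {
            s.subject_id
            for s in table.samples
            if group is None or s.condition == group
        }
    )
    return [s for s in subjects if (s, a) in index and (s, b) in index]


def confirm_group_difference(
    table: AbundanceTable, taxon: str, pair, group: str | None = None
) -> float:
    """Unpaired Wilcoxon rank-sum p for a taxon's relative abundance at
    the pair's upstream vs downstream site, across the group's samples
    (``group=None`` pools both conditions)."""
    a, b = _normalise_pair(pair)
    j = table.taxon_index(taxon)
    ra = to_relative_abundance(table)
    xa, xb = [], []
    for i, s in enumerate(table.samples):
        if group is not None and s.condition != group:
            continue
        if s.site == a:
            xa.append(ra[i, j])
        elif s.site == b:
            xb.append(ra[i, j])
    if not xa or not xb:
        raise ValueError(
            f"pair {a}-{b}: a site has no samples in group {group!r}"
        )
    _, p = diversity.wilcoxon_rank_sum(xa, xb)
    return p


def adjacent_pair_screen(
    table: AbundanceTable,
    pair,
    group: str,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    prevalence: float = DEFAULT_PREVALENCE,
    min_evaluable: int = 4,
    prevalence_over: str = "subjects",
    confirm_pooled: bool = False,
    adjust: str | None = None,
    include_failing: bool = False,
) -> list[DirectionalTaxonFinding]:
    """Screen one adjacent-site pair within one condition group.

    Directional candidate calls (see :func:`paired_evidence`) are
    aggregated per taxon over the group's evaluable subjects — those
    sampled at both sites. A taxon is reported as increased (decreased)
    along the tract when the fraction of evaluable subjects calling that
    direction is at least ``prevalence`` (the boundary counts: "at
    least"). Each reported taxon is then confirmed with an unpaired
    Wilcoxon rank-sum test between the two sites (within the group unless
    ``confirm_pooled``); p-values are reported raw unless ``adjust`` names
    a multiplicity method.

    ``prevalence_over="samples"`` switches to the looser reading in which
    a directional candidate passes when the taxon is merely detected in at
    least ``prevalence`` of the group's samples at the two sites and its
    calls favour that direction.
    """
    subjects = evaluable_subjects(table, pair, group)
    if not subjects:
        raise ValueError(f"no evaluable subjects for pair {pair} in group {group}")
    if len(subjects) < min_evaluable:
        raise ValueError(
            f"only {len(subjects)} evaluable subjects for pair {pair} in "
            f"group {group}; need >= {min_evaluable}"
        )
    a, b = _normalise_pair(pair)
    pair_name = f"{a}-{b}"
    n_eval = len(subjects)

    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for subject in subjects:
        for ev in paired_evidence(
            table, subject, (a, b), lfc_threshold, presence_threshold
        ):
            if ev.call in _UP_CALLS:
                up[ev.taxon] = up.get(ev.taxon, 0) + 1
            elif ev.call in _DOWN_CALLS:
                down[ev.taxon] = down.get(ev.taxon, 0) + 1

    if prevalence_over == "samples":
        consistency = _sample_presence_fraction(table, (a, b), group)
    elif prevalence_over != "subjects":
        raise ValueError("prevalence_over must be 'subjects' or 'samples'")

    findings: list[DirectionalTaxonFinding] = []
    for taxon in sorted(set(up) | set(down)):
        n_up = up.get(taxon, 0)
        n_down = down.get(taxon, 0)
        for direction, n_dir, n_opp in (
            ("increased", n_up, n_down),
            ("decreased", n_down, n_up),
        ):
            if n_dir == 0:
                continue
            if prevalence_over == "subjects":
                frac = n_dir / n_eval
                ok = frac >= prevalence
            else:
                frac = consistency.get(taxon, 0.0)
                ok = frac >= prevalence and n_dir > n_opp
            if ok or (include_failing and n_dir >= n_opp):
                findings.append(
                    DirectionalTaxonFinding(
                        taxon=taxon,
                        pair=pair_name,
                        group=group,
                        direction=direction,
                        n_evaluable=n_eval,
                        n_consistent=n_dir,
                        prevalence_fraction=frac,
                        wilcoxon_p=np.nan,
                        passed=bool(ok),
                    )
                )
    # Wilcoxon confirmation of reported taxa
    confirmed: list[DirectionalTaxonFinding] = []
    pvals = []
    for f in findings:
        p = confirm_group_difference(
            table, f.taxon, (a, b), None if confirm_pooled else group
        )
        pvals.append(p)
    if adjust:
        pvals = list(diversity.adjust_pvalues(pvals, method=adjust))
    for f, p in zip(findings, pvals):
        confirmed.append(
            DirectionalTaxonFinding(
                taxon=f.taxon,
                pair=f.pair,
                group=f.group,
                direction=f.direction,
                n_evaluable=f.n_evaluable,
                n_consistent=f.n_consistent,
                prevalence_fraction=f.prevalence_fraction,
                wilcoxon_p=float(p),
                passed=f.passed,
            )
        )
    return confirmed


def _sample_presence_fraction(
    table: AbundanceTable, pair: tuple[str, str], group: str
) -> dict[str, float]:
    """Fraction of the group's samples at the pair's two sites in which
    each taxon is detected (the looser prevalence reading)."""
    rows = [
        i
        for i, s in enumerate(table.samples)
        if s.condition == group and s.site in pair
    ]
    sub = table.counts[rows]
    frac = (sub > 0).mean(axis=0) if rows else np.zeros(table.n_taxa)
    return dict(zip(table.taxon_names, frac))


def screen_all_pairs(
    table: AbundanceTable, groups=("B", "M"), **kwargs
) -> pd.DataFrame:
    """Run the adjacent-site screen for every pair x group combination
    with enough evaluable subjects; returns a tidy findings table."""
    rows = []
    for group in groups:
        for pair in ADJACENT_PAIRS:
            try:
                findings = adjacent_pair_screen(table, pair, group, **kwargs)
            except ValueError as exc:
                logger.warning("screen skipped for %s/%s: %s", pair, group, exc)
                continue
            rows.extend(findings)
    columns = [
        "taxon",
        "pair",
        "group",
        "direction",
        "n_evaluable",
        "n_consistent",
        "prevalence_fraction",
        "wilcoxon_p",
        "passed",
    ]
    df = pd.DataFrame(
        [{c: getattr(f, c) for c in columns} for f in rows], columns=columns
    )
    return df.astype(
        {
            "n_evaluable": int,
            "n_consistent": int,
            "prevalence_fraction": float,
            "wilcoxon_p": float,
            "passed": bool,
        }
    )


# ---------------------------------------------------------------------------
# Site overlap (Venn) and subject selection
# ---------------------------------------------------------------------------


def site_overlap(table: AbundanceTable) -> dict[tuple[str, ...], int]:
    """Counts for the 15 nonempty regions of the four-site Venn diagram.

    A taxon belongs to a site's set when it has a positive count in at
    least one sample from that site. Returned regions are keyed by the
    exact site combination (tuple in tract order) and are disjoint: their
    counts sum to the number of distinct taxa detected anywhere.
    """
    site_sets: dict[str, set[str]] = {}
    for site in SITES:
        rows = [i for i, s in enumerate(table.samples) if s.site == site]
        if not rows:
            logger.warning("site %s has no samples; its set is empty", site)
            site_sets[site] = set()
            continue
        present = (table.counts[rows] > 0).any(axis=0)
        site_sets[site] = {
            name for name, p in zip(table.taxon_names, present) if p
        }
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, 5):
        for combo in combinations(SITES, r):
            inside = set.intersection(*(site_sets[s] for s in combo))
            outside = set.union(
                *(site_sets[s] for s in SITES if s not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return regions


def site_overlap_table(table: AbundanceTable) -> pd.DataFrame:
    regions = site_overlap(table)
    return pd.DataFrame(
        {
            "sites": ["+".join(k) for k in regions],
            "n_taxa": list(regions.values()),
        }
    )


def select_subjects_by_taxon(
    table: AbundanceTable, taxon: str, threshold: float = 0.01
) -> list[str]:
    """Subjects whose relative abundance of ``taxon`` exceeds ``threshold``
    (strictly) at one or more of their sampled sites. Default 1%."""
    try:
        j = table.taxon_index(taxon)
    except KeyError:
        near = get_close_matches(taxon, table.taxon_names, n=5, cutoff=0.4)
        raise KeyError(
            f"taxon {taxon!r} not in table; close matches: {near}"
        ) from None
    ra = to_relative_abundance(table)
    hits = {
        table.samples[i].subject_id
        for i in range(table.n_samples)
        if ra[i, j] > threshold
    }
    return sorted(hits)


def clr_condition_comparison(
    table: AbundanceTable, site: str, adjust: str = "BH"
) -> pd.DataFrame:
    """Per-taxon Wilcoxon comparison of clr abundances between conditions
    at one site.

    Plain plumbing: a simple clr-scale rank test, provided so a per-taxon
    condition contrast exists in the toolkit. It performs no
    bias-correction for compositional sampling effects and is not a
    substitute for purpose-built differential-abundance estimators.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    rows = [i for i, s in enumerate(table.samples) if s.site == site]
    if not rows:
        raise ValueError(f"no samples at site {site}")
    sub = table.select_samples(rows)
    conditions = np.array([s.condition for s in sub.samples])
    if np.unique(conditions).size < 2:
        raise ValueError(f"site {site} has samples from only one condition")
    clr = clr_transform(sub).values
    stats_rows = []
    pvals = []
    for j, name in enumerate(sub.taxon_names):
        x = clr[conditions == "B", j]
        y = clr[conditions == "M", j]
        stat, p = diversity.wilcoxon_rank_sum(x, y)
        stats_rows.append(
            {
                "taxon": name,
                "site": site,
                "median_clr_B": float(np.median(x)),
                "median_clr_M": float(np.median(y)),
                "statistic": stat,
            }
        )
        pvals.append(p)
    adj = diversity.adjust_pvalues(pvals, method=adjust)
    df = pd.DataFrame(stats_rows)
    df["p_value"] = pvals
    df["p_adjusted"] = adj
    return df
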