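"""Positional classification of kinases relative to the kinase domain.

A kinase is categorized by where its top-3 predominant phosphosites fall:
all inside the catalytic domain (PiKD), all outside (PoKD), mixed (PaKD),
or enigmatic (PeKD) when fewer than two ranked sites exist so no call can
be made. Kinases are additionally stratified by domain coverage (domain
length over protein length: >=70% high, 50-70% mid, <50% less), and each
site is annotated for disordered-region overlap and co-located missense
mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import KDLabel, Kinase, MutationRecord, PhosphoSite, PositionalCategory
from .predominance import PredominanceProfile

KD_HIGH_THRESHOLD = 0.70
KD_MID_THRESHOLD = 0.50
TOP_N_BASIS = 3


@dataclass
class KinaseCategory:
    kinase_id: str
    category: PositionalCategory
    basis: list[tuple[int, bool]]  # (position, in_domain) for the top-3 sites
    kd_ratio: float
    kd_label: KDLabel


@dataclass
class SiteContext:
    site: PhosphoSite
    in_domain: bool
    in_disorder: bool
    co_mutated: bool


def locate_site(position: int, intervals: Sequence[tuple[int, int]]) -> bool:
    """True iff ``position`` falls in any interval (inclusive both ends)."""
    return any(start <= position <= end for start, end in intervals)


def kd_coverage(
    kinase: Kinase,
    high: float = KD_HIGH_THRESHOLD,
    mid: float = KD_MID_THRESHOLD,
) -> tuple[float, KDLabel]:
    """Kinase-domain-length / protein-length ratio and its stratum.

    Multiple domain intervals (dual-domain kinases) are summed. The mid
    stratum is half-open at the top: ``mid <= ratio < high``.
    """
    covered = sum(end - start + 1 for start, end in kinase.domain_intervals)
    ratio = covered / kinase.length
    if ratio >= high:
        label = KDLabel.KD_HIGH
    elif ratio >= mid:
        label = KDLabel.KD_MID
    else:
        label = KDLabel.KD_LESS
    return ratio, label


def classify_positional(profile: PredominanceProfile, kinase: Kinase) -> KinaseCategory:
    """Categorize a kinase by its top-3 predominant site placements.

    Kinases with no sites or a single site are PeKD (enigmatic). With two
    ranked sites the same all-in / all-out / mixed rule is applied to the
    pair.
    """
    if profile.kinase_id and profile.kinase_id != kinase.kinase_id:
        raise ValueError(
            f"profile is for {profile.kinase_id!r}, kinase is {kinase.kinase_id!r}"
        )
    basis = [
        (s.position, locate_site(s.position, kinase.domain_intervals))
        for s in profile.ranked_sites[:TOP_N_BASIS]
    ]
    flags = [in_dom for _, in_dom in basis]
    if len(basis) <= 1:
        category = PositionalCategory.PeKD
    elif all(flags):
        category = PositionalCategory.PiKD
    elif not any(flags):
        category = PositionalCategory.PoKD
    else:
        category = PositionalCategory.PaKD
    ratio, kd_label = kd_coverage(kinase)
    return KinaseCategory(
        kinase_id=kinase.kinase_id,
        category=category,
        basis=basis,
        kd_ratio=ratio,
        kd_label=kd_label,
    )


def disorder_overlap(site: PhosphoSite, kinase: Kinase) -> bool:
    """True iff the site lies in a predicted disordered segment."""
    return locate_site(site.position, kinase.disordered_intervals)


def site_contexts(
    sites: Sequence[PhosphoSite],
    kinase: Kinase,
    mutations: Sequence[MutationRecord] = (),
) -> list[SiteContext]:
    """Annotate each site with domain, disorder and mutation co-location."""
    mut_positions = {m.position for m in mutations if m.kinase_id == kinase.kinase_id}
    return [
        SiteContext(
            site=s,
            in_domain=locate_site(s.position, kinase.domain_intervals),
            in_disorder=disorder_overlap(s, kinase),
            co_mutated=s.position in mut_positions,
        )
        for s in sites
    ]


def mutation_join(
    sites: Sequence[PhosphoSite],
    mutations: Sequence[MutationRecord],
    kinase: Kinase,
) -> dict[str, int]:
    """Tally co-located (site, mutation) pairs inside vs outside the domain.

    A pair is co-located iff the positions are identical (multiset join:
    two mutations at one site position yield two pairs).
    """
    tallies = {"in_domain": 0, "outside_domain": 0}
    site_positions = [s.position for s in sites if s.kinase_id == kinase.kinase_id]
    for m in mutations:
        if m.kinase_id != kinase.kinase_id:
            continue
        for pos in site_positions:
            if pos == m.position:
                key = "in_domain" if locate_site(pos, kinase.domain_intervals) else "outside_domain"
                tallies[key] += 1
    return tallies
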