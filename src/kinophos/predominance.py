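"""Detection-evidence ranking and extraction of predominant phosphosites.

Sites are ranked per kinase by how often they were detected in
high-throughput MS datasets, with the count of targeted low-throughput
studies as tie-breaker; the top ten are the kinase's "predominant" sites
and the top one its representative site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import EvidenceClass, PhosphoSite

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10


@dataclass
class PredominanceProfile:
    kinase_id: str
    ranked_sites: list[PhosphoSite]
    predominant: list[PhosphoSite]
    top_site: Optional[PhosphoSite]


def evidence_class(site: PhosphoSite) -> EvidenceClass:
    """Classify a site by its kinds of supporting evidence."""
    if site.ht_count + site.lt_count < 1:
        raise ValueError(f"{site.kinase_id}:{site.label}: unobserved site (no evidence)")
    if site.ht_count > 0 and site.lt_count > 0:
        return EvidenceClass.LT_HT
    if site.ht_count > 0:
        return EvidenceClass.HT_ONLY
    return EvidenceClass.LT_ONLY


def rank_sites(sites: Sequence[PhosphoSite]) -> list[PhosphoSite]:
    """Rank one kinase's sites by detection evidence.

    Descending by HT dataset count, ties broken descending by LT study
    count, remaining ties ascending by position — a deterministic total
    order.
    """
    kinase_ids = {s.kinase_id for s in sites}
    if len(kinase_ids) > 1:
        raise ValueError(f"rank_sites given mixed kinases: {sorted(kinase_ids)}")
    return sorted(sites, key=lambda s: (-s.ht_count, -s.lt_count, s.position))


def select_predominant(ranked: Sequence[PhosphoSite], k: int = DEFAULT_TOP_K) -> PredominanceProfile:
    """Take the top ``min(k, len(ranked))`` sites as the predominant set."""
    ranked = list(ranked)
    kid = ranked[0].kinase_id if ranked else ""
    predominant = ranked[: max(k, 0)]
    return PredominanceProfile(
        kinase_id=kid,
        ranked_sites=ranked,
        predominant=predominant,
        top_site=predominant[0] if predominant else None,
    )


def tag_orphans(sites: Sequence[PhosphoSite]) -> dict[PhosphoSite, bool]:
    """Orphan <=> the site has no curated functional association."""
    return {s: s.is_orphan for s in sites}


def join_functional_scores(
    sites: Sequence[PhosphoSite],
    score_table: Mapping[tuple[str, int], float],
) -> list[PhosphoSite]:
    """Fill ``functional_score`` from an external (kinase, position) table.

    Scores outside [0, 1] are rejected with a logged message; sites absent
    from the table keep an empty score.
    """
    annotated: list[PhosphoSite] = []
    for site in sites:
        score = score_table.get((site.kinase_id, site.position))
        if score is not None and not (0.0 <= score <= 1.0):
            logger.warning(
                "functional score %r for %s:%s outside [0, 1]; entry rejected",
                score,
                site.kinase_id,
                site.label,
            )
            score = None
        if score is None:
            annotated.append(site)
        else:
            annotated.append(
                PhosphoSite(
                    kinase_id=site.kinase_id,
                    residue=site.residue,
                    position=site.position,
                    ht_count=site.ht_count,
                    lt_count=site.lt_count,
                    function_tags=site.function_tags,
                    functional_score=score,
                )
            )
    return annotated
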