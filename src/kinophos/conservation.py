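"""Windowed family conservation scoring of phosphosites.

For a phosphosite at position ``p`` we take the 11-residue window
``[p - w, p + w]`` (``w = 5`` by default) in alignment space, and at each
of the 2w+1 columns compare the query's character against the characters
of the other family members at that column. Each column contributes a
score in [0, 1] built from three counts over the ``n`` comparison
sequences — exact matches, property matches (same physicochemical group)
and gaps:

    score_j = clamp(w_exact * exact/n + w_property * property/n
                    + w_gap * gaps/n, 0, 1)

and the total score is the mean over the window, so it is bounded in
[0, 1]: 1 for a perfectly conserved window in an identity family, 0 when
every comparison character differs in kind (or is a gap, under the
default gap weight of 0).

Sites scoring >= 0.75 are labelled highly conserved, <= 0.25 less
conserved, and < 0.1 additionally flagged family-unique — candidates for
kinase-specific regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import map_to_column
from .model import AlignedFamily, ConservationLabel, GAP, PhosphoSite

#: Physicochemical grouping of the 20 amino acids used for property
#: matches. Swappable via ScoringWeights.property_groups.
DEFAULT_PROPERTY_GROUPS: Mapping[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIM"),
    "aromatic": frozenset("FWY"),
    "polar": frozenset("STNQC"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "special": frozenset("GP"),
}

HIGH_THRESHOLD = 0.75
LESS_THRESHOLD = 0.25
UNIQUE_THRESHOLD = 0.10
DEFAULT_WINDOW = 5


def _group_of(groups: Mapping[str, frozenset[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for name, members in groups.items():
        for aa in members:
            out[aa] = name
    return out


@dataclass
class ScoringWeights:
    """Weights for the three per-position match classes.

    Defaults: an exact match is worth 1, a same-property match 0.5, and a
    gap 0 — gaps dilute the score (they occupy comparison slots without
    contributing), which realizes the gap penalty while keeping each
    position's maximum at 1. ``w_gap`` may be negative for a harsher
    penalty; the per-position score is clamped to [0, 1] regardless.
    """

    w_exact: float = 1.0
    w_property: float = 0.5
    w_gap: float = 0.0
    property_groups: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_GROUPS)
    )

    def __post_init__(self) -> None:
        if not (self.w_exact >= self.w_property >= 0):
            raise ValueError("require w_exact >= w_property >= 0")
        self._group_of = _group_of(self.property_groups)

    def same_property(self, a: str, b: str) -> bool:
        ga = self._group_of.get(a)
        return ga is not None and ga == self._group_of.get(b)


DEFAULT_WEIGHTS = ScoringWeights()


@dataclass
class SiteWindow:
    """An extracted 2w+1 window around a site, gap-padded at boundaries."""

    site: Optional[PhosphoSite]
    w: int
    window: str

    @property
    def center(self) -> str:
        return self.window[self.w]


@dataclass
class PositionScore:
    offset: int
    reference: str
    exact_matches: int
    property_matches: int
    gaps: int
    n: int
    score: float


@dataclass
class ConservationResult:
    site: PhosphoSite
    family: str
    total_score: float
    positions: list[PositionScore]
    label: ConservationLabel
    unique_flag: bool


def extract_window(sequence: str, p: int, w: int = DEFAULT_WINDOW) -> SiteWindow:
    """Extract the window ``sequence[p-w .. p+w]`` (1-based, inclusive).

    Indices falling outside the sequence are padded with ``'-'`` so the
    window always has length 2w+1 with the site at the center.
    """
    L = len(sequence)
    if not (1 <= p <= L):
        raise ValueError(f"position {p} outside 1..{L}")
    chars = []
    for q in range(p - w, p + w + 1):
        chars.append(sequence[q - 1] if 1 <= q <= L else GAP)
    return SiteWindow(site=None, w=w, window="".join(chars))


def score_position(
    reference: str,
    aligned_chars: Sequence[str],
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    offset: int = 0,
) -> PositionScore:
    """Score one window position against ``n`` comparison characters.

    Counts exact matches, same-property matches and gaps among the
    comparison characters and combines them with the weights. A gap as
    the *reference* character contributes 0 by definition (there is no
    residue to conserve).
    """
    n = len(aligned_chars)
    if n == 0:
        raise ValueError("no comparison characters (n = 0)")
    exact = prop = gaps = 0
    for a in aligned_chars:
        if a == GAP:
            gaps += 1
        elif a == reference:
            exact += 1
        elif weights.same_property(a, reference):
            prop += 1
    if reference == GAP:
        score = 0.0
    else:
        raw = (
            weights.w_exact * exact / n
            + weights.w_property * prop / n
            + weights.w_gap * gaps / n
        )
        score = min(1.0, max(0.0, raw))
    return PositionScore(
        offset=offset,
        reference=reference,
        exact_matches=exact,
        property_matches=prop,
        gaps=gaps,
        n=n,
        score=score,
    )


def conservation_score(
    af: AlignedFamily,
    site: PhosphoSite,
    w: int = DEFAULT_WINDOW,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    high: float = HIGH_THRESHOLD,
    less: float = LESS_THRESHOLD,
    unique: float = UNIQUE_THRESHOLD,
) -> ConservationResult:
    """Score a site's window against the other members of its family.

    The site position is mapped to its alignment column; the 2w+1 columns
    centered there (gap-padded beyond the alignment edges) are each scored
    against the characters of the other members (n = members - 1), and the
    total is the mean of the per-column scores.
    """
    if site.kinase_id not in af.aligned:
        raise KeyError(f"kinase {site.kinase_id!r} not in family {af.family.name!r}")
    others = [kid for kid in af.family.member_ids if kid != site.kinase_id]
    if not others:
        raise ValueError("family has no comparison members")
    center_col = map_to_column(af, site.kinase_id, site.position)
    n_cols = af.n_columns
    query_row = af.aligned[site.kinase_id]
    positions: list[PositionScore] = []
    for j in range(-w, w + 1):
        col = center_col + j
        if 1 <= col <= n_cols:
            ref = query_row[col - 1]
            chars = [af.aligned[kid][col - 1] for kid in others]
        else:
            ref = GAP
            chars = [GAP] * len(others)
        positions.append(score_position(ref, chars, weights, offset=j))
    total = sum(ps.score for ps in positions) / (2 * w + 1)
    label, unique_flag = label_conservation(total, high=high, less=less, unique=unique)
    return ConservationResult(
        site=site,
        family=af.family.name,
        total_score=total,
        positions=positions,
        label=label,
        unique_flag=unique_flag,
    )


def label_conservation(
    score: float,
    high: float = HIGH_THRESHOLD,
    less: float = LESS_THRESHOLD,
    unique: float = UNIQUE_THRESHOLD,
) -> tuple[ConservationLabel, bool]:
    """Apply the conservation thresholds to a total score.

    >= 0.75: highly conserved; <= 0.25: less conserved; strictly below
    0.1: additionally family-unique. Scores in between are intermediate.
    All three thresholds are configurable.
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    if score >= high:
        label = ConservationLabel.HIGHLY_CONSERVED
    elif score <= less:
        label = ConservationLabel.LESS_CONSERVED
    else:
        label = ConservationLabel.INTERMEDIATE
    return label, score < unique


def family_unique_sites(results: Iterable[ConservationResult]) -> list[ConservationResult]:
    """Sites with conservation score < 0.1 in their family."""
    return [r for r in results if r.unique_flag]
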