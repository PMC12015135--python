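"""Core domain types shared by every pipeline stage.

Coordinate conventions: all residue positions are 1-based and all intervals
are 1-based inclusive on both ends, matching the site-naming convention of
curated phosphosite resources (e.g. "Y419" is the tyrosine at position 419).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHOACCEPTORS = frozenset("STY")
GAP = "-"

FUNCTION_TAGS = frozenset(
    {
        "activation",
        "inhibition",
        "activity_altered",
        "localization",
        "stability",
        "degradation",
        "conformation",
        "interaction",
    }
)


class KinaseType(str, Enum):
    ST = "ST"
    Y = "Y"
    DUAL = "DUAL"
    OTHER = "OTHER"


class EvidenceClass(str, Enum):
    """Detection-evidence class of a phosphosite.

    LT_HT: supported by both targeted low-throughput studies and
    high-throughput MS datasets; HT_ONLY / LT_ONLY: one kind only.
    """

    LT_HT = "LT_HT"
    HT_ONLY = "HT_ONLY"
    LT_ONLY = "LT_ONLY"


class ConservationLabel(str, Enum):
    HIGHLY_CONSERVED = "HIGHLY_CONSERVED"
    INTERMEDIATE = "INTERMEDIATE"
    LESS_CONSERVED = "LESS_CONSERVED"


class PositionalCategory(str, Enum):
    """Kinase category by where the top-3 predominant sites fall.

    PiKD: all inside the kinase domain; PoKD: all outside; PaKD: mixed;
    PeKD: enigmatic (fewer than two ranked sites, so no call can be made).
    """

    PiKD = "PiKD"
    PoKD = "PoKD"
    PaKD = "PaKD"
    PeKD = "PeKD"


class KDLabel(str, Enum):
    """Kinase-domain coverage stratum: domain length / protein length."""

    KD_HIGH = "KD_HIGH"  # ratio >= 0.70
    KD_MID = "KD_MID"  # 0.50 <= ratio < 0.70
    KD_LESS = "KD_LESS"  # ratio < 0.50


class LengthBin(str, Enum):
    """Tryptic-peptide length bin; 8-15 residues is the MS-optimal band."""

    OPT_8_15 = "OPT_8_15"
    SHORT_LT8 = "SHORT_LT8"
    LONG_GT15 = "LONG_GT15"


@dataclass
class Kinase:
    """A protein kinase: sequence plus domain/disorder intervals and family.

    ``domain_intervals`` holds the catalytic (kinase) domain span(s);
    dual-domain kinases carry more than one. ``disordered_intervals`` are
    predicted intrinsically disordered segments. Both are lists of
    ``(start, end)`` 1-based inclusive pairs.
    """

    kinase_id: str
    gene_symbol: str
    group: str
    family: str
    kinase_type: KinaseType
    sequence: str
    domain_intervals: list[tuple[int, int]] = field(default_factory=list)
    disordered_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L < 1:
            raise ValueError(f"{self.kinase_id}: empty sequence")
        for name, ivals in (
            ("domain", self.domain_intervals),
            ("disorder", self.disordered_intervals),
        ):
            for start, end in ivals:
                if not (1 <= start <= end <= L):
                    raise ValueError(
                        f"{self.kinase_id}: {name} interval {start}-{end} "
                        f"invalid for sequence of length {L}"
                    )
        self.domain_intervals = sorted(self.domain_intervals)
        for (s1, e1), (s2, e2) in zip(self.domain_intervals, self.domain_intervals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.kinase_id}: overlapping domain intervals "
                    f"{s1}-{e1} and {s2}-{e2}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PhosphoSite:
    """One experimentally observed phosphorylated S/T/Y residue.

    ``ht_count`` is the number of high-throughput MS datasets detecting the
    site; ``lt_count`` the number of targeted low-throughput studies.
    ``functional_score`` is an externally supplied machine-learned relevance
    score in [0, 1], joined when available.
    """

    kinase_id: str
    residue: str
    position: int
    ht_count: int
    lt_count: int
    function_tags: frozenset[str] = frozenset()
    functional_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHOACCEPTORS:
            raise ValueError(
                f"{self.kinase_id}:{self.position}: residue {self.residue!r} "
                "is not a phosphoacceptor (S/T/Y)"
            )
        if self.position < 1:
            raise ValueError(f"{self.kinase_id}: position {self.position} < 1")
        if self.ht_count < 0 or self.lt_count < 0:
            raise ValueError("negative evidence counts")
        unknown = set(self.function_tags) - FUNCTION_TAGS
        if unknown:
            raise ValueError(f"unknown function tags: {sorted(unknown)}")
        if self.functional_score is not None and not (0.0 <= self.functional_score <= 1.0):
            raise ValueError(f"functional score {self.functional_score} outside [0, 1]")

    @property
    def is_orphan(self) -> bool:
        """True when the site carries no curated functional association."""
        return not self.function_tags

    @property
    def label(self) -> str:
        return f"{self.residue}{self.position}"


@dataclass
class KinaseFamily:
    name: str
    member_ids: list[str]


@dataclass
class MutationRecord:
    """A missense mutation (e.g. cancer-associated) at a kinase position."""

    kinase_id: str
    position: int
    ref_residue: str
    alt_residue: str
    disease_tag: str = ""


@dataclass
class AlignedFamily:
    """A kinase family's aligned sequences with position<->column maps.

    ``aligned`` maps each member id to its gapped row (all equal length);
    ``col_of[k][p - 1]`` gives the 1-based alignment column holding the
    1-based ungapped position ``p`` of member ``k``.
    """

    family: KinaseFamily
    aligned: dict[str, str]
    col_of: dict[str, list[int]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.aligned.values())))

    def ungapped(self, kinase_id: str) -> str:
        return self.aligned[kinase_id].replace(GAP, "")
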