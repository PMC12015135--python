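"""Synthetic kinome bundles with known ground truth.

The generator emulates the pipeline's real-world inputs — a kinase
catalog with domain and disorder intervals, family sequence sets with
alignments, a phosphosite table with heavy-tailed detection counts, and a
missense-mutation table — so every downstream stage is testable without
any database export.

Families are evolved star-wise from a random ancestor: a fraction of
columns is conserved (never substituted) and the rest are variable
(substituted independently per member). Phosphoacceptor (S/T/Y) columns
are planted in both strata, with their flanking columns forced into the
same stratum so a planted-conserved site sits in a conserved motif and a
planted-variable one in a drifting region — mirroring how functional
phosphosites tend to live in conserved sequence context. Detection
counts are zipf-distributed so one or two sites per kinase dominate, the
pattern seen in real phosphoproteomes where a single activation-loop site
can appear in a third of all datasets.

By default there are no indels, so the true alignment is the trivial
column-identity alignment; an optional deletion mode exists to stress the
alignment reader only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as kio
from .model import (
    AMINO_ACIDS,
    AlignedFamily,
    FUNCTION_TAGS,
    GAP,
    Kinase,
    KinaseFamily,
    KinaseType,
    MutationRecord,
    PhosphoSite,
    PositionalCategory,
)

_ACCEPTORS = "STY"
_FLANK = 3  # columns on each side of a planted acceptor forced into its stratum


@dataclass
class SimConfig:
    """Study conditions for the synthetic kinome.

    Defaults emulate a small kinome: families of 3-8 members (real kinase
    families mostly hold 2-15 genes), protein lengths 300-700 aa, a
    catalytic domain covering one of three strata of the length (to
    exercise the coverage labels), ~15% disorder, half the columns
    conserved, and zipf-distributed HT detection counts.
    """

    n_families: int = 12
    members_per_family: tuple[int, int] = (3, 8)
    seq_length: tuple[int, int] = (300, 700)
    conserved_column_fraction: float = 0.5
    substitution_rate_variable: float = 0.5
    planted_conserved_per_family: int = 3
    planted_variable_per_family: int = 3
    n_sites_per_kinase: tuple[int, int] = (3, 12)
    ht_zipf_exponent: float = 2.0
    ht_zero_probability: float = 0.08
    lt_positive_probability: float = 0.2
    function_tag_probability: float = 0.4
    functional_score_probability: float = 0.25
    domain_coverage_fractions: tuple[float, ...] = (0.8, 0.6, 0.3)
    disorder_fraction: float = 0.15
    mutation_rate_at_sites: float = 0.1
    deletion_probability: float = 0.0  # optional indel stress mode
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conserved_column_fraction",
            "substitution_rate_variable",
            "ht_zero_probability",
            "lt_positive_probability",
            "function_tag_probability",
            "functional_score_probability",
            "disorder_fraction",
            "mutation_rate_at_sites",
            "deletion_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for name in ("members_per_family", "seq_length", "n_sites_per_kinase"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.ht_zipf_exponent <= 1.0:
            raise ValueError("ht_zipf_exponent must exceed 1")


@dataclass
class TruthLabels:
    """Ground truth planted by the generator."""

    planted_conserved_sites: set[tuple[str, int]] = field(default_factory=set)
    planted_variable_sites: set[tuple[str, int]] = field(default_factory=set)
    expected_positional_class: dict[str, PositionalCategory] = field(default_factory=dict)

    def merge(self, other: "TruthLabels") -> None:
        self.planted_conserved_sites |= other.planted_conserved_sites
        self.planted_variable_sites |= other.planted_variable_sites
        self.expected_positional_class.update(other.expected_positional_class)


def _family_rng(cfg: SimConfig, family_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, family_index])


def generate_family(
    cfg: SimConfig, family_index: int
) -> tuple[list[Kinase], AlignedFamily, TruthLabels]:
    """Generate one family: members, true alignment, planted-site truth.

    Deterministic for a fixed (seed, family_index).
    """
    rng = _family_rng(cfg, family_index)
    name = f"FAM{family_index:03d}"
    L = int(rng.integers(cfg.seq_length[0], cfg.seq_length[1] + 1))
    n_members = int(rng.integers(cfg.members_per_family[0], cfg.members_per_family[1] + 1))

    ancestor = list(rng.choice(list(AMINO_ACIDS), size=L))

    # Plant acceptor columns well inside the sequence, mutually spaced so
    # their forced flanks never overlap across strata. A fully conserved
    # family (fraction 1) has no variable stratum to plant into.
    n_var_planted = 0 if cfg.conserved_column_fraction >= 1.0 else cfg.planted_variable_per_family
    n_planted = cfg.planted_conserved_per_family + n_var_planted
    spacing = 2 * _FLANK + 2
    candidates = list(range(_FLANK + 1, L - _FLANK + 1))
    planted_cols: list[int] = []
    rng.shuffle(candidates)
    for c in candidates:
        if len(planted_cols) >= n_planted:
            break
        if all(abs(c - q) >= spacing for q in planted_cols):
            planted_cols.append(c)
    planted_cols.sort()
    order = rng.permutation(len(planted_cols))
    n_con_planted = len(planted_cols) - min(n_var_planted, len(planted_cols))
    conserved_planted = sorted(planted_cols[i] for i in order[:n_con_planted])
    variable_planted = sorted(planted_cols[i] for i in order[n_con_planted:])
    for c in planted_cols:
        ancestor[c - 1] = str(rng.choice(list(_ACCEPTORS)))

    # Column strata: forced flanks first, then random fill to the target
    # conserved fraction.
    conserved = set()
    variable = set()
    for c in conserved_planted:
        conserved.update(range(c - _FLANK, c + _FLANK + 1))
    for c in variable_planted:
        variable.update(range(c - _FLANK, c + _FLANK + 1))
    free = [c for c in range(1, L + 1) if c not in conserved and c not in variable]
    n_target = round(cfg.conserved_column_fraction * L)
    n_extra = max(0, min(len(free), n_target - len(conserved)))
    extra = rng.choice(len(free), size=n_extra, replace=False) if n_extra else []
    conserved.update(free[i] for i in extra)
    variable.update(c for c in free if c not in conserved)

    member_ids = [f"F{family_index:03d}K{m:02d}" for m in range(n_members)]
    aligned: dict[str, str] = {}
    kinases: list[Kinase] = []
    truth = TruthLabels()

    kinase_type_cycle = [KinaseType.ST, KinaseType.Y, KinaseType.DUAL, KinaseType.OTHER]
    other_aa = {aa: [b for b in AMINO_ACIDS if b != aa] for aa in AMINO_ACIDS}

    for mi, kid in enumerate(member_ids):
        row = list(ancestor)
        for c in sorted(variable):
            if rng.random() < cfg.substitution_rate_variable:
                row[c - 1] = str(rng.choice(other_aa[ancestor[c - 1]]))
        if cfg.deletion_probability > 0:
            protected: set[int] = set()
            for v in variable_planted:
                protected.update(range(v - _FLANK, v + _FLANK + 1))
            for c in sorted(variable - protected):
                if rng.random() < cfg.deletion_probability:
                    row[c - 1] = GAP
        gapped = "".join(row)
        aligned[kid] = gapped
        seq = gapped.replace(GAP, "")

        # ungapped position of each alignment column for this member
        pos_of_col: dict[int, int] = {}
        p = 0
        for c, ch in enumerate(gapped, start=1):
            if ch != GAP:
                p += 1
                pos_of_col[c] = p

        for c in conserved_planted:
            if c in pos_of_col and seq[pos_of_col[c] - 1] in _ACCEPTORS:
                truth.planted_conserved_sites.add((kid, pos_of_col[c]))
        for c in variable_planted:
            if c in pos_of_col and seq[pos_of_col[c] - 1] in _ACCEPTORS:
                truth.planted_variable_sites.add((kid, pos_of_col[c]))

        Lm = len(seq)
        frac = cfg.domain_coverage_fractions[
            (family_index * n_members + mi) % len(cfg.domain_coverage_fractions)
        ]
        dlen = max(1, min(Lm, round(frac * Lm)))
        dstart = int(rng.integers(1, Lm - dlen + 2))
        domain = [(dstart, dstart + dlen - 1)]
        disorder: list[tuple[int, int]] = []
        if cfg.disorder_fraction > 0:
            zlen = max(1, min(Lm, round(cfg.disorder_fraction * Lm)))
            zstart = int(rng.integers(1, Lm - zlen + 2))
            disorder = [(zstart, zstart + zlen - 1)]

        kinases.append(
            Kinase(
                kinase_id=kid,
                gene_symbol=f"{name}G{mi}",
                group=f"GRP{family_index % 5}",
                family=name,
                kinase_type=kinase_type_cycle[mi % 4],
                sequence=seq,
                domain_intervals=domain,
                disordered_intervals=disorder,
            )
        )

    family = KinaseFamily(name=name, member_ids=member_ids)
    af = AlignedFamily(
        family=family,
        aligned=aligned,
        col_of={k: [c + 1 for c, ch in enumerate(v) if ch != GAP] for k, v in aligned.items()},
    )
    return kinases, af, truth


def generate_site_catalog(
    cfg: SimConfig,
    kinases: list[Kinase],
    truth: TruthLabels,
    rng: Optional[np.random.Generator] = None,
) -> list[PhosphoSite]:
    """Draw a phosphosite table over the generated kinases.

    Every planted acceptor becomes a site; extra sites are drawn from the
    remaining S/T/Y positions. HT dataset counts are zipf-distributed
    (heavy-tailed, so one or two sites dominate each kinase); with
    probability ``ht_zero_probability`` a site is HT-undetected and
    becomes LT-only, mirroring the small minority of sites known only
    from targeted studies. The expected positional class of each kinase
    is recorded from the planted top-3 placements.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 999_983])
    tag_pool = sorted(FUNCTION_TAGS)
    sites: list[PhosphoSite] = []
    for kinase in kinases:
        kid = kinase.kinase_id
        planted = sorted(
            pos
            for (k, pos) in (truth.planted_conserved_sites | truth.planted_variable_sites)
            if k == kid
        )
        acceptors = [
            i + 1
            for i, ch in enumerate(kinase.sequence)
            if ch in _ACCEPTORS and (i + 1) not in planted
        ]
        n_sites = int(rng.integers(cfg.n_sites_per_kinase[0], cfg.n_sites_per_kinase[1] + 1))
        n_extra = max(0, min(len(acceptors), n_sites - len(planted)))
        extra_idx = rng.choice(len(acceptors), size=n_extra, replace=False) if n_extra else []
        positions = sorted(planted + [acceptors[i] for i in extra_idx])
        kin_sites: list[PhosphoSite] = []
        for pos in positions:
            ht = 0 if rng.random() < cfg.ht_zero_probability else int(rng.zipf(cfg.ht_zipf_exponent))
            lt = int(rng.integers(1, 6)) if rng.random() < cfg.lt_positive_probability else 0
            if ht == 0 and lt == 0:
                lt = 1
            if rng.random() < cfg.function_tag_probability:
                k_tags = int(rng.integers(1, 3))
                idx = rng.choice(len(tag_pool), size=k_tags, replace=False)
                tags = frozenset(tag_pool[i] for i in idx)
            else:
                tags = frozenset()
            fscore = (
                float(np.round(rng.uniform(), 4))
                if rng.random() < cfg.functional_score_probability
                else None
            )
            kin_sites.append(
                PhosphoSite(
                    kinase_id=kid,
                    residue=kinase.sequence[pos - 1],
                    position=pos,
                    ht_count=ht,
                    lt_count=lt,
                    function_tags=tags,
                    functional_score=fscore,
                )
            )
        sites.extend(kin_sites)
        truth.expected_positional_class[kid] = _expected_class(kin_sites, kinase)
    return sites


def _expected_class(kin_sites: list[PhosphoSite], kinase: Kinase) -> PositionalCategory:
    # Inline restatement of the placement rule, kept independent of the
    # positional module so truth recovery is a genuine cross-check.
    ordered = sorted(kin_sites, key=lambda s: (-s.ht_count, -s.lt_count, s.position))[:3]
    if len(ordered) <= 1:
        return PositionalCategory.PeKD
    flags = [
        any(a <= s.position <= b for a, b in kinase.domain_intervals) for s in ordered
    ]
    if all(flags):
        return PositionalCategory.PiKD
    if not any(flags):
        return PositionalCategory.PoKD
    return PositionalCategory.PaKD


def generate_mutations(
    cfg: SimConfig,
    sites: list[PhosphoSite],
    rng: Optional[np.random.Generator] = None,
) -> list[MutationRecord]:
    """Point mutations at site positions with rate ``mutation_rate_at_sites``."""
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 424_243])
    muts: list[MutationRecord] = []
    for s in sites:
        if rng.random() < cfg.mutation_rate_at_sites:
            alt = str(rng.choice([aa for aa in AMINO_ACIDS if aa != s.residue]))
            muts.append(
                MutationRecord(
                    kinase_id=s.kinase_id,
                    position=s.position,
                    ref_residue=s.residue,
                    alt_residue=alt,
                    disease_tag="cancer",
                )
            )
    return muts


@dataclass
class KinomeBundle:
    """Paths of a generated input bundle on disk."""

    root: Path
    catalog: Path
    sites: Path
    mutations: Path
    family_fastas: dict[str, Path]
    family_alignments: dict[str, Path]
    truth_json: Path


def generate_kinome(cfg: SimConfig, outdir: str | Path) -> tuple[KinomeBundle, TruthLabels]:
    """Write a full input bundle (catalog, families, sites, mutations).

    Byte-identical output for identical configs (including seed).
    """
    root = Path(outdir)
    (root / "families").mkdir(parents=True, exist_ok=True)
    truth = TruthLabels()
    all_kinases: list[Kinase] = []
    fastas: dict[str, Path] = {}
    alns: dict[str, Path] = {}
    for fi in range(cfg.n_families):
        kinases, af, frag = generate_family(cfg, fi)
        truth.merge(frag)
        all_kinases.extend(kinases)
        fname = af.family.name
        fastas[fname] = root / "families" / f"{fname}.fasta"
        alns[fname] = root / "families" / f"{fname}.aln.fasta"
        kio.write_fasta({k.kinase_id: k.sequence for k in kinases}, fastas[fname])
        kio.write_alignment(af, alns[fname])
    sites = generate_site_catalog(cfg, all_kinases, truth)
    muts = generate_mutations(cfg, sites)

    catalog_path = root / "catalog.tsv"
    sites_path = root / "sites.tsv"
    muts_path = root / "mutations.tsv"
    truth_path = root / "truth.json"
    kio.write_kinase_catalog(all_kinases, catalog_path)
    kio.write_site_table(sites, sites_path)
    kio.write_mutation_table(muts, muts_path)
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "planted_conserved_sites": sorted(map(list, truth.planted_conserved_sites)),
                "planted_variable_sites": sorted(map(list, truth.planted_variable_sites)),
                "expected_positional_class": {
                    k: v.value for k, v in sorted(truth.expected_positional_class.items())
                },
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(cfg).items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    bundle = KinomeBundle(
        root=root,
        catalog=catalog_path,
        sites=sites_path,
        mutations=muts_path,
        family_fastas=fastas,
        family_alignments=alns,
        truth_json=truth_path,
    )
    return bundle, truth
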