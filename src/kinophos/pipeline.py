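"""End-to-end orchestration: ingest -> rank -> digest -> conserve ->
classify -> summarize.

One structured config (YAML file or dict) drives everything; all rule
thresholds (top-k, window size, scoring weights, conservation and
domain-coverage cutoffs) are configuration with the published defaults.
Reports are plain TSV plus a JSON run summary whose every count can be
re-derived from the per-record tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from . import io as kio
from .align import star_align
from .conservation import (
    DEFAULT_WINDOW,
    HIGH_THRESHOLD,
    LESS_THRESHOLD,
    UNIQUE_THRESHOLD,
    ConservationResult,
    ScoringWeights,
    conservation_score,
)
from .digestion import map_sites_to_peptides, trypsin_digest
from .model import (
    ConservationLabel,
    EvidenceClass,
    KDLabel,
    Kinase,
    MutationRecord,
    PhosphoSite,
    PositionalCategory,
)
from .positional import (
    KD_HIGH_THRESHOLD,
    KD_MID_THRESHOLD,
    KinaseCategory,
    classify_positional,
    site_contexts,
)
from .predominance import (
    DEFAULT_TOP_K,
    PredominanceProfile,
    evidence_class,
    rank_sites,
    select_predominant,
)
from .simulate import SimConfig, generate_kinome

logger = logging.getLogger(__name__)

ORPHAN_COLUMN = "orphan"


@dataclass
class PipelineParams:
    """All tunable rule constants, at their published defaults."""

    top_k: int = DEFAULT_TOP_K
    window: int = DEFAULT_WINDOW
    w_exact: float = 1.0
    w_property: float = 0.5
    w_gap: float = 0.0
    high_threshold: float = HIGH_THRESHOLD
    less_threshold: float = LESS_THRESHOLD
    unique_threshold: float = UNIQUE_THRESHOLD
    kd_high: float = KD_HIGH_THRESHOLD
    kd_mid: float = KD_MID_THRESHOLD
    missed_cleavages: int = 0
    digest: bool = True
    fallback_aligner: bool = False

    def weights(self) -> ScoringWeights:
        return ScoringWeights(
            w_exact=self.w_exact, w_property=self.w_property, w_gap=self.w_gap
        )


@dataclass
class RunSummary:
    seed: Optional[int]
    config: dict[str, Any]
    evidence_counts: dict[str, int] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    kd_counts: dict[str, int] = field(default_factory=dict)
    conservation_counts: dict[str, int] = field(default_factory=dict)
    n_family_unique: int = 0
    orphan_fraction_predominant: Optional[float] = None
    cross_tab: dict[str, dict[str, int]] = field(default_factory=dict)
    peptide_bin_counts: dict[str, int] = field(default_factory=dict)
    rejected_rows: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "config": self.config,
            "evidence_counts": self.evidence_counts,
            "category_counts": self.category_counts,
            "kd_counts": self.kd_counts,
            "conservation_counts": self.conservation_counts,
            "n_family_unique": self.n_family_unique,
            "orphan_fraction_predominant": self.orphan_fraction_predominant,
            "cross_tab": self.cross_tab,
            "peptide_bin_counts": self.peptide_bin_counts,
            "n_rejected_rows": len(self.rejected_rows),
            "rejected_rows": self.rejected_rows,
            "notes": self.notes,
        }


def cross_tab(
    categories: Sequence[KinaseCategory],
    sites: Sequence[PhosphoSite],
) -> dict[str, dict[str, int]]:
    """Count sites per (kinase category x function tag), orphans included.

    A site carrying several tags counts once per tag; an orphan site
    counts once in the orphan column. Row totals therefore equal the
    number of (site, annotation) pairs.
    """
    cat_of = {c.kinase_id: c.category.value for c in categories}
    tags = sorted({t for s in sites for t in s.function_tags}) + [ORPHAN_COLUMN]
    table = {
        cat.value: {t: 0 for t in tags} for cat in PositionalCategory
    }
    for s in sites:
        cat = cat_of.get(s.kinase_id)
        if cat is None:
            continue
        if s.is_orphan:
            table[cat][ORPHAN_COLUMN] += 1
        else:
            for t in sorted(s.function_tags):
                table[cat][t] += 1
    return table


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _sim_config(block: dict, seed: Optional[int]) -> SimConfig:
    kwargs = dict(block)
    if seed is not None:
        kwargs.setdefault("seed", seed)
    for name in ("members_per_family", "seq_length", "n_sites_per_kinase", "domain_coverage_fractions"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(kwargs[name])
    return SimConfig(**kwargs)


def run_pipeline(config: str | Path | dict, outdir: Optional[str | Path] = None) -> RunSummary:
    """Execute the full analysis described by ``config``.

    The config either names input files (``inputs`` block: catalog,
    sites, mutations, alignments) or requests simulation (``simulate``
    block). Reports (TSV) and ``summary.json`` are written to ``outdir``
    (or the config's ``output`` key). Deterministic given inputs + seed.
    """
    cfg = _load_config(config)
    out = Path(outdir or cfg.get("output", "kinophos_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    params = PipelineParams(
        **{
            k: v
            for k, v in cfg.get("params", {}).items()
            if k in {f.name for f in dataclass_fields(PipelineParams)}
        }
    )
    reject_log = kio.RejectLog()
    summary = RunSummary(seed=seed, config=cfg)

    # --- ingest (or simulate) -------------------------------------------
    alignment_paths: dict[str, Path] = {}
    alignment_format = "aligned_fasta"
    if "simulate" in cfg:
        bundle, _truth = generate_kinome(_sim_config(cfg["simulate"], seed), out / "sim_inputs")
        catalog_path, sites_path, muts_path = bundle.catalog, bundle.sites, bundle.mutations
        alignment_paths = dict(bundle.family_alignments)
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("catalog", "sites"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise FileNotFoundError(f"required input {key!r} missing from config or disk")
        catalog_path = Path(inputs["catalog"])
        sites_path = Path(inputs["sites"])
        muts_path = Path(inputs["mutations"]) if inputs.get("mutations") else None
        aln_block = inputs.get("alignments", {})
        alignment_format = aln_block.get("format", "aligned_fasta")
        if "dir" in aln_block:
            suffix = {"aligned_fasta": ".aln.fasta", "clustal": ".aln"}[alignment_format]
            for p in sorted(Path(aln_block["dir"]).glob(f"*{suffix}")):
                alignment_paths[p.name[: -len(suffix)]] = p
    else:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")

    kinases = kio.read_kinase_catalog(catalog_path, reject_log)
    sites = kio.read_site_table(sites_path, kinases, reject_log)
    mutations: list[MutationRecord] = (
        kio.read_mutation_table(muts_path, kinases, reject_log) if muts_path else []
    )
    by_kinase: dict[str, list[PhosphoSite]] = {k.kinase_id: [] for k in kinases}
    for s in sites:
        by_kinase[s.kinase_id].append(s)

    # --- rank / predominance --------------------------------------------
    profiles: dict[str, PredominanceProfile] = {}
    ranked_rows = []
    for k in kinases:
        ranked = rank_sites(by_kinase[k.kinase_id])
        profile = select_predominant(ranked, k=params.top_k)
        profile = PredominanceProfile(
            kinase_id=k.kinase_id,
            ranked_sites=profile.ranked_sites,
            predominant=profile.predominant,
            top_site=profile.top_site,
        )
        profiles[k.kinase_id] = profile
        for rank, s in enumerate(ranked, start=1):
            ranked_rows.append(
                {
                    "kinase_id": k.kinase_id,
                    "rank": rank,
                    "position": s.position,
                    "residue": s.residue,
                    "ht_count": s.ht_count,
                    "lt_count": s.lt_count,
                    "evidence_class": evidence_class(s).value,
                    "predominant": rank <= params.top_k,
                    "orphan": s.is_orphan,
                    "function_tags": ",".join(sorted(s.function_tags)),
                    "functional_score": "" if s.functional_score is None else s.functional_score,
                }
            )
    ranked_df = pd.DataFrame(
        ranked_rows,
        columns=[
            "kinase_id", "rank", "position", "residue", "ht_count", "lt_count",
            "evidence_class", "predominant", "orphan", "function_tags", "functional_score",
        ],
    )
    ranked_df.to_csv(out / "ranked_sites.tsv", sep="\t", index=False)

    # --- digestion (optional) -------------------------------------------
    peptide_rows = []
    if params.digest:
        for k in kinases:
            peptides = trypsin_digest(
                k.sequence, missed_cleavages=params.missed_cleavages, kinase_id=k.kinase_id
            )
            for pep in map_sites_to_peptides(by_kinase[k.kinase_id], peptides):
                peptide_rows.append(
                    {
                        "kinase_id": k.kinase_id,
                        "start": pep.start,
                        "end": pep.end,
                        "length": pep.length,
                        "length_bin": pep.length_bin.value,
                        "monoisotopic_mass": pep.monoisotopic_mass,
                        "site_positions": ",".join(map(str, pep.site_positions)),
                        "sequence": pep.sequence,
                    }
                )
    peptide_df = pd.DataFrame(
        peptide_rows,
        columns=["kinase_id", "start", "end", "length", "length_bin",
                 "monoisotopic_mass", "site_positions", "sequence"],
    )
    peptide_df.to_csv(out / "peptides.tsv", sep="\t", index=False)

    # --- conservation (per family, predominant sites) -------------------
    cons_results: list[ConservationResult] = []
    families: dict[str, list[Kinase]] = {}
    for k in kinases:
        families.setdefault(k.family, []).append(k)
    weights = params.weights()
    skipped_families = []
    for fam_name in sorted(families):
        members = families[fam_name]
        if len(members) < 2:
            continue  # single-member families are excluded from this analysis
        af = None
        if fam_name in alignment_paths:
            af = kio.read_alignment(alignment_paths[fam_name], alignment_format, name=fam_name)
        elif params.fallback_aligner:
            af = star_align({m.kinase_id: m.sequence for m in members}, family_name=fam_name)
        if af is None:
            skipped_families.append(fam_name)
            continue
        for m in members:
            if m.kinase_id not in af.aligned:
                continue
            for s in profiles[m.kinase_id].predominant:
                cons_results.append(
                    conservation_score(
                        af, s, w=params.window, weights=weights,
                        high=params.high_threshold, less=params.less_threshold,
                        unique=params.unique_threshold,
                    )
                )
    if skipped_families:
        summary.notes.append(
            "conservation skipped for families without alignments "
            f"(fallback aligner disabled): {skipped_families}"
        )
    cons_df = pd.DataFrame(
        [
            {
                "kinase_id": r.site.kinase_id,
                "family": r.family,
                "position": r.site.position,
                "residue": r.site.residue,
                "total_score": r.total_score,
                "label": r.label.value,
                "unique_flag": r.unique_flag,
                "positions_json": json.dumps(
                    [
                        {
                            "offset": p.offset, "ref": p.reference,
                            "exact": p.exact_matches, "property": p.property_matches,
                            "gaps": p.gaps, "n": p.n, "score": p.score,
                        }
                        for p in r.positions
                    ]
                ),
            }
            for r in cons_results
        ],
        columns=["kinase_id", "family", "position", "residue", "total_score",
                 "label", "unique_flag", "positions_json"],
    )
    cons_df.to_csv(out / "conservation.tsv", sep="\t", index=False)

    # --- positional classification + site context -----------------------
    categories = [
        classify_positional(profiles[k.kinase_id], k) for k in kinases
    ]
    cat_df = pd.DataFrame(
        [
            {
                "kinase_id": c.kinase_id,
                "category": c.category.value,
                "basis": ";".join(f"{pos}:{'in' if flag else 'out'}" for pos, flag in c.basis),
                "kd_ratio": round(c.kd_ratio, 6),
                "kd_label": c.kd_label.value,
            }
            for c in categories
        ],
        columns=["kinase_id", "category", "basis", "kd_ratio", "kd_label"],
    )
    cat_df.to_csv(out / "categories.tsv", sep="\t", index=False)

    context_rows = []
    kin_by_id = {k.kinase_id: k for k in kinases}
    for k in kinases:
        for ctx in site_contexts(by_kinase[k.kinase_id], k, mutations):
            context_rows.append(
                {
                    "kinase_id": k.kinase_id,
                    "position": ctx.site.position,
                    "residue": ctx.site.residue,
                    "in_domain": ctx.in_domain,
                    "in_disorder": ctx.in_disorder,
                    "co_mutated": ctx.co_mutated,
                }
            )
    ctx_df = pd.DataFrame(
        context_rows,
        columns=["kinase_id", "position", "residue", "in_domain", "in_disorder", "co_mutated"],
    )
    ctx_df.to_csv(out / "site_context.tsv", sep="\t", index=False)

    # --- summary (recounted from the emitted tables) --------------------
    summary.rejected_rows = reject_log.records
    summary.evidence_counts = {
        e.value: int((ranked_df["evidence_class"] == e.value).sum()) for e in EvidenceClass
    }
    summary.category_counts = {
        c.value: int((cat_df["category"] == c.value).sum()) for c in PositionalCategory
    }
    summary.kd_counts = {
        l.value: int((cat_df["kd_label"] == l.value).sum()) for l in KDLabel
    }
    summary.conservation_counts = {
        l.value: int((cons_df["label"] == l.value).sum()) for l in ConservationLabel
    }
    summary.n_family_unique = int(cons_df["unique_flag"].sum()) if len(cons_df) else 0
    pred_df = ranked_df[ranked_df["predominant"]] if len(ranked_df) else ranked_df
    summary.orphan_fraction_predominant = (
        float(pred_df["orphan"].mean()) if len(pred_df) else None
    )
    predominant_sites = [s for p in profiles.values() for s in p.predominant]
    summary.cross_tab = cross_tab(categories, predominant_sites)
    if len(peptide_df):
        summary.peptide_bin_counts = peptide_df["length_bin"].value_counts().to_dict()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True, default=str)
    logger.info(
        "pipeline done: %d kinases, %d sites, %d conservation rows, %d rejected rows",
        len(kinases), len(sites), len(cons_df), len(reject_log),
    )
    return summary


def summarize_reports(outdir: str | Path) -> dict[str, Any]:
    """Recount the summary statistics from the emitted per-record TSVs.

    Used for cross-footing: every count in ``summary.json`` must equal
    the recount from the tables.
    """
    out = Path(outdir)
    ranked = pd.read_csv(out / "ranked_sites.tsv", sep="\t")
    cats = pd.read_csv(out / "categories.tsv", sep="\t")
    cons = pd.read_csv(out / "conservation.tsv", sep="\t")
    result: dict[str, Any] = {
        "evidence_counts": {
            e.value: int((ranked["evidence_class"] == e.value).sum()) for e in EvidenceClass
        },
        "category_counts": {
            c.value: int((cats["category"] == c.value).sum()) for c in PositionalCategory
        },
        "kd_counts": {l.value: int((cats["kd_label"] == l.value).sum()) for l in KDLabel},
        "conservation_counts": {
            l.value: int((cons["label"] == l.value).sum()) for l in ConservationLabel
        },
        "n_family_unique": int(cons["unique_flag"].sum()) if len(cons) else 0,
    }
    pred = ranked[ranked["predominant"]] if len(ranked) else ranked
    result["orphan_fraction_predominant"] = float(pred["orphan"].mean()) if len(pred) else None
    return result
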