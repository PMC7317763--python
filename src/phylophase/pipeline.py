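"""End-to-end orchestration: QC -> CSL census -> dating -> subgenome phasing.

Each stage takes a loaded :class:`~phylophase.io.PhylomeDataset` and returns
a result object carrying the per-tree tables, the per-stage attrition counts
(every filter's input and output sizes are reported so the bookkeeping of a
real phylome run can be reproduced) and the stage's summary product.  The
``run_all`` driver shares the parsed trees between stages in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import csl as _csl
from . import dating as _dating
from . import qc as _qc
from . import subgenome as _sub
from .io import PhylomeDataset, PhylomeError

log = logging.getLogger(__name__)


@dataclass
class ParentageResult:
    """CSL census evidence: per-tree table, distance profiles, attrition."""

    table: pd.DataFrame
    census: _csl.CensusResult
    passing: list[_csl.CSLRecord]
    distance_profiles: pd.DataFrame
    attrition: dict[str, int]
    cleaned: dict[str, tuple] = field(default_factory=dict, repr=False)


def run_parentage(
    dataset: PhylomeDataset,
    qc_cfg: _qc.QCConfig | None = None,
    csl_cfg: _csl.CSLFilterConfig | None = None,
    outgroup_section: str | None = None,
) -> ParentageResult:
    """Clean (1% N preset), filter, extract CSLs and nominate the parents.

    Trees are rooted at the configured outgroup section when present, else
    midpoint-rooted; trees parsed with a bifurcating root and no outgroup
    configured are taken as already rooted.
    """
    qc_cfg = qc_cfg or _qc.CSL_PRESET
    csl_cfg = csl_cfg or _csl.CSLFilterConfig()
    attrition = {
        "input": 0, "seed_removed": 0, "species_filter_fail": 0,
        "no_csl": 0, "csl_extracted": 0, "filters_pass": 0,
    }
    rows, profiles, passing = [], [], []
    cleaned = {}
    for tree in dataset.trees:
        attrition["input"] += 1
        aln, tree, report = _qc.clean_alignment(
            dataset.alignments[tree.tree_id], tree, qc_cfg)
        if tree.unusable:
            attrition["seed_removed"] += 1
            continue
        if not _qc.species_count_filter(tree, qc_cfg):
            attrition["species_filter_fail"] += 1
            continue
        if outgroup_section is not None or len(
                tree.tree.seed_node.child_nodes()) > 2:
            _csl.root_tree(tree, outgroup_section)
        cleaned[tree.tree_id] = (aln, tree)
        try:
            rec = _csl.find_csl(tree)
        except _csl.NoCSLError:
            attrition["no_csl"] += 1
            continue
        attrition["csl_extracted"] += 1
        _csl.resolve_csl_section(rec, tree)
        flags = _csl.csl_filters(rec, csl_cfg)
        if flags.passed:
            attrition["filters_pass"] += 1
            passing.append(rec)
        rows.append({
            "tree_id": rec.tree_id, "seed_gene": rec.seed_gene,
            "resolved_section": rec.resolved_section,
            "csl_leaf": rec.csl_leaf, "csl_distance": rec.csl_distance,
            "mrca_support": rec.mrca_support, "n_species": rec.n_species,
            "pass_min_species": flags.min_species,
            "pass_max_sister_species": flags.max_sister_species,
            "pass_max_csl_distance": flags.max_csl_distance,
            "pass_min_mrca_support": flags.min_mrca_support,
            "pass_all": flags.passed,
        })
        for section, dist in _csl.closest_leaf_per_taxon(tree).items():
            profiles.append({"tree_id": rec.tree_id, "section": section,
                             "distance": dist})
    if attrition["filters_pass"] == 0:
        raise PhylomeError(
            f"no tree passed the CSL filters; attrition: {attrition}")
    census = _csl.csl_census(passing)
    log.info("parentage attrition: %s; census: %s", attrition, census.counts)
    return ParentageResult(
        table=pd.DataFrame(rows).sort_values("tree_id").reset_index(drop=True)
        if rows else pd.DataFrame(),
        census=census, passing=passing,
        distance_profiles=pd.DataFrame(profiles),
        attrition=attrition, cleaned=cleaned)


@dataclass
class DatingResult:
    """Per-tree 4D statistics and per-section divergence summaries."""

    table: pd.DataFrame
    section_summary: pd.DataFrame
    parental_time_peak: _dating.PeakResult | None
    parental_fourdtv_peak: _dating.PeakResult | None


def run_dating(
    dataset: PhylomeDataset,
    parentage: ParentageResult,
    cfg: _dating.DatingConfig | None = None,
) -> DatingResult:
    """4DTv ratios and divergence times for every tree with a valid CSL."""
    cfg = cfg or _dating.DatingConfig()
    rows = []
    times: dict[str, list[float]] = {}
    ratios: dict[str, list[float]] = {}
    for rec in parentage.passing:
        aln, _tree = parentage.cleaned[rec.tree_id]
        stats = _dating.count_4d_substitutions(
            aln, rec.seed_gene, rec.csl_leaf, tree_id=rec.tree_id)
        ratio = _dating.fourdtv_ratio(stats, rec, cfg)
        row = {
            "tree_id": rec.tree_id, "section": rec.resolved_section,
            "n_4d_sites": stats.n_4d_sites, "ti": stats.ti, "tv": stats.tv,
            "fourdtv": stats.fourdtv, "d4": stats.d4,
            "time_mya": None, "rejection_reason": ratio.rejection_reason,
        }
        if ratio.accepted and stats.d4 is not None:
            est = _dating.divergence_time(stats, cfg, rec.resolved_section)
            row["time_mya"] = est.time
            times.setdefault(est.section, []).append(est.time)
            ratios.setdefault(est.section, []).append(ratio.value)
        rows.append(row)

    summaries = []
    for section in sorted(times):
        vals = times[section]
        if len(vals) < cfg.peak_min_n:
            log.warning("section %s has only %d dated trees; no peak",
                        section, len(vals))
            continue
        tp = _dating.distribution_peak(vals, cfg.peak_min_n)
        rp = _dating.distribution_peak(ratios[section], cfg.peak_min_n)
        summaries.append({"section": section, "n": tp.n,
                          "time_mean_mya": tp.mean, "time_peak_mya": tp.peak,
                          "fourdtv_mean": rp.mean, "fourdtv_peak": rp.peak})

    parental_time = parental_ratio = None
    pair = parentage.census.parental_pair
    if pair is not None:
        tvals = [t for s in pair for t in times.get(s, [])]
        rvals = [r for s in pair for r in ratios.get(s, [])]
        if len(tvals) >= cfg.peak_min_n:
            parental_time = _dating.distribution_peak(tvals, cfg.peak_min_n)
            parental_ratio = _dating.distribution_peak(rvals, cfg.peak_min_n)
    return DatingResult(
        table=pd.DataFrame(rows),
        section_summary=pd.DataFrame(summaries),
        parental_time_peak=parental_time,
        parental_fourdtv_peak=parental_ratio)


@dataclass
class SubgenomeResult:
    """Gene and scaffold origin calls plus the per-origin summary table."""

    gene_assignments: list[_sub.GeneAssignment]
    scaffold_assignments: list[_sub.ScaffoldAssignment]
    summary: pd.DataFrame
    counts: dict[str, int]


def run_subgenome(
    dataset: PhylomeDataset,
    parental_pair: tuple[str, str],
    qc_cfg: _qc.QCConfig | None = None,
    min_support: float = 0.9,
    majority: float = 0.75,
) -> SubgenomeResult:
    """Assign genes via closest parental leaves (10% N preset), rescue
    orphans from genomic neighbors, and call scaffolds by the majority rule.

    Without gene loci, orphan inference is skipped (with a notice) and the
    scaffold step cannot run; scaffold outputs are then empty.
    """
    qc_cfg = qc_cfg or _qc.SUBGENOME_PRESET
    cleaned_trees = []
    for tree in dataset.trees:
        _aln, tree, _rep = _qc.clean_alignment(
            dataset.alignments[tree.tree_id], tree, qc_cfg)
        cleaned_trees.append(tree)
    assignments = _sub.assign_genes(cleaned_trees, parental_pair, min_support)
    maternal, paternal = parental_pair
    counts = {
        "genes_total": len(assignments),
        "tree_maternal": sum(1 for a in assignments
                             if a.provenance == "tree" and a.origin == maternal),
        "tree_paternal": sum(1 for a in assignments
                             if a.provenance == "tree" and a.origin == paternal),
        "orphans_initial": sum(1 for a in assignments if a.origin == _sub.ORPHAN),
    }
    scaffolds: list[_sub.ScaffoldAssignment] = []
    if dataset.loci:
        assignments = _sub.infer_orphans(assignments, dataset.loci)
        counts["neighbor_maternal"] = sum(
            1 for a in assignments
            if a.provenance == "neighbor" and a.origin == maternal)
        counts["neighbor_paternal"] = sum(
            1 for a in assignments
            if a.provenance == "neighbor" and a.origin == paternal)
        counts["orphans_final"] = sum(
            1 for a in assignments if a.origin == _sub.ORPHAN)
        scaffolds = _sub.assign_scaffolds(
            assignments, dataset.loci, dataset.scaffold_lengths or {},
            parental_pair, majority)
    else:
        log.warning("no gene loci available; orphan inference and scaffold "
                    "assignment skipped")
    summary = (_sub.summarize_assignments(scaffolds)
               if scaffolds else pd.DataFrame())
    log.info("subgenome counts: %s", counts)
    return SubgenomeResult(gene_assignments=assignments,
                           scaffold_assignments=scaffolds,
                           summary=summary, counts=counts)


@dataclass
class PipelineResult:
    parentage: ParentageResult
    dating: DatingResult
    subgenome: SubgenomeResult


def run_all(
    dataset: PhylomeDataset,
    qc_csl: _qc.QCConfig | None = None,
    qc_subgenome: _qc.QCConfig | None = None,
    csl_cfg: _csl.CSLFilterConfig | None = None,
    dating_cfg: _dating.DatingConfig | None = None,
    parental_pair: tuple[str, str] | None = None,
    outgroup_section: str | None = None,
    min_support: float = 0.9,
    majority: float = 0.75,
) -> PipelineResult:
    """Run parentage, dating and subgenome assignment on one dataset.

    The parental pair defaults to the census top-2 but can be pinned.
    """
    parentage = run_parentage(dataset, qc_csl, csl_cfg, outgroup_section)
    dating = run_dating(dataset, parentage, dating_cfg)
    pair = parental_pair or parentage.census.parental_pair
    if pair is None:
        raise PhylomeError("no parental pair nominated and none supplied")
    sub = run_subgenome(dataset, pair, qc_subgenome, min_support, majority)
    return PipelineResult(parentage=parentage, dating=dating, subgenome=sub)


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Write the standard TSV products of a full run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.parentage.table.to_csv(outdir / "csl_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(result.parentage.census.counts.items()),
        columns=["section", "n_csl"],
    ).to_csv(outdir / "csl_census.tsv", sep="\t", index=False)
    result.parentage.distance_profiles.to_csv(
        outdir / "distance_profiles.tsv", sep="\t", index=False)
    result.dating.table.to_csv(outdir / "dating_table.tsv", sep="\t", index=False)
    result.dating.section_summary.to_csv(
        outdir / "dating_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [a.__dict__ for a in result.subgenome.gene_assignments]
    ).sort_values("gene_id").to_csv(
        outdir / "gene_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [s.__dict__ for s in result.subgenome.scaffold_assignments]
    ).to_csv(outdir / "scaffold_assignments.tsv", sep="\t", index=False)
    result.subgenome.summary.to_csv(
        outdir / "scaffold_summary.tsv", sep="\t", index=False)
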