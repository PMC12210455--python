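"""End-to-end orchestration: candidates -> conservation -> regions ->
silencing -> genomic context, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, candidates as cand, context as ctx, io as gio
from . import regions as reg, silencing as sil

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All module thresholds plus the run seed.

    Keys in a config file use a module-prefixed flat namespace, e.g.
    ``candidate_calling.evalue_cutoff = 0.001``; unknown keys are errors.
    """

    min_orf_nt: int = 150
    evalue_cutoff: float = 0.001
    vote_window: int = 10
    self_genus: str = "Amoebozoon"
    merge_slack: int = 0
    hallmark_evalue: float = 1e-5
    methylation_threshold: float = 0.05
    min_coverage: int = 5
    methylation_window: int = 5000
    methylation_step: int = 1000
    coverage_window: int = 2500
    telomere_unit: str = "TTAGGG"
    telomere_max_mismatch: int = 1
    telomere_min_units: int = 3
    link_k: int = 15
    link_min_bp: int = 500
    link_min_identity: float = 80.0
    end_bias_permutations: int = 1000
    compaction_permutations: int = 500
    seed: int = 0

    _KEYMAP = {
        "candidate_calling.min_orf_nt": "min_orf_nt",
        "candidate_calling.evalue_cutoff": "evalue_cutoff",
        "candidate_calling.vote_window": "vote_window",
        "candidate_calling.self_genus": "self_genus",
        "conservation_regions.merge_slack": "merge_slack",
        "conservation_regions.hallmark_evalue": "hallmark_evalue",
        "silencing_profile.methylation_threshold": "methylation_threshold",
        "silencing_profile.min_coverage": "min_coverage",
        "silencing_profile.methylation_window": "methylation_window",
        "silencing_profile.methylation_step": "methylation_step",
        "silencing_profile.coverage_window": "coverage_window",
        "genome_context.telomere_unit": "telomere_unit",
        "genome_context.telomere_max_mismatch": "telomere_max_mismatch",
        "genome_context.telomere_min_units": "telomere_min_units",
        "genome_context.link_k": "link_k",
        "genome_context.link_min_bp": "link_min_bp",
        "genome_context.link_min_identity": "link_min_identity",
        "genome_context.end_bias_permutations": "end_bias_permutations",
        "genome_context.compaction_permutations": "compaction_permutations",
        "pipeline.seed": "seed",
    }

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        cfg = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in cls._KEYMAP:
                    raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
                attr = cls._KEYMAP[key]
                current = getattr(cfg, attr)
                if isinstance(current, bool):
                    setattr(cfg, attr, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, attr, int(value))
                elif isinstance(current, float):
                    setattr(cfg, attr, float(value))
                else:
                    setattr(cfg, attr, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        positive = ["min_orf_nt", "evalue_cutoff", "vote_window", "hallmark_evalue",
                    "methylation_threshold", "min_coverage", "methylation_window",
                    "methylation_step", "coverage_window", "telomere_min_units",
                    "link_k", "link_min_bp"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise PipelineError(f"config {name} must be positive")
        if self.merge_slack < 0:
            raise PipelineError("merge_slack must be >= 0")
        if not 0 < self.methylation_threshold < 1:
            raise PipelineError("methylation_threshold must be in (0, 1)")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return wrapper
    return deco


@dataclass
class StrainInputs:
    strain: str
    fasta: str
    gff: str
    hits: str
    counts: str
    methylation: str
    coverage: str
    repeats: str | None = None
    hallmarks: str | None = None
    hic: list[str] = field(default_factory=list)


def discover_inputs(data_dir: str) -> dict:
    """Locate the evidence files written by the simulator in one directory."""
    d = lambda name: os.path.join(data_dir, name)
    inputs = {"taxonomy": d("taxonomy.tsv"), "blocks": d("blocks.tsv"),
              "diff": d("diff.tsv"), "strains": {}}
    for strain in ("A", "B"):
        si = StrainInputs(
            strain=strain, fasta=d(f"{strain}.fasta"),
            gff=d(f"{strain}.genes.gff3"), hits=d(f"{strain}.hits.tsv"),
            counts=d(f"{strain}.counts.tsv"),
            methylation=d(f"{strain}.methylation.tsv"),
            coverage=d(f"{strain}.coverage.bedgraph"),
            repeats=d(f"{strain}.repeats.bed"),
            hallmarks=d(f"{strain}.hallmarks.tsv"),
            hic=sorted(glob.glob(d(f"{strain}.hic.*.tsv"))))
        for path in (si.fasta, si.gff, si.hits, si.counts, si.methylation,
                     si.coverage):
            if not os.path.exists(path):
                raise PipelineError(f"missing required input {path}")
        if not os.path.exists(si.repeats):
            si.repeats = None
        if not os.path.exists(si.hallmarks):
            si.hallmarks = None
        inputs["strains"][strain] = si
    return inputs


# ---------------------------------------------------------------------------
# per-strain analysis

@_stage("candidate_calling")
def _run_candidates(seqs, genes, hits, taxonomy, cfg):
    thresholds = cand.CallingThresholds(
        min_orf_nt=cfg.min_orf_nt, evalue_cutoff=cfg.evalue_cutoff,
        vote_window=cfg.vote_window, self_genus=cfg.self_genus)
    orfs = cand.extract_intergenic_orfs(seqs, genes, thresholds)
    table, summary = cand.call_all_candidates(genes + orfs, hits, taxonomy, thresholds)
    return orfs, table, summary


@_stage("conservation_regions")
def _run_regions(table, blocks, diff, strain, side, hallmarks, cfg):
    with_status = reg.classify_all(table, blocks, diff, strain, strain_side=side)
    summary = reg.summarize_conservation(with_status)["all"]
    regions = reg.build_divergent_regions(diff[diff["strain"] == strain],
                                          merge_slack=cfg.merge_slack)
    regions = reg.flag_viral_regions(regions, table)
    hm = (reg.hallmark_completeness(regions, hallmarks, cfg.hallmark_evalue)
          if hallmarks is not None else pd.DataFrame())
    return with_status, summary, regions, hm


@_stage("silencing_profile")
def _run_silencing(meth_sites, genes_df, counts, coverage, chrom_lengths,
                   candidate_ids, status_by_gene, cfg):
    combined = sil.combine_cpg_strands(meth_sites)
    gm = sil.gene_methylation_table(combined, genes_df,
                                    min_coverage=cfg.min_coverage,
                                    threshold=cfg.methylation_threshold)
    tpm = sil.compute_tpm(counts.rename(columns={"count": "count"}))
    mtrack = sil.methylation_track(combined, chrom_lengths,
                                   window_bp=cfg.methylation_window,
                                   step_bp=cfg.methylation_step)
    ctrack = sil.coverage_track(coverage, chrom_lengths,
                                window_bp=cfg.coverage_window)
    labels = genes_df[["gene_id"]].copy()
    labels["category"] = np.where(labels["gene_id"].isin(candidate_ids),
                                  "viral", "non_viral")
    frac_viral = sil.methylated_fraction_by_category(gm, labels)
    labels2 = labels.copy()
    labels2["category"] = labels2["gene_id"].map(status_by_gene).fillna("unresolved")
    frac_cons = sil.methylated_fraction_by_category(
        gm, labels2[labels2["category"].isin(["conserved", "non_conserved"])])
    tpm_by_gene = tpm.set_index("gene_id")["log2_tpm1"]
    groups = {}
    for name, sel in (("viral", labels["category"] == "viral"),
                      ("non_viral", labels["category"] == "non_viral")):
        vals = tpm_by_gene.reindex(labels.loc[sel, "gene_id"]).dropna().to_numpy()
        if len(vals) >= 2:
            groups[name] = vals
    comps = sil.compare_categories(groups) if len(groups) == 2 else []
    return gm, tpm, mtrack, ctrack, frac_viral, frac_cons, comps


@_stage("genome_context")
def _run_context(seqs, regions_df, repeats, hic_paths, chrom_lengths, rng, cfg):
    out = {}
    tel_rows = []
    for chrom, seq in seqs.items():
        for a in ctx.detect_telomeric_arrays(
                seq, chrom, cfg.telomere_unit, cfg.telomere_max_mismatch,
                cfg.telomere_min_units):
            tel_rows.append(dataclasses.asdict(a))
    out["telomeres"] = pd.DataFrame(tel_rows)
    viral = regions_df[regions_df["is_viral"]]
    if len(viral):
        out["end_bias"] = ctx.end_distance_enrichment(
            viral, chrom_lengths, n_permutations=cfg.end_bias_permutations,
            seed=rng)
    else:
        out["end_bias"] = {"p_value": None, "n_features": 0}
    # mobile-element context table
    if repeats is not None and len(repeats):
        contexts = []
        other = regions_df[~regions_df["is_viral"]]
        for r in repeats.itertuples():
            mid = (r.start + r.end) // 2
            in_viral = ((viral["chromosome"] == r.chromosome)
                        & (viral["start"] <= mid) & (viral["end"] > mid)).any()
            in_other = ((other["chromosome"] == r.chromosome)
                        & (other["start"] <= mid) & (other["end"] > mid)).any()
            contexts.append("viral_region" if in_viral
                            else "other_divergent" if in_other
                            else "conserved_background")
        table = pd.crosstab(repeats["name"], pd.Series(contexts, name="context"))
        out["mobile_table"] = table
        try:
            out["mobile_chisq"] = ctx.mobile_element_context_chisq(table, seed=rng)
        except ValueError as exc:
            out["mobile_chisq"] = {"error": str(exc)}
    gc_rows = []
    for chrom, seq in seqs.items():
        track, shifts = ctx.gc_shift_track(seq, chrom)
        gc_rows.append((chrom, len(shifts)))
    out["gc_shift_counts"] = dict(gc_rows)
    # similarity links between viral region sequences
    region_seqs = {}
    for r in viral.itertuples():
        seq = seqs.get(r.chromosome)
        if seq is not None:
            region_seqs[r.region_id] = seq[r.start:r.end]
    out["links"] = (ctx.region_similarity_links(
        region_seqs, k=cfg.link_k, min_link_bp=cfg.link_min_bp,
        min_identity=cfg.link_min_identity) if len(region_seqs) >= 2 else [])
    # Hi-C O/E and compaction
    oe_by_chrom, bin_size = {}, None
    for path in hic_paths:
        mat, bs, chrom = gio.read_hic_triplets(path)
        oe_by_chrom[chrom] = ctx.detrend_contact_matrix(mat)
        bin_size = bs
    if oe_by_chrom and len(viral):
        out["compaction"] = ctx.compaction_permutation_test(
            oe_by_chrom, viral, bin_size,
            n_permutations=cfg.compaction_permutations, seed=rng)
        scores = []
        for r in viral.itertuples():
            oe = oe_by_chrom.get(r.chromosome)
            s = (ctx.region_compaction_score(oe, r.start, r.end, bin_size)
                 if oe is not None else None)
            scores.append((r.region_id, s))
        out["compaction_scores"] = dict(scores)
    return out


def run_pipeline(data_dir: str, out_dir: str,
                 config: PipelineConfig | None = None) -> dict:
    """Run every stage on a directory of evidence files; returns per-strain
    reports and writes report/artifact files plus a run manifest."""
    config = config or PipelineConfig()
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    inputs = discover_inputs(data_dir)
    taxonomy = gio.read_taxonomy(inputs["taxonomy"])
    blocks = gio.read_blocks(inputs["blocks"])
    diff = gio.read_diff(inputs["diff"])
    reports = {}
    for strain, si in inputs["strains"].items():
        rng = np.random.default_rng([config.seed, ord(strain)])
        seqs = gio.read_fasta(si.fasta)
        chrom_lengths = {c: len(s) for c, s in seqs.items()}
        genes = gio.read_gff3_genes(si.gff)
        hits = gio.read_hits(si.hits)
        orfs, table, cand_summary = _run_candidates(seqs, genes, hits, taxonomy,
                                                    config)
        hallmarks = (pd.read_csv(si.hallmarks, sep="\t")
                     if si.hallmarks else None)
        side = "ref" if strain == "A" else "query"
        with_status, cons_summary, regions, hm = _run_regions(
            table, blocks, diff, strain, side, hallmarks, config)
        regions_df = reg.regions_to_frame(regions)

        meth = gio.read_bedmethyl(si.methylation)
        counts = gio.read_counts(si.counts)
        coverage = gio.read_bedgraph(si.coverage)
        genes_df = pd.DataFrame([{
            "gene_id": g.id, "chromosome": g.chromosome, "start": g.start,
            "end": g.end} for g in genes])
        status_by_gene = dict(zip(with_status["gene_id"],
                                  with_status["conservation_status"]))
        gm, tpm, mtrack, ctrack, frac_viral, frac_cons, comps = _run_silencing(
            meth, genes_df, counts, coverage, chrom_lengths,
            set(table["gene_id"]), status_by_gene, config)

        repeats = gio.read_bed(si.repeats) if si.repeats else None
        context = _run_context(seqs, regions_df, repeats, si.hic, chrom_lengths,
                               rng, config)

        # integrated region table
        region_rows = []
        for r in regions_df.itertuples():
            msel = mtrack[(mtrack["chromosome"] == r.chromosome)
                          & (mtrack["start"] >= r.start) & (mtrack["end"] <= r.end)]
            region_rows.append({
                "region_id": r.region_id, "chromosome": r.chromosome,
                "start": r.start, "end": r.end, "is_viral": bool(r.is_viral),
                "n_full_viral_genes": int(r.n_full_viral_genes),
                "methylation_mean": float(msel["value"].mean())
                if len(msel.dropna()) else None,
                "compaction_score": context.get("compaction_scores", {}).get(
                    r.region_id),
                "end_distance": min(r.start, chrom_lengths[r.chromosome] - r.end),
            })
        region_table = pd.DataFrame(region_rows)

        prefix = os.path.join(out_dir, strain)
        table.to_csv(f"{prefix}.candidates.tsv", sep="\t", index=False)
        with_status.to_csv(f"{prefix}.candidates.status.tsv", sep="\t", index=False)
        region_table.to_csv(f"{prefix}.regions.tsv", sep="\t", index=False)
        gm.to_csv(f"{prefix}.gene_methylation.tsv", sep="\t", index=False)
        tpm.to_csv(f"{prefix}.tpm.tsv", sep="\t", index=False)
        gio.write_bedgraph(mtrack.dropna(), f"{prefix}.methylation_track.bedgraph")
        gio.write_bedgraph(ctrack, f"{prefix}.coverage_track.bedgraph")

        reports[strain] = {
            "strain": strain,
            "candidates": cand_summary,
            "conservation": cons_summary,
            "n_intergenic_orfs": len(orfs),
            "n_regions": len(regions_df),
            "n_viral_regions": int(regions_df["is_viral"].sum()),
            "hallmark_full_suite_any": bool(hm["full_suite"].any()) if len(hm) else False,
            "methylated_fraction_viral": frac_viral.to_dict(orient="records"),
            "methylated_fraction_conservation": frac_cons.to_dict(orient="records"),
            "expression_comparisons": [dataclasses.asdict(c) for c in comps],
            "end_bias": context["end_bias"],
            "mobile_chisq": context.get("mobile_chisq"),
            "n_links": len(context["links"]),
            "compaction": context.get("compaction"),
            "n_telomere_arrays": len(context["telomeres"]),
        }

    manifest = {
        "gevescan_version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {
            os.path.basename(p): _sha256(p)
            for p in sorted(glob.glob(os.path.join(data_dir, "*")))
            if os.path.isfile(p)},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True, default=str)
    return reports


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(data_dir: str) -> dict:
    """Check format dialects, coordinate bounds, taxonomy coverage and CpG
    positions.  Returns {"fatal": [...], "warnings": [...]}."""
    fatal, warnings = [], []
    try:
        inputs = discover_inputs(data_dir)
    except PipelineError as exc:
        return {"fatal": [str(exc)], "warnings": []}
    try:
        taxonomy = gio.read_taxonomy(inputs["taxonomy"])
    except Exception as exc:
        return {"fatal": [f"taxonomy: {exc}"], "warnings": []}
    try:
        gio.read_blocks(inputs["blocks"])
        gio.read_diff(inputs["diff"])
    except Exception as exc:
        fatal.append(f"alignment: {exc}")
    for strain, si in inputs["strains"].items():
        try:
            seqs = gio.read_fasta(si.fasta)
            genes = gio.read_gff3_genes(si.gff)
        except Exception as exc:
            fatal.append(f"{strain}: {exc}")
            continue
        for g in genes:
            if g.chromosome not in seqs or g.end > len(seqs[g.chromosome]):
                fatal.append(f"{strain}: gene {g.id} outside chromosome bounds")
                break
        try:
            hits = gio.read_hits(si.hits)
            known = set(taxonomy["sseqid"])
            miss = set(hits["sseqid"]) - known
            if miss:
                warnings.append(
                    f"{strain}: {len(miss)} hit subjects lack taxonomy")
        except Exception as exc:
            fatal.append(f"{strain} hits: {exc}")
        try:
            meth = gio.read_bedmethyl(si.methylation)
            bad = 0
            for chrom, grp in meth.groupby("chromosome"):
                seq = seqs.get(chrom)
                if seq is None:
                    fatal.append(f"{strain}: methylation on unknown {chrom}")
                    continue
                arr = np.frombuffer(seq.encode(), dtype=np.uint8)
                pos = grp["position"].to_numpy()
                plus = grp["strand"].to_numpy() == "+"
                cpos = np.where(plus, pos, pos - 1)
                valid = (cpos >= 0) & (cpos + 1 < len(arr))
                okc = np.zeros(len(pos), dtype=bool)
                okc[valid] = ((arr[cpos[valid]] == ord("C"))
                              & (arr[cpos[valid] + 1] == ord("G")))
                bad += int((~okc).sum())
            if bad:
                warnings.append(
                    f"{strain}: {bad} methylation sites not at CpG positions")
        except Exception as exc:
            fatal.append(f"{strain} methylation: {exc}")
        try:
            gio.read_bedgraph(si.coverage)
        except Exception as exc:
            fatal.append(f"{strain} coverage: {exc}")
    return {"fatal": fatal, "warnings": warnings}
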