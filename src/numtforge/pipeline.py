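"""End-to-end orchestration: scan -> cluster -> frame-classify -> dN/dS ->
trees -> codon-model fits, with tabular reports and a reproducibility manifest.

Reports mirror the shapes a numt survey publishes: a per-numt discovery table
(scaffold, fragments, length, mitochondrial origin), a per-gene dN/dS table
restricted to intact-mitochondrial-frame genes, Newick trees for genes whose
numt copies carry more than ``min_substitutions`` changes, and a model/LRT
table for the codon selection analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import divergence, numt_discovery, phylo, selection_models
from .divergence import CodonAlignment, pairwise_dnds
from .phylo import distance_matrix, label_numt_clade, neighbor_joining, write_newick
from .seqio_codes import (
    SeqRecord,
    VERTEBRATE_MITO_CODE,
    classify_reading_frame,
    read_fasta,
    reverse_complement,
    write_intervals,
)
from .selection_models import CodonMSA, CodonModelSpec, fit, lrt
from .synthetic_data import GeneAnnotation, default_landscape

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "classify_numt_age",
    "best_orientation_report",
]

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("one_ratio", "two_ratio", "two_ratio_fixed")
STANDARD_LRTS = (
    ("one_ratio", "two_ratio"),
    ("two_ratio_fixed", "two_ratio"),
    ("two_ratio", "cladeC"),
    ("M1a", "cladeC"),
    ("M2a", "cladeC"),
    ("cladeC_fixed", "cladeC"),
)


@dataclass
class PipelineConfig:
    """All knobs of the analysis; defaults are the package's study settings."""

    mito_fasta: str | None = None
    nuclear_fasta: str | None = None
    annotation_gff: str | None = None
    comparison_fastas: list = field(default_factory=list)
    simulate: bool = False           # generate the default synthetic landscape
    out_dir: str = "numtforge_out"
    word_size: int = 20
    min_len: int = 200
    cluster_gap: int = 10000
    e_cutoff: float = 0.01
    min_substitutions: int = 5       # "> 5 substitutions" follow-up trigger
    ds_high: float = 1.0             # ancient-insertion dS threshold
    ds_low: float = 0.1              # recent-insertion dS threshold
    models: tuple = DEFAULT_MODELS
    seed: int = 0

    def __post_init__(self):
        for name in ("word_size", "min_len", "cluster_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.models) - set(selection_models.MODEL_KINDS)
        if bad:
            raise ValueError(f"unsupported models: {sorted(bad)}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)  # name -> {counts, outputs, sha256}
    started: float = 0.0
    finished: float = 0.0
    failed_stage: str | None = None

    def record(self, stage: str, counts: dict, outputs: list):
        self.stages[stage] = {
            "counts": counts,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_gff_genes(path) -> list:
    genes = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] not in ("CDS", "gene"):
            continue
        gene_id = "gene"
        for kv in f[8].split(";"):
            if kv.startswith("ID="):
                gene_id = kv[3:]
        genes.append(GeneAnnotation(gene_id, int(f[3]), int(f[4]), f[6]))
    return genes


def best_orientation_report(
    fragment_seq: str,
    gene_seq: str,
    gene_id: str,
    min_identity: float = 0.8,
    min_block: int = 150,
):
    """Frame-classify the fragment against the gene in both orientations;
    returns (report, oriented_fragment_seq) for the homologous orientation.

    The defaults are deliberately stricter than the unit-level classifier:
    a genuine numt gene copy aligns over hundreds of bases at >80% identity,
    whereas chance local alignments between a fragment and an unrelated gene
    rarely exceed a few dozen columns.
    """
    kw = dict(gene_id=gene_id, min_identity=min_identity,
              min_block=min(min_block, len(gene_seq)))
    fwd = classify_reading_frame(fragment_seq, gene_seq, **kw)
    rc = reverse_complement(fragment_seq)
    rev = classify_reading_frame(rc, gene_seq, **kw)
    if fwd.no_homology and rev.no_homology:
        return fwd, fragment_seq
    if rev.no_homology:
        return fwd, fragment_seq
    if fwd.no_homology:
        return rev, rc
    fwd_span = fwd.aligned_gene_end - fwd.aligned_gene_start
    rev_span = rev.aligned_gene_end - rev.aligned_gene_start
    return (fwd, fragment_seq) if fwd_span >= rev_span else (rev, rc)


def _codon_alignment_from_report(report, oriented_frag, gene_seq, gene_id):
    """In-frame gap-free paired alignment over the aligned block.

    Returns (CodonAlignment, gene_codon_start) or None; the start is the
    1-based gene coordinate of the block's first complete codon, used to
    project copies onto shared gene coordinates for the tree stage.
    """
    g0, g1 = report.aligned_gene_start, report.aligned_gene_end
    f0 = report.aligned_fragment_start
    lead = (3 - (g0 - 1) % 3) % 3
    g0 += lead
    f0 += lead
    length = ((g1 - g0 + 1) // 3) * 3
    if length < 30:
        return None
    gene_sub = gene_seq[g0 - 1 : g0 - 1 + length]
    frag_sub = oriented_frag[f0 - 1 : f0 - 1 + length]
    try:
        return CodonAlignment(gene_id, gene_sub, frag_sub, code=VERTEBRATE_MITO_CODE), g0
    except ValueError as exc:
        logger.info("skipping %s: %s", gene_id, exc)
        return None


def classify_numt_age(
    numt, ds, conservation_profiles=None, ds_high: float = 1.0, ds_low: float = 0.1
):
    """Rule-based insertion-age label: (label, rationale).

    Ancient when dS exceeds ``ds_high`` or the numt is present at high query
    cover in every comparison genome; recent when dS is below ``ds_low`` or
    the numt is found only in the focal genome; otherwise intermediate.
    dS takes precedence over cross-genome presence.
    """
    profiles = conservation_profiles or []
    if ds is not None:
        if ds > ds_high:
            return "ancient", f"dS={ds:.4f} > {ds_high} (substantial neutral divergence)"
        if ds < ds_low:
            return "recent", f"dS={ds:.4f} < {ds_low} (little neutral divergence)"
    if profiles:
        covers = [p.query_cover for p in profiles]
        if all(c >= 50.0 for c in covers):
            return "ancient", "present at high query cover in all comparison genomes"
        if all(c == 0.0 for c in covers):
            return "recent", "absent from all comparison genomes (focal-genome only)"
    if ds is None and not profiles:
        return "unclassified", "no dS estimate and no conservation profiles"
    return "intermediate", "dS and/or conservation patterns are intermediate"


def run_pipeline(config: PipelineConfig):
    """Run the full analysis; returns (RunManifest, results dict).

    Every stage appends its row counts and output checksums to the manifest;
    a stage failure is recorded and downstream stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=_version(), started=time.time())
    results: dict = {}

    try:
        # ---- inputs -------------------------------------------------------
        if config.simulate:
            dataset = default_landscape(seed=config.seed)
            mito, annotations, nuclear = dataset.mito, dataset.annotations, dataset.nuclear
            results["truth"] = dataset.events
        else:
            if not (config.mito_fasta and config.nuclear_fasta):
                raise ValueError("mito_fasta and nuclear_fasta required unless simulate=True")
            mito = read_fasta(config.mito_fasta)[0]
            mito.circular = True
            nuclear = read_fasta(config.nuclear_fasta)
            annotations = (
                _read_gff_genes(config.annotation_gff) if config.annotation_gff else []
            )

        # ---- discovery ----------------------------------------------------
        hits = numt_discovery.scan(
            mito, nuclear, word_size=config.word_size, e_cutoff=config.e_cutoff
        )
        kept = numt_discovery.filter_hits(hits, min_length=config.min_len)
        logger.info("scan: %d hits, %d pass the >%d bp filter",
                    len(hits), len(kept), config.min_len)
        numts = numt_discovery.cluster_fragments(kept, max_gap=config.cluster_gap) if kept else []
        numt_tsv = out / "numts.tsv"
        write_intervals(numts, numt_tsv, "TSV")
        write_intervals(numts, out / "numts.bed", "BED")
        manifest.record(
            "discovery",
            {"hits": len(hits), "fragments_kept": len(kept), "numts": len(numts)},
            [numt_tsv, out / "numts.bed"],
        )
        results["numts"] = numts

        scaffold_seq = {r.id: r.seq for r in nuclear}

        # ---- reading frames and dN/dS ------------------------------------
        gene_seqs = {
            a.gene_id: mito.seq[a.start - 1 : a.end] for a in annotations
        }
        dnds_rows = []
        flagged = {}  # gene_id -> list of (taxon_name, in-frame seq)
        n_intact = 0
        for numt in numts:
            for fi, frag in enumerate(numt.fragments, start=1):
                frag_seq = scaffold_seq[numt.scaffold][
                    frag.nuclear_start - 1 : frag.nuclear_end
                ]
                for gene_id, gseq in gene_seqs.items():
                    report, oriented = best_orientation_report(frag_seq, gseq, gene_id)
                    if report.no_homology:
                        continue
                    row = {
                        "numt": numt.id, "fragment": fi, "gene": gene_id,
                        "intact_mito_frame": report.intact_mito_frame,
                        "gap_free": report.gap_free,
                        "mito_internal_stops": report.mito_internal_stops,
                        "nuclear_internal_stops": report.nuclear_internal_stops,
                        "n_substitutions": report.n_substitutions,
                    }
                    if not report.intact_mito_frame:
                        logger.info("dropped %s/%s: frame not intact", numt.id, gene_id)
                        continue
                    n_intact += 1
                    built = _codon_alignment_from_report(report, oriented, gseq, gene_id)
                    if built is None:
                        continue
                    aln, gene_codon_start = built
                    summary = pairwise_dnds(aln)
                    row.update(
                        syn_subs=summary.syn_subs_int,
                        nonsyn_subs=summary.nonsyn_subs_int,
                        dn=summary.dn, ds=summary.ds, omega=summary.omega,
                        p_value=summary.p_value,
                    )
                    dnds_rows.append(row)
                    if summary.n_substitutions > config.min_substitutions:
                        coding_len = (len(gseq) // 3) * 3 - 3  # drop terminal stop
                        block = aln.seq_b[:coding_len - (gene_codon_start - 1)]
                        padded = (
                            "N" * (gene_codon_start - 1)
                            + block
                            + "N" * (coding_len - (gene_codon_start - 1) - len(block))
                        )
                        flagged.setdefault(gene_id, []).append(
                            (f"{numt.id}_f{fi}", padded)
                        )
        dnds_tsv = out / "dnds.tsv"
        _write_dnds(dnds_rows, dnds_tsv)
        manifest.record(
            "dnds",
            {"intact_gene_copies": n_intact, "rows": len(dnds_rows),
             "flagged_genes": len(flagged)},
            [dnds_tsv],
        )
        results["dnds"] = dnds_rows

        # ---- phylogenetics + selection ------------------------------------
        tree_files, selection_rows, lrt_rows = [], [], []
        for gene_id, copies in flagged.items():
            gseq = gene_seqs[gene_id]
            coding_len = (len(gseq) // 3) * 3 - 3
            taxa = [(f"{gene_id}_mt", gseq[:coding_len])] + list(copies)
            if len(taxa) < 3:
                logger.info("gene %s: <3 taxa, skipping tree", gene_id)
                continue
            try:
                dm = distance_matrix([n for n, _ in taxa], [s for _, s in taxa])
                tree = neighbor_joining(dm)
            except ValueError as exc:
                logger.warning("gene %s: tree failed (%s)", gene_id, exc)
                continue
            numt_taxa = [n for n, _ in taxa if n != f"{gene_id}_mt"]
            try:
                tree = label_numt_clade(tree, numt_taxa)
            except ValueError as exc:
                logger.warning("gene %s: %s; selection stage skipped", gene_id, exc)
                tree_path = out / f"tree_{gene_id}.nwk"
                tree_path.write_text(write_newick(tree) + "\n")
                tree_files.append(tree_path)
                continue
            tree_path = out / f"tree_{gene_id}.nwk"
            tree_path.write_text(write_newick(tree) + "\n")
            tree_files.append(tree_path)

            if len(taxa) >= 4 and config.models:
                msa = CodonMSA([n for n, _ in taxa], [s for _, s in taxa])
                fits = {}
                order = [k for k in selection_models.MODEL_KINDS if k in config.models]
                for kind in order:
                    spec = CodonModelSpec(kind, code=VERTEBRATE_MITO_CODE)
                    extra = []
                    if kind == "two_ratio" and "two_ratio_fixed" in fits:
                        prev = fits["two_ratio_fixed"]
                        extra.append(
                            (prev.params, selection_models.fit_lengths(prev))
                        )
                    if kind == "two_ratio" and "one_ratio" in fits:
                        prev = fits["one_ratio"]
                        extra.append(
                            (prev.params, selection_models.fit_lengths(prev))
                        )
                    fits[kind] = fit(
                        tree, msa, spec, seed=config.seed, extra_starts=extra
                    )
                for kind, fr in fits.items():
                    for k in range(len(fr.params.proportions)):
                        selection_rows.append({
                            "gene": gene_id, "model": kind,
                            "site_class": k + 1 if len(fr.params.proportions) > 1 else "/",
                            "proportion": fr.params.proportions[k],
                            "omega_mito": fr.params.omega_background[k],
                            "omega_numt": fr.params.omega_numt[k],
                            "logL": fr.log_likelihood,
                        })
                for null_kind, alt_kind in STANDARD_LRTS:
                    if null_kind in fits and alt_kind in fits:
                        try:
                            r = lrt(fits[null_kind], fits[alt_kind])
                        except ValueError as exc:
                            logger.warning("LRT %s vs %s: %s", null_kind, alt_kind, exc)
                            continue
                        lrt_rows.append({
                            "gene": gene_id, "null": null_kind, "alt": alt_kind,
                            "statistic": r.statistic, "df": r.df, "p_value": r.p_value,
                        })
        sel_tsv = out / "selection.tsv"
        _write_table(
            selection_rows,
            ["gene", "model", "site_class", "proportion", "omega_mito",
             "omega_numt", "logL"],
            sel_tsv,
        )
        lrt_tsv = out / "lrt.tsv"
        _write_table(lrt_rows, ["gene", "null", "alt", "statistic", "df", "p_value"], lrt_tsv)
        manifest.record(
            "selection",
            {"trees": len(tree_files), "model_rows": len(selection_rows),
             "lrts": len(lrt_rows)},
            [sel_tsv, lrt_tsv] + tree_files,
        )
        results["selection"] = selection_rows
        results["lrt"] = lrt_rows

        # ---- age classification -------------------------------------------
        age_rows = []
        ds_by_numt: dict = {}
        for row in dnds_rows:
            if row.get("ds") is not None:
                ds_by_numt.setdefault(row["numt"], []).append(row["ds"])
        for numt in numts:
            ds_vals = ds_by_numt.get(numt.id)
            ds = max(ds_vals) if ds_vals else None
            label, why = classify_numt_age(
                numt, ds, ds_high=config.ds_high, ds_low=config.ds_low
            )
            age_rows.append({"numt": numt.id, "ds": ds, "age_class": label,
                             "rationale": why})
        age_tsv = out / "numt_ages.tsv"
        _write_table(age_rows, ["numt", "ds", "age_class", "rationale"], age_tsv)
        manifest.record("age", {"rows": len(age_rows)}, [age_tsv])
        results["ages"] = age_rows

    except Exception as exc:  # stage failure: record and re-raise
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest, results


def _write_dnds(rows, path):
    cols = ["numt", "fragment", "gene", "syn_subs", "nonsyn_subs",
            "dn", "ds", "omega", "p_value"]
    _write_table(rows, cols, path)


def _fmt(v):
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_table(rows, cols, path):
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(_fmt(r.get(c)) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("numtforge")
    except Exception:
        return "unknown"
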