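"""End-to-end orchestration: structure → repeats → diversity → codon → Ka/Ks.

A single mapping (usually loaded from YAML) configures inputs, stage toggles,
and stage parameters; each stage writes its TSV tables into the output
directory and a run manifest records parameters, input checksums, and the
package version. Reruns with identical config and inputs produce
byte-identical outputs (floats are printed at six significant digits).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from . import codon_bias, diversity, genome_io, repeat_scan, selection

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "min_ir_len": 1000,
    "ssr_thresholds": dict(repeat_scan.DEFAULT_SSR_THRESHOLDS),
    "compound_gap": 100,
    "dispersed_min_len": 30,
    "dispersed_max_mismatch": 3,
    "tandem_min_unit": 7,
    "window": 600,
    "step": 200,
    "hotspot": 0.06,
    "pi_high": 0.02,
    "pi_low": 0.01,
    "variant_bin": 100,
    "distance_model": "K2P",
    "cds_min_len": 300,
    "optimal_top_frac": 0.05,
    "optimal_delta_min": 0.08,
    "kaks_eps": 1e-9,
}

STAGES = ("structure", "repeats", "diversity", "codon", "kaks")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class DependencyError(RuntimeError):
    """A stage needs the outputs of a stage that was toggled off."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def _load_genomes(config: Mapping) -> list[genome_io.GenomeRecord]:
    paths: list[Path] = []
    if config.get("inputs"):
        paths = [Path(p) for p in config["inputs"]]
    elif config.get("input_dir"):
        d = Path(config["input_dir"])
        if not d.is_dir():
            raise ConfigError(f"input_dir {d} does not exist")
        for pat in ("*.gb", "*.gbk", "*.gbff", "*.fasta", "*.fa"):
            paths.extend(sorted(d.glob(pat)))
    if not paths:
        raise ConfigError("no input genomes (set 'inputs' or 'input_dir')")
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    records = []
    seen: set[str] = set()
    for p in paths:
        rec = genome_io.read_annotated_genome(
            p,
            gene_table=config.get("gene_table"),
            group_table=config.get("group_table"),
        )
        if rec.accession in seen:
            continue  # e.g. a FASTA sibling of an already-loaded GenBank file
        seen.add(rec.accession)
        records.append(rec)
    return records


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages and write the full table set.

    Raises :class:`ConfigError` before any stage runs when the configuration
    is invalid, and :class:`DependencyError` when a stage's prerequisite
    stage is disabled. Partial outputs are retained on stage failure.
    """
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params") or {})
    stages = {s: True for s in STAGES}
    stages.update(config.get("stages") or {})
    out = Path(out_dir or config.get("output_dir") or "plastokit_out")
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    t_start = time.time()

    records = _load_genomes(config)
    checksums = {}
    for key in ("inputs", "gene_table", "group_table", "alignment"):
        val = config.get(key)
        if not val:
            continue
        for p in val if isinstance(val, (list, tuple)) else [val]:
            p = Path(p)
            if p.exists():
                checksums[str(p)] = _sha256(p)

    partitions: dict[str, genome_io.RegionPartition] = {}
    canonical: dict[str, genome_io.GenomeRecord] = {}

    if stages.get("structure"):
        t0 = time.time()
        pairs = []
        junction_reports = []
        for rec in records:
            part = genome_io.detect_quadripartite(rec, min_ir_len=params["min_ir_len"])
            rec_c, part_c = genome_io.canonicalize(rec, part)
            canonical[rec.accession] = rec_c
            partitions[rec.accession] = part_c
            pairs.append((rec_c, part_c))
            junction_reports.append(genome_io.analyze_junctions(rec_c, part_c))
            logger.info("stage=structure accession=%s genes=%d", rec.accession, len(rec.genes))
        written["regions"] = str(
            _write_tsv(pd.DataFrame(genome_io.regions_table(pairs)), out / "regions.tsv")
        )
        written["junctions"] = str(
            _write_tsv(pd.DataFrame(genome_io.junctions_table(junction_reports)), out / "junctions.tsv")
        )
        summary = []
        for rec_c, part_c in pairs:
            gc = genome_io.gc_content_by_region(rec_c, part_c)
            kinds = {}
            for g in rec_c.genes:
                kinds[g.kind] = kinds.get(g.kind, 0) + 1
            summary.append(
                {
                    "accession": rec_c.accession,
                    "taxon": rec_c.taxon,
                    "length": rec_c.length,
                    "region_lengths": part_c.lengths(),
                    "gc": gc,
                    "gene_counts": kinds,
                }
            )
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        written["summary"] = str(out / "summary.json")
        logger.info("stage=structure done wall=%.2fs", time.time() - t0)

    if stages.get("repeats"):
        if not partitions:
            raise DependencyError("repeats stage requires the structure stage")
        t0 = time.time()
        ssr_rows, disp_rows, tand_rows = [], [], []
        totals: dict[str, Any] = {"ssr": 0, "dispersed": {k: 0 for k in repeat_scan.REPEAT_KINDS}, "tandem": 0}
        by_region: dict[str, int] = {}
        by_context: dict[str, int] = {}
        for acc, rec in canonical.items():
            part = partitions[acc]
            ssrs = repeat_scan.find_ssrs(rec.sequence, thresholds=params["ssr_thresholds"])
            ssrs = repeat_scan.merge_compound(ssrs, max_gap=params["compound_gap"])
            repeat_scan.localize(ssrs, part, rec.genes, rec.length)
            disp = repeat_scan.find_dispersed(
                rec.sequence,
                min_len=params["dispersed_min_len"],
                max_mismatch=params["dispersed_max_mismatch"],
                ir_mask=(part.irb, part.ira),
            )
            repeat_scan.localize(disp, part, rec.genes, rec.length)
            tand = repeat_scan.find_tandem(rec.sequence, min_unit=params["tandem_min_unit"])
            repeat_scan.localize(tand, part, rec.genes, rec.length)
            for r in ssrs:
                ssr_rows.append(
                    {
                        "accession": acc, "motif": r.motif, "unit_len": r.unit_len,
                        "copies": r.copies, "start": r.start + 1, "end": r.end,
                        "region": r.region, "context": r.context,
                        "compound_id": r.compound_id or "",
                    }
                )
                by_region[r.region] = by_region.get(r.region, 0) + 1
                by_context[r.context] = by_context.get(r.context, 0) + 1
            for r in disp:
                disp_rows.append(
                    {
                        "accession": acc, "kind": r.kind, "length": r.length,
                        "pos1": r.pos1 + 1, "pos2": r.pos2 + 1,
                        "mismatches": r.mismatches, "region": r.region, "context": r.context,
                    }
                )
                totals["dispersed"][r.kind] += 1
            for r in tand:
                tand_rows.append(
                    {
                        "accession": acc, "unit": r.unit, "copies": r.copies,
                        "start": r.start + 1, "end": r.end, "identity": r.identity,
                        "region": r.region, "context": r.context,
                    }
                )
            totals["ssr"] += len(ssrs)
            totals["tandem"] += len(tand)
            logger.info(
                "stage=repeats accession=%s ssr=%d dispersed=%d tandem=%d wall=%.2fs",
                acc, len(ssrs), len(disp), len(tand), time.time() - t0,
            )
        written["ssrs"] = str(_write_tsv(pd.DataFrame(ssr_rows), out / "ssrs.tsv"))
        written["dispersed"] = str(_write_tsv(pd.DataFrame(disp_rows), out / "dispersed.tsv"))
        written["tandem"] = str(_write_tsv(pd.DataFrame(tand_rows), out / "tandem.tsv"))
        n_ssr = max(totals["ssr"], 1)
        totals["ssr_region_frac"] = {k: v / n_ssr for k, v in by_region.items()}
        totals["ssr_context_frac"] = {k: v / n_ssr for k, v in by_context.items()}
        (out / "repeat_summary.json").write_text(json.dumps(totals, indent=1, default=float))
        written["repeat_summary"] = str(out / "repeat_summary.json")

    if stages.get("diversity"):
        aln_path = config.get("alignment")
        if not aln_path:
            raise ConfigError("diversity stage needs an 'alignment' input (aligned FASTA)")
        t0 = time.time()
        aln = diversity.AlignmentMatrix.from_fasta(aln_path)
        windows = diversity.sliding_window_pi(aln, window=params["window"], step=params["step"])
        windows, hotspots = diversity.classify_variability(
            windows, hotspot=params["hotspot"], high=params["pi_high"], low=params["pi_low"]
        )
        written["pi_windows"] = str(_write_tsv(diversity.windows_table(windows), out / "pi_windows.tsv"))
        written["hotspots"] = str(
            _write_tsv(
                pd.DataFrame(
                    [
                        {"start": h.start + 1, "end": h.end, "mean_pi": h.mean_pi, "name": h.name}
                        for h in hotspots
                    ]
                ),
                out / "hotspots.tsv",
            )
        )
        if config.get("reference"):
            vt = diversity.call_variants(aln, config["reference"], bin_size=params["variant_bin"])
            written["variants"] = str(_write_tsv(vt.bins, out / "variants.tsv"))
            written["variants_per_row"] = str(_write_tsv(vt.per_row, out / "variants_per_row.tsv"))
        dm = diversity.genetic_distance(aln, model=params["distance_model"])
        long_rows = []
        for i, a in enumerate(dm.accessions):
            for j, b in enumerate(dm.accessions):
                if i < j:
                    long_rows.append({"a": a, "b": b, "distance": dm.values[i, j], "model": dm.model})
        written["distances"] = str(_write_tsv(pd.DataFrame(long_rows), out / "distances.tsv"))
        dm.to_frame().to_csv(out / "distances_square.tsv", sep="\t", float_format="%.6g")
        written["distances_square"] = str(out / "distances_square.tsv")
        logger.info("stage=diversity windows=%d hotspots=%d wall=%.2fs", len(windows), len(hotspots), time.time() - t0)

    if stages.get("codon"):
        t0 = time.time()
        source = list(canonical.values()) if canonical else records
        counts = codon_bias.extract_cds_set(source, min_len=params["cds_min_len"])
        if not counts:
            raise ConfigError("codon stage found no usable CDS")
        encs = {id(c): codon_bias.enc(c) for c in counts}
        weights_source = sorted(
            counts, key=lambda c: (encs[id(c)] if not math.isnan(encs[id(c)]) else 99.0, c.gene)
        )
        k = max(1, math.ceil(params["optimal_top_frac"] * len(counts)))
        weights = codon_bias.ReferenceWeights.from_counts(
            codon_bias.pooled_counts(weights_source[:k], "reference")
        )
        index_rows, rscu_rows = [], []
        gene_table = []
        for cc in counts:
            iset = codon_bias.compute_indices(cc, weights)
            index_rows.append(iset.as_row())
            gene_table.append((cc, iset.enc))
            for codon, val in sorted(iset.rscu.items()):
                rscu_rows.append(
                    {"accession": cc.accession, "gene": cc.gene, "codon": codon,
                     "aa": codon_bias.CODON_TO_AA[codon], "rscu": val}
                )
        idx_df = pd.DataFrame(index_rows)
        written["indices"] = str(_write_tsv(idx_df, out / "indices.tsv"))
        written["rscu"] = str(_write_tsv(pd.DataFrame(rscu_rows), out / "rscu.tsv"))
        enc_cols = [c for c in ("accession", "gene", "gc3s", "enc", "enc_expected", "enc_deviation", "enc_class") if c in idx_df.columns]
        written["encplot"] = str(_write_tsv(idx_df[enc_cols], out / "encplot.tsv"))
        pr2_cols = [c for c in ("accession", "gene", "pr2_x", "pr2_y") if c in idx_df.columns]
        written["pr2"] = str(_write_tsv(idx_df[pr2_cols], out / "pr2.tsv"))
        try:
            oct_ = codon_bias.optimal_codons(
                gene_table,
                top_frac=params["optimal_top_frac"],
                delta_min=params["optimal_delta_min"],
            )
            written["optimal_codons"] = str(_write_tsv(oct_.table, out / "optimal_codons.tsv"))
        except ValueError as exc:
            logger.warning("optimal-codon screen skipped: %s", exc)
        num_cols = [c for c in ("enc", "gc3s", "cai", "cbi", "fop", "n_codons") if c in idx_df.columns]
        if len(idx_df) >= 3 and num_cols:
            corr, bands = codon_bias.index_correlation(idx_df[num_cols])
            corr.to_csv(out / "correlations.tsv", sep="\t", float_format="%.6g")
            bands.to_csv(out / "correlation_bands.tsv", sep="\t")
            written["correlations"] = str(out / "correlations.tsv")
        logger.info("stage=codon genes=%d wall=%.2fs", len(counts), time.time() - t0)

    if stages.get("kaks"):
        aln_dir = config.get("gene_alignments")
        outgroup = config.get("outgroup")
        if not aln_dir or not outgroup:
            raise ConfigError("kaks stage needs 'gene_alignments' (dir) and 'outgroup'")
        t0 = time.time()
        grouping: dict[str, dict[str, str]] = {}
        if config.get("group_table"):
            grouping = genome_io.read_group_table(config["group_table"])
        gene_classes = None
        if config.get("gene_classes"):
            df = pd.read_csv(config["gene_classes"], sep="\t")
            gene_classes = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        alns = []
        for path in sorted(Path(aln_dir).glob("*.fasta")):
            rows = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
            alns.append(selection.CodonAlignment(path.stem, rows))
        if not alns:
            raise ConfigError(f"no per-gene alignments found in {aln_dir}")
        recs = selection.group_kaks(alns, grouping, outgroup, gene_classes)
        rows = [
            {
                "gene": r.gene, "group": r.group, "level": r.level, "ka": r.ka,
                "ks": r.ks, "omega": r.omega, "selection_class": r.selection_class,
                "n_pairs": r.n_pairs,
            }
            for r in recs
        ]
        df = pd.DataFrame(rows)
        written["kaks_pairs"] = str(_write_tsv(df[df["level"] == "pair"], out / "kaks_pairs.tsv"))
        written["kaks_groups"] = str(_write_tsv(df[df["level"] != "pair"], out / "kaks_groups.tsv"))
        try:
            hist = selection.ks_summary([r for r in recs if r.level == "pair"])
            written["ks_hist"] = str(_write_tsv(hist, out / "ks_hist.tsv"))
        except ValueError as exc:
            logger.warning("ks histogram skipped: %s", exc)
        heat = selection.selection_heatmap(recs, level="tribe")
        heat.to_csv(out / "selection_heatmap.tsv", sep="\t", float_format="%.6g")
        written["selection_heatmap"] = str(out / "selection_heatmap.tsv")
        logger.info("stage=kaks genes=%d wall=%.2fs", len(alns), time.time() - t0)

    logger.info("pipeline done wall=%.2fs", time.time() - t_start)
    manifest = {
        "version": __version__,
        "parameters": params,
        "stages": stages,
        "inputs": checksums,
        "outputs": {k: _sha256(Path(v)) for k, v in written.items()},
        "n_genomes": len(records),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["run_manifest"] = str(out / "run_manifest.json")
    return written
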