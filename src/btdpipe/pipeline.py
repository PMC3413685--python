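"""End-to-end orchestration: simulate -> filter -> assemble (multi-k) ->
homology merge -> coverage/completeness -> enzyme annotation -> target-site
scan, with a machine-readable manifest.

Every stage writes plain-text outputs (FASTA/FASTQ/TSV/JSON) into the run
directory; the manifest records input hashes, thresholds and per-stage
counts, and is byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate, assembler, homology, metrics, readqc, simdata

DEFAULT_K_VALUES = tuple(range(21, 42, 2))

EC_CYCLE = ("1.14.14.1", "2.5.1.18", "3.1.1.1", "3.1.1.7")


@dataclass
class Thresholds:
    min_aa: int = 60
    max_e: float = 1e-5
    mrna_identity: float = 0.95
    mrna_cov: float = 0.80
    targetsite_identity: float = 0.90
    quality_window: int = 35
    quality_min_good: int = 25
    quality_min_q: int = 30


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    base_k: int = 31
    min_count: int = 2  # singleton k-mers are almost surely sequencing errors
    max_paths: int = 16
    min_isotig_length: int = 100
    thresholds: Thresholds = field(default_factory=Thresholds)
    protein_db_identity: float = 0.75
    enzyme_gene_fraction: float = 0.4
    n_target_genes: int = 2
    n_known_mrnas: int = 3
    target_divergence: float = 0.03

    def validate(self) -> None:
        if self.base_k not in self.k_values:
            raise ValueError(f"base_k={self.base_k} not in k_values {self.k_values}")
        for k in self.k_values:
            if k % 2 == 0:
                raise ValueError(f"k values must be odd (got {k})")
        t = self.thresholds
        if not (0 < t.mrna_identity <= 1 and 0 < t.mrna_cov <= 1 and 0 < t.targetsite_identity <= 1):
            raise ValueError("identity/coverage thresholds must lie in (0, 1]")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simdata.SimConfig(**raw.pop("sim", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        cfg = cls(sim=sim, thresholds=thresholds, **raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[i] = [b for b in "ACGT" if b != arr[i]][int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_study(config: PipelineConfig) -> dict:
    """Build the synthetic study inputs: transcriptome with planted enzyme
    motifs, reads, homologue protein database, EC-tagged enzyme subset,
    known-mRNA set and diverged target-site references."""
    rng = np.random.default_rng(config.sim.seed + 17)
    transcripts = simdata.generate_transcriptome(config.sim)
    genes = sorted({t.gene_id for t in transcripts})
    n_enzyme = int(round(config.enzyme_gene_fraction * len(genes)))
    enzyme_ec = {g: EC_CYCLE[i % len(EC_CYCLE)] for i, g in enumerate(genes[:n_enzyme])}
    library = annotate.default_motif_library()
    planted = []
    for t in transcripts:
        ec = enzyme_ec.get(t.gene_id)
        if ec is None:
            planted.append(t)
            continue
        pattern = library[ec][0]
        planted.append(
            simdata.plant_motif(t, pattern, seed=int(rng.integers(0, 2**31)))
        )
    transcripts = planted
    pairs = simdata.simulate_reads(transcripts, config.sim)
    protein_db = simdata.build_protein_db(
        transcripts, config.protein_db_identity, seed=config.sim.seed + 29,
        min_orf_aa=config.sim.min_orf_aa,
    )
    enzyme_db = {
        pid: (seq, enzyme_ec[pid.removeprefix("prot_")])
        for pid, seq in protein_db.items()
        if pid.removeprefix("prot_") in enzyme_ec
    }
    by_gene: dict[str, simdata.TranscriptModel] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, t)
    target_genes = genes[-config.n_target_genes :] if config.n_target_genes else []
    references = {
        f"ref_{g}": _mutate_nt(by_gene[g].sequence, config.target_divergence, rng)
        for g in target_genes
    }
    known = {
        f"mrna_{g}": by_gene[g].sequence for g in genes[: config.n_known_mrnas]
    }
    return {
        "transcripts": transcripts,
        "pairs": pairs,
        "protein_db": protein_db,
        "enzyme_db": enzyme_db,
        "enzyme_ec": enzyme_ec,
        "references": references,
        "known_mrnas": known,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and return the manifest (also written to
    ``manifest.json`` in the run directory)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    manifest: dict = {"thresholds": asdict(t), "k_values": list(config.k_values),
                      "base_k": config.base_k, "seed": config.sim.seed}

    study = simulate_study(config)
    transcripts, pairs = study["transcripts"], study["pairs"]
    simdata.write_transcripts_fasta(transcripts, out / "transcripts.fa")
    simdata.write_fasta(study["protein_db"], out / "protein_db.fa")
    with open(out / "enzyme_db.fa", "w") as fh:
        for pid, (seq, ec) in sorted(study["enzyme_db"].items()):
            fh.write(f">{pid} EC={ec}\n{seq}\n")
    simdata.write_fasta(study["references"], out / "target_references.fa")
    simdata.write_fasta(study["known_mrnas"], out / "known_mrnas.fa")
    readqc.write_fastq((p.read1 for p in pairs), out / "reads_1.fq")
    readqc.write_fastq((p.read2 for p in pairs), out / "reads_2.fq")
    simdata.write_truth_tables(transcripts, pairs, out)
    manifest["inputs"] = {
        name: _sha256(out / name)
        for name in ("reads_1.fq", "reads_2.fq", "protein_db.fa", "enzyme_db.fa")
    }
    manifest["simulate"] = {
        "n_genes": len({x.gene_id for x in transcripts}),
        "n_transcripts": len(transcripts),
        "n_read_pairs": len(pairs),
    }

    # --- read filtering -------------------------------------------------
    kept_pairs, singles, report = readqc.filter_pairs(
        ((p.read1, p.read2) for p in pairs),
        adapters=[config.sim.adapter],
        window=t.quality_window, min_good=t.quality_min_good, min_q=t.quality_min_q,
    )
    readqc.write_filtered(kept_pairs, singles, out)
    manifest["readqc"] = {
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "n_paired_retained": report.n_paired_retained,
        "n_single_retained": report.n_single_retained,
        "total_retained_length": report.total_retained_length,
        "rejection_tally": dict(sorted(report.rejection_tally.items())),
    }
    retained_seqs = [r.bases for p in kept_pairs for r in p] + [r.bases for r in singles]

    # --- multi-k assembly + homology assignment -------------------------
    pindex = homology.ProteinIndex(study["protein_db"])
    per_k_isotigs: dict[int, list[assembler.Isotig]] = {}
    assignments: dict[str, str | None] = {}
    assignment_objs: dict[str, homology.HomologueAssignment] = {}
    manifest["assembly"] = {}
    for k in config.k_values:
        graph = assembler.build_graph(retained_seqs, k)
        contigs = assembler.extract_contigs(graph, min_count=config.min_count)
        isotigs, _ = assembler.build_isotigs(
            graph, contigs, max_paths=config.max_paths,
            min_length=config.min_isotig_length,
        )
        per_k_isotigs[k] = isotigs
        with open(out / f"isotigs.k{k}.fa", "w") as fh:
            for it in isotigs:
                fh.write(f">{it.isotig_id}\n{it.sequence}\n")
        for it in isotigs:
            a = homology.assign_best_homologue(
                it.isotig_id, it.sequence, pindex, min_aa=t.min_aa, max_e=t.max_e
            )
            assignments[it.isotig_id] = a.subject_id if a else None
            if a:
                assignment_objs[it.isotig_id] = a
        stats = assembler.assembly_stats([it.sequence for it in isotigs])
        manifest["assembly"][str(k)] = {
            "n_contigs": len(contigs),
            "n_isotigs": len(isotigs),
            "n50": stats["n50"],
            "total_length": stats["total_length"],
            "n_with_homologue": sum(
                1 for it in isotigs if assignments[it.isotig_id] is not None
            ),
        }

    merged, tally = homology.merge_multi_k(per_k_isotigs, assignments, base_k=config.base_k)
    merged_seqs = {it.isotig_id: it.sequence for it in merged}
    with open(out / "isotigs.merged.fa", "w") as fh:
        for iid in sorted(merged_seqs):
            fh.write(f">{iid}\n{merged_seqs[iid]}\n")
    manifest["merge"] = {
        "n_merged_isotigs": len(merged),
        "additional_subjects_per_k": {str(k): v for k, v in sorted(tally.items())},
    }

    # --- known-mRNA validation ------------------------------------------
    validation = homology.validate_against_known(
        merged_seqs, study["known_mrnas"],
        min_identity=t.mrna_identity, min_cov=t.mrna_cov,
    )
    _write_tsv(out / "validation.tsv", validation)
    manifest["validation"] = {
        "n_known_mrnas": len(study["known_mrnas"]),
        "n_mrnas_recovered": len({r["mrna_id"] for r in validation}),
        "n_passing_isotigs": len({r["isotig_id"] for r in validation}),
    }

    # --- coverage and completeness --------------------------------------
    all_reads = [r for p in kept_pairs for r in p] + list(singles)
    profiles, mapstats = metrics.map_reads(merged_seqs, all_reads)
    coverages = {iid: prof.mean_depth for iid, prof in profiles.items()}
    with open(out / "coverage.tsv", "w") as fh:
        fh.write("isotig_id\tlength\tmean_depth\n")
        for iid in sorted(coverages):
            fh.write(f"{iid}\t{len(merged_seqs[iid])}\t{coverages[iid]:.4f}\n")
    records = [
        metrics.completeness(a, study["protein_db"], coverage=coverages.get(iid, 0.0))
        for iid, a in sorted(assignment_objs.items())
        if iid in merged_seqs
    ]
    manifest["coverage"] = {
        "n_reads_mapped": mapstats.n_mapped,
        "n_reads_unmapped": mapstats.n_unmapped,
    }
    if records:
        summary = metrics.completeness_coverage_summary(records)
        _write_tsv(out / "completeness_bins.tsv", summary)
        manifest["completeness"] = {
            "n_records": len(records),
            "n_ge_80pct": sum(1 for r in records if r.completeness > 0.8),
        }

    # --- enzyme prediction ----------------------------------------------
    library = annotate.default_motif_library()
    enzseqs = {sid: s for sid, (s, _) in study["enzyme_db"].items()}
    ez_index = homology.ProteinIndex(enzseqs) if enzseqs else None
    predictions = []
    for iid in sorted(merged_seqs):
        if ez_index is None:
            break
        pred = annotate.predict_ec(
            iid, merged_seqs[iid], study["enzyme_db"], library,
            min_aa=t.min_aa, max_e=t.max_e, index=ez_index,
        )
        if pred:
            predictions.append(pred)
    lengths = {iid: len(s) for iid, s in merged_seqs.items()}
    deduped = annotate.dedupe_by_coverage(predictions, coverages, lengths)
    clusters, tally_table = annotate.collapse_genes(deduped, coverages)
    _write_tsv(
        out / "ec_predictions.tsv",
        [
            {
                "isotig_id": p.isotig_id,
                "ec_number": p.ec_number,
                "subject_id": p.source_hit.subject_id,
                "evalue": p.source_hit.evalue,
                "motif_confirmed": p.motif_confirmed,
                "resolved": p.resolved,
            }
            for p in deduped
        ],
    )
    _write_tsv(out / "gene_tally.tsv", tally_table)
    manifest["annotate"] = {
        "n_ec_predictions": len(predictions),
        "n_after_dedupe": len(deduped),
        "n_gene_clusters": len(clusters),
        "n_motif_confirmed": sum(1 for p in deduped if p.motif_confirmed),
    }

    # --- target-site discovery ------------------------------------------
    target_rows = homology.translated_scan(
        merged_seqs, study["references"],
        min_identity=t.targetsite_identity, max_e=t.max_e,
    )
    _write_tsv(out / "target_sites.tsv", target_rows)
    manifest["target_sites"] = {
        "n_references": len(study["references"]),
        "n_hits_above_identity": sum(1 for r in target_rows if r["above_threshold"]),
        "n_references_recovered": len(
            {r["reference"] for r in target_rows if r["above_threshold"]}
        ),
    }

    # invariants the manifest must satisfy
    assert manifest["readqc"]["n_retained"] == (
        manifest["readqc"]["n_paired_retained"] + manifest["readqc"]["n_single_retained"]
    )
    assert manifest["merge"]["n_merged_isotigs"] >= manifest["assembly"][str(config.base_k)]["n_isotigs"]
    assert manifest["annotate"]["n_gene_clusters"] <= manifest["annotate"]["n_after_dedupe"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Headline experiments (reused by the test suite and the acceptance script)


def reconstruction_experiment(
    n_transcripts: int = 200, k: int = 31, depth: int = 30, seed: int = 0
) -> dict:
    """Exact-recovery rate of the assembler on error-free tiling reads.

    Transcripts are random (so k-mer sharing between genes is negligible),
    reads tile each transcript end to end at the given depth, and a
    transcript counts as recovered when some isotig equals it exactly
    (up to reverse complement).
    """
    cfg = simdata.SimConfig(
        n_genes=n_transcripts, isoform_probability=0.0, error_rate=0.0,
        adapter_rate=0.0, n_rate=0.0, cds_codons_min=100, cds_codons_max=300,
        seed=seed,
    )
    transcripts = simdata.generate_transcriptome(cfg)
    reads = simdata.tile_reads(transcripts, read_length=cfg.read_length, depth=depth)
    graph = assembler.build_graph(reads, k)
    contigs = assembler.extract_contigs(graph, min_count=1)
    isotigs, _ = assembler.build_isotigs(graph, contigs)
    assembled = {min(it.sequence, assembler.revcomp(it.sequence)) for it in isotigs}
    recovered = sum(
        1
        for t in transcripts
        if min(t.sequence, assembler.revcomp(t.sequence)) in assembled
    )
    return {
        "n_transcripts": len(transcripts),
        "n_isotigs": len(isotigs),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(transcripts),
    }


def completeness_coverage_experiment(
    n_genes: int = 500, n_fragments: int = 20_000, seed: int = 11
) -> dict:
    """Assemble a lognormal-expression simulation and relate assembly
    completeness to read coverage.

    The fragment count puts mean depth near 10x so that, under the wide
    lognormal expression law, completeness actually spans its range:
    poorly expressed genes fragment, well expressed ones assemble fully.
    Returns the per-bin summary plus paired per-gene (expression,
    estimated coverage) series for rank-correlation analysis.
    """
    cfg = simdata.SimConfig(
        n_genes=n_genes, isoform_probability=0.0, error_rate=0.0,
        adapter_rate=0.0, n_rate=0.0, cds_codons_min=100, cds_codons_max=300,
        n_fragments=n_fragments, seed=seed,
    )
    transcripts = simdata.generate_transcriptome(cfg)
    pairs = simdata.simulate_reads(transcripts, cfg)
    reads = [p.read1.bases for p in pairs] + [p.read2.bases for p in pairs]
    graph = assembler.build_graph(reads, 31)
    contigs = assembler.extract_contigs(graph, min_count=1)
    isotigs, _ = assembler.build_isotigs(graph, contigs, min_length=100)
    protein_db = simdata.build_protein_db(transcripts, 0.75, seed=seed + 1)
    index = homology.ProteinIndex(protein_db)
    seqs = {it.isotig_id: it.sequence for it in isotigs}
    assignments = {}
    for iid in sorted(seqs):
        a = homology.assign_best_homologue(iid, seqs[iid], index)
        if a:
            assignments[iid] = a
    profiles, mapstats = metrics.map_reads(seqs, reads)
    coverages = {iid: p.mean_depth for iid, p in profiles.items()}
    records = [
        metrics.completeness(a, protein_db, coverage=coverages[iid])
        for iid, a in sorted(assignments.items())
    ]
    table = metrics.completeness_coverage_summary(records)
    expression = {f"prot_{t.gene_id}": t.expression for t in transcripts}
    best: dict[str, tuple[int, float]] = {}
    for iid, a in assignments.items():
        L = len(seqs[iid])
        if a.subject_id not in best or L > best[a.subject_id][0]:
            best[a.subject_id] = (L, coverages[iid])
    genes = sorted(set(expression) & set(best))
    return {
        "records": records,
        "table": table,
        "bin_indices": [row["bin_index"] for row in table],
        "bin_medians": [row["median_coverage"] for row in table],
        "gene_expression": [expression[g] for g in genes],
        "gene_coverage": [best[g][1] for g in genes],
        "n_isotigs": len(isotigs),
        "n_assigned": len(assignments),
        "n_reads_mapped": mapstats.n_mapped,
    }


def _write_tsv(path: Path, rows: list[dict]) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("\n")
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
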