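"""End-to-end orchestration: clean -> map/annotate -> conserved -> novel ->
targets -> differential expression -> enrichment, with publication-style TSV
summary tables and a run manifest.

Every stage threshold is a named config key; the defaults are the
conventional values of this pipeline family (-18 kcal/mol hairpin energy,
5-read support, 2 reference mismatches,
score < 4 and seed score <= 2.5 for targets, 75% energy ratio, p and q below
0.05, |log2 ratio| > 1, 18-30 nt clean inserts, 18-25 nt novel candidates).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import conserved as conserved_mod
from . import diffexpr, novel as novel_mod, synthetic_data, tag_mapping, targets as targets_mod
from .io import read_fastq, write_tsv
from .preprocess import CleanConfig, FilterStats, UniqueTag, clean_reads, collapse_tags, length_distribution
from .rna_structure import FOLD_BACKEND
from .synthetic_data import LIBRARIES, ReferenceBundle, SimulationConfig


@dataclass
class PipelineConfig:
    clean: CleanConfig = field(default_factory=CleanConfig)
    map_max_mismatch: int = 1  # "less than two mismatches"
    reference_max_mismatch: int = 2  # miRBase alignment tolerance
    ncrna_max_mismatch: int = 1
    novel: novel_mod.NovelConfig = field(default_factory=novel_mod.NovelConfig)
    de: diffexpr.DEConfig = field(default_factory=diffexpr.DEConfig)
    enrichment_q: float = 0.05
    index_k: int = 6

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(
            clean=CleanConfig(**d.get("clean", {})),
            novel=novel_mod.NovelConfig(**d.get("novel", {})),
            de=diffexpr.DEConfig(**d.get("de", {})),
            **{
                k: v
                for k, v in d.items()
                if k in ("map_max_mismatch", "reference_max_mismatch", "ncrna_max_mismatch", "enrichment_q", "index_k")
            },
        )


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    tags: list[UniqueTag]
    filter_stats: dict[str, FilterStats]
    partition: tag_mapping.CategoryPartition
    family_expressions: list[conserved_mod.FamilyExpression]
    family_reference: dict[str, tuple[str, str]]
    novel_mirnas: list[novel_mod.NovelMiRNA]
    novel_candidates: list[novel_mod.HairpinCandidate]
    target_hits: list[targets_mod.TargetHit]
    target_counts: dict[str, int]
    de_table: pd.DataFrame
    enrichment: pd.DataFrame | None
    venn: dict[str, int]
    library_totals: dict[str, int]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    bundle: ReferenceBundle,
    fastq: dict[str, str | Path],
    out_dir: str | os.PathLike,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run every stage on two FASTQ libraries against a reference bundle.

    ``fastq`` maps library name -> path; the first library is the baseline
    (leaves), the second the focal tissue (trichomes).
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    libs = list(fastq)
    if len(libs) != 2:
        raise ValueError("exactly two libraries required")
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)

        return _T()

    # 1. clean + collapse
    with stage("clean"):
        per_lib_counts: dict[str, dict[str, int]] = {}
        filter_stats: dict[str, FilterStats] = {}
        for lib in libs:
            counts, stats = clean_reads(
                read_fastq(fastq[lib], cfg.clean.phred_offset), cfg.clean, lib
            )
            per_lib_counts[lib] = counts
            filter_stats[lib] = stats
        tags = collapse_tags(per_lib_counts)
        totals = {lib: filter_stats[lib].clean for lib in libs}

    # 2. map to the transcriptome
    with stage("map"):
        index = tag_mapping.build_index(bundle.transcriptome, k=cfg.index_k)
        hits = tag_mapping.map_tags(
            (t.seq for t in tags), index, max_mismatch=cfg.map_max_mismatch
        )
        hits_by_tag: dict[str, list[tag_mapping.TagHit]] = {}
        for h in hits:
            hits_by_tag.setdefault(h.tag, []).append(h)

    # 3. conserved assignment + annotation partition
    with stage("conserved"):
        assignments = conserved_mod.assign_to_families(
            tags, bundle.mirna_mature, bundle.mirna_precursor, cfg.reference_max_mismatch
        )
        partition = tag_mapping.annotate_tags(
            tags,
            {cat: [r.seq for r in recs] for cat, recs in bundle.ncrna.items()},
            assignments,
            libraries=libs,
            max_mismatch=cfg.ncrna_max_mismatch,
        )
        family_reference = conserved_mod.build_family_reference(assignments, tags, bundle.mirna_mature)
        mirna_tags = [t for t in tags if partition.categories[t.seq] == "miRNA"]
        family_expressions = conserved_mod.quantify_families(
            mirna_tags, family_reference, libs, cfg.reference_max_mismatch, totals
        )
        venn = conserved_mod.venn_counts(family_expressions, libs[0], libs[1])

    # 4. novel miRNAs from unannotated mapped tags
    with stage("novel"):
        unannotated = [t for t in tags if partition.categories[t.seq] == "unannotated"]
        support = {t.seq: t.total for t in unannotated}
        unannotated_hits = [h for t in unannotated for h in hits_by_tag.get(t.seq, ())]
        novel_mirnas, novel_candidates, skipped = novel_mod.predict_novel(
            unannotated_hits, {k: v for k, v in index.transcripts.items()}, support, cfg.novel
        )

    # 5. target prediction for identified miRNAs
    with stage("targets"):
        mirna_set: dict[str, str] = {
            f"{fam}": seq for fam, (_rid, seq) in family_reference.items()
        }
        for i, nm in enumerate(novel_mirnas):
            mirna_set[f"novel-mir-{i + 1}"] = nm.mature
        target_hits, target_counts = targets_mod.predict_targets(mirna_set, index.transcripts)

    # 6. differential expression (conserved families + novel matures)
    with stage("de"):
        counts2: dict[str, tuple[int, int]] = {}
        for fe in family_expressions:
            counts2[fe.family] = (fe.counts.get(libs[0], 0), fe.counts.get(libs[1], 0))
        novel_names = {}
        for i, nm in enumerate(novel_mirnas):
            name = f"novel-mir-{i + 1}"
            tag = next((t for t in tags if t.seq == nm.mature), None)
            counts2[name] = (
                tag.count(libs[0]) if tag else 0,
                tag.count(libs[1]) if tag else 0,
            )
            novel_names[name] = nm.mature
        de_table = diffexpr.call_de(counts2, (totals[libs[0]], totals[libs[1]]), cfg.de)

    # 7. enrichment of DE-miRNA target transcripts
    with stage("enrich"):
        enrichment = None
        if bundle.annotation_map:
            de_ids = set(de_table.loc[de_table["call"] != "ns", "id"])
            selected = sorted(
                {
                    h.alignment.transcript_id
                    for h in target_hits
                    if h.accepted and h.alignment.mirna_id in de_ids
                }
            )
            if selected:
                enrichment = diffexpr.enrich_terms(
                    selected, bundle.annotation_map, bundle.transcriptome.keys(), cfg.enrichment_q
                )

    # --- outputs -----------------------------------------------------------------
    with stage("write"):
        files = _write_outputs(
            out, libs, tags, filter_stats, partition, family_expressions, venn,
            novel_mirnas, novel_candidates, target_hits, de_table, enrichment,
        )
    manifest = {
        "seed": seed,
        "libraries": libs,
        "fold_backend": FOLD_BACKEND,
        "de_test": cfg.de.test,
        "timings_s": timings,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        tags=tags,
        filter_stats=filter_stats,
        partition=partition,
        family_expressions=family_expressions,
        family_reference=family_reference,
        novel_mirnas=novel_mirnas,
        novel_candidates=novel_candidates,
        target_hits=target_hits,
        target_counts=target_counts,
        de_table=de_table,
        enrichment=enrichment,
        venn=venn,
        library_totals=totals,
        manifest=manifest,
    )


def _write_outputs(out, libs, tags, filter_stats, partition, family_expressions, venn,
                   novel_mirnas, novel_candidates, target_hits, de_table, enrichment) -> list[str]:
    files: list[str] = []

    def emit(name: str, df: pd.DataFrame, comment: str | None = None) -> None:
        write_tsv(out / name, df, comment)
        files.append(name)

    emit("filter_stats.tsv", pd.DataFrame([filter_stats[lib].as_dict() for lib in libs]))
    emit(
        "tags.tsv",
        pd.DataFrame(
            [
                {"seq": t.seq, "length": t.length, **{f"count_{lib}": t.count(lib) for lib in libs}}
                for t in tags
            ]
        ),
    )
    emit("categories.tsv", partition.summary)
    rows = []
    for lib in libs:
        for length, (n, frac) in length_distribution(tags, lib).items():
            rows.append({"library": lib, "length": length, "reads": n, "fraction": frac})
    emit("length_distribution.tsv", pd.DataFrame(rows))
    emit(
        "conserved_families.tsv",
        pd.DataFrame(
            [
                {
                    "family": fe.family,
                    "representative": fe.representative,
                    **{f"count_{lib}": fe.counts.get(lib, 0) for lib in libs},
                    **{f"tpm_{lib}": fe.tpm.get(lib, 0.0) for lib in libs},
                }
                for fe in family_expressions
            ]
        ),
    )
    emit("venn.tsv", pd.DataFrame([venn]))
    emit(
        "novel_mirnas.tsv",
        pd.DataFrame(
            [
                {
                    "mature": nm.mature,
                    "arm": nm.arm,
                    "support": nm.support,
                    "transcript": nm.best.window.transcript_id,
                    "precursor_start": nm.best.window.start,
                    "precursor_end": nm.best.window.end,
                    "energy": nm.best.fold.energy,
                    "structure": nm.best.fold.structure,
                }
                for nm in novel_mirnas
            ]
        ),
    )
    emit(
        "novel_candidates.tsv",
        pd.DataFrame(
            [
                {
                    "tag": c.window.tag,
                    "transcript": c.window.transcript_id,
                    "window_start": c.window.start,
                    "window_end": c.window.end,
                    "energy": c.fold.energy if c.fold else float("nan"),
                    "arm": c.arm or "",
                    "support": c.support,
                    "accepted": c.accepted,
                    "reason": c.reason,
                }
                for c in novel_candidates
            ]
        ),
    )
    # precursor energy / length histograms for accepted novel miRNAs
    energies = [nm.best.fold.energy for nm in novel_mirnas]
    emit(
        "novel_summary_hist.tsv",
        pd.DataFrame(
            {
                "mature_length": [len(nm.mature) for nm in novel_mirnas],
                "precursor_length": [nm.best.window.end - nm.best.window.start for nm in novel_mirnas],
                "energy": energies,
            }
        ),
    )
    emit(
        "targets.tsv",
        pd.DataFrame(
            [
                {
                    "mirna": h.alignment.mirna_id,
                    "transcript": h.alignment.transcript_id,
                    "site_start": h.alignment.start + 1,  # 1-based inclusive in reports
                    "site_end": h.alignment.end,
                    "score": h.alignment.score,
                    "seed_score": h.alignment.seed_score,
                    "mfe_ratio": round(h.mfe_ratio, 4),
                    "rules": "".join("1" if r else "0" for r in h.rules),
                    "accepted": h.accepted,
                }
                for h in target_hits
            ]
        ),
    )
    emit("de_mirnas.tsv", de_table)
    if enrichment is not None:
        emit("enrichment.tsv", enrichment)
    return files


def run_synthetic(
    out_dir: str | os.PathLike,
    sim_config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[ReferenceBundle, synthetic_data.SimulationResult, PipelineResult]:
    """Simulate the default study and run the full pipeline on it."""
    sim_config = sim_config or SimulationConfig()
    out = Path(out_dir)
    bundle = synthetic_data.generate_reference(sim_config)
    sim = synthetic_data.simulate_libraries(bundle, sim_config, out / "reads")
    cfg = pipeline_config or PipelineConfig(
        clean=CleanConfig(adapter3=sim_config.adapter3, adapter5=sim_config.adapter5,
                          phred_offset=sim_config.phred_offset)
    )
    result = run_pipeline(
        bundle, {lib: sim.fastq[lib] for lib in LIBRARIES}, out / "results", cfg, seed=sim_config.seed
    )
    return bundle, sim, result
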