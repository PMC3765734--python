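"""End-to-end pipeline driver: reference -> extract -> clean -> map -> quantify
-> differential expression -> patterns -> overlaps -> summary, with a
checksummed run manifest so reruns are verifiably reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from . import mapping as dmap
from . import overlap as dov
from . import expression as dex
from . import processing as dproc
from . import reference as dref

log = logging.getLogger("dgetag")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    reference: Path
    libraries: dict[tuple[str, str], Path]  # (species, stage) -> reads/tags path
    outdir: Path
    input_format: str = "auto"  # fastq | tsv | auto (by extension)
    reference_mode: str = "canonical"
    anchor: str = dref.DEFAULT_ANCHOR
    tag_length: int = dref.DEFAULT_TAG_LENGTH
    filter: dproc.FilterConfig = field(default_factory=dproc.FilterConfig)
    ambiguous: str = "count"
    alpha: float = 0.05
    lfc_min: float = 1.0
    venn_universe: str = "tags"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        libs = {
            (lib["species"], lib["stage"]): base / lib["path"]
            for lib in raw["libraries"]
        }
        fcfg = raw.get("filter", {})
        return cls(
            reference=base / raw["reference"],
            libraries=libs,
            outdir=base / raw.get("outdir", "dgetag_out"),
            input_format=raw.get("input_format", "auto"),
            reference_mode=raw.get("reference_mode", "canonical"),
            anchor=raw.get("anchor", dref.DEFAULT_ANCHOR),
            tag_length=int(raw.get("tag_length", dref.DEFAULT_TAG_LENGTH)),
            filter=dproc.FilterConfig(
                min_copy=int(fcfg.get("min_copy", 2)),
                adaptor_sequences=tuple(
                    fcfg.get("adaptor_sequences", [dproc.DEFAULT_ADAPTOR])
                ),
                drop_n=bool(fcfg.get("drop_n", True)),
            ),
            ambiguous=raw.get("ambiguous", "count"),
            alpha=float(raw.get("alpha", 0.05)),
            lfc_min=float(raw.get("lfc_min", 1.0)),
        )

    def validate(self) -> None:
        if not Path(self.reference).exists():
            raise PipelineConfigError(f"reference FASTA not found: {self.reference}")
        for lib_id, path in self.libraries.items():
            if not Path(path).exists():
                raise PipelineConfigError(f"input for {lib_id} not found: {path}")
        if self.ambiguous not in ("count", "distribute", "drop"):
            raise PipelineConfigError(f"unknown ambiguous policy {self.ambiguous!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_library(path: Path, fmt: str, species: str, stage: str,
                  anchor: str, tag_length: int) -> dproc.TagLibrary:
    path = Path(path)
    if fmt == "auto":
        name = path.name.removesuffix(".gz")
        fmt = "fastq" if name.endswith((".fq", ".fastq")) else "tsv"
    if fmt == "fastq":
        return dproc.TagLibrary.from_reads(
            species, stage, dio.read_fastq(path), anchor=anchor, tag_length=tag_length
        )
    counts = dio.read_tag_counts(path)
    return dproc.TagLibrary(
        species, stage, counts, raw_reads=sum(counts.values())
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "reference_mode": config.reference_mode,
            "anchor": config.anchor,
            "tag_length": config.tag_length,
            "min_copy": config.filter.min_copy,
            "ambiguous": config.ambiguous,
            "alpha": config.alpha,
            "lfc_min": config.lfc_min,
        },
        "inputs": {},
        "outputs": {},
        "complete": False,
    }
    manifest["inputs"]["reference"] = _sha256(config.reference)
    for (species, stage), path in sorted(config.libraries.items()):
        manifest["inputs"][f"{species}:{stage}"] = _sha256(path)

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        dio.write_tsv(df, path)
        manifest["outputs"][name] = {"sha256": _sha256(path), "rows": len(df)}
        return path

    stage_name = "build-ref"
    try:
        log.info("building virtual tag index from %s", config.reference)
        ref_pairs = [(r.id, str(r.seq)) for r in dio.read_fasta(config.reference)]
        index = dref.build_index(
            ref_pairs, config.reference_mode, config.anchor, config.tag_length
        )
        emit("virtual_tags.tsv", dref.virtual_tag_table(
            ref_pairs, config.reference_mode, config.anchor, config.tag_length
        ))

        stage_name = "extract/clean/map"
        libraries: dict[tuple[str, str], dproc.TagLibrary] = {}
        per_transcript: dict[tuple[str, str], dict[str, float]] = {}
        summary_rows = []
        for (species, stage), path in sorted(config.libraries.items()):
            lib = _load_library(path, config.input_format, species, stage,
                                config.anchor, config.tag_length)
            lib.clean(config.filter)
            libraries[(species, stage)] = lib
            result, counts = dmap.map_library(
                lib.clean_counts, index, ambiguous=config.ambiguous
            )
            per_transcript[(species, stage)] = counts
            tag = f"{species}_{stage}"
            emit(f"raw_{tag}.tsv", pd.DataFrame(
                sorted(lib.raw_counts.items()), columns=["tag", "count"]))
            emit(f"clean_{tag}.tsv", pd.DataFrame(
                sorted(lib.clean_counts.items()), columns=["tag", "count"]))
            emit(f"assignments_{tag}.tsv", dmap.assignment_table(result))
            summary_rows.append({
                "species": species, "stage": stage,
                "raw_reads": lib.raw_reads,
                "clean_tags": lib.clean_tag_total,
                "unique_clean_tags": lib.distinct_clean,
                "mapped_unique_tags": result.mapped_unique_tags,
                "genes_hit": result.genes_hit,
            })

        stage_name = "quant"
        lib_ids = sorted(libraries)
        genes = sorted({g for c in per_transcript.values() for g in c})
        counts = pd.DataFrame(
            {lid: [per_transcript[lid].get(g, 0.0) for g in genes] for lid in lib_ids},
            index=genes,
        )
        depths = {lid: libraries[lid].clean_tag_total for lid in lib_ids}
        tpm, _ = dex.normalize(counts, depths)
        flat = counts.copy()
        flat.columns = [f"{s}_{st}" for s, st in flat.columns]
        flat.insert(0, "gene", flat.index)
        emit("counts.tsv", flat.reset_index(drop=True))
        flat_tpm = tpm.copy()
        flat_tpm.columns = [f"{s}_{st}" for s, st in flat_tpm.columns]
        flat_tpm.insert(0, "gene", flat_tpm.index)
        emit("tpm.tsv", flat_tpm.reset_index(drop=True))

        stage_name = "diffexp/patterns"
        species_list = sorted({s for s, _ in lib_ids})
        stages = [st for st in dproc.STAGES if any((sp, st) in libraries
                                                   for sp in species_list)]
        if len(species_list) == 2 and len(genes) > 0:
            sp_a, sp_b = species_list
            shared = [st for st in stages
                      if (sp_a, st) in libraries and (sp_b, st) in libraries]
            de_frames = []
            for st in shared:
                de = dex.call_de(counts, ((sp_a, st), (sp_b, st)), depths,
                                 config.alpha, config.lfc_min)
                de.insert(0, "stage", st)
                de_frames.append(de.reset_index())
            if de_frames:
                emit("diffexp.tsv", pd.concat(de_frames, ignore_index=True))
                patt = dex.classify_patterns(
                    counts, depths, (sp_a, sp_b), tuple(shared),
                    config.alpha, config.lfc_min,
                ).reset_index(names="gene")
                emit("patterns.tsv", patt)

        stage_name = "venn/summary"
        for species in species_list:
            sp_sets = [
                dov.ExpressedSet.from_counts(
                    f"{species}:{st}", libraries[(species, st)].clean_counts, "tags"
                )
                for st in stages if (species, st) in libraries
            ]
            if 2 <= len(sp_sets) <= 4:
                regions = dov.venn_partition(sp_sets)
                emit(f"venn_{species}.tsv", pd.DataFrame(
                    sorted(regions.items()), columns=["region", "count"]))
        summary = dov.summarize_libraries(
            pd.DataFrame(summary_rows), reference_size=index.reference_size
        )
        emit("summary.tsv", summary.to_table())
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
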