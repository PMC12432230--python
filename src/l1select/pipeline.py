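"""End-to-end orchestration: simulate -> diagnose -> design -> ispcr ->
score -> validate, driven by a TOML config, with a hashed output manifest.

Every stage writes plain-text, independently inspectable intermediates
(FASTA/BED/TSV). Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import diagnostics, insilico_pcr, lineage_sim, selectivity, validation
from .diagnostics import CandidateRegion, ConsensusSet
from .io_formats import (
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
    read_annotation,
    read_fasta,
    write_bed,
    write_fasta,
)
from .primer_design import DesignConstraints, PrimerPair, design_pairs

__all__ = [
    "ConfigError",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "candidate_pairs_for_target",
    "score_pairs",
    "synthetic_selectivity_experiment",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


_KNOWN_KEYS = {
    "": {"seed", "outdir", "simulate", "diagnose", "design", "ispcr", "score", "validate"},
    "simulate": {
        "n_subfamilies",
        "consensus_length",
        "step_substitution_rate",
        "copies_per_subfamily",
        "copy_divergence",
        "truncation_prob",
        "truncation_range",
        "genome_length",
        "name_prefix",
    },
    "diagnose": {"target", "comparison", "max_region_len", "footprint_len_range"},
    "design": {
        "len_range",
        "gc_range",
        "tm_method",
        "tm_range",
        "require_diag_in_3prime_k",
        "min_diag_per_footprint",
        "max_candidate_pairs",
        "pairs_per_region",
    },
    "ispcr": {"max_mismatch", "anchor_len", "max_product", "min_product"},
    "score": {"full_length_min"},
    "validate": {"n_fragments", "frag_len", "min_support"},
}


def load_config(path) -> dict:
    """Read and validate a TOML run configuration (unknown keys rejected)."""
    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS[""]
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    for stage, keys in _KNOWN_KEYS.items():
        if stage and stage in config:
            block = config[stage]
            if not isinstance(block, dict):
                raise ConfigError(f"config section [{stage}] must be a table")
            bad = set(block) - keys
            if bad:
                raise ConfigError(f"unknown keys in [{stage}]: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _listify(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def candidate_pairs_for_target(
    consensuses: ConsensusSet,
    target: str,
    comparison: Optional[Sequence[str]] = None,
    msa: Optional[diagnostics.Alignment] = None,
    max_region_len: int = 200,
    footprint_len_range: tuple[int, int] = (18, 22),
    constraints: DesignConstraints = DesignConstraints(),
    max_candidate_pairs: int = 25,
    pairs_per_region: int = 3,
) -> tuple[list[diagnostics.DiagnosticColumn], list[CandidateRegion], list[PrimerPair]]:
    """Diagnose the target and design a ranked slate of candidate pairs.

    Candidate regions are tried in order of decreasing discriminating-base
    coverage of their two footprints (more discriminating bases make a
    primer pair more selective), taking up to ``pairs_per_region`` ranked
    pairs from each until ``max_candidate_pairs`` distinct pairs are
    collected.
    """
    columns, regions = diagnostics.diagnose(
        consensuses,
        target,
        comparison=comparison,
        msa=msa,
        max_region_len=max_region_len,
        footprint_len_range=footprint_len_range,
    )
    ordered = sorted(
        regions,
        key=lambda r: (-(len(r.left_diag) + len(r.right_diag)), r.region),
    )
    consensus = consensuses[target]
    pairs: list[PrimerPair] = []
    seen: set[tuple[str, str, tuple, tuple]] = set()
    for region in ordered:
        if len(pairs) >= max_candidate_pairs:
            break
        for pair in design_pairs(region, consensus, constraints, max_pairs=pairs_per_region):
            key = (
                pair.forward.seq,
                pair.reverse.seq,
                pair.forward.footprint,
                pair.reverse.footprint,
            )
            if key in seen:
                continue
            seen.add(key)
            pairs.append(pair)
            if len(pairs) >= max_candidate_pairs:
                break
    return columns, regions, pairs


def score_pairs(
    genome: SequenceRecord,
    pairs: Sequence[PrimerPair],
    annotation: Sequence[RepeatAnnotation],
    lineage_names: Sequence[str],
    max_mismatch: int = 2,
    anchor_len: int = 5,
    max_product: int = 1000,
    min_product: int = 40,
) -> list[tuple[PrimerPair, list[insilico_pcr.Amplicon], selectivity.CategoryReport]]:
    """In-silico PCR + selectivity report for each candidate pair."""
    index = selectivity.AnnotationIndex(annotation)
    results = []
    for pair in pairs:
        amplicons = insilico_pcr.predict_amplicons(
            genome,
            pair,
            max_product=max_product,
            min_product=min_product,
            max_mismatch=max_mismatch,
            anchor_len=anchor_len,
        )
        report = selectivity.selectivity_report(amplicons, index, lineage_names)
        results.append((pair, amplicons, report))
    return results


@dataclass(frozen=True)
class EndToEndResult:
    """Outcome of a synthetic design-and-score experiment."""

    consensuses: ConsensusSet
    genome: SequenceRecord
    annotation: list[RepeatAnnotation]
    truth: pd.DataFrame
    target: str
    adjacent: str
    scored: list  # (PrimerPair, amplicons, CategoryReport)

    def target_or_adjacent_percent(self, report) -> float:
        if report.total == 0:
            return 0.0
        hits = report.count(self.target) + report.count(self.adjacent)
        from .primer_design import round_half_up

        return round_half_up(100.0 * hits / report.total, 1)

    def best(self):
        """The scored pair maximizing target-or-adjacent percent (ties to
        the earlier-ranked pair); None if no pair produced amplicons."""
        best = None
        best_pct = -1.0
        for pair, amplicons, report in self.scored:
            if report.total == 0:
                continue
            pct = self.target_or_adjacent_percent(report)
            if pct > best_pct:
                best, best_pct = (pair, amplicons, report), pct
        return best


def synthetic_selectivity_experiment(
    params: lineage_sim.SimParams = lineage_sim.SimParams(),
    target: Optional[str] = None,
    constraints: DesignConstraints = DesignConstraints(),
    max_candidate_pairs: int = 25,
    max_mismatch: int = 2,
    anchor_len: int = 5,
    max_product: int = 1000,
) -> EndToEndResult:
    """Full synthetic experiment: simulate a lineage, design primers for the
    youngest subfamily (or ``target``), run in-silico PCR on the simulated
    genome, and score every candidate pair against the planted annotation."""
    consensuses = lineage_sim.simulate_lineage(params)
    genome, annotation, truth = lineage_sim.plant_copies(params, consensuses)
    names = consensuses.names
    target = target or names[0]
    t_idx = names.index(target)
    adjacent = names[t_idx + 1] if t_idx + 1 < len(names) else names[t_idx - 1]
    _, _, pairs = candidate_pairs_for_target(
        consensuses,
        target,
        constraints=constraints,
        max_candidate_pairs=max_candidate_pairs,
    )
    scored = score_pairs(
        genome,
        pairs,
        annotation,
        names,
        max_mismatch=max_mismatch,
        anchor_len=anchor_len,
        max_product=max_product,
    )
    return EndToEndResult(
        consensuses, genome, annotation, truth, target, adjacent, scored
    )


def run_pipeline(config: dict | str | Path, outdir: Optional[Path] = None) -> dict:
    """Execute all stages and write a manifest; returns the manifest dict.

    The manifest records, per stage, the parameters used and a sha256 of
    every output file; a rerun with the same config reproduces identical
    hashes.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(outdir or config.get("outdir", "l1select_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": []}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "params": {k: params[k] for k in sorted(params)},
                "outputs": {f.name: _sha256(f) for f in sorted(files)},
            }
        )

    # --- simulate ---------------------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    if "truncation_range" in sim_cfg:
        sim_cfg["truncation_range"] = tuple(sim_cfg["truncation_range"])
    params = lineage_sim.SimParams(seed=seed, **sim_cfg)
    try:
        consensuses = lineage_sim.simulate_lineage(params)
        genome, annotation, truth = lineage_sim.plant_copies(params, consensuses)
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    write_fasta(consensuses.to_records(), out / "consensus.fa")
    write_fasta([genome], out / "genome.fa")
    write_bed([a.interval for a in annotation], out / "annotation.bed")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    record(
        "simulate",
        {**sim_cfg, "seed": seed},
        [out / f for f in ("consensus.fa", "genome.fa", "annotation.bed", "truth.tsv")],
    )

    # --- diagnose + design ------------------------------------------------
    diag_cfg = dict(config.get("diagnose", {}))
    design_cfg = dict(config.get("design", {}))
    target = diag_cfg.get("target", consensuses.names[0])
    constraint_keys = {
        "len_range",
        "gc_range",
        "tm_method",
        "tm_range",
        "require_diag_in_3prime_k",
        "min_diag_per_footprint",
    }
    ckw = {k: _listify(v) for k, v in design_cfg.items() if k in constraint_keys}
    constraints = DesignConstraints(**ckw)
    try:
        columns, regions, pairs = candidate_pairs_for_target(
            consensuses,
            target,
            comparison=diag_cfg.get("comparison"),
            max_region_len=int(diag_cfg.get("max_region_len", 200)),
            footprint_len_range=tuple(diag_cfg.get("footprint_len_range", (18, 22))),
            constraints=constraints,
            max_candidate_pairs=int(design_cfg.get("max_candidate_pairs", 25)),
            pairs_per_region=int(design_cfg.get("pairs_per_region", 3)),
        )
    except Exception as exc:
        raise PipelineError(f"stage diagnose/design failed: {exc}") from exc
    pd.DataFrame(
        [
            {
                "column_index": c.column_index,
                "consensus_pos": c.target_consensus_pos[target],
                "residues": ",".join(f"{n}={r}" for n, r in sorted(c.residues.items())),
            }
            for c in columns
        ]
    ).to_csv(out / "columns.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "target": r.target_subfamily,
                "start": r.region[0],
                "end": r.region[1],
                "left_fp_start": r.left_footprint[0],
                "left_fp_end": r.left_footprint[1],
                "right_fp_start": r.right_footprint[0],
                "right_fp_end": r.right_footprint[1],
                "n_left_diag": len(r.left_diag),
                "n_right_diag": len(r.right_diag),
            }
            for r in regions
        ]
    ).to_csv(out / "regions.tsv", sep="\t", index=False)
    record("diagnose", {**diag_cfg, "target": target}, [out / "columns.tsv", out / "regions.tsv"])

    primer_rows = []
    for i, pair in enumerate(pairs):
        for primer in (pair.forward, pair.reverse):
            primer_rows.append(
                {
                    "pair_id": f"pair{i}",
                    "name": primer.name,
                    "orientation": primer.orientation,
                    "seq": primer.seq,
                    "footprint_start": primer.footprint[0],
                    "footprint_end": primer.footprint[1],
                    "gc_percent": primer.gc,
                    "tm_c": primer.tm_c,
                    "expected_product_len": pair.expected_product_len,
                }
            )
    pd.DataFrame(primer_rows).to_csv(out / "primers.tsv", sep="\t", index=False)
    record("design", design_cfg, [out / "primers.tsv"])
    if not pairs:
        raise PipelineError("stage design failed: no primer pair satisfies constraints")

    # --- ispcr + score ----------------------------------------------------
    ispcr_cfg = dict(config.get("ispcr", {}))
    try:
        scored = score_pairs(
            genome,
            pairs,
            annotation,
            consensuses.names,
            max_mismatch=int(ispcr_cfg.get("max_mismatch", 2)),
            anchor_len=int(ispcr_cfg.get("anchor_len", 5)),
            max_product=int(ispcr_cfg.get("max_product", 1000)),
            min_product=int(ispcr_cfg.get("min_product", 40)),
        )
    except Exception as exc:
        raise PipelineError(f"stage ispcr failed: {exc}") from exc
    amp_intervals = []
    amp_records = []
    for i, (pair, amplicons, _) in enumerate(scored):
        for j, amp in enumerate(amplicons):
            name = f"pair{i}_{amp.product_len}"
            amp_intervals.append(amp.interval.with_name(name))
            amp_records.append(SequenceRecord(f"pair{i}_amp{j}", amp.seq))
    write_bed(amp_intervals, out / "amplicons.bed")
    if amp_records:
        write_fasta(amp_records, out / "amplicons.fa")
    else:
        (out / "amplicons.fa").write_text("")
    record("ispcr", ispcr_cfg, [out / "amplicons.bed", out / "amplicons.fa"])

    score_cfg = dict(config.get("score", {}))
    report_rows = []
    for i, (pair, amplicons, report) in enumerate(scored):
        for cat, (count, pct) in report.per_category.items():
            report_rows.append(
                {
                    "pair_id": f"pair{i}",
                    "category": cat,
                    "count": count,
                    "percent": pct,
                    "total": report.total,
                    "top2_share": report.top2_share,
                }
            )
    pd.DataFrame(report_rows).to_csv(out / "report.tsv", sep="\t", index=False)
    chrom_sizes = {genome.id: len(genome.seq)}
    full_length_min = int(
        score_cfg.get("full_length_min", int(0.9 * params.consensus_length))
    )
    tracks = selectivity.build_annotation_tracks(
        annotation, chrom_sizes, intact_loci=(), full_length_min=full_length_min
    )
    for name, intervals in tracks.as_dict().items():
        write_bed(intervals, out / f"track_{name}.bed")
    record(
        "score",
        {**score_cfg, "full_length_min": full_length_min},
        [out / "report.tsv"] + [out / f"track_{n}.bed" for n in tracks.as_dict()],
    )

    # --- validate ---------------------------------------------------------
    val_cfg = dict(config.get("validate", {}))
    names = consensuses.names
    t_idx = names.index(target)
    adjacent = names[t_idx + 1] if t_idx + 1 < len(names) else names[t_idx - 1]
    best = EndToEndResult(
        consensuses, genome, annotation, truth, target, adjacent, scored
    ).best()
    if best is None:
        raise PipelineError("stage validate failed: no pair produced amplicons")
    _, _, best_report = best
    weights = {
        name: float(best_report.count(name)) for name in consensuses.names
    }
    if all(v == 0 for v in weights.values()):
        weights = {target: 1.0}
    try:
        fragments = lineage_sim.simulate_fragments(
            annotation,
            weights,
            n_fragments=int(val_cfg.get("n_fragments", 2000)),
            frag_len=int(val_cfg.get("frag_len", 200)),
            seed=seed + 1,
        )
    except Exception as exc:
        raise PipelineError(f"stage validate failed: {exc}") from exc
    write_bed(fragments, out / "fragments.bed")
    frag_report = validation.count_fragments_by_category(
        fragments, annotation, consensuses.names
    )
    pd.DataFrame(
        [
            {"category": cat, "count": count, "percent": pct}
            for cat, (count, pct) in frag_report.per_category.items()
        ]
    ).to_csv(out / "fragment_report.tsv", sep="\t", index=False)
    loci = validation.call_amplified_loci(
        fragments, min_support=int(val_cfg.get("min_support", 3))
    )
    write_bed(
        [l.interval.with_name(f"support{l.support}") for l in loci],
        out / "loci.bed",
    )
    track_counts = validation.intersect_loci_with_tracks(loci, tracks)
    pd.Series(track_counts).rename("n_loci").to_csv(
        out / "track_counts.tsv", sep="\t", index_label="track"
    )
    record(
        "validate",
        val_cfg,
        [
            out / f
            for f in (
                "fragments.bed",
                "fragment_report.tsv",
                "loci.bed",
                "track_counts.tsv",
            )
        ],
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
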