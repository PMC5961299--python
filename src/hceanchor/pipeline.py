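"""End-to-end orchestration: preprocess, databank, anchor, chain, net, report.

The pipeline reads a chromosome-level reference, a scaffold-level target and
an HCE multi-FASTA, runs the five stages, and leaves the intermediate PSL /
chain / net files plus a TSV report and a JSON manifest in the output
directory.  A temporary working folder holds scratch files and is removed on
success.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from . import aligner as al
from . import anchoring, chainnet, databank as dbk, io_formats as iof

__all__ = ["RunConfig", "PipelineError", "validate_inputs", "run_pipeline"]

log = logging.getLogger("hceanchor")

# references more fragmented than this slow anchoring down noticeably
FRAGMENTED_REFERENCE_WARNING = 200


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    reference: Path
    target: Path
    hce: Path
    outdir: Path
    hce_bed: Path | None = None
    min_identity: float = 0.90
    min_ali: float = 0.95
    fast_mode: bool = False
    occ_threshold: int | None = None
    split_long: bool = False
    split_max_len: int = 500
    split_piece: int = 250
    min_hce_len: int = dbk.MIN_HCE_LENGTH
    min_score: float = 3000.0
    linear_gap: str = "loose"
    min_space: int = 25
    cores: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("reference", "target", "hce", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.hce_bed is not None:
            self.hce_bed = Path(self.hce_bed)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_inputs(config: RunConfig) -> list[str]:
    """Pre-flight checks; returns a list of problems (empty = clean)."""
    problems: list[str] = []
    for name in ("reference", "target", "hce"):
        path = getattr(config, name)
        if not path.exists():
            problems.append(f"{name} file not found: {path}")
    if problems:
        return problems
    try:
        ref = iof.read_fasta(config.reference)
        if len(ref) > FRAGMENTED_REFERENCE_WARNING:
            problems.append(
                f"warning: reference has {len(ref)} sequences; a fragmented "
                "reference can dramatically increase running time"
            )
    except iof.FormatError as exc:
        problems.append(f"reference: {exc}")
    try:
        iof.read_fasta(config.target)
    except iof.FormatError as exc:
        problems.append(f"target: {exc}")
    try:
        iof.read_fasta(config.hce)  # duplicate ids raise here
    except iof.FormatError as exc:
        problems.append(f"hce: {exc}")
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    problems = validate_inputs(config)
    errors = [p for p in problems if not p.startswith("warning")]
    if errors:
        raise PipelineError("preflight", "; ".join(errors))
    config.outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(config.outdir / "run.log", mode="w")
    log.addHandler(handler)
    tmpdir = Path(tempfile.mkdtemp(prefix="hceanchor_"))
    manifest: dict = {
        "parameters": {
            "min_identity": config.min_identity,
            "min_ali": config.min_ali,
            "fast_mode": config.fast_mode,
            "occ_threshold": config.occ_threshold,
            "split_long": config.split_long,
            "min_score": config.min_score,
            "linear_gap": config.linear_gap,
            "cores": config.cores,
            "seed": config.seed,
        },
        "inputs": {
            "reference": {"path": str(config.reference), "sha256": _digest(config.reference)},
            "target": {"path": str(config.target), "sha256": _digest(config.target)},
            "hce": {"path": str(config.hce), "sha256": _digest(config.hce)},
        },
        "counts": {},
        "warnings": [p for p in problems if p.startswith("warning")],
    }
    counts = manifest["counts"]
    try:
        # stage 1: preprocessing
        log.info("stage 1: reading genomes and computing sizes")
        reference = iof.read_fasta(config.reference)
        target = iof.read_fasta(config.target)
        iof.compute_sizes(reference).to_csv(
            tmpdir / "reference.sizes", sep="\t", index=False, header=False
        )
        iof.compute_sizes(target).to_csv(
            tmpdir / "target.sizes", sep="\t", index=False, header=False
        )

        hces = dbk.load_hces(config.hce, config.hce_bed)
        counts["hce_input"] = len(hces)
        hces = dbk.filter_min_length(hces, config.min_hce_len)
        counts["hce_length_filtered"] = len(hces)
        split_max = config.split_max_len if config.split_long else al.FAST_MODE_MAX_QUERY
        if config.split_long or config.fast_mode:
            piece = config.split_piece if config.split_long else al.FAST_MODE_MAX_QUERY // 2
            hces = dbk.split_long_hce(hces, split_max, piece, config.min_hce_len)
        counts["hce_after_split"] = len(hces)

        # databank: unique perfect placements on the reference
        log.info("building databank against the reference")
        db_params = dbk.DatabankParams(
            aligner=al.AlignerParams(
                min_identity=0.90, fast_mode=config.fast_mode
            )
        )
        ref_index = al.build_index(reference, occ_threshold=config.occ_threshold)
        entries, db_stats = dbk.build_databank(hces, reference, db_params, ref_index)
        counts["databank"] = len(entries)
        manifest["databank_stats"] = db_stats
        if not entries:
            raise PipelineError("databank", "no HCE passed the databank filters")
        iof.write_fasta(
            iof.GenomeSequences({e.hce.hce_id: e.hce.sequence for e in entries}),
            config.outdir / "databank.fa",
        )
        iof.write_bed(
            [
                (e.ref_placement[0], e.ref_placement[1], e.ref_placement[2],
                 e.hce.hce_id, e.ref_placement[3])
                for e in entries
            ],
            config.outdir / "databank.bed",
        )
        iof.write_psl([e.ref_alignment for e in entries],
                      config.outdir / "databank.psl")

        # stages 2-3: map to the target, filter to anchors
        log.info("stage 2-3: aligning databank to target, filtering anchors")
        anchor_params = anchoring.AnchorParams(
            min_identity=config.min_identity, min_ali=config.min_ali
        )
        tgt_index = al.build_index(target, occ_threshold=config.occ_threshold)
        records = anchoring.map_databank(
            entries, target, anchor_params, tgt_index,
            al.AlignerParams(
                min_identity=config.min_identity, fast_mode=config.fast_mode
            ),
            cores=config.cores,
        )
        counts["target_alignments"] = len(records)
        iof.write_psl(records, config.outdir / "target.psl")
        anchors = anchoring.filter_anchors(records, entries, anchor_params)
        counts["anchors"] = len(anchors)
        if not anchors:
            raise PipelineError("anchor", "no anchors passed the filters")
        iof.write_bed(
            [
                (a.ref[0], a.ref[1], a.ref[2], a.hce_id, a.ref[3])
                for a in anchors
            ],
            config.outdir / "anchors.ref.bed",
        )
        iof.write_bed(
            [
                (a.tgt[0], a.tgt[1], a.tgt[2], a.hce_id, a.tgt[3])
                for a in anchors
            ],
            config.outdir / "anchors.tgt.bed",
        )

        # stage 4: transfer onto the reference frame
        log.info("stage 4: transferring anchors onto the reference")
        ref_frame = anchoring.transfer_to_reference(anchors)
        iof.write_psl(ref_frame, config.outdir / "anchors.ref.psl")

        # stage 5: chain, net, report
        log.info("stage 5: chaining and netting")
        chain_params = chainnet.ChainParams(
            min_score=config.min_score,
            gap_model=chainnet.GapModel.preset(config.linear_gap),
        )
        chains = chainnet.chain_blocks(ref_frame, chain_params)
        counts["chains"] = len(chains)
        iof.write_chain(chains, config.outdir / "anchors.chain")
        nets = chainnet.net_chains(
            chains, reference.sizes(), min_space=config.min_space
        )
        nets = chainnet.annotate_syntenic(nets)
        iof.write_net(nets, config.outdir / "anchors.net")
        report = chainnet.scaffold_report(nets, anchors, target.sizes())
        counts["netted_scaffolds"] = int(report["scaffold"].nunique())
        report.to_csv(config.outdir / "report.tsv", sep="\t", index=False)
        manifest["outputs"] = sorted(
            p.name for p in config.outdir.iterdir() if p.is_file()
        )
        with open(config.outdir / "manifest.json", "w") as out:
            json.dump(manifest, out, indent=1, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("internal", str(exc)) from exc
    finally:
        shutil.rmtree(tmpdir, ignore_errors=True)
        log.removeHandler(handler)
        handler.close()
    return manifest
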