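"""End-to-end convenience wrapper: screen -> remap -> call.

Chains the library stages over files on disk the same way the CLI
subcommands compose, for scripted runs and tests. Detection can remap the
trimmed host flanks single-end ("trimmed-read detection") or jointly with
their mates ("guided detection", which rescues flanks that are ambiguous
alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .baits import BaitSet, baits_from_fasta
from .caller import CallerParams, DetectionResult, detect_integrations
from .formats import read_fastq
from .mapper import MappingParams, index_reference, map_fastq
from .screen import ScreenOutputs, ScreenParams, screen_library

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    screen: ScreenOutputs
    sam: Path
    detection: DetectionResult


def run_pipeline(
    reads_fastq: Union[str, Path],
    te_ref_fasta: Union[str, Path],
    host_ref_fasta: Union[str, Path],
    out_dir: Union[str, Path],
    bait_length: int = 15,
    paired: bool = True,
    guided: bool = True,
    screen_params: ScreenParams = ScreenParams(),
    mapping_params: MappingParams = MappingParams(),
    caller_params: CallerParams = CallerParams(),
    known_bed: Optional[Union[str, Path]] = None,
    sva_bed: Optional[Union[str, Path]] = None,
    repeats_bed: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Screen a FASTQ library, remap trimmed reads and call integrations.

    ``guided`` requires ``paired`` input; the first (and only) sequence of
    ``te_ref_fasta`` provides the bait set.
    """
    if guided and not paired:
        raise ValueError("guided detection requires paired input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    baitset: BaitSet = baits_from_fasta(te_ref_fasta, bait_length)[0]
    screen_out = screen_library(
        read_fastq(reads_fastq),
        baitset,
        screen_params,
        paired=paired,
        out_prefix=out_dir / "screen",
    )
    index = index_reference(host_ref_fasta, k=mapping_params.seed_k)
    mode = "guided" if guided else "single"
    sam = out_dir / f"remap.{mode}.sam"
    map_fastq(
        screen_out.trimmed_path,
        index,
        sam,
        params=mapping_params,
        mates=screen_out.mates_path if guided else None,
    )
    detection = detect_integrations(
        sam,
        out_prefix=out_dir / f"calls.{mode}",
        params=caller_params,
        known_bed=known_bed,
        sva_bed=sva_bed,
        repeats_bed=repeats_bed,
    )
    return PipelineResult(screen=screen_out, sam=sam, detection=detection)
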