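"""Self-contained simulate-map-evaluate pipelines for benchmarking."""

from __future__ import annotations

import io
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .evaluate import EvalReport, PredictedInversion, evaluate
from .index import build_index
from .mapper import RunConfig, map_reads
from .simulate import SimConfig, simulate


@dataclass
class PipelineResult:
    report: EvalReport
    n_reads: int
    n_calls: int


def run_pipeline(sim: SimConfig, run: RunConfig | None = None,
                 full_span_only: bool = False) -> PipelineResult:
    """Simulate a genome + reads, map them, and score against truth."""
    run = run or RunConfig()
    ref, alt, svs, reads, truth = simulate(sim)
    index = build_index(ref, k=run.k, w=run.w, max_occ=run.max_occ)
    refseqs = [s for _, s in ref.sequences]
    buf = io.StringIO()
    mappings = map_reads(reads, index, refseqs, run, sam_out=buf)
    calls = [PredictedInversion(m.qname, c.seq_id, c.ps_ref, c.pe_ref,
                                c.ps_read, c.pe_read)
             for m in mappings for c in m.calls]
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(buf.getvalue())
        path = fh.name
    try:
        rep = evaluate(path, truth, calls, full_span_only)
    finally:
        Path(path).unlink(missing_ok=True)
    return PipelineResult(rep, len(reads), len(calls))
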