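"""End-to-end orchestration: stage cascades, run manifests, reproducibility.

Two entry points mirror the two halves of the artifact:
:func:`run_repertoire_pipeline` (paired FASTQ -> consensus -> annotation)
and :func:`run_doe_analysis` (response CSV -> ANOVA report -> optimal
condition).  Both write a :class:`RunManifest` recording the config hash,
input checksums, seeds and per-stage record counts, so identical inputs and
config reproduce identical outputs (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (AnnotationConfig, annotate_sequences,
                       load_germline_reference, write_rearrangement_tsv)
from .doe import (anova_decompose, decomposition_to_frame, default_factors,
                  factors_from_yaml, marginal_means, read_response_table,
                  select_optimal, sensitivity_indices)
from .readproc import (PipelineConfig, PrimerScheme, process_read_pairs,
                       read_fastq_pairs, write_consensus_fasta)

__all__ = ["RunManifest", "ConfigError", "DataError",
           "run_repertoire_pipeline", "run_doe_analysis"]


class ConfigError(ValueError):
    """Invalid configuration (CLI maps this to its own exit code)."""


class DataError(ValueError):
    """Structurally invalid input data."""


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: dict
    stage_counts: dict
    seeds: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def equivalent_to(self, other: "RunManifest") -> bool:
        """Equality ignoring timestamps (the rerun-determinism check)."""
        keys = ("tool_version", "config_hash", "input_checksums",
                "stage_counts", "seeds")
        return all(getattr(self, k) == getattr(other, k) for k in keys)


def run_repertoire_pipeline(
    r1_path,
    r2_path,
    refs_fasta,
    anchors_tsv,
    out_dir,
    scheme_yaml=None,
    config: PipelineConfig | None = None,
    annot_config: AnnotationConfig | None = None,
    stop_after: str | None = None,
) -> RunManifest:
    """Paired FASTQ -> consensus FASTA + ledger -> rearrangement TSV.

    Stages run in the library's narrative order: quality filter, merge,
    orient, barcode, isotype, trim, consensus, then frame / V-J similarity
    filtering inside annotation.  ``stop_after="consensus"`` skips
    annotation for partial runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    for p in (r1_path, r2_path, refs_fasta, anchors_tsv):
        if not Path(p).exists():
            raise ConfigError(f"missing input: {p}")
    scheme = PrimerScheme.from_yaml(scheme_yaml) if scheme_yaml else PrimerScheme()
    config = config or PipelineConfig()
    refs = load_germline_reference(refs_fasta, anchors_tsv)
    try:
        pairs = read_fastq_pairs(r1_path, r2_path)
    except Exception as exc:  # malformed FASTQ
        raise DataError(f"could not parse FASTQ: {exc}") from exc

    records, ledger, counts = process_read_pairs(pairs, scheme, refs.constants, config)
    write_consensus_fasta(records, out / "consensus.fasta")
    ledger.to_csv(out / "read_ledger.tsv", sep="\t", index=False)

    stage_counts = {k: dict(v) for k, v in counts.items()}
    stage_counts["input_pairs"] = {"in": len(pairs), "out": len(pairs)}
    stage_counts["consensus_records"] = {"in": len(records), "out": len(records)}

    if stop_after != "consensus":
        triples = [(f"consensus_{i}", rec.isotype, rec.consensus)
                   for i, rec in enumerate(records)]
        rearr = annotate_sequences(triples, refs, annot_config)
        write_rearrangement_tsv(rearr, out / "rearrangements.tsv")
        stage_counts["annotation"] = {
            "in": len(rearr), "out": int((rearr["status"] == "ok").sum()),
        }

    with open(out / "stage_counts.json", "w") as fh:
        json.dump(stage_counts, fh, indent=2)

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash({"pipeline": config.__dict__,
                                  "annotation": (annot_config or AnnotationConfig()).__dict__,
                                  "stop_after": stop_after}),
        input_checksums={str(p): _sha256_file(p)
                         for p in (r1_path, r2_path, refs_fasta, anchors_tsv)},
        stage_counts=stage_counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "run_manifest.json")
    return manifest


def run_doe_analysis(
    responses_csv,
    out_dir,
    factors_yaml=None,
    max_order: int = 2,
    alpha: float = 0.05,
    block_donor: bool = True,
) -> RunManifest:
    """Response CSV -> per-isotype ANOVA/sensitivity report + optimal condition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    if not Path(responses_csv).exists():
        raise ConfigError(f"missing input: {responses_csv}")
    factors = factors_from_yaml(factors_yaml) if factors_yaml else default_factors()
    names = [f.name for f in factors]
    try:
        table = read_response_table(responses_csv, names)
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    isotypes = sorted(table["isotype"].unique()) if "isotype" in table else ["total"]
    stage_counts: dict = {"rows": {"in": len(table), "out": len(table)}}
    optima = {}
    for iso in isotypes:
        sub = table[table["isotype"] == iso] if "isotype" in table else table
        decomp = anova_decompose(sub, names, max_order=max_order,
                                 include_donor_block=block_donor)
        frame = decomposition_to_frame(decomp)
        frame.to_csv(out / f"anova_{iso}.tsv", sep="\t", index=False)
        report = sensitivity_indices(decomp)
        marg = {f.name: marginal_means(sub, f.name) for f in factors}
        opt = select_optimal(report, marg, factors, alpha=alpha)
        optima[iso] = json.loads(opt.to_json())
        stage_counts[f"terms_{iso}"] = {"in": len(frame), "out": len(frame)}
    with open(out / "optimal_conditions.json", "w") as fh:
        json.dump(optima, fh, indent=2)

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash({"max_order": max_order, "alpha": alpha,
                                  "block_donor": block_donor,
                                  "factors": [f.name for f in factors]}),
        input_checksums={str(responses_csv): _sha256_file(responses_csv)},
        stage_counts=stage_counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "run_manifest.json")
    return manifest
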