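"""Germline V/J annotation, reading-frame check, SHM% and CDRH3 length.

A deliberately simple junction annotator: each consensus sequence is aligned
locally against a germline V and J reference set (k-mer-seeded candidate
selection, then Smith-Waterman via :class:`Bio.Align.PairwiseAligner`);
sequences without significant V/J similarity are removed as
non-immunoglobulin, frame is checked by translating from the germline V
phase, somatic hypermutation is the percentage of mismatched nucleotides
over the aligned V span (excluding the FR1-primer-covered span, whose bases
are synthetic, and any gap columns), and CDRH3 is the stretch of codons
strictly between the V 2nd-CYS codon and the J-gene W/F anchor codon.

This stands in for full IMGT-style annotation: it produces exactly the two
statistics the downstream repertoire summaries need (SHM% at nucleotide
level and CDRH3 length in nucleotides) and nothing more.  Note the CDRH3
reported here excludes both anchor codons; IMGT junction lengths are 6 nt
longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "VAllele",
    "JAllele",
    "GermlineReference",
    "AnnotationConfig",
    "VJAssignment",
    "assign_v_gene",
    "assign_j_gene",
    "check_reading_frame",
    "compute_shm",
    "find_cdrh3",
    "annotate_sequences",
    "write_rearrangement_tsv",
    "read_rearrangement_tsv",
    "load_germline_reference",
    "write_germline_reference",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
ANCHOR_CODONS = {"TGG", "TTT", "TTC"}  # tryptophan or phenylalanine


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAllele:
    id: str
    sequence: str
    cys_codon_start: int          # 0-based start of the 2nd-CYS codon
    primer_span: tuple[int, int]  # FR1-primer-covered span, 0-based half-open

    def __post_init__(self) -> None:
        if not (0 <= self.cys_codon_start <= len(self.sequence) - 3):
            raise ValueError(f"{self.id}: 2nd-CYS anchor outside sequence")


@dataclass(frozen=True)
class JAllele:
    id: str
    sequence: str
    j_motif_start: int  # 0-based start of the W/F anchor codon

    def __post_init__(self) -> None:
        if not (0 <= self.j_motif_start <= len(self.sequence) - 3):
            raise ValueError(f"{self.id}: J motif outside sequence")


@dataclass
class GermlineReference:
    """V, J and constant-region references with their anchor coordinates."""

    v_alleles: dict[str, VAllele]
    j_alleles: dict[str, JAllele]
    constants: dict[str, tuple[str, str]]  # allele id -> (isotype, sequence)

    def __post_init__(self) -> None:
        ids = list(self.v_alleles) + list(self.j_alleles) + list(self.constants)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate allele ids across reference sets")


@dataclass
class AnnotationConfig:
    """Similarity-retention thresholds standing in for a BLAST screen."""

    v_min_identity: float = 80.0
    v_min_aligned: int = 100
    j_min_identity: float = 80.0
    j_min_aligned: int = 25
    seed_k: int = 10       # k-mer size for V candidate pre-screening
    n_candidates: int = 3  # V candidates carried into full alignment


@dataclass
class VJAssignment:
    allele_id: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    identity: float        # percent over aligned (non-gap) columns
    aligned_length: int    # aligned column count, gaps excluded
    blocks: tuple          # ((qstart,qend),(rstart,rend)) aligned block pairs


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _align(query: str, ref: str) -> VJAssignment | None:
    try:
        aln = _ALIGNER.align(query, ref)[0]
    except (IndexError, ValueError):
        return None
    q_blocks, r_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    matches = 0
    aligned = 0
    blocks = []
    for (qs, qe), (rs, re) in zip(q_blocks, r_blocks):
        a = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
        b = np.frombuffer(ref[rs:re].encode(), dtype=np.uint8)
        matches += int((a == b).sum())
        aligned += qe - qs
        blocks.append(((int(qs), int(qe)), (int(rs), int(re))))
    return VJAssignment(
        allele_id="",
        query_start=int(q_blocks[0][0]), query_end=int(q_blocks[-1][1]),
        ref_start=int(r_blocks[0][0]), ref_end=int(r_blocks[-1][1]),
        identity=100.0 * matches / aligned, aligned_length=aligned,
        blocks=tuple(blocks),
    )


def _kmer_count(a: str, b: str, k: int) -> int:
    ka = {a[i: i + k] for i in range(len(a) - k + 1)}
    kb = {b[i: i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)


# ---------------------------------------------------------------------------
# V / J assignment
# ---------------------------------------------------------------------------

def assign_v_gene(
    seq: str, refs: GermlineReference, config: AnnotationConfig | None = None
) -> VJAssignment | None:
    """Best local V-gene alignment; ``None`` when below the retention rule.

    Candidate alleles are pre-ranked by shared k-mers, the top few aligned in
    full, and the best alignment retained only with identity >=
    ``v_min_identity`` over >= ``v_min_aligned`` aligned nucleotides.
    """
    config = config or AnnotationConfig()
    if not refs.v_alleles:
        raise ValueError("empty V reference set")
    if len(seq) < config.seed_k:
        raise ValueError("query shorter than seed length")
    ranked = sorted(
        refs.v_alleles.values(),
        key=lambda v: (-_kmer_count(seq, v.sequence, config.seed_k), v.id),
    )
    best: VJAssignment | None = None
    for allele in ranked[: config.n_candidates]:
        asgn = _align(seq, allele.sequence)
        if asgn is None:
            continue
        asgn.allele_id = allele.id
        score = asgn.identity * asgn.aligned_length
        if best is None or score > best.identity * best.aligned_length:
            best = asgn
    if (best is None or best.identity < config.v_min_identity
            or best.aligned_length < config.v_min_aligned):
        return None
    return best


def assign_j_gene(
    seq: str, refs: GermlineReference, config: AnnotationConfig | None = None
) -> VJAssignment | None:
    """Best local J-gene alignment (all alleles tried; J genes are short)."""
    config = config or AnnotationConfig()
    if not refs.j_alleles:
        raise ValueError("empty J reference set")
    best: VJAssignment | None = None
    for allele in sorted(refs.j_alleles.values(), key=lambda j: j.id):
        asgn = _align(seq, allele.sequence)
        if asgn is None:
            continue
        asgn.allele_id = allele.id
        score = asgn.identity * asgn.aligned_length
        if best is None or score > best.identity * best.aligned_length:
            best = asgn
    if (best is None or best.identity < config.j_min_identity
            or best.aligned_length < config.j_min_aligned):
        return None
    return best


# ---------------------------------------------------------------------------
# Frame / SHM / CDRH3
# ---------------------------------------------------------------------------

def check_reading_frame(
    seq: str, v_asgn: VJAssignment, j_asgn: VJAssignment | None = None
) -> bool:
    """True iff the sequence is in frame as inherited from the germline V.

    The reading frame is anchored on germline V codon phase (reference
    position 0 starts a codon).  The query is translated from the first full
    codon of the V alignment through the end of the aligned region (the J
    alignment end when available); any stop codon fails.  When a J assignment
    is given, its alignment must sit in the same codon phase as the V
    alignment, so a 1-nt indel in the junction shifts phase and fails.
    """
    phase_v = (v_asgn.query_start - v_asgn.ref_start) % 3
    if j_asgn is not None:
        phase_j = (j_asgn.query_start - j_asgn.ref_start) % 3
        if phase_j != phase_v:
            return False
    start = v_asgn.query_start + ((-(v_asgn.ref_start)) % 3)
    end = j_asgn.query_end if j_asgn is not None else v_asgn.query_end
    end = start + ((end - start) // 3) * 3
    for i in range(start, end, 3):
        if seq[i: i + 3] in STOP_CODONS:
            return False
    return True


def compute_shm(seq: str, v_asgn: VJAssignment, refs: GermlineReference) -> float:
    """SHM as % mismatched nucleotides over the eligible aligned V span.

    Eligible positions are aligned (non-gap) columns of the V alignment whose
    reference coordinate falls outside the FR1-primer-covered span — primer
    bases are synthetic and would mask true mutations.  Indels are not
    counted as mutation events.
    """
    allele = refs.v_alleles[v_asgn.allele_id]
    p_start, p_end = allele.primer_span
    mism = 0
    eligible = 0
    for (qs, qe), (rs, re) in v_asgn.blocks:
        for q, r in zip(range(qs, qe), range(rs, re)):
            if p_start <= r < p_end:
                continue
            eligible += 1
            if seq[q] != allele.sequence[r]:
                mism += 1
    if eligible == 0:
        raise ValueError("no eligible aligned V positions outside the primer span")
    return 100.0 * mism / eligible


def _ref_to_query(asgn: VJAssignment, ref_pos: int) -> int | None:
    for (qs, qe), (rs, re) in asgn.blocks:
        if rs <= ref_pos < re:
            return qs + (ref_pos - rs)
    return None


def find_cdrh3(
    seq: str,
    v_asgn: VJAssignment,
    j_asgn: VJAssignment,
    refs: GermlineReference,
) -> int | None:
    """CDRH3 length in nucleotides, anchors excluded; ``None`` if unlocatable.

    CDRH3 spans the codons strictly between the V 2nd-CYS codon and the J
    W/F anchor codon.  The anchor codon observed in the query must still be
    TGG (W) or TTT/TTC (F); a mutated-away motif leaves CDRH3 undefined.
    """
    v_allele = refs.v_alleles[v_asgn.allele_id]
    j_allele = refs.j_alleles[j_asgn.allele_id]
    cys_q = _ref_to_query(v_asgn, v_allele.cys_codon_start)
    anchor_q = _ref_to_query(j_asgn, j_allele.j_motif_start)
    if cys_q is None or anchor_q is None:
        return None
    if anchor_q + 3 > len(seq) or seq[anchor_q: anchor_q + 3] not in ANCHOR_CODONS:
        return None
    length = anchor_q - (cys_q + 3)
    if length < 0:
        return None
    return length


# ---------------------------------------------------------------------------
# Record-level driver
# ---------------------------------------------------------------------------

AIRR_COLUMNS = [
    "sequence_id", "sequence", "c_call", "v_call", "j_call", "v_identity",
    "productive", "shm_pct", "junction_length_nt", "status",
]


def annotate_sequences(
    seqs: "list[tuple[str, str, str]]",
    refs: GermlineReference,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Annotate ``(sequence_id, isotype_call, sequence)`` triples.

    Returns an AIRR-flavoured rearrangement frame.  ``status`` is ``"ok"``
    for fully annotated in-frame records, else the first failed filter
    (``no_v`` / ``no_j`` / ``out_of_frame``); SHM and CDRH3 are NaN where the
    prerequisite assignment is missing.
    """
    config = config or AnnotationConfig()
    rows = []
    for seq_id, c_call, seq in seqs:
        row = {
            "sequence_id": seq_id, "sequence": seq, "c_call": c_call,
            "v_call": "", "j_call": "", "v_identity": np.nan,
            "productive": False, "shm_pct": np.nan,
            "junction_length_nt": np.nan, "status": "no_v",
        }
        rows.append(row)
        v = assign_v_gene(seq, refs, config)
        if v is None:
            continue
        row["v_call"] = v.allele_id
        row["v_identity"] = v.identity
        row["shm_pct"] = compute_shm(seq, v, refs)
        j = assign_j_gene(seq, refs, config)
        if j is None:
            row["status"] = "no_j"
            continue
        row["j_call"] = j.allele_id
        if not check_reading_frame(seq, v, j):
            row["status"] = "out_of_frame"
            continue
        row["productive"] = True
        row["status"] = "ok"
        cdrh3 = find_cdrh3(seq, v, j, refs)
        row["junction_length_nt"] = np.nan if cdrh3 is None else float(cdrh3)
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_rearrangement_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rearrangement_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=True,
                       dtype={"c_call": str, "v_call": str, "j_call": str})


# ---------------------------------------------------------------------------
# Reference I/O: FASTA + anchors sidecar TSV
# ---------------------------------------------------------------------------

def write_germline_reference(refs: GermlineReference, fasta_path, anchors_path) -> None:
    """Write all alleles to FASTA and their anchors/spans to a sidecar TSV."""
    with open(fasta_path, "w") as fh:
        for v in refs.v_alleles.values():
            fh.write(f">{v.id}\n{v.sequence}\n")
        for j in refs.j_alleles.values():
            fh.write(f">{j.id}\n{j.sequence}\n")
        for cid, (iso, seq) in refs.constants.items():
            fh.write(f">{cid}\n{seq}\n")
    rows = []
    for v in refs.v_alleles.values():
        rows.append({"allele_id": v.id, "kind": "V", "anchor": v.cys_codon_start,
                     "primer_start": v.primer_span[0], "primer_end": v.primer_span[1],
                     "isotype": ""})
    for j in refs.j_alleles.values():
        rows.append({"allele_id": j.id, "kind": "J", "anchor": j.j_motif_start,
                     "primer_start": "", "primer_end": "", "isotype": ""})
    for cid, (iso, _) in refs.constants.items():
        rows.append({"allele_id": cid, "kind": "C", "anchor": "",
                     "primer_start": "", "primer_end": "", "isotype": iso})
    pd.DataFrame(rows).to_csv(anchors_path, sep="\t", index=False)


def load_germline_reference(fasta_path, anchors_path) -> GermlineReference:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    anchors = pd.read_csv(anchors_path, sep="\t", dtype={"allele_id": str})
    v_alleles: dict[str, VAllele] = {}
    j_alleles: dict[str, JAllele] = {}
    constants: dict[str, tuple[str, str]] = {}
    for _, row in anchors.iterrows():
        aid = row["allele_id"]
        if aid not in seqs:
            raise ValueError(f"anchors reference unknown allele {aid!r}")
        if row["kind"] == "V":
            v_alleles[aid] = VAllele(
                aid, seqs[aid], int(row["anchor"]),
                (int(row["primer_start"]), int(row["primer_end"])),
            )
        elif row["kind"] == "J":
            j_alleles[aid] = JAllele(aid, seqs[aid], int(row["anchor"]))
        elif row["kind"] == "C":
            constants[aid] = (str(row["isotype"]), seqs[aid])
        else:
            raise ValueError(f"unknown allele kind {row['kind']!r}")
    return GermlineReference(v_alleles, j_alleles, constants)
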