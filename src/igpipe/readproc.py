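"""Barcoded IgH amplicon read processing.

Implements the filtering cascade that turns raw paired MiSeq reads from a
barcoded 5'RACE-style IgH library into molecule-level consensus sequences:

1.  median-Phred quality filter (strict ``> 34``),
2.  exact overlap merging of read pairs (identical overlap ``> 50`` bp,
    otherwise the pair is discarded),
3.  orientation so sequences read V-primer -> constant-region primer,
4.  extraction of the 14-nt molecular barcode carried by the constant-region
    RT primer (template ``NNNNTNNNNTNNNN``; conserved T at 1-based positions
    5 and 10),
5.  isotype assignment by shared-10-mer counting against the first 50 bp of
    each constant-region reference,
6.  trimming of the V FR1 primer and the constant/handle block, and
7.  per-(barcode, isotype) group consensus, retained only when the group's
    positionwise sequence certainty exceeds 0.80.

Every input pair is tracked through a per-read ledger so that stage counts
are conserved (input = retained + rejected at each stage).
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequencingRead",
    "MergedRead",
    "PrimerScheme",
    "PipelineConfig",
    "IsotypeCall",
    "ConsensusRecord",
    "revcomp",
    "median_phred_filter",
    "merge_pairs",
    "orient_read",
    "extract_barcode",
    "assign_isotype",
    "trim_primers",
    "barcode_consensus",
    "process_read_pairs",
    "read_fastq_pairs",
    "write_consensus_fasta",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

ISOTYPES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequencingRead:
    id: str
    bases: str
    quals: np.ndarray  # per-base Phred, same length as bases

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != self.quals.size:
            raise ValueError(f"read {self.id}: |bases| != |quals|")

    def reverse_complement(self) -> "SequencingRead":
        return SequencingRead(self.id, revcomp(self.bases), self.quals[::-1].copy())


@dataclass
class MergedRead:
    id: str
    bases: str
    quals: np.ndarray
    overlap_length: int
    source_ids: tuple[str, str]


@dataclass(frozen=True)
class PrimerScheme:
    """The primer set of the barcoded IgH library.

    Each constant-region RT primer is ``handle + barcode template + isotype
    tail``; the barcode template is shared across isotypes.  The 3' universal
    reverse primer contains uracils, matched as T in sequence space.
    """

    handle: str = "TGTCCAGCACGCTTCAGGCT"
    barcode_template: str = "NNNNTNNNNTNNNN"
    constant_tails: dict = field(default_factory=lambda: {
        "IGHA": "GAYGACCACGTTCCCATCT",
        "IGHM": "TCGTATCCGACGGGGAATTC",
        "IGHD": "GGGCTGTTATCCTTTGGGTG",
        "IGHE": "AGAGTCACGGAGGTGGCATT",
        "IGHG": "AGTAGTCCTTGACCAGGCAG",
    })
    vh_fr1_primers: dict = field(default_factory=lambda: {
        "VH1-FR1": "GGCCTCAGTGAAGGTCTCCTGCAAG",
        "VH2-FR1": "GTCTGGTCCTACGCTGGTGAAACCC",
        "VH3-FR1": "CTGGGGGGTCCCTGAGACTCTCCTG",
        "VH4-FR1": "CTTCGGAGACCCTGTCCCTCACCTG",
        "VH5-FR1": "CGGGGAGTCTCTGAACATCTCCTGT",
        "VH6-FR1": "TCGCAGACCCTCTCACTCACCTGTG",
    })
    universal_3p: str = "TGUCCAGCACGCTUCAGGC"

    @property
    def barcode_length(self) -> int:
        return len(self.barcode_template)

    @property
    def conserved_positions(self) -> tuple[int, ...]:
        """0-based barcode positions that must be T (template non-N bases)."""
        return tuple(i for i, b in enumerate(self.barcode_template) if b != "N")

    def constant_primer(self, isotype: str) -> str:
        return self.handle + self.barcode_template + self.constant_tails[isotype]

    @classmethod
    def from_yaml(cls, path) -> "PrimerScheme":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml
        d = {
            "handle": self.handle,
            "barcode_template": self.barcode_template,
            "constant_tails": dict(self.constant_tails),
            "vh_fr1_primers": dict(self.vh_fr1_primers),
            "universal_3p": self.universal_3p,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """Numeric thresholds of the filtering cascade (strict inequalities noted)."""

    median_phred_min: float = 34.0   # pass iff median Phred strictly > this
    min_overlap: int = 50            # merge iff identical overlap strictly > this
    kmer_k: int = 10
    constant_ref_prefix: int = 50    # bp of constant reference used for matching
    certainty_min: float = 0.80      # retain iff group certainty strictly > this
    kmer_score_min: int = 5          # minimum shared-k-mer count for an isotype call
    fr1_max_mismatch: int = 2        # tolerated mismatches locating the V FR1 primer
    length_tolerance: int = 2        # nt around the modal length kept within a group

    def __post_init__(self) -> None:
        if self.kmer_k > self.constant_ref_prefix:
            raise ValueError("k-mer size exceeds constant reference prefix")
        if min(self.median_phred_min, self.min_overlap, self.kmer_k,
               self.constant_ref_prefix, self.certainty_min) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class IsotypeCall:
    isotype: str
    allele_id: str
    kmer_score: int
    margin: int  # score gap to the best allele of any other isotype


@dataclass
class TrimmedRead:
    id: str
    bases: str
    quals: np.ndarray
    fr1_primer: str
    barcode: str
    isotype: str


@dataclass
class ConsensusRecord:
    barcode: str
    isotype: str
    consensus: str
    support: int          # members at the modal length that voted
    n_members: int        # all members assigned to the group
    certainty: float      # mean positionwise plurality fraction


# ---------------------------------------------------------------------------
# Stage 1: quality filter
# ---------------------------------------------------------------------------

def median_phred_filter(read: SequencingRead, config: PipelineConfig) -> bool:
    """True iff the read's median Phred is strictly above the threshold.

    The median of an even-length list is the mean of the central pair, so a
    read whose median lands exactly on 34 fails.
    """
    if read.quals.size == 0:
        raise ValueError("empty read")
    return float(np.median(read.quals)) > config.median_phred_min


# ---------------------------------------------------------------------------
# Stage 2: pair merging
# ---------------------------------------------------------------------------

def merge_pairs(
    fwd: SequencingRead, rev: SequencingRead, config: PipelineConfig
) -> MergedRead | None:
    """Merge a pair on the longest identical fwd-suffix / revcomp(rev)-prefix.

    The reverse read is reverse-complemented first; the merge requires an
    exact (0-mismatch) overlap strictly longer than ``min_overlap`` bases.
    Overlap quality takes the per-position maximum of the two reads.  Returns
    ``None`` (discard) when no qualifying overlap exists.
    """
    rc = rev.reverse_complement()
    max_l = min(len(fwd.bases), len(rc.bases))
    for olen in range(max_l, config.min_overlap, -1):
        if fwd.bases[-olen:] == rc.bases[:olen]:
            bases = fwd.bases + rc.bases[olen:]
            quals = np.concatenate([
                fwd.quals[: len(fwd.bases) - olen],
                np.maximum(fwd.quals[len(fwd.bases) - olen:], rc.quals[:olen]),
                rc.quals[olen:],
            ])
            return MergedRead(
                id=fwd.id, bases=bases, quals=quals,
                overlap_length=olen, source_ids=(fwd.id, rev.id),
            )
    return None


# ---------------------------------------------------------------------------
# Stage 3: orientation
# ---------------------------------------------------------------------------

def orient_read(merged: MergedRead, scheme: PrimerScheme) -> tuple[MergedRead | None, str]:
    """Orient a merged read to run V-primer -> constant-region primer.

    In that orientation the reverse complement of the universal handle sits at
    the 3' end.  Returns ``(read, status)`` with status ``"oriented"``,
    ``"unassigned"`` (handle not found) or ``"chimeric"`` (handle on both
    strands).
    """
    fwd_hit = scheme.handle in merged.bases
    rc_hit = revcomp(scheme.handle) in merged.bases
    if fwd_hit and rc_hit:
        return None, "chimeric"
    if rc_hit:
        return merged, "oriented"
    if fwd_hit:
        flipped = MergedRead(
            id=merged.id, bases=revcomp(merged.bases), quals=merged.quals[::-1].copy(),
            overlap_length=merged.overlap_length, source_ids=merged.source_ids,
        )
        return flipped, "oriented"
    return None, "unassigned"


# ---------------------------------------------------------------------------
# Stage 4: barcode extraction
# ---------------------------------------------------------------------------

def extract_barcode(read: MergedRead, scheme: PrimerScheme) -> tuple[str | None, str]:
    """Extract the 14-nt barcode adjacent to the universal handle.

    On the primer strand the barcode is the 14 nt immediately following the
    handle; on a V->C oriented read this is the 14 nt immediately preceding
    the reverse-complemented handle, read back in primer orientation.  The
    call is rejected unless the template's conserved positions (T at 1-based
    5 and 10) hold and all bases are unambiguous.

    Returns ``(barcode, "ok")`` or ``(None, reason)``.
    """
    n = scheme.barcode_length
    i = read.bases.find(scheme.handle)
    if i >= 0:
        raw = read.bases[i + len(scheme.handle): i + len(scheme.handle) + n]
        if len(raw) < n:
            return None, "truncated_barcode"
        bc = raw
    else:
        j = read.bases.rfind(revcomp(scheme.handle))
        if j < 0:
            return None, "no_handle"
        if j < n:
            return None, "truncated_barcode"
        bc = revcomp(read.bases[j - n: j])
    if any(b not in "ACGT" for b in bc):
        return None, "ambiguous_base"
    for pos in scheme.conserved_positions:
        if bc[pos] != "T":
            return None, "conserved_base"
    return bc, "ok"


# ---------------------------------------------------------------------------
# Stage 5: isotype assignment
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def assign_isotype(
    read_bases: str,
    constant_refs: dict[str, tuple[str, str]],
    config: PipelineConfig,
) -> IsotypeCall | None:
    """Call the isotype by shared-10-mer counting against constant references.

    ``constant_refs`` maps allele id -> (isotype, sequence); only the first
    ``constant_ref_prefix`` bases of each reference are used.  The score of an
    allele is the number of distinct k-mers it shares with the read.  A call
    below ``kmer_score_min``, or tied between alleles of different isotypes,
    is ambiguous (``None``).
    """
    k = config.kmer_k
    if len(read_bases) < k:
        raise ValueError("read shorter than k")
    read_k = _kmers(read_bases, k)
    scores: list[tuple[int, str, str]] = []
    for allele_id, (isotype, seq) in constant_refs.items():
        prefix = seq[: config.constant_ref_prefix]
        if len(prefix) < config.constant_ref_prefix:
            raise ValueError(f"constant reference {allele_id} shorter than "
                             f"{config.constant_ref_prefix} bp")
        scores.append((len(read_k & _kmers(prefix, k)), allele_id, isotype))
    scores.sort(key=lambda t: (-t[0], t[1]))
    best_score, best_allele, best_iso = scores[0]
    if best_score < config.kmer_score_min:
        return None
    other = [s for s, _, iso in scores if iso != best_iso]
    margin = best_score - max(other) if other else best_score
    if margin == 0:
        return None  # tied across isotypes
    return IsotypeCall(best_iso, best_allele, best_score, margin)


# ---------------------------------------------------------------------------
# Stage 6: primer / constant trimming
# ---------------------------------------------------------------------------

def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(
    read: MergedRead,
    scheme: PrimerScheme,
    call: IsotypeCall,
    barcode: str,
    config: PipelineConfig,
) -> tuple[TrimmedRead | None, str]:
    """Trim the V FR1 primer and the constant/barcode/handle block.

    The FR1 primer must sit at the 5' end of the oriented read with at most
    ``fr1_max_mismatch`` mismatches (best-scoring primer of the multiplex is
    recorded).  The 3' cut removes the reverse-complemented handle, the
    barcode and ``constant_ref_prefix`` bases of constant region, leaving the
    V(D)J insert.
    """
    best_name, best_mm = None, None
    for name, primer in scheme.vh_fr1_primers.items():
        if len(read.bases) < len(primer):
            continue
        mm = _mismatches(read.bases[: len(primer)], primer)
        if best_mm is None or mm < best_mm:
            best_name, best_mm = name, mm
    if best_mm is None or best_mm > config.fr1_max_mismatch:
        return None, "no_fr1_primer"
    start = len(scheme.vh_fr1_primers[best_name])
    j = read.bases.rfind(revcomp(scheme.handle))
    if j < 0:
        return None, "no_handle"
    end = j - scheme.barcode_length - config.constant_ref_prefix
    if end <= start:
        return None, "empty_insert"
    return (
        TrimmedRead(
            id=read.id, bases=read.bases[start:end], quals=read.quals[start:end].copy(),
            fr1_primer=best_name, barcode=barcode, isotype=call.isotype,
        ),
        "ok",
    )


# ---------------------------------------------------------------------------
# Stage 7: barcode-group consensus
# ---------------------------------------------------------------------------

_BASE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)


def barcode_consensus(
    members: list[TrimmedRead], config: PipelineConfig
) -> tuple[ConsensusRecord | None, str]:
    """Collapse one (barcode, isotype) group to a consensus, or discard it.

    Members further than ``length_tolerance`` nt from the group's modal length
    are dropped; certainty is the mean, over positions, of the plurality-base
    fraction among the modal-length members.  The group is retained only when
    certainty is strictly above ``certainty_min``; the consensus takes the
    plurality base per position, ties broken by highest summed Phred, then
    alphabetically.  A singleton group has certainty 1.0 by vacuous agreement.
    """
    if not members:
        raise ValueError("empty barcode group")
    lengths = Counter(len(m.bases) for m in members)
    modal = sorted(lengths, key=lambda l: (-lengths[l], l))[0]
    kept = [m for m in members if abs(len(m.bases) - modal) <= config.length_tolerance]
    if not kept:
        return None, "length_scatter"
    voting = [m for m in kept if len(m.bases) == modal]
    arr = np.vstack([np.frombuffer(m.bases.encode(), dtype=np.uint8) for m in voting])
    quals = np.vstack([m.quals for m in voting]).astype(np.int64)
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASE_ORDER])  # 4 x L
    qsums = np.stack([np.where(arr == b, quals, 0).sum(axis=0) for b in _BASE_ORDER])
    plurality = counts.max(axis=0)
    certainty = float(plurality.mean() / len(voting))
    if certainty <= config.certainty_min:
        return None, "low_certainty"
    # plurality base; ties -> highest summed Phred -> alphabetical (stable argmax)
    rank = counts.astype(np.float64) * 1e9 + qsums
    cons_idx = rank.argmax(axis=0)
    consensus = bytes(_BASE_ORDER[cons_idx]).decode()
    barcode, isotype = members[0].barcode, members[0].isotype
    return (
        ConsensusRecord(
            barcode=barcode, isotype=isotype, consensus=consensus,
            support=len(voting), n_members=len(members), certainty=certainty,
        ),
        "ok",
    )


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

STAGES = ("quality", "merge", "orient", "barcode", "isotype", "trim", "consensus")


def process_read_pairs(
    pairs: "list[tuple[SequencingRead, SequencingRead]]",
    scheme: PrimerScheme,
    constant_refs: dict[str, tuple[str, str]],
    config: PipelineConfig | None = None,
) -> tuple[list[ConsensusRecord], pd.DataFrame, dict[str, dict[str, int]]]:
    """Run the full cascade over read pairs.

    Returns retained consensus records, a per-pair ledger
    (read_id, stage_reached, reject_reason, barcode, isotype) and per-stage
    in/out counts.  A pair passes the quality stage only if both mates pass
    the median-Phred filter.
    """
    config = config or PipelineConfig()
    ledger_rows: list[dict] = []
    counts: dict[str, dict[str, int]] = {s: {"in": 0, "out": 0} for s in STAGES}
    groups: dict[tuple[str, str], list[TrimmedRead]] = defaultdict(list)
    row_by_id: dict[str, dict] = {}

    for fwd, rev in pairs:
        row = {"read_id": fwd.id, "stage_reached": "quality", "reject_reason": "",
               "barcode": "", "isotype": ""}
        ledger_rows.append(row)
        row_by_id[fwd.id] = row
        counts["quality"]["in"] += 1
        if not (median_phred_filter(fwd, config) and median_phred_filter(rev, config)):
            row["reject_reason"] = "median_phred"
            continue
        counts["quality"]["out"] += 1

        counts["merge"]["in"] += 1
        row["stage_reached"] = "merge"
        merged = merge_pairs(fwd, rev, config)
        if merged is None:
            row["reject_reason"] = "no_identical_overlap"
            continue
        counts["merge"]["out"] += 1

        counts["orient"]["in"] += 1
        row["stage_reached"] = "orient"
        oriented, status = orient_read(merged, scheme)
        if oriented is None:
            row["reject_reason"] = status
            continue
        counts["orient"]["out"] += 1

        counts["barcode"]["in"] += 1
        row["stage_reached"] = "barcode"
        barcode, reason = extract_barcode(oriented, scheme)
        if barcode is None:
            row["reject_reason"] = reason
            continue
        row["barcode"] = barcode
        counts["barcode"]["out"] += 1

        counts["isotype"]["in"] += 1
        row["stage_reached"] = "isotype"
        call = assign_isotype(oriented.bases, constant_refs, config)
        if call is None:
            row["reject_reason"] = "ambiguous_isotype"
            continue
        row["isotype"] = call.isotype
        counts["isotype"]["out"] += 1

        counts["trim"]["in"] += 1
        row["stage_reached"] = "trim"
        trimmed, reason = trim_primers(oriented, scheme, call, barcode, config)
        if trimmed is None:
            row["reject_reason"] = reason
            continue
        counts["trim"]["out"] += 1
        row["stage_reached"] = "consensus"
        groups[(barcode, call.isotype)].append(trimmed)

    records: list[ConsensusRecord] = []
    for (barcode, isotype), members in groups.items():
        counts["consensus"]["in"] += len(members)
        rec, reason = barcode_consensus(members, config)
        if rec is None:
            for m in members:
                row_by_id[m.id]["reject_reason"] = reason
            continue
        counts["consensus"]["out"] += len(members)
        for m in members:
            row_by_id[m.id]["stage_reached"] = "retained"
        records.append(rec)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["read_id", "stage_reached", "reject_reason", "barcode", "isotype"],
    )
    return records, ledger, counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_maybe_gz(path):
    p = str(path)
    return gzip.open(p, "rt") if p.endswith(".gz") else open(p)


def read_fastq_pairs(r1_path, r2_path) -> list[tuple[SequencingRead, SequencingRead]]:
    """Load paired FASTQ (optionally gzipped) into SequencingRead pairs."""
    from Bio import SeqIO

    pairs = []
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            pairs.append((
                SequencingRead(rec1.id, str(rec1.seq),
                               np.array(rec1.letter_annotations["phred_quality"])),
                SequencingRead(rec2.id, str(rec2.seq),
                               np.array(rec2.letter_annotations["phred_quality"])),
            ))
    return pairs


def write_consensus_fasta(records: list[ConsensusRecord], path) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fh.write(f">consensus_{i}|barcode={rec.barcode}|isotype={rec.isotype}"
                     f"|support={rec.support}|certainty={rec.certainty:.4f}\n")
            fh.write(rec.consensus + "\n")
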