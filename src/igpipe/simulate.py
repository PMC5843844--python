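"""Synthetic IgH repertoires, paired reads, and factorial response tables.

Everything the pipeline and the DoE engine consume can be generated here
with a complete ground-truth ledger, so the whole artifact is testable
offline:

* :func:`make_toy_references` builds a toy germline set — mutually divergent
  V alleles whose 5' ends are the six multiplex VH FR1 primers, short J
  alleles with a W anchor codon, and five isotype constant-region references
  whose primer-annealing tails equal the default scheme's constant-primer tails —
  plus the matching primer scheme.
* :func:`simulate_repertoire` builds clonal, in-frame V-junction-J-constant
  amplicon molecules with per-molecule 14-nt barcodes and per-site somatic
  hypermutation over the non-primer V positions.
* :func:`simulate_reads` turns molecules into overlapping paired reads with
  Phred-annotated substitution errors, emulating 300 bp paired-end MiSeq.
* :func:`simulate_doe_response` builds balanced 3^4 factorial Ig-secretion
  tables with known main effects, pairwise interactions, donor offsets and
  Gaussian noise.

Substitution-only models throughout (no indels): this matches the
mismatch-fraction SHM statistic and fixed-frame CDRH3 definition used
downstream and keeps every oracle closed-form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GermlineReference, JAllele, VAllele
from .doe import Factor, FactorialDesign
from .readproc import PrimerScheme, SequencingRead, revcomp

__all__ = [
    "RepertoireSimParams",
    "DoESimParams",
    "Molecule",
    "DEFAULT_ISOTYPE_MIXTURES",
    "DEFAULT_CDRH3_DISTRIBUTION",
    "make_toy_references",
    "simulate_repertoire",
    "simulate_reads",
    "simulate_doe_response",
    "default_recovery_params",
    "write_paired_fastq",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)
BASES = "ACGT"

# Observed-regime isotype mixtures per sorted memory-B-cell subset: IgM+
# subsets stay essentially IgM, the double-negative subset carries a stable
# IgG/IgA class mixture.
DEFAULT_ISOTYPE_MIXTURES = {
    "IgM+IgD+": {"IGHM": 0.85, "IGHD": 0.15},
    "IgM+IgD-": {"IGHM": 0.95, "IGHD": 0.05},
    "IgM-IgD-": {"IGHG": 0.55, "IGHA": 0.40, "IGHE": 0.05},
    "IgM-IgD+": {"IGHD": 0.90, "IGHM": 0.10},
}

# CDRH3 nucleotide lengths (anchors excluded, multiples of 3) roughly
# mirroring the 30-70 nt bulk of human repertoires.
DEFAULT_CDRH3_DISTRIBUTION = {
    30: 0.08, 36: 0.17, 42: 0.25, 48: 0.23, 54: 0.15, 60: 0.08, 66: 0.04,
}


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimParams:
    """Knobs of the repertoire/read simulator (seed mandatory)."""

    seed: int
    n_clones: int = 50
    molecules_per_clone: int = 4
    subset: str = "IgM-IgD-"
    isotype_mixture: dict | None = None     # default: subset preset
    shm_rate: float = 0.0                   # per-site, non-primer V positions
    cdrh3_distribution: dict | None = None  # nt length -> probability
    reads_per_molecule: int = 20            # typical UMI family depth
    seq_error_rate: float = 0.0             # per-base substitution probability
    phred: int = 38                         # flat Phred profile
    read_length: int = 300                  # paired-end MiSeq geometry
    force_overlap: int | None = None        # exact R1/R2 overlap override
    barcode_collision_rate: float = 0.0     # stress-test knob

    def __post_init__(self) -> None:
        if self.isotype_mixture is None:
            self.isotype_mixture = dict(DEFAULT_ISOTYPE_MIXTURES[self.subset])
        if self.cdrh3_distribution is None:
            self.cdrh3_distribution = dict(DEFAULT_CDRH3_DISTRIBUTION)
        for p in (*self.isotype_mixture.values(), self.shm_rate,
                  self.seq_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.isotype_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("isotype mixture must sum to 1")
        if abs(sum(self.cdrh3_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("CDRH3 length distribution must sum to 1")
        if any(l % 3 != 0 for l in self.cdrh3_distribution):
            raise ValueError("CDRH3 lengths must be multiples of 3")


@dataclass
class DoESimParams:
    """Effect truth for a balanced factorial Ig-secretion table."""

    seed: int
    grand_mean: float = 1000.0
    main_effects: dict = field(default_factory=dict)    # factor -> {level: effect}
    interactions: dict = field(default_factory=dict)    # (fa, fb) -> {(la, lb): effect}
    donor_offsets: dict = field(default_factory=dict)   # donor id -> offset
    noise_sd: float = 0.0
    replicates: int = 3
    isotypes: tuple = ("total",)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >=1 replicate")


@dataclass
class Molecule:
    """One simulated IgH transcript with its amplicon and truth fields."""

    id: str
    clone_id: str
    subset: str
    isotype: str
    c_allele: str
    v_allele: str
    j_allele: str
    barcode: str
    sequence: str            # full amplicon, V-primer -> revcomp(handle)
    insert: str              # true trimmed insert: V (minus FR1 primer) + junction + J
    mutations: tuple         # 0-based mutated positions within the V allele
    cdrh3_nt: int


# ---------------------------------------------------------------------------
# Toy references
# ---------------------------------------------------------------------------

def _fix_stops(seq: list[str], rng: np.random.Generator, start_codon: int = 0) -> None:
    """Replace frame-0 stop codons in-place by rewriting their last base."""
    for i in range(start_codon * 3, len(seq) - 2, 3):
        while "".join(seq[i: i + 3]) in STOP_CODONS:
            seq[i + 2] = BASES[rng.integers(4)]


def _resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    table = {"Y": "CT", "R": "AG", "W": "AT", "S": "CG", "K": "GT", "M": "AC"}
    return "".join(b if b in BASES else table[b][rng.integers(len(table[b]))]
                   for b in seq)


def make_toy_references(seed: int) -> tuple[GermlineReference, PrimerScheme]:
    """Deterministic toy germline set + the default primer scheme.

    Six 300-nt V alleles (one per multiplex FR1 primer, mutually divergent
    random bodies, frame 0, 2nd-CYS = final TGT codon), four 48-nt J alleles
    opening with the W anchor codon, and five 50-bp constant references whose
    3' ends reverse-complement the scheme's isotype primer tails.
    """
    rng = np.random.default_rng(seed)
    scheme = PrimerScheme()

    v_alleles: dict[str, VAllele] = {}
    for k, (pname, primer) in enumerate(sorted(scheme.vh_fr1_primers.items())):
        body = [BASES[i] for i in rng.integers(4, size=300 - len(primer))]
        seq = list(primer) + body
        _fix_stops(seq, rng)
        seq[297:300] = list("TGT")  # 2nd-CYS codon
        vid = f"IGHV{k + 1}-TOY*01"
        v_alleles[vid] = VAllele(vid, "".join(seq), 297, (0, len(primer)))

    j_alleles: dict[str, JAllele] = {}
    for k in range(4):
        tail = [BASES[i] for i in rng.integers(4, size=45)]
        seq = list("TGG") + tail
        _fix_stops(seq, rng)
        jid = f"IGHJ{k + 1}-TOY*01"
        j_alleles[jid] = JAllele(jid, "".join(seq), 0)

    constants: dict[str, tuple[str, str]] = {}
    for iso in ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE"):
        tail_rc = revcomp(_resolve_iupac(scheme.constant_tails[iso], rng))
        head = "".join(BASES[i] for i in rng.integers(4, size=50 - len(tail_rc)))
        constants[f"{iso}-TOY*01"] = (iso, head + tail_rc)

    return GermlineReference(v_alleles, j_alleles, constants), scheme


# ---------------------------------------------------------------------------
# Repertoire simulation
# ---------------------------------------------------------------------------

def _draw_barcode(rng: np.random.Generator, scheme: PrimerScheme,
                  used: set[str], collision_rate: float) -> str:
    if used and collision_rate > 0 and rng.random() < collision_rate:
        return sorted(used)[rng.integers(len(used))]
    conserved = set(scheme.conserved_positions)
    while True:
        bc = "".join(
            "T" if i in conserved else BASES[rng.integers(4)]
            for i in range(scheme.barcode_length)
        )
        if bc not in used:
            used.add(bc)
            return bc


def _mutate_v(v_seq: str, rate: float, primer_end: int,
              rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """Per-site substitutions over non-primer V positions, never creating a
    frame-0 stop codon (an alternative base always exists)."""
    seq = list(v_seq)
    hit = np.flatnonzero(rng.random(len(seq) - primer_end) < rate) + primer_end
    placed = []
    for pos in hit:
        orig = seq[pos]
        choices = [b for b in BASES if b != orig]
        order = rng.permutation(len(choices))
        c0 = (pos // 3) * 3
        for idx in order:
            seq[pos] = choices[idx]
            if "".join(seq[c0: c0 + 3]) not in STOP_CODONS:
                break
        else:
            seq[pos] = orig
            continue
        placed.append(int(pos))
    return "".join(seq), tuple(placed)


def simulate_repertoire(
    params: RepertoireSimParams,
    refs: GermlineReference,
    scheme: PrimerScheme | None = None,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Build clonal amplicon molecules and the per-molecule truth ledger.

    A clone fixes (V, J, junction, isotype); each of its molecules gets an
    independent SHM draw and a unique template-conformant barcode.  The
    amplicon runs FR1 primer -> V -> junction -> J -> first 50 bp of the
    constant region -> revcomp(barcode) -> revcomp(handle), i.e. already in
    V -> constant-primer orientation.
    """
    scheme = scheme or PrimerScheme()
    rng = np.random.default_rng(params.seed)
    iso_by_allele = {cid: iso for cid, (iso, _) in refs.constants.items()}
    alleles_by_iso: dict[str, list[str]] = {}
    for cid, iso in iso_by_allele.items():
        alleles_by_iso.setdefault(iso, []).append(cid)
    for iso in params.isotype_mixture:
        if iso not in alleles_by_iso:
            raise ValueError(f"isotype {iso!r} in mixture has no constant reference")

    v_ids = sorted(refs.v_alleles)
    j_ids = sorted(refs.j_alleles)
    iso_names = sorted(params.isotype_mixture)
    iso_probs = np.array([params.isotype_mixture[i] for i in iso_names])
    lens = sorted(params.cdrh3_distribution)
    len_probs = np.array([params.cdrh3_distribution[l] for l in lens])

    used_barcodes: set[str] = set()
    molecules: list[Molecule] = []
    rows = []
    mol_n = 0
    for c in range(params.n_clones):
        clone_id = f"C{c:05d}"
        v_id = v_ids[rng.integers(len(v_ids))]
        j_id = j_ids[rng.integers(len(j_ids))]
        isotype = iso_names[rng.choice(len(iso_names), p=iso_probs)]
        c_allele = sorted(alleles_by_iso[isotype])[
            rng.integers(len(alleles_by_iso[isotype]))]
        jl = int(np.asarray(lens)[rng.choice(len(lens), p=len_probs)])
        junction = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(len(_NONSTOP_CODONS), size=jl // 3)
        )
        v_ref = refs.v_alleles[v_id]
        j_seq = refs.j_alleles[j_id].sequence
        c_seq = refs.constants[c_allele][1][:50]
        for _ in range(params.molecules_per_clone):
            v_mut, muts = _mutate_v(v_ref.sequence, params.shm_rate,
                                    v_ref.primer_span[1], rng)
            barcode = _draw_barcode(rng, scheme, used_barcodes,
                                    params.barcode_collision_rate)
            insert = v_mut[v_ref.primer_span[1]:] + junction + j_seq
            amplicon = (v_mut + junction + j_seq + c_seq
                        + revcomp(barcode) + revcomp(scheme.handle))
            mol = Molecule(
                id=f"M{mol_n:06d}", clone_id=clone_id, subset=params.subset,
                isotype=isotype, c_allele=c_allele, v_allele=v_id, j_allele=j_id,
                barcode=barcode, sequence=amplicon, insert=insert,
                mutations=muts, cdrh3_nt=jl,
            )
            molecules.append(mol)
            rows.append({
                "molecule_id": mol.id, "clone_id": clone_id,
                "subset": params.subset, "isotype": isotype,
                "c_allele": c_allele, "v_allele": v_id, "j_allele": j_id,
                "barcode": barcode, "n_mutations": len(muts),
                "mutation_positions": ";".join(map(str, muts)),
                "cdrh3_nt": jl, "insert": insert,
            })
            mol_n += 1
    return molecules, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _add_errors(bases: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return bases
    arr = list(bases)
    for pos in np.flatnonzero(rng.random(len(arr)) < rate):
        alt = [b for b in BASES if b != arr[pos]]
        arr[pos] = alt[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    molecules: list[Molecule], params: RepertoireSimParams
) -> tuple[list[tuple[SequencingRead, SequencingRead]], pd.DataFrame]:
    """Emit overlapping R1/R2 pairs per molecule with substitution errors.

    R1 reads the amplicon 5' end in sense orientation, R2 the 3' end
    reverse-complemented; their true overlap is ``2 * read_length - |amplicon|``
    (or exactly ``force_overlap`` when set).  Quality values follow the flat
    Phred profile.  Returns the pairs plus a read-to-molecule truth ledger.
    """
    rng = np.random.default_rng(params.seed + 1)
    pairs: list[tuple[SequencingRead, SequencingRead]] = []
    rows = []
    for mol in molecules:
        n = len(mol.sequence)
        if params.force_overlap is not None:
            o = params.force_overlap
            l1 = (n + o + 1) // 2
            l2 = n + o - l1
            if l1 > n or l2 > n or l2 < 1:
                raise ValueError(f"molecule {mol.id} shorter than required span")
        else:
            l1 = l2 = min(params.read_length, n)
            if l1 + l2 <= n:
                raise ValueError(f"molecule {mol.id} too long for overlapping "
                                 f"{params.read_length} nt reads")
        for k in range(params.reads_per_molecule):
            rid = f"{mol.id}:r{k}"
            r1 = _add_errors(mol.sequence[:l1], params.seq_error_rate, rng)
            r2 = _add_errors(revcomp(mol.sequence[n - l2:]),
                             params.seq_error_rate, rng)
            q1 = np.full(l1, params.phred, dtype=np.int16)
            q2 = np.full(l2, params.phred, dtype=np.int16)
            pairs.append((SequencingRead(rid, r1, q1), SequencingRead(rid, r2, q2)))
            rows.append({"read_id": rid, "molecule_id": mol.id,
                         "barcode": mol.barcode, "isotype": mol.isotype})
    return pairs, pd.DataFrame(rows)


def write_paired_fastq(
    pairs: list[tuple[SequencingRead, SequencingRead]], r1_path, r2_path
) -> None:
    def _dump(reads, path):
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.id}\n{r.bases}\n+\n")
                fh.write("".join(chr(q + 33) for q in r.quals) + "\n")

    _dump([p[0] for p in pairs], r1_path)
    _dump([p[1] for p in pairs], r2_path)


# ---------------------------------------------------------------------------
# Factorial response simulation
# ---------------------------------------------------------------------------

def simulate_doe_response(
    design: FactorialDesign, params: DoESimParams
) -> pd.DataFrame:
    """Balanced factorial response table from known effects.

    ``response = grand_mean + main effects + pairwise interactions + donor
    offset + N(0, noise_sd)``, replicated ``replicates`` times per condition,
    donor and isotype.
    """
    factor_names = [f.name for f in design.factors]
    for fname, levels in params.main_effects.items():
        fac = design.factor(fname)
        for lv in levels:
            if lv not in fac.labels:
                raise KeyError(f"effect references unknown level {lv!r} of {fname!r}")
    for (fa, fb), cells in params.interactions.items():
        fa_l, fb_l = design.factor(fa).labels, design.factor(fb).labels
        for la, lb in cells:
            if la not in fa_l or lb not in fb_l:
                raise KeyError(f"interaction references unknown cell {(la, lb)!r}")

    rng = np.random.default_rng(params.seed)
    donors = sorted(params.donor_offsets) or ["D1"]
    rows = []
    for pt in design.points:
        a = pt.as_dict()
        base = params.grand_mean
        for fname, levels in params.main_effects.items():
            base += levels.get(a[fname], 0.0)
        for (fa, fb), cells in params.interactions.items():
            base += cells.get((a[fa], a[fb]), 0.0)
        for iso in params.isotypes:
            for donor in donors:
                mu = base + params.donor_offsets.get(donor, 0.0)
                noise = rng.normal(0.0, params.noise_sd, size=params.replicates) \
                    if params.noise_sd > 0 else np.zeros(params.replicates)
                for rep in range(params.replicates):
                    rows.append({**a, "donor": donor, "replicate": rep + 1,
                                 "isotype": iso, "response": mu + noise[rep]})
    return pd.DataFrame(rows, columns=factor_names
                        + ["donor", "replicate", "isotype", "response"])


def default_recovery_params(seed: int) -> DoESimParams:
    """The study-conditions simulation for DoE parameter recovery.

    Three donors in triplicate over the 3^4 grid; dose-increasing main
    effects for IL-21, R848 and CD40; a synergistic IL-21 x CD40 high-high
    interaction; a truly null CpG; Gaussian noise with SD equal to 25% of
    the largest effect.
    """
    return DoESimParams(
        seed=seed,
        grand_mean=1000.0,
        main_effects={
            "IL21": {"10": 0.0, "50": 5.0, "100": 10.0},
            "R848": {"0": 0.0, "0.25": 4.0, "0.5": 8.0},
            "CD40": {"1:5": 0.0, "1:2": 3.0, "1:1": 6.0},
        },
        interactions={("IL21", "CD40"): {("100", "1:1"): 6.0}},
        donor_offsets={"D1": -8.0, "D2": 0.0, "D3": 8.0},
        noise_sd=2.5,
        replicates=3,
    )
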