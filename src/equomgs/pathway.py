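"""Equol-pathway genotyping by translated homology search.

The equol pathway reduces the soy isoflavone daidzein to equol through four
enzymes: daidzein reductase (dzr), dihydrodaidzein reductase (ddr),
tetrahydrodaidzein reductase (tdr) and a racemase.  A genome is genotyped by
searching each protein against all six reading frames of its contigs
(bacterial genetic code), keeping the best local alignment, and calling a
protein detected when amino-acid identity >= 90% and query coverage >= 90%.
A strain carrying at least 75% of the four proteins (i.e. >= 3) is called an
equol producer.

The search is seeded with exact amino-acid k-mer matches for speed (frames
are split at stop codons and segments with enough seeds are aligned with
BLOSUM62 / affine gaps); ``exhaustive=True`` forces full dynamic programming
over every segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = [
    "ROLES",
    "ProteinQuery",
    "ProteinHit",
    "ProducerCall",
    "six_frame_translate",
    "search_protein",
    "detect_protein",
    "call_producer",
    "genotype_genome",
]

ROLES = ("dzr", "ddr", "tdr", "racemase")

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinQuery:
    """A pathway protein: role, accession label, amino-acid sequence."""

    role: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not one of {ROLES}")
        if not self.sequence or not set(self.sequence) <= _AA20:
            raise ValueError("sequence must be nonempty over the 20-letter alphabet")


@dataclass
class ProteinHit:
    """Best translated-search hit of one query in one genome."""

    role: str
    identity: float  # % over aligned columns (gap columns excluded)
    coverage: float  # % of query residues aligned
    contig: int | None = None
    frame: int | None = None  # +1..+3 forward, -1..-3 reverse
    start: int | None = None  # aa position within the translated frame segment
    score: float = 0.0


@dataclass
class ProducerCall:
    """Per-genome equol-producer genotype from the four protein detections."""

    genome_id: str
    detected: dict[str, bool]
    detected_fraction: float
    is_producer: bool
    hits: dict[str, ProteinHit] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def six_frame_translate(contig: str) -> list[str]:
    """Translate a contig in all six frames with the bacterial code (table 11).

    Returns frames [+1, +2, +3, -1, -2, -3]; stop codons render as '*',
    trailing 1-2 bases are dropped, N codons translate to X.  Characters
    outside ACGTN are rejected.
    """
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    up = contig.upper()
    if set(up) - set("ACGTN"):
        raise ValueError(f"invalid characters in contig: {sorted(set(up) - set('ACGTN'))[:5]}")
    fwd = Seq(up)
    rev = fwd.reverse_complement()
    frames = []
    for strand in (fwd, rev):
        for off in (0, 1, 2):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            frames.append(str(sub.translate(table=11)))
    return frames


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _segments(frame: str):
    """Stop-free segments of a translated frame, with their aa offsets."""
    start = 0
    for part in frame.split("*"):
        if part:
            yield start, part
        start += len(part) + 1


def _align_local(query: str, segment: str) -> tuple[float, float, float]:
    """Best local alignment of query vs segment: (score, identity%, coverage%)."""
    q = bseq.ProteinSequence(query)
    s = bseq.ProteinSequence(segment)
    alns = balign.align_optimal(
        q, s, _BLOSUM62, gap_penalty=(-11, -1), local=True, max_number=1
    )
    if not alns:
        return 0.0, 0.0, 0.0
    aln = alns[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    if not both.any():
        return 0.0, 0.0, 0.0
    qs = np.asarray(q.code)[trace[both, 0]]
    ss = np.asarray(s.code)[trace[both, 1]]
    matches = int((qs == ss).sum())
    identity = 100.0 * matches / int(both.sum())
    coverage = 100.0 * int((trace[:, 0] >= 0).sum()) / len(query)
    return float(aln.score), identity, coverage


def search_protein(
    query: ProteinQuery,
    genome,
    seed_word: int = 4,
    min_seed_hits: int = 2,
    exhaustive: bool = False,
) -> ProteinHit:
    """Best local alignment of a pathway protein across all frames of a genome.

    Frames are split at stop codons; segments sharing at least
    ``min_seed_hits`` exact ``seed_word``-mers with the query are aligned
    (BLOSUM62, affine gaps open 11 / extend 1).  Queries shorter than twice
    the seed word fall back to exhaustive alignment.  If no segment qualifies
    the hit has identity 0 and coverage 0.
    """
    qseq = query.sequence
    if not qseq:
        raise ValueError("empty query")
    if len(qseq) < 2 * seed_word:
        exhaustive = True
    seeds = {qseq[i : i + seed_word] for i in range(len(qseq) - seed_word + 1)}
    best = ProteinHit(role=query.role, identity=0.0, coverage=0.0)
    for ci, contig in enumerate(genome.contigs):
        if len(contig) < 3:
            continue
        frames = six_frame_translate(contig)
        for fi, frame in enumerate(frames):
            frame_label = fi + 1 if fi < 3 else -(fi - 2)
            for off, seg in _segments(frame):
                if len(seg) < min(3, len(qseq)):
                    continue
                if not exhaustive:
                    hits = sum(
                        seg[i : i + seed_word] in seeds
                        for i in range(len(seg) - seed_word + 1)
                    )
                    if hits < min_seed_hits:
                        continue
                score, identity, coverage = _align_local(qseq, seg)
                if score > best.score:
                    best = ProteinHit(
                        role=query.role,
                        identity=identity,
                        coverage=coverage,
                        contig=ci,
                        frame=frame_label,
                        start=off,
                        score=score,
                    )
    return best


def detect_protein(hit: ProteinHit, min_identity: float = 90.0, min_coverage: float = 90.0) -> bool:
    """Detection rule: identity >= min_identity AND coverage >= min_coverage."""
    return hit.identity >= min_identity and hit.coverage >= min_coverage


def call_producer(detections: dict[str, bool], min_fraction: float = 0.75) -> bool:
    """Producer rule: detected fraction of the four roles >= min_fraction."""
    missing = set(ROLES) - set(detections)
    if missing:
        raise ValueError(f"missing roles: {sorted(missing)}")
    fraction = sum(bool(detections[r]) for r in ROLES) / len(ROLES)
    return fraction >= min_fraction


def genotype_genome(
    genome,
    queries: list[ProteinQuery],
    min_identity: float = 90.0,
    min_coverage: float = 90.0,
    producer_min_fraction: float = 0.75,
    exhaustive: bool = False,
) -> ProducerCall:
    """Search all four pathway proteins in a genome and call producer status."""
    roles = [q.role for q in queries]
    if sorted(roles) != sorted(ROLES):
        raise ValueError(f"queries must cover roles {ROLES}, got {roles}")
    hits = {
        q.role: search_protein(q, genome, exhaustive=exhaustive) for q in queries
    }
    detected = {
        r: detect_protein(h, min_identity, min_coverage) for r, h in hits.items()
    }
    fraction = sum(detected.values()) / len(ROLES)
    return ProducerCall(
        genome_id=genome.genome_id,
        detected=detected,
        detected_fraction=fraction,
        is_producer=fraction >= producer_min_fraction,
        hits=hits,
    )
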