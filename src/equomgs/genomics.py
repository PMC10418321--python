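"""Genomospecies delineation from genome assemblies.

The workflow mirrors how bacterial species are delineated from assembly
collections: quality-filter the genomes (completeness/contamination), compute
pairwise Average Nucleotide Identity (ANI) with a fragment-based k-mer
estimator, build a symmetric matrix, cluster with UPGMA on the 1 - ANI/100
distance, cut the dendrogram at the conventional 95% ANI species threshold,
embed the matrix with non-metric multidimensional scaling for visualisation,
and test cluster-metadata associations with a chi-squared test.

The ANI estimator splits the query into non-overlapping fragments
(default 3,000 bp), assigns each fragment to the reference diagonal sharing
the most exact 16-mers, and inverts the expected intact-k-mer fraction
m = p^k to a per-fragment identity p = m^(1/k).  An exact-alignment
per-fragment mode (``mode="alignment"``) recomputes fragment identity by
optimal global alignment and serves as an internal oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import TestResult, chi_squared

__all__ = [
    "GenomeRecord",
    "AniEstimate",
    "AniMatrix",
    "Dendrogram",
    "PhylogroupAssignment",
    "NmdsEmbedding",
    "qc_filter",
    "pairwise_ani",
    "symmetric_ani",
    "build_ani_matrix",
    "upgma",
    "cut_clusters",
    "nmds",
    "metadata_association",
]

ANI_FLOOR = 70.0  # assigned to pairs with no mappable fragment in either direction

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i


@dataclass
class GenomeRecord:
    """An assembled genome with QC values and host metadata."""

    genome_id: str
    contigs: list[str]
    source: str = "MAG"  # "MAG" or "isolate"
    completeness: float | None = None
    contamination: float | None = None
    host_species: str = "human"
    geography: str | None = None

    def __post_init__(self) -> None:
        if self.total_length == 0:
            raise ValueError(f"genome {self.genome_id} is empty")
        for value, name in ((self.completeness, "completeness"), (self.contamination, "contamination")):
            if value is not None and not (0.0 <= value <= 100.0):
                raise ValueError(f"{name} {value} outside [0, 100]")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class AniEstimate:
    """Directed ANI estimate: mean per-fragment identity of query vs reference."""

    query_id: str
    reference_id: str
    ani: float  # percent; NaN when no fragment mapped
    fragments_total: int
    fragments_mapped: int


@dataclass
class AniMatrix:
    """Symmetric matrix of pairwise ANI percentages."""

    ids: list[str]
    values: np.ndarray
    floored_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("ANI matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("ANI matrix diagonal must be 100")
        self.values = v

    def distances(self) -> np.ndarray:
        """Distance matrix 1 - ANI/100, in [0, 1]."""
        return (100.0 - self.values) / 100.0


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    genomes: list[GenomeRecord],
    min_completeness: float = 80.0,
    max_contamination: float = 5.0,
) -> list[GenomeRecord]:
    """Keep genomes with completeness >= min and contamination <= max.

    Both boundaries are inclusive.  Isolate genomes without QC values pass by
    default (a warning flags them); MAGs must carry QC values.
    """
    kept = []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            if g.source == "isolate":
                warnings.warn(
                    f"isolate {g.genome_id} has no QC values; kept by default",
                    stacklevel=2,
                )
                kept.append(g)
            else:
                raise ValueError(f"MAG {g.genome_id} lacks completeness/contamination")
        elif g.completeness >= min_completeness and g.contamination <= max_contamination:
            kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# ANI estimation
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for all k-mers plus a validity mask (no non-ACGT base)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + arr[j : j + n].astype(np.uint64)
    bad = np.concatenate([[0], np.cumsum(arr >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


class _AniIndex:
    """Per-genome cache: fragment k-mer codes (query role) and a unique-k-mer
    position index (reference role)."""

    def __init__(self, genome: GenomeRecord, fragment_length: int, k: int):
        self.genome = genome
        self.k = k
        self.fragment_length = fragment_length
        # fragments: list of (codes, valid) per fragment, positions local to fragment
        self.fragments: list[tuple[np.ndarray, np.ndarray]] = []
        all_codes = []
        all_pos = []
        offset = 0
        frag_slices: list[tuple[int, int, int]] = []  # (contig idx, start, end)
        for ci, contig in enumerate(genome.contigs):
            arr = _encode(contig)
            codes, valid = _kmer_codes(arr, k)
            if len(codes):
                all_codes.append(codes[valid])
                all_pos.append(np.nonzero(valid)[0].astype(np.int64) + offset)
            nfrag = len(contig) // fragment_length
            for f in range(nfrag):
                frag_slices.append((ci, f * fragment_length, (f + 1) * fragment_length))
            offset += len(contig) + k  # gap so cross-contig diagonals never collide
        if not frag_slices:
            # genome shorter than one fragment: whole contigs as fragments
            frag_slices = [(ci, 0, len(c)) for ci, c in enumerate(genome.contigs)]
        self._contig_arrays = [_encode(c) for c in genome.contigs]
        self._contig_offsets = np.cumsum(
            [0] + [len(c) + k for c in genome.contigs[:-1]]
        )
        for ci, start, end in frag_slices:
            codes, valid = _kmer_codes(self._contig_arrays[ci][start:end], k)
            self.fragments.append((codes[valid], np.nonzero(valid)[0]))
        self.frag_slices = frag_slices
        if all_codes:
            codes = np.concatenate(all_codes)
            pos = np.concatenate(all_pos)
            order = np.argsort(codes, kind="stable")
            codes, pos = codes[order], pos[order]
            uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
            single = counts == 1
            self.ref_codes = uniq[single]
            self.ref_pos = pos[first[single]]
        else:
            self.ref_codes = np.empty(0, dtype=np.uint64)
            self.ref_pos = np.empty(0, dtype=np.int64)

    def fragment_sequence(self, idx: int) -> str:
        ci, start, end = self.frag_slices[idx]
        return self.genome.contigs[ci][start:end]

    def reference_window(self, global_start: int, length: int) -> str:
        """Concatenated-coordinate window (within a single contig)."""
        starts = self._contig_offsets
        ci = int(np.searchsorted(starts, global_start, side="right")) - 1
        local = global_start - int(starts[ci])
        contig = self.genome.contigs[ci]
        local = max(0, min(local, max(len(contig) - 1, 0)))
        return contig[local : local + length]


def _directed_ani(
    qidx: _AniIndex,
    ridx: _AniIndex,
    min_fragment_kmer_hits: int,
    band: int,
    mode: str,
) -> AniEstimate:
    k = qidx.k
    identities = []
    mapped = 0
    for fi, (codes, qpos) in enumerate(qidx.fragments):
        nk = len(codes)
        if nk == 0:
            continue
        if len(ridx.ref_codes) == 0:
            continue
        hit = np.searchsorted(ridx.ref_codes, codes)
        hit = np.minimum(hit, len(ridx.ref_codes) - 1)
        match = ridx.ref_codes[hit] == codes
        if not match.any():
            continue
        diags = ridx.ref_pos[hit[match]] - qpos[match]
        uniq, counts = np.unique(diags, return_counts=True)
        best_i = int(np.argmax(counts))
        best_diag = uniq[best_i]
        votes = int(counts[np.abs(uniq - best_diag) <= band].sum())
        if votes <= min_fragment_kmer_hits:
            continue
        mapped += 1
        if mode == "kmer":
            m = votes / nk
            identities.append(100.0 * m ** (1.0 / k))
        elif mode == "alignment":
            identities.append(
                _fragment_alignment_identity(qidx, fi, ridx, int(best_diag))
            )
        else:
            raise ValueError(f"unknown ANI mode {mode!r}")
    ani = float(np.mean(identities)) if identities else float("nan")
    return AniEstimate(
        query_id=qidx.genome.genome_id,
        reference_id=ridx.genome.genome_id,
        ani=ani,
        fragments_total=len(qidx.fragments),
        fragments_mapped=mapped,
    )


def _fragment_alignment_identity(
    qidx: _AniIndex, frag_idx: int, ridx: _AniIndex, diag: int
) -> float:
    """Oracle-mode fragment identity by optimal global alignment."""
    from Bio import Align

    frag = qidx.fragment_sequence(frag_idx)
    window = ridx.reference_window(diag, len(frag) + 2 * qidx.k)
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    aligner.target_end_open_gap_score = 0
    aligner.target_end_extend_gap_score = 0
    aligner.query_end_open_gap_score = 0
    aligner.query_end_extend_gap_score = 0
    aln = aligner.align(frag, window)[0]
    counts = aln.counts()
    identities, mismatches = counts.identities, counts.mismatches
    aligned = identities + mismatches
    return 100.0 * identities / aligned if aligned else 0.0


def pairwise_ani(
    query: GenomeRecord,
    reference: GenomeRecord,
    fragment_length: int = 3000,
    k: int = 16,
    min_fragment_kmer_hits: int = 5,
    band: int = 5,
    mode: str = "kmer",
) -> AniEstimate:
    """Directed ANI of ``query`` against ``reference``.

    Fragments with a banded best-diagonal k-mer vote count strictly above
    ``min_fragment_kmer_hits`` are considered mapped; ANI is the mean
    per-fragment identity over mapped fragments (NaN if none map).
    """
    if fragment_length <= k:
        raise ValueError("fragment_length must exceed k")
    qidx = _AniIndex(query, fragment_length, k)
    ridx = _AniIndex(reference, fragment_length, k)
    return _directed_ani(qidx, ridx, min_fragment_kmer_hits, band, mode)


def symmetric_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    floor: float = ANI_FLOOR,
    **kwargs,
) -> float:
    """Symmetric ANI: mean of the two directed estimates.

    If only one direction has mapped fragments its value is used; if neither
    does, the pair is unalignable and gets the ``floor`` value (below any
    species threshold) so the matrix stays complete for clustering.
    """
    fwd = pairwise_ani(a, b, **kwargs).ani
    rev = pairwise_ani(b, a, **kwargs).ani
    vals = [v for v in (fwd, rev) if not np.isnan(v)]
    if not vals:
        return float(floor)
    return float(np.mean(vals))


def build_ani_matrix(
    genomes: list[GenomeRecord],
    fragment_length: int = 3000,
    k: int = 16,
    min_fragment_kmer_hits: int = 5,
    band: int = 5,
    floor: float = ANI_FLOOR,
) -> AniMatrix:
    """All-vs-all symmetric ANI matrix (diagonal 100)."""
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    indexes = [_AniIndex(g, fragment_length, k) for g in genomes]
    n = len(genomes)
    mat = np.full((n, n), 100.0)
    floored = []
    for i in range(n):
        for j in range(i + 1, n):
            fwd = _directed_ani(indexes[i], indexes[j], min_fragment_kmer_hits, band, "kmer").ani
            rev = _directed_ani(indexes[j], indexes[i], min_fragment_kmer_hits, band, "kmer").ani
            vals = [v for v in (fwd, rev) if not np.isnan(v)]
            if vals:
                ani = float(np.mean(vals))
            else:
                ani = float(floor)
                floored.append((ids[i], ids[j]))
            mat[i, j] = mat[j, i] = ani
    return AniMatrix(ids=ids, values=mat, floored_pairs=floored)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge history on the 1 - ANI/100 distance.

    Each merge records the two cluster labels joined (a cluster is labelled
    by its lexicographically smallest member), the merge height, and the new
    cluster size.  Heights are non-decreasing.
    """

    leaves: list[str]
    merges: list[tuple[str, str, float, int]]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        node: dict[str, str] = {leaf: leaf for leaf in self.leaves}
        height: dict[str, float] = {leaf: 0.0 for leaf in self.leaves}
        for la, lb, h, _size in self.merges:
            bl_a = h - height[la]
            bl_b = h - height[lb]
            sub = f"({node[la]}:{bl_a:.6g},{node[lb]}:{bl_b:.6g})"
            lab = min(la, lb)
            node[lab] = sub
            height[lab] = h
            for other in (la, lb):
                if other != lab:
                    node.pop(other, None)
        (root,) = node.values()
        return root + ";"


def upgma(matrix: AniMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering on 1 - ANI/100.

    At each step the closest pair of clusters merges; the distance from the
    merged cluster to any other is the size-weighted average of the member
    distances.  Ties are broken by the lexicographically smallest pair of
    cluster labels, which makes the dendrogram reproducible.
    """
    ids = list(matrix.ids)
    dist = {
        (a, b): (100.0 - matrix.values[i, j]) / 100.0
        for i, a in enumerate(ids)
        for j, b in enumerate(ids)
        if i < j
    }

    def d(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = {g: 1 for g in ids}  # label -> size
    merges: list[tuple[str, str, float, int]] = []
    while len(active) > 1:
        labels = sorted(active)
        best = None
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                dd = d(la, lb)
                if best is None or dd < best[0] or (dd == best[0] and (la, lb) < best[1:]):
                    best = (dd, la, lb)
        dd, la, lb = best
        na, nb = active[la], active[lb]
        new_label = min(la, lb)
        merges.append((la, lb, dd, na + nb))
        for other in labels:
            if other in (la, lb):
                continue
            dn = (na * d(la, other) + nb * d(lb, other)) / (na + nb)
            dist[(min(new_label, other), max(new_label, other))] = dn
        del active[la], active[lb]
        active[new_label] = na + nb
    return Dendrogram(leaves=ids, merges=merges)


@dataclass
class PhylogroupAssignment:
    """Flat clusters from a dendrogram cut; labels 0..k-1 by decreasing size."""

    labels: dict[str, int]
    dendrogram: Dendrogram

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, []).append(g)
        return {c: sorted(m) for c, m in out.items()}


def cut_clusters(dendrogram: Dendrogram, ani_cutoff: float = 95.0) -> PhylogroupAssignment:
    """Cut the dendrogram at distance (100 - ani_cutoff)/100.

    Only merges strictly below the cut height join genomes, so a merge at
    exactly the cut height separates clusters (genomes sharing exactly the
    cutoff ANI belong to distinct genomospecies).
    """
    h_cut = (100.0 - ani_cutoff) / 100.0
    parent = {leaf: leaf for leaf in dendrogram.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for la, lb, h, _size in dendrogram.merges:
        if h < h_cut:
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for leaf in dendrogram.leaves:
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), sorted(m)[0]))
    labels = {g: ci for ci, members in enumerate(ordered) for g in members}
    return PhylogroupAssignment(labels=labels, dendrogram=dendrogram)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsEmbedding:
    """Low-dimensional non-metric MDS embedding of an ANI distance matrix."""

    ids: list[str]
    coordinates: np.ndarray  # (n, dims)
    stress: float  # Kruskal stress-1 of the best restart
    restarts_used: int


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    w = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w)


def nmds(
    matrix: AniMatrix,
    dims: int = 2,
    n_restarts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsEmbedding:
    """Non-metric MDS of the 1 - ANI/100 matrix by SMACOF majorization.

    Runs ``n_restarts`` random starts plus one classical-scaling start and
    keeps the configuration with the lowest Kruskal stress-1.
    """
    from sklearn.manifold import smacof

    d = matrix.distances()
    n = d.shape[0]
    if dims >= n:
        raise ValueError("dims must be smaller than the number of genomes")
    rng = np.random.default_rng(seed)
    best_x, best_stress = None, np.inf
    inits: list[np.ndarray | None] = [_classical_scaling(d, dims)]
    inits += [None] * n_restarts
    runs = 0
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x, stress = smacof(
                d,
                metric=False,
                n_components=dims,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                random_state=int(rng.integers(2**31 - 1)),
                normalized_stress=True,
            )
        runs += 1
        if stress < best_stress:
            best_x, best_stress = x, float(stress)
    return NmdsEmbedding(
        ids=list(matrix.ids),
        coordinates=best_x,
        stress=best_stress,
        restarts_used=runs,
    )


# ---------------------------------------------------------------------------
# metadata association
# ---------------------------------------------------------------------------

def metadata_association(
    assignment: PhylogroupAssignment, metadata: dict[str, str]
) -> TestResult:
    """Chi-squared test of cluster x metadata-category independence."""
    import pandas as pd

    genomes = list(assignment.labels)
    missing = [g for g in genomes if g not in metadata]
    if missing:
        raise ValueError(f"genomes without metadata: {missing[:5]}")
    df = pd.DataFrame(
        {
            "cluster": [assignment.labels[g] for g in genomes],
            "category": [metadata[g] for g in genomes],
        }
    )
    table = pd.crosstab(df["cluster"], df["category"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 categories")
    return chi_squared(table.to_numpy())
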