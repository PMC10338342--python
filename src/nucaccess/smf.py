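"""Single-molecule footprinting (SMF) read pipeline.

An exogenous GpC methyltransferase (M.CviPI) methylates accessible GpC
cytosines in nuclei; bisulfite conversion then deaminates unmethylated
cytosines to uracil (read T). Sequencing a bisulfite PCR amplicon therefore
reads out, per molecule, which GCH cytosines (GpC not followed by G, to
avoid CpG confounding) were protected by bound protein:

    read C at a GCH  -> methylated    -> accessible  -> call 0
    read T at a GCH  -> unmethylated  -> protected   -> call 1

Pipeline: primer pre-selection of read pairs -> scored alignment of each
mate to the bisulfite-converted reference -> quality-aware pair merging ->
PCR deduplication and equal-depth downsampling -> GCH protection matrix ->
binary-matrix-decomposition clustering -> per-cluster protection profiles.

Alignments use Biopython's PairwiseAligner with match/mismatch/gap scores
of 1.0 / -0.2 / -0.5; the final alignment score is the total score divided
by the alignment length, so a perfect alignment scores exactly 1.0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, validate_dna

__all__ = [
    "AmpliconRef",
    "ConvertedRef",
    "AlignmentResult",
    "GchMatrix",
    "ClusterResult",
    "BinaryMatrixClustering",
    "score_align",
    "select_by_primer",
    "convert_reference",
    "map_full_length",
    "merge_pair",
    "dedup_and_downsample",
    "min_unique_depth",
    "call_gch",
    "cluster_binary",
    "protection_profile",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP = 1.0, -0.2, -0.5

_ALPHABET = "ACGTYRN"


def _substitution_matrix(match: float, mismatch: float):
    from Bio.Align import substitution_matrices

    n = len(_ALPHABET)
    m = np.full((n, n), mismatch)
    np.fill_diagonal(m, match)
    idx = {c: i for i, c in enumerate(_ALPHABET)}
    for deg, bases in (("Y", "CT"), ("R", "AG")):
        for b in bases:
            m[idx[deg], idx[b]] = m[idx[b], idx[deg]] = match
    m[idx["N"], idx["N"]] = mismatch  # N matches nothing, not even itself
    return substitution_matrices.Array(_ALPHABET, 2, m)


def _make_aligner(match: float, mismatch: float, gap: float, mode: str):
    import warnings as _w

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _substitution_matrix(match, mismatch)
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aligner.mode = "global"
    if mode == "semi-global":
        # target overhangs are free: end gaps in the query cost nothing
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            aligner.query_end_gap_score = 0.0
    elif mode != "global":
        raise ValueError(f"mode must be 'global' or 'semi-global', got {mode!r}")
    return aligner


@dataclass(frozen=True)
class AmpliconRef:
    """A bisulfite PCR amplicon: reference sequence and primer pair."""

    name: str
    sequence: str
    fwd_primer: str
    rev_primer: str
    genomic_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty amplicon sequence")
        object.__setattr__(self, "sequence", validate_dna(self.sequence, "amplicon"))


@dataclass(frozen=True)
class ConvertedRef:
    """Bisulfite-converted (degenerate) reference with per-C context classes.

    Conversion rules on the forward strand: a cytosine in HCH context reads T
    unconditionally (always unmethylated, always converted); cytosines in
    GCH, HCG or GCG contexts may be protected/methylated and are therefore
    degenerate Y (C or T). ``context`` holds one of {"GCH", "HCG", "GCG",
    "HCH"} for each C position and "" elsewhere.
    """

    sequence: str
    context: tuple[str, ...]
    gch_positions: tuple[int, ...]


@dataclass
class AlignmentResult:
    """A scored pairwise alignment with its normalised final score."""

    query_aligned: str
    target_aligned: str
    score: float
    length: int
    final_score: float
    target_to_query: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.final_score > 1.0 + 1e-9:
            raise AssertionError("final score cannot exceed 1.0")


def score_align(
    query: str,
    target: str,
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap: float = GAP,
    mode: str = "global",
) -> AlignmentResult:
    """Optimal pairwise alignment under the linear 1.0/-0.2/-0.5 scheme.

    The final score is the total alignment score divided by the alignment
    length. In semi-global mode the target's end overhangs are gap-free and
    the length counts only the columns spanning the query, so a read mapped
    perfectly inside a longer target still scores 1.0. Degenerate target
    symbols (Y = C/T, R = A/G) score as matches against compatible bases.
    """
    for s, nm in ((query, "query"), (target, "target")):
        if not s:
            raise ValueError(f"empty {nm}")
        bad = set(s.upper()) - set(_ALPHABET)
        if bad:
            raise ValueError(f"{nm} contains non-DNA characters: {sorted(bad)}")
    aligner = _make_aligner(match, mismatch, gap, mode)
    aln = aligner.align(target.upper(), query.upper())[0]
    t_idx, q_idx = aln.indices  # per-column sequence indices, -1 for gaps

    if mode == "semi-global":
        cols = np.nonzero(q_idx >= 0)[0]
        lo, hi = int(cols[0]), int(cols[-1]) + 1
    else:
        lo, hi = 0, aln.length
    length = hi - lo

    t_str, q_str = str(aln[0]), str(aln[1])
    mapping = {
        int(t): int(q)
        for t, q in zip(t_idx[lo:hi], q_idx[lo:hi])
        if t >= 0 and q >= 0
    }
    return AlignmentResult(
        query_aligned=q_str[lo:hi],
        target_aligned=t_str[lo:hi],
        score=float(aln.score),
        length=length,
        final_score=float(aln.score) / length,
        target_to_query=mapping,
    )


def select_by_primer(
    pairs,
    ref: AmpliconRef,
    prefix_len: int = 25,
    threshold: float = 0.8,
) -> tuple[list, dict[str, int]]:
    """Keep read pairs whose prefixes match the primer pair; orient them.

    Each pair is ``(read1, read2)`` where a read is ``(sequence, quality)``
    (quality = Phred scores, array-like) or a plain sequence string. The
    first ``prefix_len`` bases of each mate are globally aligned to the
    forward and reverse primers (trimmed to a common length); a pair is kept
    when one mate matches the forward and the other the reverse primer with
    final score strictly greater than ``threshold``. Pairs passing in both
    orientations are ambiguous and dropped.

    Returns (oriented pairs, fate counts). In an oriented pair, mate 1 is
    the forward-primer mate.
    """
    # "higher than" is a strict inequality; the epsilon keeps float noise from
    # nudging an exact-boundary score past it
    eps = 1e-12

    def _prefix_score(read_seq: str, primer: str) -> float:
        L = min(prefix_len, len(primer), len(read_seq))
        return score_align(read_seq[:L], primer[:L], mode="global").final_score

    kept: list = []
    fate = {"kept": 0, "no_primer": 0, "ambiguous": 0}
    for r1, r2 in pairs:
        s1 = r1[0] if isinstance(r1, tuple) else str(r1)
        s2 = r2[0] if isinstance(r2, tuple) else str(r2)
        fwd_ok_1 = _prefix_score(s1, ref.fwd_primer) > threshold + eps
        rev_ok_2 = _prefix_score(s2, ref.rev_primer) > threshold + eps
        rev_ok_1 = _prefix_score(s1, ref.rev_primer) > threshold + eps
        fwd_ok_2 = _prefix_score(s2, ref.fwd_primer) > threshold + eps
        forward = fwd_ok_1 and rev_ok_2
        reverse = rev_ok_1 and fwd_ok_2
        if forward and reverse:
            fate["ambiguous"] += 1
        elif forward:
            kept.append((r1, r2))
            fate["kept"] += 1
        elif reverse:
            kept.append((r2, r1))
            fate["kept"] += 1
        else:
            fate["no_primer"] += 1
    return kept, fate


def convert_reference(ref: AmpliconRef | str) -> ConvertedRef:
    """Bisulfite-convert a reference into degenerate space.

    Per-cytosine context classification (is the preceding base G? the
    following base G?) decides the converted symbol: HCH -> T (always
    converted), GCH / HCG / GCG -> Y (pyrimidine; methylation-dependent).
    G positions and the complementary strand are untouched.
    """
    seq = ref.sequence if isinstance(ref, AmpliconRef) else validate_dna(ref)
    out = list(seq)
    context: list[str] = [""] * len(seq)
    gch: list[int] = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        prev_g = i > 0 and seq[i - 1] == "G"
        next_g = i + 1 < len(seq) and seq[i + 1] == "G"
        if prev_g and next_g:
            cls = "GCG"
        elif prev_g:
            cls = "GCH"
            gch.append(i)
        elif next_g:
            cls = "HCG"
        else:
            cls = "HCH"
        context[i] = cls
        out[i] = "T" if cls == "HCH" else "Y"
    return ConvertedRef(sequence="".join(out), context=tuple(context), gch_positions=tuple(gch))


def map_full_length(
    pair,
    conv: ConvertedRef,
    threshold: float = 0.7,
) -> tuple[AlignmentResult, AlignmentResult] | None:
    """Map an oriented read pair to the converted reference (semi-global).

    Mate 1 aligns directly; mate 2 is reverse-complemented first. Both mates
    must achieve a final alignment score strictly greater than ``threshold``,
    otherwise the pair is dropped (returns None).
    """
    (s1, *rest1), (s2, *rest2) = (_as_read(pair[0]), _as_read(pair[1]))
    a1 = score_align(s1, conv.sequence, mode="semi-global")
    a2 = score_align(revcomp(s2), conv.sequence, mode="semi-global")
    # strict inequality ("higher than"), float-noise guarded
    if a1.final_score > threshold + 1e-12 and a2.final_score > threshold + 1e-12:
        return a1, a2
    return None


def _as_read(read) -> tuple:
    if isinstance(read, tuple):
        return read
    return (str(read),)


def merge_pair(
    pair,
    alns: tuple[AlignmentResult, AlignmentResult],
    ref_len: int,
    missing: str = ".",
) -> str:
    """Reconstitute the full-length molecule from a mapped pair.

    Outside the mates' overlap the covering mate's base is taken; inside the
    overlap the base with the higher quality score wins, ties going to
    mate 1. Reference positions covered by neither mate are padded with the
    ``missing`` symbol (a warning is emitted when the mates leave an
    internal gap).
    """
    r1, r2 = _as_read(pair[0]), _as_read(pair[1])
    s1, q1 = r1[0], r1[1] if len(r1) > 1 else None
    s2, q2 = r2[0], r2[1] if len(r2) > 1 else None
    s2 = revcomp(s2)
    if q2 is not None:
        q2 = np.asarray(q2)[::-1]
    if q1 is not None:
        q1 = np.asarray(q1)

    a1, a2 = alns
    mol = [missing] * ref_len
    qual = np.full(ref_len, -1.0)
    for mate_rank, (s, q, aln) in enumerate(((s1, q1, a1), (s2, q2, a2))):
        for tpos, qpos in aln.target_to_query.items():
            base = s[qpos]
            bq = float(q[qpos]) if q is not None else 0.0
            # strictly higher quality replaces; ties keep the earlier mate (mate 1)
            if mol[tpos] == missing or bq > qual[tpos]:
                mol[tpos] = base
                qual[tpos] = bq

    covered = [i for i, b in enumerate(mol) if b != missing]
    if covered and any(mol[i] == missing for i in range(covered[0], covered[-1])):
        warnings.warn("mates leave an internal gap; molecule padded with missing symbols", stacklevel=2)
    return "".join(mol)


def min_unique_depth(molecules_by_sample: dict[str, list[str]]) -> int:
    """Equal-depth target: the unique-molecule count of the poorest sample."""
    return min(len(set(mols)) for mols in molecules_by_sample.values())


def dedup_and_downsample(
    molecules_by_sample: dict[str, list[str]],
    n: int,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Collapse PCR duplicates and sample exactly ``n`` molecules per sample.

    Duplicates are molecules with identical reconstructed sequences.
    Selection is uniform without replacement with a per-sample seeded
    substream, so runs are reproducible and samples independent.
    """
    from ._util import substream

    out: dict[str, list[str]] = {}
    for sample, mols in molecules_by_sample.items():
        uniq = sorted(set(mols))
        if len(uniq) < n:
            raise ValueError(
                f"sample {sample!r} has only {len(uniq)} unique molecules, fewer than n={n}"
            )
        rng = substream(seed, f"smf/downsample/{sample}")
        idx = rng.choice(len(uniq), size=n, replace=False)
        out[sample] = [uniq[i] for i in sorted(idx)]
    return out


@dataclass
class GchMatrix:
    """Molecules x GCH-position protection calls (0/1, NaN missing)."""

    values: np.ndarray  # float array, entries in {0, 1, nan}
    positions: tuple[int, ...]
    samples: tuple[str, ...] = ()
    replicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        v = self.values[~np.isnan(self.values)]
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("calls must be 0, 1 or missing")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        tab = pd.DataFrame(self.values, columns=[f"pos_{p}" for p in self.positions])
        if self.samples:
            tab.insert(0, "sample", self.samples)
        if self.replicates:
            tab.insert(1 if self.samples else 0, "replicate", self.replicates)
        return tab

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=True, index_label="molecule")


def call_gch(molecule: str, conv: ConvertedRef, missing: str = ".") -> np.ndarray:
    """Protection calls for one reconstructed molecule.

    At each GCH cytosine of the reference: read base C -> 0 (methylated by
    M.CviPI, i.e. accessible/unprotected), T -> 1 (unmethylated, protected),
    anything else (error, gap, missing) -> NaN.
    """
    if len(molecule) != len(conv.sequence):
        raise ValueError("molecule must be reference-length (pad with the missing symbol)")
    out = np.full(len(conv.gch_positions), np.nan)
    for j, i in enumerate(conv.gch_positions):
        b = molecule[i]
        if b == "C":
            out[j] = 0.0
        elif b == "T":
            out[j] = 1.0
    return out


def build_gch_matrix(
    molecules_by_sample: dict[str, list[str]],
    conv: ConvertedRef,
    replicate_of: dict[str, str] | None = None,
) -> GchMatrix:
    rows, samples, reps = [], [], []
    for sample, mols in molecules_by_sample.items():
        for mol in mols:
            rows.append(call_gch(mol, conv))
            samples.append(sample)
            reps.append((replicate_of or {}).get(sample, sample))
    return GchMatrix(
        values=np.array(rows) if rows else np.empty((0, len(conv.gch_positions))),
        positions=conv.gch_positions,
        samples=tuple(samples),
        replicates=tuple(reps),
    )


@dataclass
class ClusterResult:
    """Cluster labels with per-cluster protection summaries."""

    labels: np.ndarray
    prototypes: np.ndarray  # (k, n_positions) in [0, 1]
    objective: float
    objective_path: np.ndarray
    k: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


class BinaryMatrixClustering:
    """Binary-matrix-decomposition clustering of protection calls.

    Decomposes the molecules x positions call matrix X (entries 0/1, NaN
    missing) as a hard assignment of each row to one of ``n_clusters``
    prototype rows in [0, 1]^p, minimising the masked squared error

        sum_{observed (i,j)} (X_ij - P_{c(i), j})^2

    by alternating minimisation (assignment step / masked-mean prototype
    update), best of ``n_restarts`` seeded initialisations. The objective is
    non-increasing across iterations within a restart.

    Follows the scikit-learn estimator convention: ``fit`` sets ``labels_``,
    ``cluster_centers_`` and ``inertia_``.
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 8, max_iter: int = 200,
                 tol: float = 1e-9, seed: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X: np.ndarray) -> "BinaryMatrixClustering":
        X = np.asarray(X, float)
        n, p = X.shape
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds the number of rows {n}")
        mask = ~np.isnan(X)
        Xf = np.where(mask, X, 0.0)

        from ._util import substream

        best = None
        for r in range(self.n_restarts):
            rng = substream(self.seed, f"bmd/restart/{r}")
            labels, protos, path = self._run_once(Xf, mask, k, rng)
            obj = path[-1]
            if best is None or obj < best[2]:
                best = (labels, protos, obj, path)
        labels, protos, obj, path = best
        self.labels_ = labels
        self.cluster_centers_ = protos
        self.inertia_ = float(obj)
        self.objective_path_ = np.asarray(path)
        return self

    def fit_predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).labels_

    def _run_once(self, Xf, mask, k, rng):
        n, p = Xf.shape
        protos = Xf[rng.choice(n, size=k, replace=False)].astype(float)
        labels = np.zeros(n, int)
        path = []
        prev = np.inf
        for _ in range(self.max_iter):
            # assignment: masked squared error of each row against each prototype
            # cost[i, c] = sum_j mask_ij (x_ij - p_cj)^2
            cost = (
                (Xf**2 * mask).sum(1)[:, None]
                - 2 * (Xf * mask) @ protos.T
                + mask @ (protos.T**2)
            )
            labels = cost.argmin(1)
            obj = cost[np.arange(n), labels].sum()
            path.append(obj)
            if prev - obj <= self.tol:
                break
            prev = obj
            # update: masked mean per cluster
            for c in range(k):
                rows = labels == c
                if not rows.any():
                    # re-seed an empty cluster from the worst-fit row
                    worst = cost[np.arange(n), labels].argmax()
                    protos[c] = Xf[worst]
                    continue
                num = (Xf[rows] * mask[rows]).sum(0)
                den = mask[rows].sum(0)
                upd = den > 0
                protos[c, upd] = num[upd] / den[upd]
        return labels, protos, path


def cluster_binary(
    matrix: GchMatrix,
    k: int,
    restarts: int = 8,
    seed: int = 0,
) -> ClusterResult:
    """Cluster molecules by their GCH protection patterns (masked BMD)."""
    est = BinaryMatrixClustering(n_clusters=k, n_restarts=restarts, seed=seed).fit(matrix.values)
    return ClusterResult(
        labels=est.labels_,
        prototypes=est.cluster_centers_,
        objective=est.inertia_,
        objective_path=est.objective_path_,
        k=k,
    )


def protection_profile(
    result: ClusterResult,
    matrix: GchMatrix,
    replicates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-cluster, per-position % protection with mean +/- s.e.m. over replicates.

    %% protection = 100 * mean(call == 1 over non-missing calls), computed
    per replicate within each cluster; positions with no observed calls in a
    replicate are excluded from that replicate's mean (logged).
    """
    reps = replicates if replicates is not None else matrix.replicates
    if len(reps) != matrix.n_molecules:
        raise ValueError("replicate labels must cover all molecules")
    reps = np.asarray(reps)
    rows = []
    for c in range(result.k):
        in_c = result.labels == c
        rep_ids = sorted(set(reps[in_c])) if in_c.any() else []
        per_rep = []
        for rid in rep_ids:
            sub = matrix.values[in_c & (reps == rid)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                prot = 100.0 * np.nanmean(sub, axis=0)
            if np.isnan(prot).any():
                logger.info("cluster %d replicate %s: %d position(s) all-missing",
                            c, rid, int(np.isnan(prot).sum()))
            per_rep.append(prot)
        per_rep = np.array(per_rep) if per_rep else np.empty((0, len(matrix.positions)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(per_rep, axis=0) if len(per_rep) else np.full(len(matrix.positions), np.nan)
            nrep = (~np.isnan(per_rep)).sum(0) if len(per_rep) else np.zeros(len(matrix.positions))
            sem = np.where(
                nrep > 1,
                np.nanstd(per_rep, axis=0, ddof=1) / np.sqrt(np.maximum(nrep, 1)),
                0.0,
            ) if len(per_rep) else np.full(len(matrix.positions), np.nan)
        for j, pos in enumerate(matrix.positions):
            rows.append((c, pos, mean[j], sem[j], int(in_c.sum())))
    return pd.DataFrame(rows, columns=["cluster", "position", "pct_protection", "sem", "cluster_size"])


def run_pipeline(
    pairs_by_sample: dict[str, list],
    ref: AmpliconRef,
    k: int,
    n: int | None = None,
    seed: int = 0,
    replicate_of: dict[str, str] | None = None,
    primer_threshold: float = 0.8,
    map_threshold: float = 0.7,
) -> tuple[GchMatrix, ClusterResult, pd.DataFrame, dict]:
    """End-to-end SMF analysis from paired reads to protection profiles.

    Returns (gch_matrix, clusters, protection_table, per-sample fate log).
    ``n=None`` sets the downsampling depth to the unique-molecule count of
    the poorest sample.
    """
    conv = convert_reference(ref)
    molecules: dict[str, list[str]] = {}
    log: dict[str, dict[str, int]] = {}
    for sample, pairs in pairs_by_sample.items():
        oriented, fate = select_by_primer(pairs, ref, threshold=primer_threshold)
        mols = []
        dropped_map = 0
        for pair in oriented:
            alns = map_full_length(pair, conv, threshold=map_threshold)
            if alns is None:
                dropped_map += 1
                continue
            mols.append(merge_pair(pair, alns, len(ref.sequence)))
        fate["dropped_mapping"] = dropped_map
        fate["molecules"] = len(mols)
        molecules[sample] = mols
        log[sample] = fate

    depth = min_unique_depth(molecules) if n is None else n
    selected = dedup_and_downsample(molecules, depth, seed=seed)
    matrix = build_gch_matrix(selected, conv, replicate_of)
    clusters = cluster_binary(matrix, k=k, seed=seed)
    table = protection_profile(clusters, matrix)
    return matrix, clusters, table, log
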