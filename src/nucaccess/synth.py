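"""Seeded synthetic-data generators with ground truth.

Each generator forward-models the data-generating process one pipeline
stage assumes — tiled-library read pools, toy atomic models, protection
fragments, bisulfite amplicon read pairs, oscillation traces, dwell-time
mixtures — and returns a :class:`TruthBundle` carrying the exact ground
truth needed for recovery tests. All generators draw from named substreams
of a single top-level seed, so outputs are bit-for-bit reproducible and
adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, substream
from .seenseq import BackboneSpec, MotifSpec, VariantLibrary, flank_and_digest, occurs_on_either_strand
from .smf import AmpliconRef, convert_reference
from .structscan import AtomModel, ProbeModel, superpose
from .curvefit import DwellSet, TimeSeries, damped_cosine
from .fragprof import Fragment, MotifAnchor

__all__ = [
    "TruthBundle",
    "gen_backbone",
    "gen_seen_reads",
    "gen_toy_structures",
    "gen_fragments",
    "gen_smf_reads",
    "gen_protection_matrix",
    "gen_osc_trace",
    "gen_dwells",
]

BASES = np.array(list("ACGT"))


@dataclass
class TruthBundle:
    """Ground truth emitted alongside generated data."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def gen_backbone(
    length: int = 147,
    forbidden: tuple[str, ...] = ("CACGTG", "GATATC"),
    seed: int = 0,
    max_rounds: int = 1000,
) -> BackboneSpec:
    """Random DNA backbone free of the forbidden motifs on both strands.

    Uniform random sequence, locally re-drawn wherever a forbidden motif
    appears, until clean. A stand-in for a motif-free nucleosome
    positioning sequence.
    """
    if any(len(m) > length for m in forbidden):
        raise ValueError("forbidden motif longer than the backbone")
    rng = substream(seed, "backbone")
    seq = list(_random_dna(rng, length))
    for _ in range(max_rounds):
        dirty = False
        s = "".join(seq)
        for m in forbidden:
            for probe in (m, revcomp(m)):
                i = s.find(probe)
                if i >= 0:
                    dirty = True
                    for j in range(i, i + len(probe)):
                        seq[j] = rng.choice(BASES)
        if not dirty:
            return BackboneSpec(sequence="".join(seq), forbidden_motifs=tuple(forbidden))
    raise RuntimeError("could not satisfy the forbidden-motif constraint")


def gen_seen_reads(
    library: VariantLibrary,
    true_profile: dict[int, float],
    depth: int = 100_000,
    spike_ratio: float = 30.0,
    noise: float = 0.001,
    seed: int = 0,
) -> tuple[list[str], list[str], TruthBundle]:
    """Bound/unbound SeEN-seq read pools from a known enrichment profile.

    Unbound reads are multinomial over the variants (uniform) plus the
    spike-in competitor at ``spike_ratio`` : 1 (competitor : whole pool,
    mirroring a 1:30 pool:competitor spike). Bound reads are multinomial
    proportional to uniform x ``true_profile`` (no spike-in: the competitor
    carries no motif and is never TF-bound). Reads are full digested
    constructs with per-base substitution errors at rate ``noise``.

    Returns (bound reads, unbound reads, truth).
    """
    positions = library.positions()
    if any(true_profile.get(p, 0) <= 0 for p in positions):
        raise ValueError("true_profile must be positive on every library position")
    rng = substream(seed, "seen_reads")

    constructs = {p: flank_and_digest(library.entries[p])[0] for p in positions}
    spike_seq = None
    if library.spike_in is not None:
        spike_seq = flank_and_digest(library.spike_in)[0]

    def _emit(weights: np.ndarray, seqs: list[str], n: int) -> list[str]:
        if n == 0:
            return []
        counts = rng.multinomial(n, weights / weights.sum())
        reads = []
        for seq, c in zip(seqs, counts):
            for _ in range(c):
                reads.append(_mutate(rng, seq, noise))
        return reads

    # unbound: uniform variants + spike-in
    u_seqs = [constructs[p] for p in positions]
    u_weights = np.ones(len(positions))
    if spike_seq is not None:
        u_seqs.append(spike_seq)
        u_weights = np.append(u_weights, spike_ratio * len(positions))
    unbound = _emit(u_weights, u_seqs, depth)

    # bound: uniform x profile, no spike-in
    b_weights = np.array([true_profile[p] for p in positions], float)
    bound = _emit(b_weights, [constructs[p] for p in positions], depth)

    truth = TruthBundle(
        generator="seen_reads",
        seed=seed,
        params=dict(depth=depth, spike_ratio=spike_ratio, noise=noise),
        tables={
            "true_profile": pd.DataFrame(
                {"position": positions, "enrichment": [true_profile[p] for p in positions]}
            )
        },
    )
    return bound, unbound, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice(BASES[BASES != arr[i]])
    return "".join(arr)


def gen_toy_structures(
    n_bp: int = 60,
    probe_bp: int = 10,
    n_core_atoms: int = 1500,
    n_tf_atoms: int = 60,
    superhelix_radius_A: float = 41.9,
    pitch_A: float = 25.9,
    turns: float = 1.65,
    tf_offset_A: float = 12.0,
    threshold_A: float = 1.0,
    seed: int = 0,
) -> tuple[AtomModel, np.ndarray, ProbeModel, TruthBundle]:
    """Toy nucleosome + TF-DNA probe models with brute-force clash truth.

    The nucleosomal DNA anchors lie on an ideal superhelix (two strands
    axially offset); histone-proxy atoms fill the core. The probe carries a
    straight ideal-helix DNA of ``probe_bp`` base pairs with a compact TF
    pseudo-atom cloud hovering ``tf_offset_A`` outside the DNA, close enough
    to clash with the core at inward-facing registers. Truth clash counts
    per register are computed by direct all-pairs distances at
    ``threshold_A`` (strictly-closer counting).

    Returns (nucleosome model, nucleosome anchors, probe model, truth).
    """
    if n_bp < probe_bp:
        raise ValueError("n_bp must be >= probe_bp")
    rng = substream(seed, "toy_structures")

    # nucleosomal DNA anchors along a superhelix
    t = np.arange(n_bp) / n_bp * turns * 2 * np.pi
    z = np.arange(n_bp) / n_bp * turns * pitch_A
    strand1 = np.c_[superhelix_radius_A * np.cos(t), superhelix_radius_A * np.sin(t), z]
    strand2 = strand1 + np.array([0.0, 0.0, 9.0])  # second backbone, axial offset
    nuc_anchors = np.stack([strand1, strand2], axis=1)

    core = rng.normal(0, 1, (n_core_atoms, 3))
    core = core / np.linalg.norm(core, axis=1, keepdims=True) * rng.uniform(
        0, superhelix_radius_A - 8.0, (n_core_atoms, 1)
    )
    core[:, 2] = rng.uniform(z.min(), z.max(), n_core_atoms)

    nuc_rows = []
    for i, (a, b) in enumerate(zip(strand1, strand2)):
        nuc_rows.append(("P", "P", "I", i + 1, "DA", *a, "nucleosome-dna"))
        # antiparallel residue numbering on the complementary strand
        nuc_rows.append(("P", "P", "J", n_bp - i, "DT", *b, "nucleosome-dna"))
    for i, c in enumerate(core):
        nuc_rows.append(("C", "CA", "A", i + 1, "HIS", *c, "nucleosome-histone"))
    nucleosome = AtomModel(pd.DataFrame(nuc_rows, columns=list(AtomModel.REQUIRED)))

    # straight ideal B-helix probe DNA (two phase-shifted backbone strands)
    rise, twist, helix_r = 3.4, np.deg2rad(36.0), 9.0
    pz = np.arange(probe_bp) * rise
    ang = np.arange(probe_bp) * twist
    p1 = np.c_[helix_r * np.cos(ang), helix_r * np.sin(ang), pz]
    ang2 = ang + np.deg2rad(140.0)
    p2 = np.c_[helix_r * np.cos(ang2), helix_r * np.sin(ang2), pz]
    probe_anchors = np.stack([p1, p2], axis=1)
    tf = rng.normal(0, 2.0, (n_tf_atoms, 3))
    tf[:, 0] += tf_offset_A
    tf[:, 2] += pz.mean()
    probe_rows = []
    for i, (a, b) in enumerate(zip(p1, p2)):
        probe_rows.append(("P", "P", "X", i + 1, "DA", *a, "probe-dna"))
        probe_rows.append(("P", "P", "Y", probe_bp - i, "DT", *b, "probe-dna"))
    for i, c in enumerate(tf):
        probe_rows.append(("C", "CA", "T", i + 1, "TF", *c, "tf-protein"))
    probe = ProbeModel(
        model=AtomModel(pd.DataFrame(probe_rows, columns=list(AtomModel.REQUIRED))),
        anchors=probe_anchors,
    )

    # brute-force truth: all-pairs distances after anchor superposition
    nuc_xyz = nucleosome.coords()
    truth_counts = []
    p_anch = probe_anchors.reshape(-1, 3)
    for r in range(n_bp - probe_bp + 1):
        t_anch = nuc_anchors[r: r + probe_bp].reshape(-1, 3)
        R, tvec, _ = superpose(p_anch, t_anch)
        moved = tf @ R.T + tvec
        d = np.linalg.norm(moved[:, None, :] - nuc_xyz[None, :, :], axis=2)
        truth_counts.append(int(np.sum(d.min(axis=1) < threshold_A)))

    truth = TruthBundle(
        generator="toy_structures",
        seed=seed,
        params=dict(n_bp=n_bp, probe_bp=probe_bp, threshold_A=threshold_A),
        tables={
            "clash": pd.DataFrame(
                {"register": np.arange(n_bp - probe_bp + 1), "clash_count": truth_counts}
            )
        },
    )
    return nucleosome, nuc_anchors, probe, truth


def gen_fragments(
    architecture: list[tuple[int, int, str]],
    n: int = 10_000,
    ref_len: int = 1000,
    ref: str = "synth_ref",
    motif_centre: float | None = None,
    motif_len: int = 6,
    linker_bp: int = 40,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[Fragment], list[MotifAnchor], TruthBundle]:
    """Protection fragments around a motif with a known architecture.

    ``architecture`` lists protected intervals (start, end, class label),
    e.g. a 147-bp nucleosome span with an edge-bound TF, or a short
    TF-only footprint on linker DNA. For each fragment a class is sampled
    (by ``class_weights``, uniform default), then cut sites are drawn
    uniformly from the unprotected linker on each side of that class's
    protected span — nuclease cleavage cannot fall inside protection.
    """
    if not architecture:
        raise ValueError("architecture must list at least one protected interval")
    for s, e, _ in architecture:
        if not (0 <= s < e <= ref_len):
            raise ValueError(f"protected interval [{s}, {e}) outside reference")
        if s == 0 and e == ref_len:
            raise ValueError("fully protected reference: no cleavable positions")
    labels = [lab for _, _, lab in architecture]
    w = np.array([(class_weights or {}).get(lab, 1.0) for lab in labels], float)
    rng = substream(seed, "fragments")

    frags, classes = [], []
    choices = rng.choice(len(architecture), size=n, p=w / w.sum())
    for idx in choices:
        s, e, lab = architecture[idx]
        left_lo = max(0, s - linker_bp)
        right_hi = min(ref_len, e + linker_bp)
        start = int(rng.integers(left_lo, s + 1))
        end = int(rng.integers(e, right_hi + 1))
        if end <= start:
            end = start + 1
        frags.append(Fragment(ref, start, end))
        classes.append(lab)

    centre = motif_centre if motif_centre is not None else (ref_len - 1) / 2.0
    anchors = [MotifAnchor(ref, centre, motif_len, "+")]
    truth = TruthBundle(
        generator="fragments",
        seed=seed,
        params=dict(n=n, ref_len=ref_len, linker_bp=linker_bp),
        tables={"classes": pd.DataFrame({"class": classes})},
    )
    return frags, anchors, truth


def gen_smf_ref(
    length: int = 437,
    primer_len: int = 25,
    seed: int = 0,
    name: str = "synthetic_enhancer",
) -> AmpliconRef:
    """Synthetic bisulfite amplicon with conversion-invariant primer sites.

    The first and last ``primer_len`` bases carry no cytosine on the top
    strand, so the primer sequences are identical before and after
    bisulfite conversion (as real bisulfite primers are designed to be).
    """
    rng = substream(seed, "smf_ref")
    noC = np.array(list("AGT"))
    head = "".join(rng.choice(noC, size=primer_len))
    tail = "".join(rng.choice(noC, size=primer_len))
    mid = _random_dna(rng, length - 2 * primer_len)
    seq = head + mid + tail
    return AmpliconRef(
        name=name,
        sequence=seq,
        fwd_primer=head,
        rev_primer=revcomp(tail),
        genomic_label="synthetic",
    )


def gen_smf_reads(
    ref: AmpliconRef,
    molecule_classes: list[tuple[list[tuple[int, int]], float]],
    methylation_efficiency: float = 0.95,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    dup_rate: float = 0.1,
    n_per_sample: int = 500,
    read_len: int = 250,
    samples: tuple[str, ...] = ("s1",),
    base_quality: int = 40,
    error_quality: int = 10,
    seed: int = 0,
) -> tuple[dict[str, list], TruthBundle]:
    """Paired bisulfite reads forward-modelling the SMF assay.

    Per molecule: a footprint class (list of protected intervals) is drawn
    by weight; GCH cytosines outside every footprint are methylated by the
    GpC methyltransferase with ``methylation_efficiency``; bisulfite then
    converts unmethylated cytosines (all contexts) to T with
    ``conversion_rate``; the converted molecule is read as a
    ``read_len``-bp pair (mate 2 reverse-complemented) with per-base
    substitution errors and Phred+33 qualities (errored bases get
    ``error_quality``). PCR duplicates re-read an earlier molecule with
    probability ``dup_rate``.

    Returns ({sample: [((seq1, qual1), (seq2, qual2)), ...]}, truth); truth
    tables carry each molecule's class and expected GCH call vector.
    """
    conv = convert_reference(ref)
    gch = np.array(conv.gch_positions, int)
    if gch.size == 0:
        raise ValueError("reference contains no GCH position")
    weights = np.array([w for _, w in molecule_classes], float)
    weights /= weights.sum()

    def class_truth(intervals) -> np.ndarray:
        out = np.zeros(gch.size)
        for a, b in intervals:
            out[(gch >= a) & (gch < b)] = 1.0
        return out

    pairs_by_sample: dict[str, list] = {}
    truth_rows = []
    for sample in samples:
        rng = substream(seed, f"smf_reads/{sample}")
        molecules: list[tuple[str, int]] = []  # (converted sequence, class index)
        pairs = []
        for i in range(n_per_sample):
            if molecules and rng.random() < dup_rate:
                mol_seq, cls = molecules[int(rng.integers(len(molecules)))]
                is_dup = True
            else:
                cls = int(rng.choice(len(molecule_classes), p=weights))
                intervals = molecule_classes[cls][0]
                mol_seq = _bisulfite_molecule(
                    rng, ref.sequence, conv, intervals,
                    methylation_efficiency, conversion_rate,
                )
                is_dup = False
            molecules.append((mol_seq, cls))
            truth_rows.append((sample, i, cls, is_dup, mol_seq))

            r1 = mol_seq[:read_len]
            r2 = revcomp(mol_seq[-read_len:])
            pairs.append((
                _with_errors(rng, r1, error_rate, base_quality, error_quality),
                _with_errors(rng, r2, error_rate, base_quality, error_quality),
            ))
        pairs_by_sample[sample] = pairs

    truth = TruthBundle(
        generator="smf_reads",
        seed=seed,
        params=dict(
            methylation_efficiency=methylation_efficiency,
            conversion_rate=conversion_rate, error_rate=error_rate,
            dup_rate=dup_rate, n_per_sample=n_per_sample, read_len=read_len,
        ),
        tables={
            "molecules": pd.DataFrame(
                truth_rows, columns=["sample", "index", "class", "is_duplicate", "sequence"]
            ),
            "class_calls": pd.DataFrame(
                {f"class_{i}": class_truth(iv) for i, (iv, _) in enumerate(molecule_classes)},
                index=gch,
            ),
        },
    )
    return pairs_by_sample, truth


def _bisulfite_molecule(rng, seq: str, conv, footprints, efficiency: float, conversion: float) -> str:
    protected = np.zeros(len(seq), bool)
    for a, b in footprints:
        protected[a:b] = True
    out = list(seq)
    for i, base in enumerate(seq):
        if base != "C":
            continue
        ctx = conv.context[i]
        accessible_gch = ctx == "GCH" and not protected[i]
        methylated = accessible_gch and (rng.random() < efficiency)
        if not methylated and rng.random() < conversion:
            out[i] = "T"
    return "".join(out)


def _with_errors(rng, seq: str, rate: float, q_hi: int, q_lo: int) -> tuple[str, np.ndarray]:
    arr = np.array(list(seq))
    qual = np.full(len(arr), q_hi)
    if rate > 0:
        hits = np.nonzero(rng.random(len(arr)) < rate)[0]
        for i in hits:
            arr[i] = rng.choice(BASES[BASES != arr[i]])
            qual[i] = q_lo
    return "".join(arr), qual


def gen_protection_matrix(
    prototypes: np.ndarray,
    n_per_cluster: int = 100,
    flip_rate: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary call matrix from known cluster prototypes with flip noise.

    Each row copies its cluster's 0/1 prototype, flips each call with
    ``flip_rate`` and masks it missing (NaN) with ``missing_rate``.
    Returns (matrix, true labels).
    """
    rng = substream(seed, "protection_matrix")
    prototypes = np.asarray(prototypes, float)
    k, p = prototypes.shape
    rows, labels = [], []
    for c in range(k):
        for _ in range(n_per_cluster):
            row = prototypes[c].copy()
            flips = rng.random(p) < flip_rate
            row[flips] = 1.0 - row[flips]
            row[rng.random(p) < missing_rate] = np.nan
            rows.append(row)
            labels.append(c)
    return np.array(rows), np.array(labels)


def gen_osc_trace(
    m: float = 0.0,
    c: float = 0.0,
    amplitude: float = 1000.0,
    k: float = 0.02,
    phase: float = 0.0,
    period: float = 24.0,
    duration_h: float = 168.0,
    dt_h: float = 0.25,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TimeSeries, TruthBundle]:
    """Noisy damped-cosine bioluminescence trace (7 days at 15 min default)."""
    rng = substream(seed, "osc_trace")
    t = np.arange(0, duration_h + dt_h / 2, dt_h)
    y = damped_cosine(t, m, c, amplitude, k, phase, period)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, t.size)
    truth = TruthBundle(
        generator="osc_trace", seed=seed,
        params=dict(m=m, c=c, amplitude=amplitude, k=k, phase=phase,
                    period=period, noise_sd=noise_sd),
    )
    return TimeSeries(time=t, signal=y), truth


def gen_dwells(
    weights: tuple[float, ...] = (0.5, 0.5),
    taus_s: tuple[float, ...] = (1.0, 10.0),
    n: int = 10_000,
    kind: str = "bright",
    seed: int = 0,
) -> tuple[DwellSet, TruthBundle]:
    """Exponential-mixture dwell times (smTIRF bright/dark durations)."""
    w = np.asarray(weights, float)
    tau = np.asarray(taus_s, float)
    if w.shape != tau.shape or np.any(w < 0) or np.any(tau <= 0):
        raise ValueError("weights and taus must pair up, weights >= 0, taus > 0")
    w = w / w.sum()
    rng = substream(seed, f"dwells/{kind}")
    comp = rng.choice(len(w), size=n, p=w)
    d = rng.exponential(tau[comp])
    truth = TruthBundle(
        generator="dwells", seed=seed,
        params=dict(weights=tuple(w), taus_s=tuple(tau), n=n, kind=kind),
    )
    return DwellSet(durations=d, kind=kind), truth
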