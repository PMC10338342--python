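"""V-plots and DNaseI cut-site profiles from sequenced fragments.

A V-plot bins each fragment by (midpoint offset from a binding motif,
fragment length). Fragments that fully contain the motif fall "inside the
V": |offset| <= (length - motif_len) / 2. Nucleosome-adjacent TF binding
produces long (>150 bp) inside-V fragments, whereas a TF alone on linker
DNA produces short (<100 bp) motif-centred ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substream

__all__ = [
    "Fragment",
    "MotifAnchor",
    "VMatrix",
    "vmatrix",
    "inside_v",
    "cutsite_profile",
    "read_fragments_bed",
    "read_fragments_sam",
    "read_anchors",
]


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment: 0-based half-open [start, end) on a reference."""

    ref: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        # half-integer for even-length fragments
        return (self.start + self.end - 1) / 2.0


@dataclass(frozen=True)
class MotifAnchor:
    """A motif occurrence to centre fragments on."""

    ref: str
    centre: float
    motif_len: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class VMatrix:
    """2-D fragment counts over (midpoint offset bin, length bin)."""

    counts: np.ndarray  # shape (n_offset_bins, n_length_bins)
    offset_edges: np.ndarray
    length_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format table: offset (bin left edge), length, count."""
        io, il = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "offset": self.offset_edges[io],
                "length": self.length_edges[il],
                "count": self.counts[io, il].astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, **imshow_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(
            self.counts.T,
            origin="lower",
            aspect="auto",
            extent=(self.offset_edges[0], self.offset_edges[-1],
                    self.length_edges[0], self.length_edges[-1]),
            **imshow_kw,
        )
        ax.set_xlabel("fragment midpoint offset from motif (bp)")
        ax.set_ylabel("fragment length (bp)")
        return ax


def vmatrix(
    fragments,
    anchors,
    offset_range: float = 500.0,
    length_range: tuple[float, float] = (0.0, 400.0),
    bin_bp: int = 1,
) -> VMatrix:
    """Accumulate fragments into a V-plot matrix around motif anchors.

    Every (fragment, same-reference anchor) pair with
    |midpoint - centre| <= offset_range contributes one count at
    (midpoint - centre, fragment length); the offset sign is flipped for
    minus-strand anchors. Bins are half-open [x, x + bin_bp).
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchors must be non-empty")
    by_ref: dict[str, list[MotifAnchor]] = {}
    for a in anchors:
        by_ref.setdefault(a.ref, []).append(a)

    offsets, lengths = [], []
    for f in fragments:
        for a in by_ref.get(f.ref, ()):
            off = f.midpoint - a.centre
            if a.strand == "-":
                off = -off
            if abs(off) <= offset_range:
                offsets.append(off)
                lengths.append(f.length)

    o_edges = np.arange(-offset_range, offset_range + bin_bp, bin_bp, dtype=float)
    l_edges = np.arange(length_range[0], length_range[1] + bin_bp, bin_bp, dtype=float)
    if not offsets:
        warnings.warn("no (fragment, anchor) pairs in range; empty V matrix", stacklevel=2)
        counts = np.zeros((len(o_edges) - 1, len(l_edges) - 1), int)
        return VMatrix(counts, o_edges, l_edges)

    # half-open binning [x, x+bin): clip the last edge out of np.histogram2d's
    # closed-right convention by nudging values exactly on the last edge out.
    counts, _, _ = np.histogram2d(
        np.asarray(offsets), np.asarray(lengths), bins=[o_edges, l_edges]
    )
    # np.histogram2d closes the final bin on the right; drop such values to
    # keep every bin half-open
    sel = (np.asarray(offsets) == o_edges[-1]) | (np.asarray(lengths) == l_edges[-1])
    if sel.any():
        drop, _, _ = np.histogram2d(
            np.asarray(offsets)[sel], np.asarray(lengths)[sel], bins=[o_edges, l_edges]
        )
        counts -= drop
    return VMatrix(counts.astype(int), o_edges, l_edges)


def inside_v(offset: float, length: float, motif_len: int) -> bool:
    """True iff a fragment of this length/offset fully contains the motif.

    A fragment contains the motif exactly when |offset| <= (length - motif_len)/2;
    fragments shorter than the motif can never contain it.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if motif_len > length:
        return False
    return abs(offset) <= (length - motif_len) / 2.0


def cutsite_profile(
    condition_a: list[np.ndarray],
    condition_b: list[np.ndarray],
    ref_len: int,
    depth: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bp DNaseI cut-site counts and between-condition difference.

    Each replicate (an array of 0-based read start positions = cut sites) is
    downsampled without replacement to exactly ``depth`` cuts (seeded,
    per-replicate substreams), binned at 1 bp over [0, ref_len), and the
    difference profile mean(A) - mean(B) reported.

    Returns a DataFrame with columns position, a_rep_i..., b_rep_j...,
    mean_a, mean_b, difference.
    """
    def _prep(reps: list[np.ndarray], label: str) -> list[np.ndarray]:
        out = []
        for i, starts in enumerate(reps):
            starts = np.asarray(starts, int)
            if starts.size and (starts.min() < 0 or starts.max() >= ref_len):
                raise ValueError(f"{label} replicate {i}: cut sites outside [0, {ref_len})")
            if starts.size < depth:
                raise ValueError(
                    f"{label} replicate {i} has {starts.size} reads, fewer than depth {depth}"
                )
            # keyed by replicate index only: identical conditions downsample
            # identically, so their difference profile is exactly zero
            rng = substream(seed, f"cutsites/rep{i}")
            sub = rng.choice(starts, size=depth, replace=False)
            out.append(np.bincount(sub, minlength=ref_len))
        return out

    a = _prep(condition_a, "A")
    b = _prep(condition_b, "B")
    tab = pd.DataFrame({"position": np.arange(ref_len)})
    for i, v in enumerate(a):
        tab[f"a_rep_{i}"] = v
    for i, v in enumerate(b):
        tab[f"b_rep_{i}"] = v
    tab["mean_a"] = np.mean(a, axis=0)
    tab["mean_b"] = np.mean(b, axis=0)
    tab["difference"] = tab["mean_a"] - tab["mean_b"]
    return tab


# ---------------------------------------------------------------------------
# I/O

def read_fragments_bed(path) -> list[Fragment]:
    """Read BED3 (ref, start, end) fragments."""
    tab = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                      names=["ref", "start", "end"], comment="#")
    return [Fragment(str(r.ref), int(r.start), int(r.end)) for r in tab.itertuples()]


def read_fragments_sam(path) -> list[Fragment]:
    """Extract paired-end fragment spans from a SAM/BAM file.

    Uses TLEN semantics: one fragment per properly mapped read-1 with
    positive template length; secondary/supplementary/unmapped records are
    skipped.
    """
    import pysam

    frags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired and (not rec.is_read1 or rec.template_length <= 0):
                continue
            start = rec.reference_start
            length = rec.template_length if rec.is_paired else rec.query_alignment_length
            if length > 0:
                frags.append(Fragment(rec.reference_name, start, start + length))
    return frags


def read_anchors(path) -> list[MotifAnchor]:
    """Read an anchor table (TSV: ref, centre, motif_len, strand)."""
    tab = pd.read_csv(path, sep="\t")
    return [
        MotifAnchor(str(r.ref), float(r.centre), int(r.motif_len), str(r.strand))
        for r in tab.itertuples()
    ]
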